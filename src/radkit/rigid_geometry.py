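"""Rigid-body superposition and rotation algebra.

This is the geometric engine of the package: weighted least-squares
superposition (Kabsch, with a reflection guard), axis–angle extraction, and
the screw-axis decomposition of a general rigid transform.  Angles cross the
module boundary in degrees (the field's convention for reporting subunit
rotation); radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "superpose",
    "axis_angle",
    "rotation_about_axis",
    "screw_axis",
    "ScrewAxis",
    "DegenerateRotationError",
    "ORTHONORMALITY_TOL",
    "DEGENERATE_ANGLE_DEG",
]

#: tolerance on R Rᵀ = I and det R = 1
ORTHONORMALITY_TOL = 1e-9
#: below this rotation angle the rotation axis is considered undefined
DEGENERATE_ANGLE_DEG = 0.25


class DegenerateRotationError(ValueError):
    """Raised when an operation needs a well-defined rotation axis but the
    rotation angle is below the degeneracy cutoff."""


def _check_rotation(matrix: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {matrix.shape}")
    if not np.allclose(matrix @ matrix.T, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(matrix) < 0:
        raise ValueError("improper rotation (determinant -1)")
    return matrix


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation, x ↦ R x + t (Å).

    Composition and inversion are closed; ``apply`` maps an (N, 3) array of
    coordinates.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        center: np.ndarray | None = None,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis`` through ``center``,
        followed by an optional extra translation."""
        rot = rotation_about_axis(axis, angle_deg)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - rot @ c
        return cls(rot, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def angle_deg(self) -> float:
        """Net rotation angle (Euler–Rodrigues angle) in degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix: right-handed rotation by ``angle_deg``
    about the (normalised) ``axis``."""
    a = np.asarray(axis, dtype=float).reshape(3)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("zero rotation axis")
    a = a / norm
    th = np.radians(angle_deg)
    k = np.array(
        [[0.0, -a[2], a[1]], [a[2], 0.0, -a[0]], [-a[1], a[0], 0.0]]
    )
    return np.eye(3) + np.sin(th) * k + (1.0 - np.cos(th)) * (k @ k)


def superpose(
    ref_points: np.ndarray,
    model_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``model_points`` onto ``ref_points``.

    Returns the proper rigid transform ``T`` minimising the (weighted)
    least-squares deviation ``|T(model) - ref|`` together with the minimised
    RMSD (Å).  A reflection guard flips the smallest singular direction when
    the raw Kabsch solution is improper, so the result is always a rotation.

    Parameters
    ----------
    ref_points, model_points : (N, 3) arrays, N ≥ 3, not collinear.
    weights : optional (N,) non-negative weights.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(model_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    ref_c = (w @ ref) / wsum
    mov_c = (w @ mov) / wsum
    x = mov - mov_c
    y = ref - ref_c
    cov = (x * w[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    # collinear/degenerate geometry leaves the in-plane orientation free
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ref_c - rot @ mov_c
    transform = RigidTransform(rot, t)
    dev = transform.apply(mov) - ref
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", dev, dev)).sum() / wsum))
    return transform, rmsd


def axis_angle(
    transform: RigidTransform, degenerate_tol_deg: float = DEGENERATE_ANGLE_DEG
) -> tuple[np.ndarray | None, float]:
    """Axis and angle of a rigid transform's rotation part.

    The angle is ``arccos((trace - 1)/2)`` in [0°, 180°]; the axis follows
    the right-hand convention (rotation by +angle about the returned axis).
    For angles below ``degenerate_tol_deg`` the axis is undefined and
    ``None`` is returned in its place.
    """
    rot = transform.rotation
    angle = transform.angle_deg()
    if angle < max(degenerate_tol_deg, 1e-12):
        return None, angle
    if angle > 180.0 - 1e-6:
        # near-π: axis from the symmetric part, R = 2 a aᵀ - I
        m = (rot + np.eye(3)) / 2.0
        i = int(np.argmax(np.diag(m)))
        a = m[:, i] / np.sqrt(m[i, i])
        # fix sign from the skew part where it is non-zero, else arbitrary
        skew = np.array(
            [rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]]
        )
        if np.linalg.norm(skew) > 1e-12 and np.dot(skew, a) < 0:
            a = -a
        return a / np.linalg.norm(a), angle
    skew = np.array(
        [rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]]
    )
    axis = skew / (2.0 * np.sin(np.radians(angle)))
    return axis / np.linalg.norm(axis), angle


@dataclass(frozen=True)
class ScrewAxis:
    """The screw decomposition of a rigid transform: the line of points with
    minimal displacement, the rotation about it and the slide along it."""

    direction: np.ndarray  # unit vector
    point: np.ndarray      # point on the axis (closest to the anchor)
    angle_deg: float
    slide: float           # displacement component along the axis, Å


def screw_axis(
    transform: RigidTransform,
    anchor: np.ndarray | None = None,
    degenerate_tol_deg: float = DEGENERATE_ANGLE_DEG,
) -> ScrewAxis:
    """Screw-axis decomposition of a rigid transform.

    Every rigid motion with rotation angle above the degeneracy cutoff is a
    rotation about a unique line plus a slide along it; points on that line
    move the least.  ``point`` is the axis point closest to ``anchor``
    (default: origin).

    Raises
    ------
    DegenerateRotationError
        if the rotation angle is below ``degenerate_tol_deg`` (the caller
        is expected to fall back to a pure-translation description).
    """
    axis, angle = axis_angle(transform, degenerate_tol_deg)
    if axis is None:
        raise DegenerateRotationError(
            f"rotation angle {angle:.4g}° below {degenerate_tol_deg}°"
        )
    t = transform.translation
    slide = float(np.dot(t, axis))
    t_perp = t - slide * axis
    # solve (I - R) c = t_perp in the plane perpendicular to the axis:
    # c = ½ (t_perp + (axis × t_perp) / tan(θ/2))
    half = np.radians(angle) / 2.0
    c = 0.5 * (t_perp + np.cross(axis, t_perp) / np.tan(half))
    if anchor is None:
        anchor = np.zeros(3)
    anchor = np.asarray(anchor, dtype=float)
    point = c + np.dot(anchor - c, axis) * axis
    return ScrewAxis(direction=axis, point=point, angle_deg=angle, slide=slide)
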