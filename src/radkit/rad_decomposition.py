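"""Angle decomposition of domain orientations and pairwise comparisons.

A domain's net rigid transform (relative to the classical reference, in the
frame-of-reference core's coordinates) is split into

* ϕ — primary rotation about the fixed reference axis R̂_ref,
* θ — tilt: the angle between the current axis R̂ = R·R̂_ref and R̂_ref,
* ψ — tilt direction: azimuth of the tilt axis (line of nodes) measured from
  the frame's zero direction, right-handed about R̂_ref,
* x_c — the point on the reference axis minimising the residual translation,
* Δx — that minimal residual translation.

The convention is rotation = tilt ∘ primary, i.e. R = Rot(T̂, θ)·Rot(R̂_ref, ϕ):
the tilt is a second rotation applied after rotating about the reference
axis, so it re-orients the (body- or head-fixed) rotation axis itself.  With
the alternative order ψ would measure the tilt azimuth in the rotated frame
instead; this choice is fixed throughout the package.

Pairwise metrics: the Euler–Rodrigues angle (net 1D rotation difference
between two orientations) and δθ (angle between two structures' current
rotation axes — a tilt difference independent of the primary rotation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_identification import CoreMap
from .reference_frames import ReferenceFrame
from .rigid_geometry import (
    DEGENERATE_ANGLE_DEG,
    RigidTransform,
    axis_angle,
    rotation_about_axis,
    superpose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RADAngles",
    "OrientationComparison",
    "net_domain_transform",
    "decompose",
    "reconstruct",
    "er_angle",
    "delta_theta",
    "nearest_neighbors",
]


@dataclass(frozen=True)
class RADAngles:
    """The decomposed orientation of one domain of one structure.

    ``psi_deg`` is ``None`` (undefined) when θ is below the degeneracy
    tolerance; ϕ then falls back to the signed rotation angle about
    R̂_ref.  ``rotated_axis`` is the current orientation R̂ of the reference
    axis under the domain rotation.
    """

    domain: str                  # body | head
    phi_deg: float               # signed primary rotation
    theta_deg: float             # tilt, ≥ 0
    psi_deg: float | None        # tilt direction in (-180, 180], or None
    x_c: np.ndarray              # center of rotation on the reference axis, Å
    delta_x: np.ndarray          # residual translation, Å
    rotated_axis: np.ndarray     # unit R̂
    accession: str | None = None

    @property
    def delta_x_norm(self) -> float:
        return float(np.linalg.norm(self.delta_x))

    def as_record(self) -> dict:
        return {
            "accession": self.accession,
            "domain": self.domain,
            "phi_deg": self.phi_deg,
            "theta_deg": self.theta_deg,
            "psi_deg": np.nan if self.psi_deg is None else self.psi_deg,
            "delta_x_A": self.delta_x_norm,
        }


@dataclass(frozen=True)
class OrientationComparison:
    structure_a: str
    structure_b: str
    domain: str
    er_angle_deg: float
    delta_theta_deg: float


def net_domain_transform(
    cores: dict[str, CoreMap], frame: ReferenceFrame
) -> RigidTransform:
    """Net rigid transform of a domain relative to the classical reference.

    The model is first placed into the reference coordinate frame by
    superposing its frame-of-reference core (LSU core for body angles, SSU
    body core for head angles) onto the reference's; in that common frame
    the returned transform maps the reference domain core onto the model
    domain core.  For the classical reference itself this is the identity.

    ``cores`` maps domain names to :class:`CoreMap` objects of the model
    against the reference (as produced by
    :func:`~radkit.core_identification.domain_cores`).
    """
    if frame.domain == "body":
        frame_key, domain_key = "LSU", "SSU_body"
    elif frame.domain == "head":
        frame_key, domain_key = "SSU_body", "SSU_head"
    else:
        raise ValueError(f"unknown frame domain {frame.domain!r}")
    if frame_key not in cores:
        raise ValueError(
            f"{frame.domain} angles need the {frame_key} core as frame of "
            f"reference, which is missing (isolated subunit?)"
        )
    if domain_key not in cores:
        raise ValueError(f"missing {domain_key} core")
    frame_core, domain_core = cores[frame_key], cores[domain_key]
    to_reference, _ = superpose(
        frame_core.ref_core_coords, frame_core.model_core_coords
    )
    model_in_ref = to_reference.apply(domain_core.model_core_coords)
    transform, _ = superpose(model_in_ref, domain_core.ref_core_coords)
    return transform


def _signed_angle_about(
    v_from: np.ndarray, v_to: np.ndarray, axis: np.ndarray
) -> float:
    """Signed angle (degrees) from v_from to v_to, right-handed about axis."""
    s = float(np.dot(np.cross(v_from, v_to), axis))
    c = float(np.dot(v_from, v_to))
    return float(np.degrees(np.arctan2(s, c)))


def decompose(
    transform: RigidTransform,
    frame: ReferenceFrame,
    domain: str | None = None,
    theta_tolerance_deg: float = DEGENERATE_ANGLE_DEG,
    accession: str | None = None,
) -> RADAngles:
    """Decompose a net domain transform into (ϕ, θ, ψ, x_c, Δx).

    The rotation part factors exactly as R = Rot(T̂, θ)·Rot(R̂_ref, ϕ) with
    T̂ ⊥ R̂_ref (the line of nodes), so the reconstruction is exact up to
    numerics.  x_c is the point on the reference axis line minimising the
    residual displacement |(R − I)x + t| (closed-form 1D least squares) and
    Δx is that residual.  Degeneracies (θ or ϕ near zero) are flagged, not
    fatal: for θ below tolerance ψ is undefined and ϕ is the signed
    axis-angle about R̂_ref.

    In the degenerate branch the x_c minimisation uses the projected pure
    rotation Rot(R̂_ref, ϕ) rather than the raw rotation: against a spurious
    sub-tolerance tilt the unconstrained 1D minimiser slides x_c arbitrarily
    far along the axis and silently absorbs genuine perpendicular
    translation, so |Δx| would be ill-defined exactly where θ ≈ 0.
    """
    rot = transform.rotation
    t = transform.translation
    r_ref = frame.axis_direction
    r_cur = rot @ r_ref
    theta = float(np.degrees(np.arccos(np.clip(np.dot(r_cur, r_ref), -1.0, 1.0))))

    if theta >= theta_tolerance_deg:
        nodes = np.cross(r_ref, r_cur)
        nodes = nodes / np.linalg.norm(nodes)
        psi = _signed_angle_about(frame.zero_tilt_direction, nodes, r_ref)
        tilt = rotation_about_axis(nodes, theta)
        residual = RigidTransform(tilt.T @ rot)
        axis, phi_mag = axis_angle(residual, degenerate_tol_deg=0.0)
        if axis is None or phi_mag < 1e-12:
            phi = 0.0
        else:
            phi = float(np.sign(np.dot(axis, r_ref)) * phi_mag)
    else:
        psi = None
        axis, phi_mag = axis_angle(RigidTransform(rot), degenerate_tol_deg=0.0)
        if axis is None or phi_mag < 1e-12:
            phi = 0.0
        else:
            phi = float(np.sign(np.dot(axis, r_ref)) * phi_mag)

    # x_c: minimise |A(p + s r̂) + t|² over s, with A = R - I
    # (degenerate tilt: R projected onto a pure rotation about the axis)
    a_rot = rot if psi is not None else rotation_about_axis(r_ref, phi) if phi else np.eye(3)
    a_mat = a_rot - np.eye(3)
    a_axis = a_mat @ r_ref
    base = a_mat @ frame.axis_point + t
    denom = float(np.dot(a_axis, a_axis))
    s = -float(np.dot(a_axis, base)) / denom if denom > 1e-18 else 0.0
    x_c = frame.axis_point + s * r_ref
    delta_x = a_mat @ x_c + t

    return RADAngles(
        domain=domain or frame.domain,
        phi_deg=phi,
        theta_deg=theta,
        psi_deg=psi,
        x_c=x_c,
        delta_x=delta_x,
        rotated_axis=r_cur,
        accession=accession,
    )


def reconstruct(
    angles: RADAngles, frame: ReferenceFrame
) -> RigidTransform:
    """Rebuild the rigid transform from decomposed angles (inverse of
    :func:`decompose`): R = Rot(T̂(ψ), θ)·Rot(R̂_ref, ϕ) applied about x_c,
    plus the residual translation Δx."""
    r_ref = frame.axis_direction
    rot = rotation_about_axis(r_ref, angles.phi_deg)
    if angles.theta_deg > 0 and angles.psi_deg is not None:
        nodes = rotation_about_axis(r_ref, angles.psi_deg) @ frame.zero_tilt_direction
        rot = rotation_about_axis(nodes, angles.theta_deg) @ rot
    t = angles.x_c - rot @ angles.x_c + angles.delta_x
    return RigidTransform(rot, t)


def er_angle(a: RigidTransform, b: RigidTransform) -> float:
    """Euler–Rodrigues angle between two orientations (degrees).

    The single net rotation relating the two rotation parts:
    arccos((trace(R_a R_bᵀ) − 1)/2).  Symmetric; zero iff the rotations are
    equal.  It mixes rotation and tilt into one 1D measure.
    """
    cos = (np.trace(a.rotation @ b.rotation.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def delta_theta(a: RigidTransform, b: RigidTransform, frame: ReferenceFrame) -> float:
    """Tilt difference between two structures (degrees): the angle between
    their current primary rotation axes R̂ = R·R̂_ref.

    Independent of the primary rotation, because rotating about the
    (domain-fixed) axis leaves the axis itself in place.  When the tilt
    directions coincide it reduces to the difference of the tilt values;
    when they are antiparallel, to their sum.
    """
    ra = a.rotation @ frame.axis_direction
    rb = b.rotation @ frame.axis_direction
    return float(np.degrees(np.arccos(np.clip(np.dot(ra, rb), -1.0, 1.0))))


def nearest_neighbors(
    ensemble: list[tuple[str, RigidTransform | float]],
    metric: str = "er_angle",
) -> list[dict]:
    """Per-structure nearest neighbour under an orientation metric.

    ``metric="er_angle"``: entries carry transforms; each structure's
    neighbour minimises the pairwise E–R angle.  ``metric="phi-gap"``:
    entries carry ϕ values (degrees); structures are ordered by ϕ and the
    gaps between sequential structures are reported (each structure paired
    with its closer sequential neighbour).
    """
    if len(ensemble) < 2:
        raise ValueError("need at least two structures")
    out: list[dict] = []
    if metric == "er_angle":
        names = [name for name, _ in ensemble]
        transforms = [tr for _, tr in ensemble]
        n = len(names)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = er_angle(transforms[i], transforms[j])
                dist[i, j] = dist[j, i] = d
        np.fill_diagonal(dist, np.inf)
        for i in range(n):
            j = int(np.argmin(dist[i]))
            out.append(
                {"accession": names[i], "neighbor": names[j],
                 "distance_deg": float(dist[i, j])}
            )
    elif metric == "phi-gap":
        ordered = sorted(ensemble, key=lambda item: item[1])
        for k, (name, phi) in enumerate(ordered):
            candidates = []
            if k > 0:
                candidates.append((ordered[k - 1][0], phi - ordered[k - 1][1]))
            if k < len(ordered) - 1:
                candidates.append((ordered[k + 1][0], ordered[k + 1][1] - phi))
            neighbor, gap = min(candidates, key=lambda c: c[1])
            out.append(
                {"accession": name, "neighbor": neighbor,
                 "distance_deg": float(gap)}
            )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return out
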