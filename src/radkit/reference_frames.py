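"""Reference rotation axes and zero-tilt directions.

The coordinate system of the decomposition is pinned by three reference
structures: a classical (unrotated/untilted) ribosome, a body-rotated one
and a head-rotated one.  Superposing each rotated structure onto the
classical one (on the frame-of-reference core: LSU for the body, SSU body
for the head) yields a reference rotation whose screw axis defines the fixed
rotation axis R̂_ref of that domain; its positive sense is the
classical → rotated direction (ratchet for the body, swivel toward the E
site for the head).  The ψ = 0 tilt direction is anchored geometrically: for
the body, the in-plane direction toward helix h44 of the 16S rRNA; for the
head, the in-plane component of the E-site → A-site codon-region vector
(roughly the mRNA binding track).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import data as _data
from .core_identification import AlignParams, CoreMap, PruneParams, domain_cores
from .rigid_geometry import RigidTransform, screw_axis, superpose
from .structure_io import RibosomeStructure

__all__ = [
    "ReferenceFrame",
    "DegenerateReferenceError",
    "build_body_frame",
    "build_head_frame",
    "save_frames",
    "load_frames",
]

#: the classical → rotated reference rotation must exceed this angle
MIN_REFERENCE_ANGLE_DEG = 1.0


class DegenerateReferenceError(ValueError):
    """The reference pair differs by less than the minimum rotation angle."""


@dataclass(frozen=True)
class ReferenceFrame:
    """A domain's fixed rotation axis and ψ = 0 direction.

    All vectors live in the classical reference structure's coordinate
    frame.  ``frame_of`` names the core whose superposition places a model
    into this frame (LSU core for the body, SSU body core for the head).
    """

    domain: str                     # body | head
    axis_direction: np.ndarray      # unit R̂_ref
    axis_point: np.ndarray          # a point on the reference axis, Å
    zero_tilt_direction: np.ndarray  # unit, perpendicular to axis_direction
    frame_of: str                   # LSU_core | SSU_body_core
    reference_angle_deg: float      # classical → rotated rotation magnitude
    provenance: dict | None = None

    def __post_init__(self) -> None:
        for name in ("axis_direction", "axis_point", "zero_tilt_direction"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        if abs(np.linalg.norm(self.axis_direction) - 1.0) > 1e-9:
            raise ValueError("axis_direction must be a unit vector")
        if abs(np.linalg.norm(self.zero_tilt_direction) - 1.0) > 1e-9:
            raise ValueError("zero_tilt_direction must be a unit vector")
        if abs(float(np.dot(self.axis_direction, self.zero_tilt_direction))) > 1e-9:
            raise ValueError("zero_tilt_direction must be perpendicular to the axis")


def _reference_rotation(
    frame_core: CoreMap, domain_core: CoreMap
) -> tuple[RigidTransform, np.ndarray]:
    """Classical → rotated transform of a domain, in the classical frame.

    ``frame_core``/``domain_core`` are cores of the *rotated* structure
    matched against the classical one (model = rotated, ref = classical).
    The rotated structure is first placed into the classical frame by
    superposing the frame-of-reference core; the returned transform then
    maps the classical domain core onto the so-placed rotated domain core.
    Also returns the classical domain core centroid (the screw anchor).
    """
    to_classical, _ = superpose(
        frame_core.ref_core_coords, frame_core.model_core_coords
    )
    rotated_in_frame = to_classical.apply(domain_core.model_core_coords)
    classical_coords = domain_core.ref_core_coords
    transform, _ = superpose(rotated_in_frame, classical_coords)
    return transform, classical_coords.mean(axis=0)


def _perpendicular_unit(vector: np.ndarray, axis: np.ndarray) -> np.ndarray:
    perp = vector - np.dot(vector, axis) * axis
    norm = np.linalg.norm(perp)
    if norm < 1e-9:
        raise ValueError("zero-tilt anchor vector is parallel to the rotation axis")
    return perp / norm


def _anchor_centroid(structure: RibosomeStructure, numbers: frozenset[int]) -> np.ndarray:
    """Centroid of P atoms of SSU residues with the given reference numbers
    in the classical structure (which carries reference numbering)."""
    coords = []
    for res in structure.ssu_chain.residues:
        if res.number in numbers:
            p = res.atom("P")
            if p is not None:
                coords.append(p.coords)
    if not coords:
        raise ValueError("no anchor residues found in the classical SSU chain")
    return np.asarray(coords).mean(axis=0)


def _build_frame(
    classical: RibosomeStructure,
    rotated: RibosomeStructure,
    domain: str,
    align_params: AlignParams,
    prune_params: PruneParams,
) -> ReferenceFrame:
    if domain == "body":
        frame_domain, moving_domain, frame_of = "LSU", "SSU_body", "LSU_core"
    else:
        frame_domain, moving_domain, frame_of = "SSU_body", "SSU_head", "SSU_body_core"
    cores = domain_cores(
        rotated, classical, domains=(frame_domain, moving_domain),
        align_params=align_params, prune_params=prune_params,
    )
    transform, anchor = _reference_rotation(cores[frame_domain], cores[moving_domain])
    angle = transform.angle_deg()
    if angle < MIN_REFERENCE_ANGLE_DEG:
        raise DegenerateReferenceError(
            f"reference {domain} rotation is only {angle:.3f}° "
            f"(< {MIN_REFERENCE_ANGLE_DEG}°); the reference pair is degenerate"
        )
    screw = screw_axis(transform, anchor=anchor)

    anchors = _data.load_anchors()
    if domain == "body":
        target = _anchor_centroid(classical, anchors["h44"])
        zero_tilt = _perpendicular_unit(target - screw.point, screw.direction)
    else:
        a_site = _anchor_centroid(classical, anchors["a_site"])
        e_site = _anchor_centroid(classical, anchors["e_site"])
        zero_tilt = _perpendicular_unit(a_site - e_site, screw.direction)

    return ReferenceFrame(
        domain=domain,
        axis_direction=screw.direction,
        axis_point=screw.point,
        zero_tilt_direction=zero_tilt,
        frame_of=frame_of,
        reference_angle_deg=angle,
        provenance={
            "classical": classical.accession,
            "rotated": rotated.accession,
            "n_core_frame": cores[frame_domain].n_core,
            "n_core_domain": cores[moving_domain].n_core,
        },
    )


def build_body_frame(
    classical: RibosomeStructure,
    body_rotated: RibosomeStructure,
    align_params: AlignParams = AlignParams(),
    prune_params: PruneParams = PruneParams(),
) -> ReferenceFrame:
    """Body rotation axis and ψ = 0 direction from the classical and
    body-rotated reference structures (frame of reference: LSU core).

    The classical → rotated rotation about the returned axis is positive by
    construction; ψ = 0 points from the axis toward the h44 helix centroid,
    projected into the plane perpendicular to the axis (the helix itself is
    not perpendicular to the axis, so projection is mandatory).
    """
    return _build_frame(classical, body_rotated, "body", align_params, prune_params)


def build_head_frame(
    classical: RibosomeStructure,
    head_rotated: RibosomeStructure,
    align_params: AlignParams = AlignParams(),
    prune_params: PruneParams = PruneParams(),
) -> ReferenceFrame:
    """Head rotation axis and ψ = 0 direction from the classical and
    head-rotated reference structures (frame of reference: SSU body core).

    ψ_head = 0 tilts the head about the mRNA binding track: the zero
    direction is the in-plane component of the E-site → A-site codon-region
    vector in the classical structure.
    """
    return _build_frame(classical, head_rotated, "head", align_params, prune_params)


def save_frames(
    frames: dict[str, ReferenceFrame], path: str | Path, package_version: str | None = None
) -> None:
    """Write a body/head frame pair to a small JSON file (exact round-trip)."""
    if package_version is None:
        from . import __version__ as package_version
    payload = {"format": "radkit-frames-1", "package_version": package_version}
    for name, frame in frames.items():
        payload[name] = {
            "domain": frame.domain,
            "axis_direction": frame.axis_direction.tolist(),
            "axis_point": frame.axis_point.tolist(),
            "zero_tilt_direction": frame.zero_tilt_direction.tolist(),
            "frame_of": frame.frame_of,
            "reference_angle_deg": frame.reference_angle_deg,
            "provenance": frame.provenance,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_frames(path: str | Path) -> dict[str, ReferenceFrame]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "radkit-frames-1":
        raise ValueError(f"{path}: not a frames file")
    frames = {}
    for name, raw in payload.items():
        if not isinstance(raw, dict) or "axis_direction" not in raw:
            continue
        frames[name] = ReferenceFrame(
            domain=raw["domain"],
            axis_direction=np.array(raw["axis_direction"]),
            axis_point=np.array(raw["axis_point"]),
            zero_tilt_direction=np.array(raw["zero_tilt_direction"]),
            frame_of=raw["frame_of"],
            reference_angle_deg=raw["reference_angle_deg"],
            provenance=raw.get("provenance"),
        )
    return frames
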