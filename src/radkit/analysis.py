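"""End-to-end orientation analysis of a structure against the reference.

Bundles the classical reference structure with the body/head frames and
drives: core identification (alignment + partition + pruning) → net domain
transforms → angle decomposition, for the body, the head, or both.  Isolated
SSUs get head angles only (the body frame needs an LSU); isolated LSUs carry
no decomposable domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .core_identification import AlignParams, CoreMap, PruneParams, domain_cores
from .rad_decomposition import RADAngles, decompose, net_domain_transform
from .reference_frames import ReferenceFrame, build_body_frame, build_head_frame
from .rigid_geometry import RigidTransform
from .structure_io import RibosomeStructure

logger = logging.getLogger(__name__)

__all__ = ["ReferenceSet", "StructureResult", "analyze_structure", "synthetic_reference_set"]


@dataclass
class ReferenceSet:
    """The classical reference structure plus the body/head frames."""

    classical: RibosomeStructure
    frames: dict[str, ReferenceFrame]
    align_params: AlignParams = field(default_factory=AlignParams)
    prune_params: PruneParams = field(default_factory=PruneParams)

    @classmethod
    def from_structures(
        cls,
        classical: RibosomeStructure,
        body_rotated: RibosomeStructure,
        head_rotated: RibosomeStructure,
        align_params: AlignParams = AlignParams(),
        prune_params: PruneParams = PruneParams(),
    ) -> "ReferenceSet":
        frames = {
            "body": build_body_frame(classical, body_rotated, align_params, prune_params),
            "head": build_head_frame(classical, head_rotated, align_params, prune_params),
        }
        return cls(classical, frames, align_params, prune_params)


@dataclass
class StructureResult:
    """Per-structure analysis output: angles, transforms and core stats."""

    accession: str
    angles: dict[str, RADAngles]
    transforms: dict[str, RigidTransform]
    cores: dict[str, CoreMap]

    def records(self) -> list[dict]:
        out = []
        for domain, ang in self.angles.items():
            rec = ang.as_record()
            core_key = "SSU_body" if domain == "body" else "SSU_head"
            core = self.cores.get(core_key)
            if core is not None:
                rec["n_core"] = core.n_core
                rec["core_rmsd_A"] = core.core_rmsd
            out.append(rec)
        return out


def analyze_structure(
    model: RibosomeStructure,
    reference: ReferenceSet,
    domains: str = "both",
) -> StructureResult:
    """Compute the angle decomposition of a model's SSU body and/or head.

    ``domains`` is ``"body"``, ``"head"`` or ``"both"``.  An isolated SSU
    (no LSU chain) yields head angles only; requesting body angles for one
    raises.
    """
    wanted = {"body", "head"} if domains == "both" else {domains}
    if "body" in wanted and model.lsu_chain is None:
        if domains == "both" and model.ssu_chain is not None:
            logger.info(
                "%s: isolated SSU, computing head angles only", model.accession
            )
            wanted = {"head"}
        else:
            raise ValueError(
                f"{model.accession}: body angles need an LSU chain (isolated SSU?)"
            )
    needed: set[str] = set()
    if "body" in wanted:
        needed.update({"LSU", "SSU_body"})
    if "head" in wanted:
        needed.update({"SSU_body", "SSU_head"})
    cores = domain_cores(
        model, reference.classical, domains=tuple(sorted(needed)),
        align_params=reference.align_params, prune_params=reference.prune_params,
    )
    angles: dict[str, RADAngles] = {}
    transforms: dict[str, RigidTransform] = {}
    for domain in sorted(wanted):
        frame = reference.frames[domain]
        transform = net_domain_transform(cores, frame)
        transforms[domain] = transform
        angles[domain] = decompose(transform, frame, accession=model.accession)
    return StructureResult(
        accession=model.accession, angles=angles, transforms=transforms, cores=cores
    )


def synthetic_reference_set(seed: int = 20220) -> ReferenceSet:
    """The packaged synthetic reference set.

    A deterministic stand-in for the three crystallographic reference
    models, generated from a fixed seed by
    :mod:`radkit.synthetic_fixtures`; frames rebuilt from it are
    bit-identical across runs.
    """
    from .synthetic_fixtures import FixtureSpec, generate_reference_fixture

    fixture = generate_reference_fixture(FixtureSpec(seed=seed))
    return ReferenceSet.from_structures(
        fixture.classical, fixture.body_rotated, fixture.head_rotated
    )
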