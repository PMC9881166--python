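"""Residue correspondence to the reference and structurally conserved cores.

The decomposition only makes sense on residues that occupy equivalent
positions in every ribosome, so each model rRNA is first mapped onto the
*E. coli* reference numbering by global sequence alignment
(Needleman–Wunsch), the SSU map is partitioned into head and body using the
packaged head-residue set, and each matched set is then pruned — iterated
least-squares superposition, discarding the worst-deviating residues — until
the spatial RMSD of what remains reaches ~1 Å.  The surviving residues are
the domain's "core" and everything downstream is computed on core P atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from . import data as _data
from .rigid_geometry import RigidTransform, superpose
from .structure_io import ChainModel

logger = logging.getLogger(__name__)

__all__ = [
    "AlignParams",
    "PruneParams",
    "ResidueCorrespondence",
    "CoreMap",
    "AlignmentFailedError",
    "PartitionError",
    "align_to_reference",
    "partition_head_body",
    "prune_core",
    "correspond_chains",
    "domain_cores",
]


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring (Needleman–Wunsch)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    #: floor on the alignment score as a fraction of the maximum attainable
    #: score (match score x shorter sequence length); unrelated sequences
    #: score near zero under these penalties while homologous rRNAs score
    #: well above it
    min_score_fraction: float = 0.20


@dataclass(frozen=True)
class PruneParams:
    """Iterative core-pruning schedule.

    Each iteration superposes the current core and removes residues whose
    deviation exceeds ``deviation_factor`` × current RMSD; when none qualify
    but the RMSD is still above target, the worst ``worst_fraction`` are
    removed instead.  Matched pairs deviating more than ``initial_cutoff``
    after the first superposition are dropped before the loop (spatial
    consistency filter).
    """

    target_rmsd: float = 1.0          # Å
    deviation_factor: float = 2.0
    worst_fraction: float = 0.05
    initial_cutoff: float = 8.0       # Å
    min_core: int = 100               # use 50 for the (smaller) head
    max_iterations: int = 200


class AlignmentFailedError(ValueError):
    """Sequence alignment matched too small a fraction to be trusted."""


class PartitionError(ValueError):
    """Head/body partition left one side below its minimum size."""


@dataclass(frozen=True)
class ResidueCorrespondence:
    """One-to-one map between model residues and reference residue numbers.

    ``pairs`` is ordered along the model sequence; reference numbers are
    strictly increasing along it (a property of global alignment).
    """

    pairs: tuple[tuple[str, int], ...]   # (model residue id, ref residue number)
    domain: str                          # LSU | SSU | SSU_body | SSU_head
    identity: float = float("nan")       # identical fraction of matched region

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def ref_numbers(self) -> tuple[int, ...]:
        return tuple(ref for _, ref in self.pairs)

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _ in self.pairs)


@dataclass(frozen=True)
class CoreMap:
    """The pruned, structurally conserved core of one domain.

    ``model_coords``/``ref_coords`` hold P-atom coordinates for every matched
    pair; ``core_idx`` indexes the surviving core subset.  ``transform`` maps
    model core coordinates onto the reference frame.
    """

    correspondence: ResidueCorrespondence
    model_coords: np.ndarray
    ref_coords: np.ndarray
    core_idx: np.ndarray
    core_rmsd: float
    transform: RigidTransform
    n_iterations: int
    converged: bool = True
    rmsd_history: tuple[float, ...] = ()

    @property
    def n_core(self) -> int:
        return int(self.core_idx.size)

    @property
    def model_core_coords(self) -> np.ndarray:
        return self.model_coords[self.core_idx]

    @property
    def ref_core_coords(self) -> np.ndarray:
        return self.ref_coords[self.core_idx]

    @property
    def core_pairs(self) -> tuple[tuple[str, int], ...]:
        pairs = self.correspondence.pairs
        return tuple(pairs[i] for i in self.core_idx)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_to_reference(
    model_seq: str,
    ref_seq: str,
    model_ids: list[str] | None = None,
    ref_numbers: list[int] | None = None,
    domain: str = "LSU",
    params: AlignParams = AlignParams(),
) -> ResidueCorrespondence:
    """Globally align a model rRNA sequence to the reference sequence and
    assign reference residue numbers to the model.

    Gaps leave residues unmatched; the identity of the matched region is
    recorded.  ``model_ids``/``ref_numbers`` give the residue labels for
    each sequence position (defaults: 1-based positions).

    Raises
    ------
    AlignmentFailedError
        when the optimal alignment score falls below
        ``params.min_score_fraction`` of the maximum attainable score.
    """
    if not model_seq or not ref_seq:
        raise ValueError("sequences must be non-empty")
    if model_ids is None:
        model_ids = [str(i + 1) for i in range(len(model_seq))]
    if ref_numbers is None:
        ref_numbers = list(range(1, len(ref_seq) + 1))
    if len(model_ids) != len(model_seq) or len(ref_numbers) != len(ref_seq):
        raise ValueError("id lists must match sequence lengths")

    aligner = _make_aligner(params)
    alignment = aligner.align(ref_seq, model_seq)[0]
    ref_blocks, model_blocks = alignment.aligned
    pairs: list[tuple[str, int]] = []
    n_identical = 0
    for (rs, re), (ms, me) in zip(ref_blocks, model_blocks):
        for r, m in zip(range(rs, re), range(ms, me)):
            pairs.append((model_ids[m], ref_numbers[r]))
            if ref_seq[r] == model_seq[m]:
                n_identical += 1
    shorter = min(len(model_seq), len(ref_seq))
    score_fraction = alignment.score / (params.match * shorter)
    if score_fraction < params.min_score_fraction:
        raise AlignmentFailedError(
            f"alignment failed: score is {score_fraction:.1%} of the maximum "
            f"(floor {params.min_score_fraction:.0%})"
        )
    identity = n_identical / len(pairs) if pairs else 0.0
    return ResidueCorrespondence(tuple(pairs), domain=domain, identity=identity)


def partition_head_body(
    ssu_correspondence: ResidueCorrespondence,
    head_set: frozenset[int] | None = None,
    min_head: int = 50,
    min_body: int = 100,
) -> tuple[ResidueCorrespondence, ResidueCorrespondence]:
    """Split an SSU correspondence into head and body by the packaged head
    residue set (16S numbering).  Every matched residue lands in exactly one
    partition.

    Raises
    ------
    PartitionError
        when either partition falls below its minimum size guard.
    """
    if head_set is None:
        head_set = _data.load_head_set()
    head_pairs = tuple(p for p in ssu_correspondence.pairs if p[1] in head_set)
    body_pairs = tuple(p for p in ssu_correspondence.pairs if p[1] not in head_set)
    if len(head_pairs) < min_head:
        raise PartitionError(
            f"head partition has {len(head_pairs)} residues (< {min_head})"
        )
    if len(body_pairs) < min_body:
        raise PartitionError(
            f"body partition has {len(body_pairs)} residues (< {min_body})"
        )
    head = replace(ssu_correspondence, pairs=head_pairs, domain="SSU_head")
    body = replace(ssu_correspondence, pairs=body_pairs, domain="SSU_body")
    return head, body


def prune_core(
    correspondence: ResidueCorrespondence,
    model_coords: np.ndarray,
    ref_coords: np.ndarray,
    params: PruneParams = PruneParams(),
) -> CoreMap:
    """Prune a matched residue set to its structurally conserved core.

    Iterates: superpose the current core's P atoms (Kabsch); stop when the
    RMSD reaches ``params.target_rmsd``; otherwise remove the
    worst-deviating residues and repeat.  The RMSD is non-increasing across
    iterations.  If the core would shrink below ``params.min_core`` before
    reaching the target, the best core so far is returned with
    ``converged=False`` and a warning.
    """
    model_coords = np.asarray(model_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    n = len(correspondence)
    if model_coords.shape != (n, 3) or ref_coords.shape != (n, 3):
        raise ValueError("coordinate arrays must be (n_pairs, 3)")
    if n < params.min_core:
        raise ValueError(
            f"{n} matched residues is below the minimum core size {params.min_core}"
        )

    idx = np.arange(n)
    transform, rmsd = superpose(ref_coords, model_coords)
    dev = np.linalg.norm(transform.apply(model_coords) - ref_coords, axis=1)
    keep = dev <= params.initial_cutoff
    if keep.sum() >= params.min_core and not keep.all():
        idx = idx[keep]

    n_iter = 0
    converged = False
    history: list[float] = []
    while True:
        transform, rmsd = superpose(ref_coords[idx], model_coords[idx])
        history.append(float(rmsd))
        n_iter += 1
        if rmsd <= params.target_rmsd:
            converged = True
            break
        if n_iter >= params.max_iterations:
            break
        dev = np.linalg.norm(
            transform.apply(model_coords[idx]) - ref_coords[idx], axis=1
        )
        worst = dev > params.deviation_factor * rmsd
        if not worst.any():
            k = max(1, int(np.ceil(params.worst_fraction * idx.size)))
            worst = np.zeros(idx.size, dtype=bool)
            worst[np.argsort(dev)[-k:]] = True
        if idx.size - worst.sum() < params.min_core:
            # remove only as many of the worst as the guard allows
            allowed = idx.size - params.min_core
            if allowed <= 0:
                break
            worst = np.zeros(idx.size, dtype=bool)
            worst[np.argsort(dev)[-allowed:]] = True
            idx = idx[~worst]
            transform, rmsd = superpose(ref_coords[idx], model_coords[idx])
            history.append(float(rmsd))
            n_iter += 1
            converged = rmsd <= params.target_rmsd
            break
        idx = idx[~worst]

    if not converged:
        logger.warning(
            "core pruning for %s stopped at RMSD %.2f Å with %d residues "
            "(target %.2f Å); returning best core so far",
            correspondence.domain, rmsd, idx.size, params.target_rmsd,
        )
    return CoreMap(
        correspondence=correspondence,
        model_coords=model_coords,
        ref_coords=ref_coords,
        core_idx=idx,
        core_rmsd=float(rmsd),
        transform=transform,
        n_iterations=n_iter,
        converged=converged,
        rmsd_history=tuple(history),
    )


def correspond_chains(
    model_chain: ChainModel,
    ref_chain: ChainModel,
    domain: str,
    params: AlignParams = AlignParams(),
) -> tuple[ResidueCorrespondence, np.ndarray, np.ndarray]:
    """Align two rRNA chains and collect paired P-atom coordinates.

    Returns the correspondence restricted to residue pairs where both sides
    carry a P atom, together with the matching model/reference coordinate
    arrays (reference numbering taken from the reference chain's author
    numbers).
    """
    model_ids = [r.residue_id for r in model_chain.residues]
    ref_numbers = [r.number for r in ref_chain.residues]
    corr = align_to_reference(
        model_chain.sequence, ref_chain.sequence,
        model_ids=model_ids, ref_numbers=ref_numbers,
        domain=domain, params=params,
    )
    model_by_id = {r.residue_id: r for r in model_chain.residues}
    ref_by_num = {r.number: r for r in ref_chain.residues}
    pairs, mc, rc = [], [], []
    for mid, ref_num in corr.pairs:
        pm = model_by_id[mid].atom("P")
        pr = ref_by_num[ref_num].atom("P")
        if pm is None or pr is None:
            continue
        pairs.append((mid, ref_num))
        mc.append(pm.coords)
        rc.append(pr.coords)
    corr = replace(corr, pairs=tuple(pairs))
    return corr, np.asarray(mc), np.asarray(rc)


def _subset_by_pairs(
    corr_sub: ResidueCorrespondence,
    corr_full: ResidueCorrespondence,
    model_coords: np.ndarray,
    ref_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    row = {pair: i for i, pair in enumerate(corr_full.pairs)}
    take = np.array([row[p] for p in corr_sub.pairs], dtype=int)
    return model_coords[take], ref_coords[take]


def domain_cores(
    model,
    reference,
    domains: tuple[str, ...] = ("LSU", "SSU_body", "SSU_head"),
    align_params: AlignParams = AlignParams(),
    prune_params: PruneParams = PruneParams(),
    head_set: frozenset[int] | None = None,
) -> dict[str, CoreMap]:
    """Identify the pruned cores of a model against the classical reference.

    ``model`` and ``reference`` are :class:`~radkit.structure_io.RibosomeStructure`
    objects.  The LSU core needs both structures' LSU chains; the SSU is
    aligned once and partitioned into head and body via the packaged head
    set.  The head uses a smaller minimum-core guard (50 vs 100).
    """
    if head_set is None:
        head_set = _data.load_head_set()
    cores: dict[str, CoreMap] = {}
    if "LSU" in domains:
        if model.lsu_chain is None or reference.lsu_chain is None:
            raise ValueError("LSU core requested but an LSU chain is missing")
        corr, mc, rc = correspond_chains(
            model.lsu_chain, reference.lsu_chain, "LSU", align_params
        )
        cores["LSU"] = prune_core(corr, mc, rc, prune_params)
    if "SSU_body" in domains or "SSU_head" in domains:
        if model.ssu_chain is None or reference.ssu_chain is None:
            raise ValueError("SSU cores requested but an SSU chain is missing")
        corr, mc, rc = correspond_chains(
            model.ssu_chain, reference.ssu_chain, "SSU", align_params
        )
        head, body = partition_head_body(corr, head_set=head_set)
        if "SSU_body" in domains:
            bmc, brc = _subset_by_pairs(body, corr, mc, rc)
            cores["SSU_body"] = prune_core(body, bmc, brc, prune_params)
        if "SSU_head" in domains:
            hmc, hrc = _subset_by_pairs(head, corr, mc, rc)
            head_params = replace(prune_params, min_core=min(prune_params.min_core, 50))
            cores["SSU_head"] = prune_core(head, hmc, hrc, head_params)
    return cores
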