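"""Inter-probe distances for smFRET designs and their response to rotation.

Computes the label-site distances used in published intersubunit-rotation
smFRET assays — Cα–Cα distances between ribosomal proteins (S6 res 41 ↔ L9
res 11; S11 res 75 ↔ L9 res 11) and the distance between the geometric
centers of the turns of 16S helix h44 (U1450–G1453) and 23S helix H101
(C2853–U2865) — and fits their dependence on the body/head rotation angles
with a sigmoid (tanh) or a power law.  Only the distances between labeled
sites are considered; fluorophore photophysics and linker dynamics are out
of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from Bio import Align

from .structure_io import ChainModel, RibosomeStructure

logger = logging.getLogger(__name__)

__all__ = [
    "SiteSpec",
    "ProbeSpec",
    "FitResult",
    "BUILTIN_PROBES",
    "UnresolvableSiteError",
    "probe_distance",
    "fit_sigmoid",
    "fit_powerlaw",
    "correlate",
    "resolution_filter",
]

#: structures worse than this resolution (Å) are excluded from fits
DEFAULT_MAX_RESOLUTION = 5.0


class UnresolvableSiteError(ValueError):
    """A probe site's molecule/residues are absent from the structure (the
    structure is skipped with a report, not failed)."""


@dataclass(frozen=True)
class SiteSpec:
    """One label site: a molecule, a residue set and an atom rule.

    ``molecule`` is either a rRNA selector ("16S"/"SSU", "23S"/"LSU") or a
    protein name resolved by sequence match against a reference-sequence
    registry (chain naming is inconsistent across entries, so chains are
    matched by ≥60% sequence identity, not by id).  ``atom_rule`` is
    ``"CA"`` (single Cα) or ``"center"`` (geometric center of the residue
    set's atoms).
    """

    molecule: str
    residues: tuple[int, ...]
    atom_rule: str = "center"  # CA | center


@dataclass(frozen=True)
class ProbeSpec:
    label: str
    site_a: SiteSpec
    site_b: SiteSpec


BUILTIN_PROBES: dict[str, ProbeSpec] = {
    "S6-L9": ProbeSpec(
        "S6-L9",
        SiteSpec("S6", (41,), "CA"),
        SiteSpec("L9", (11,), "CA"),
    ),
    "S11-L9": ProbeSpec(
        "S11-L9",
        SiteSpec("S11", (75,), "CA"),
        SiteSpec("L9", (11,), "CA"),
    ),
    "h44-H101": ProbeSpec(
        "h44-H101",
        SiteSpec("16S", (1450, 1451, 1452, 1453), "center"),
        SiteSpec("23S", (2853, 2854, 2855, 2856, 2857, 2858, 2859, 2860,
                         2861, 2862, 2863, 2864, 2865), "center"),
    ),
}

_MIN_PROTEIN_IDENTITY = 0.60


def _match_protein_chain(
    structure: RibosomeStructure, name: str,
    reference_sequences: dict[str, str] | None,
) -> ChainModel | None:
    if reference_sequences is None or name not in reference_sequences:
        return None
    ref_seq = reference_sequences[name]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.2
    best: tuple[float, ChainModel] | None = None
    for chain in structure.chains:
        if chain.kind != "protein" or len(chain) < 10:
            continue
        identity = aligner.align(ref_seq, chain.sequence).score / max(
            len(ref_seq), len(chain)
        )
        if identity >= _MIN_PROTEIN_IDENTITY and (best is None or identity > best[0]):
            best = (identity, chain)
    return best[1] if best else None


def _resolve_site(
    structure: RibosomeStructure,
    site: SiteSpec,
    reference_sequences: dict[str, str] | None,
    chain_map: dict[str, str] | None,
) -> np.ndarray:
    mol = site.molecule.upper()
    chain: ChainModel | None = None
    if chain_map and site.molecule in chain_map:
        chain = structure.chain(chain_map[site.molecule])
    elif mol in {"16S", "SSU"}:
        chain = structure.ssu_chain
    elif mol in {"23S", "LSU"}:
        chain = structure.lsu_chain
    else:
        chain = _match_protein_chain(structure, site.molecule, reference_sequences)
    if chain is None:
        raise UnresolvableSiteError(
            f"{structure.accession}: cannot resolve molecule {site.molecule!r}"
        )
    coords = []
    for number in site.residues:
        res = chain.residue_by_number(number)
        if res is None:
            raise UnresolvableSiteError(
                f"{structure.accession}: residue {number} missing in "
                f"{site.molecule}"
            )
        if site.atom_rule == "CA":
            atom = res.atom("CA")
            if atom is None:
                raise UnresolvableSiteError(
                    f"{structure.accession}: no CA atom at {site.molecule}:{number}"
                )
            coords.append(atom.coords)
        else:
            coords.extend(a.coords for a in res.atoms)
    return np.asarray(coords).mean(axis=0)


def probe_distance(
    structure: RibosomeStructure,
    spec: ProbeSpec,
    reference_sequences: dict[str, str] | None = None,
    chain_map: dict[str, str] | None = None,
) -> float:
    """Euclidean distance (Å) between the two resolved site points.

    Invariant under global rigid transforms of the structure.  Raises
    :class:`UnresolvableSiteError` when a site is absent — callers skip
    such structures and report them, mirroring the convention that only
    structures containing the labeled residues enter the analysis.
    """
    a = _resolve_site(structure, spec.site_a, reference_sequences, chain_map)
    b = _resolve_site(structure, spec.site_b, reference_sequences, chain_map)
    return float(np.linalg.norm(a - b))


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of a probe-distance response curve."""

    kind: str                 # sigmoid | powerlaw
    params: dict[str, float]
    residuals: np.ndarray
    ok: bool
    message: str = ""

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    @property
    def responsive_range(self) -> tuple[float, float] | None:
        """For a sigmoid: the angle window [x₀ − w, x₀ + w] over which the
        distance changes fastest."""
        if self.kind != "sigmoid" or not self.ok:
            return None
        return (
            self.params["midpoint"] - self.params["width"],
            self.params["midpoint"] + self.params["width"],
        )


def _sigmoid(x: np.ndarray, a: float, b: float, x0: float, w: float) -> np.ndarray:
    return a + b * np.tanh((x - x0) / w)


def fit_sigmoid(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Fit y = a + b·tanh((x − x₀)/w) to distance-vs-angle data.

    Needs ≥ 5 points spanning more than 1° of x.  Non-convergence or an
    unidentifiable midpoint (flat data) is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(x) <= 1.0:
        raise ValueError("x range must span more than 1 degree")
    if np.ptp(y) < 1e-9:
        return FitResult(
            "sigmoid", {"baseline": float(y.mean()), "amplitude": 0.0,
                        "midpoint": np.nan, "width": np.nan},
            y - y.mean(), ok=False, message="constant data: midpoint unidentifiable",
        )
    slope_sign = 1.0 if stats.pearsonr(x, y)[0] >= 0 else -1.0
    p0 = [float(y.mean()), slope_sign * float(np.ptp(y)) / 2.0,
          float(np.median(x)), float(np.ptp(x)) / 4.0]
    try:
        popt, _ = optimize.curve_fit(
            _sigmoid, x, y, p0=p0,
            bounds=([-np.inf, -np.inf, x.min() - np.ptp(x), 1e-6],
                    [np.inf, np.inf, x.max() + np.ptp(x), 10 * np.ptp(x)]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        return FitResult(
            "sigmoid",
            {"baseline": np.nan, "amplitude": np.nan, "midpoint": np.nan,
             "width": np.nan},
            np.full_like(y, np.nan), ok=False, message=str(exc),
        )
    params = dict(zip(("baseline", "amplitude", "midpoint", "width"), map(float, popt)))
    residuals = y - _sigmoid(x, *popt)
    return FitResult("sigmoid", params, residuals, ok=True)


def _powerlaw(x: np.ndarray, a: float, b: float, c: float, x_min: float) -> np.ndarray:
    return a + b * np.power(x - x_min + 1.0, c)


def fit_powerlaw(x: np.ndarray, y: np.ndarray) -> FitResult:
    """Fit y = a + b·(x − x_min + 1)^c (x shifted positive by its minimum)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    if np.ptp(x) <= 1.0:
        raise ValueError("x range must span more than 1 degree")
    x_min = float(x.min())
    if np.ptp(y) < 1e-9:
        return FitResult(
            "powerlaw", {"offset": float(y.mean()), "scale": 0.0, "exponent": 0.0},
            y - y.mean(), ok=False, message="constant data: exponent unidentifiable",
        )
    p0 = [float(y.min()), float(np.ptp(y)) / np.ptp(x), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, a, b, c: _powerlaw(xx, a, b, c, x_min), x, y, p0=p0,
            maxfev=20000,
        )
    except RuntimeError as exc:
        return FitResult(
            "powerlaw", {"offset": np.nan, "scale": np.nan, "exponent": np.nan},
            np.full_like(y, np.nan), ok=False, message=str(exc),
        )
    params = dict(zip(("offset", "scale", "exponent"), map(float, popt)))
    params["x_min"] = x_min
    residuals = y - _powerlaw(x, *popt, x_min)
    return FitResult("powerlaw", params, residuals, ok=True)


def correlate(
    records: pd.DataFrame,
    distance_key: str,
    angle_key: str,
    export_path: str | None = None,
) -> dict[str, float]:
    """Pearson and Spearman correlation between a probe distance and a
    rotation angle over an ensemble, with optional TSV scatter export.

    ``records`` needs the two named columns (plus ``accession`` for the
    export); rows with missing values are dropped.
    """
    sub = records[[c for c in (distance_key, angle_key, "accession")
                   if c in records.columns]].dropna()
    x = sub[angle_key].to_numpy(dtype=float)
    y = sub[distance_key].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 complete records")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    if export_path is not None:
        sub.sort_values(sub.columns[-1] if "accession" not in sub else "accession").to_csv(
            export_path, sep="\t", index=False, float_format="%.6f"
        )
    return {
        "pearson_r": float(pearson[0]),
        "pearson_p": float(pearson[1]),
        "spearman_rho": float(spearman[0]),
        "spearman_p": float(spearman[1]),
        "n": int(x.size),
    }


def resolution_filter(
    structures: list[RibosomeStructure],
    max_resolution: float = DEFAULT_MAX_RESOLUTION,
) -> list[RibosomeStructure]:
    """Keep structures at the given resolution or better (unknown → drop)."""
    return [
        s for s in structures
        if s.resolution is not None and s.resolution <= max_resolution
    ]
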