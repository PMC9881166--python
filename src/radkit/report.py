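"""Ensemble summaries and figure-style exports.

Aggregates per-structure decomposition records into the quantities used to
characterise an ensemble: per-domain angle spans, threshold counts (how many
structures are essentially untilted, how many need more than a small
residual translation), per-group extremes and nearest-neighbour tables.
Deterministic: the same inputs produce byte-identical TSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EnsembleSummary", "summarize", "radius_of_gyration", "export_scatter",
           "read_manifest"]

MANIFEST_COLUMNS = ["path", "accession", "lsu_chain", "ssu_chain", "group", "resolution"]


@dataclass
class EnsembleSummary:
    """Per-domain, per-group ensemble statistics."""

    n_structures: int
    domains: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for domain, stats_ in self.domains.items():
            row = {"domain": domain}
            row.update({k: v for k, v in stats_.items() if not isinstance(v, dict)})
            rows.append(row)
        return pd.DataFrame(rows)


def summarize(
    results: pd.DataFrame,
    theta_threshold_deg: float = 1.0,
    delta_x_threshold: float = 3.0,
) -> EnsembleSummary:
    """Summarise an ensemble of decomposition records.

    ``results`` columns: accession, domain, phi_deg, theta_deg, psi_deg,
    delta_x_A and optionally group.  Reports, per domain (and per group when
    present): min/max/span of ϕ and θ, the count of essentially untilted
    structures (θ below threshold), the count within the translation
    threshold, and the accessions at the extremes.
    """
    if results.empty:
        raise ValueError("no results to summarise")
    summary = EnsembleSummary(n_structures=results["accession"].nunique())
    for domain, df in results.groupby("domain"):
        phi = df["phi_deg"].to_numpy(dtype=float)
        theta = df["theta_deg"].to_numpy(dtype=float)
        dx = df["delta_x_A"].to_numpy(dtype=float)
        stats_: dict = {
            "n": len(df),
            "phi_min_deg": float(phi.min()),
            "phi_max_deg": float(phi.max()),
            "phi_span_deg": float(phi.max() - phi.min()),
            "theta_min_deg": float(theta.min()),
            "theta_max_deg": float(theta.max()),
            "theta_span_deg": float(theta.max() - theta.min()),
            "n_untilted": int((theta < theta_threshold_deg).sum()),
            "n_small_translation": int((dx <= delta_x_threshold).sum()),
            "phi_min_accession": str(df.loc[df["phi_deg"].idxmin(), "accession"]),
            "phi_max_accession": str(df.loc[df["phi_deg"].idxmax(), "accession"]),
        }
        if "group" in df.columns:
            groups = {}
            for group, gdf in df.groupby("group"):
                if gdf.empty:
                    continue
                groups[str(group)] = {
                    "n": len(gdf),
                    "phi_span_deg": float(gdf["phi_deg"].max() - gdf["phi_deg"].min()),
                    "theta_max_deg": float(gdf["theta_deg"].max()),
                }
            stats_["groups"] = groups
        summary.domains[str(domain)] = stats_
    return summary


def radius_of_gyration(points: np.ndarray) -> float:
    """Mass-uniform radius of gyration (Å) of a point set (P atoms)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (N, 3) array")
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt(np.einsum("ij,ij->i", centered, centered).mean()))


def export_scatter(
    results: pd.DataFrame,
    x_key: str,
    y_key: str,
    path: str | Path,
    plot: bool = False,
) -> pd.DataFrame:
    """Export an (x, y) scatter table as TSV, ordered by accession.

    Columns: x, y, accession, group (group blank when absent).  Float
    formatting is fixed so re-runs are byte-identical.  ``plot=True``
    additionally writes a diagnostic PNG next to the TSV.
    """
    cols = {"x": results[x_key], "y": results[y_key],
            "accession": results["accession"]}
    cols["group"] = results["group"] if "group" in results.columns else ""
    df = pd.DataFrame(cols).sort_values("accession", kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", na_rep="NA")
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(df["x"], df["y"], s=12)
        ax.set_xlabel(x_key)
        ax.set_ylabel(y_key)
        fig.tight_layout()
        fig.savefig(Path(path).with_suffix(".png"), dpi=120)
        plt.close(fig)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest: TSV with columns path, accession, lsu_chain,
    ssu_chain, group, resolution (missing trailing columns tolerated)."""
    df = pd.read_csv(path, sep="\t", dtype={"lsu_chain": str, "ssu_chain": str})
    missing = [c for c in ("path", "accession") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[MANIFEST_COLUMNS]
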