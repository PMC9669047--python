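"""Selection of derepressed genes and clustering into regulatory modes.

Genes showing an increase in any of the four measures — newly-synthesised
mRNA, total mRNA, mRNA stability or ribosome-protected mRNA — are pooled and
hierarchically clustered on the correlation between their z-scores for
transcription (new), stability and translation (ribo).  Total-mRNA z is kept
in the matrix for reporting but excluded from the distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "SelectionThresholds",
    "select_derepressed",
    "cluster_modes",
    "summarize_clusters",
    "RegulatoryModes",
]

CLUSTER_MEASURES = ("z_new", "z_stability", "z_ribo")


@dataclass(frozen=True)
class SelectionThresholds:
    """Per-measure cutoffs for calling a gene derepressed (increase only).

    Defaults: newly-synthesised FDR < 0.1, total FDR < 0.001, stability
    z > 2, ribosome-protected FDR < 0.05.
    """

    new_fdr: float = 0.1
    total_fdr: float = 0.001
    stability_z: float = 2.0
    ribo_fdr: float = 0.05


def _increased(diff: pd.DataFrame, fdr_cut: float) -> pd.Index:
    ok = (diff["fdr"] < fdr_cut) & (diff["lfc"] > 0)
    return pd.Index(diff.loc[ok, "gene_id"])


def select_derepressed(
    diff_new: pd.DataFrame,
    diff_total: pd.DataFrame,
    stab: pd.DataFrame,
    diff_ribo: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.Index:
    """Union of genes increased in any assay at its threshold.

    The increase requirement (``lfc > 0``, or a positive stability score) is
    applied per criterion: a gene highly significant for a *decrease* in one
    assay does not qualify through that assay.
    """
    for name, tbl, cols in (
        ("diff_new", diff_new, {"gene_id", "fdr", "lfc"}),
        ("diff_total", diff_total, {"gene_id", "fdr", "lfc"}),
        ("stab", stab, {"gene_id", "z", "score"}),
        ("diff_ribo", diff_ribo, {"gene_id", "fdr", "lfc"}),
    ):
        missing = cols - set(tbl.columns)
        if missing:
            raise ValueError(f"{name} is missing columns {sorted(missing)}")
    sel = _increased(diff_new, thresholds.new_fdr)
    sel = sel.union(_increased(diff_total, thresholds.total_fdr))
    stab_ok = (stab["z"] > thresholds.stability_z) & (stab["score"] > 0)
    sel = sel.union(pd.Index(stab.loc[stab_ok, "gene_id"]))
    sel = sel.union(_increased(diff_ribo, thresholds.ribo_fdr))
    return sel.sort_values()


@dataclass
class RegulatoryModes:
    """Clustering result: z matrix, linkage tree, assignments, exclusions."""

    z_matrix: pd.DataFrame
    linkage: np.ndarray
    clusters: pd.Series  # gene_id -> 1..k
    excluded: pd.Index  # constant rows (correlation undefined)


def cluster_modes(z_matrix: pd.DataFrame, k: int = 5) -> RegulatoryModes:
    """Complete-linkage clustering on 1 - Pearson correlation of z rows.

    Only the transcription/stability/translation columns
    (``z_new, z_stability, z_ribo``) enter the distance; ``z_total`` may be
    present for reporting.  Rows constant across the three clustering columns
    have undefined correlation and are excluded with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    missing = set(CLUSTER_MEASURES) - set(z_matrix.columns)
    if missing:
        raise ValueError(f"z_matrix missing columns {sorted(missing)}")
    X = z_matrix.loc[:, list(CLUSTER_MEASURES)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("z_matrix contains non-finite values")
    const = X.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s) excluded from clustering "
            "(correlation undefined)",
            stacklevel=2,
        )
    kept = z_matrix.index[~const]
    Xk = X[~const]
    if kept.size < k:
        raise ValueError("fewer variable rows than requested clusters")
    dist = pdist(Xk, metric="correlation")  # 1 - Pearson(rows)
    Z = linkage(dist, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel clusters 1..k by order of first appearance for determinism
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    clusters = pd.Series([relabel[c] for c in raw], index=kept, name="cluster")
    return RegulatoryModes(
        z_matrix=z_matrix.loc[kept].copy(),
        linkage=Z,
        clusters=clusters,
        excluded=z_matrix.index[const],
    )


def summarize_clusters(
    modes: RegulatoryModes,
    strong: float = 1.2,
    up: float = 0.4,
    down: float = -0.4,
) -> pd.DataFrame:
    """Median z per cluster per measure with categorical labels.

    Labels: ``++`` if median > 1.2, ``+`` if in (0.4, 1.2], ``-`` if
    < -0.4, blank otherwise.
    """
    measures = [c for c in modes.z_matrix.columns if c.startswith("z_")]
    med = modes.z_matrix.groupby(modes.clusters)[measures].median()

    def label(v: float) -> str:
        if v > strong:
            return "++"
        if v > up:
            return "+"
        if v < down:
            return "-"
        return ""

    out = med.rename(columns=lambda c: f"median_{c}")
    for m in measures:
        out[f"label_{m}"] = med[m].map(label)
    out.insert(0, "n_genes", modes.clusters.value_counts().sort_index())
    return out.reset_index().rename(columns={"index": "cluster"})
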