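"""Normalisation and differential statistics for the four count-based assays.

The central statistic is :func:`intensity_diff`, a z-score computed against
the *local* standard deviation of genes with similar mean expression.  RNA-seq
differences are strongly heteroscedastic in expression: lowly expressed genes
show larger log-fold-change noise, so a single global SD either drowns
low-expression signal or inflates it.  ``intensity_diff`` slides a window of
the ``w`` nearest genes in mean expression and standardises each gene's
difference against the mean and SD of differences within its own window.

A simpler global z (:func:`zscore_from_lfc`) is retained for cross-assay
comparison of fold changes on a common dimensionless scale.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors_median_of_ratios",
    "normalize_counts",
    "compute_fpkm",
    "log2_fold_change",
    "zscore_from_lfc",
    "intensity_diff",
    "diff_expression",
    "filter_expressed",
    "bh_fdr",
]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Reference genes are those with a nonzero count in *every* sample.  For
    sample ``j`` the factor is the median over reference genes of
    ``count_gj / geometric_mean_g``.

    Parameters
    ----------
    counts
        Genes x samples non-negative integer matrix.

    Returns
    -------
    pandas.Series of positive factors indexed by sample.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("negative counts are not allowed")
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no reference gene: every gene has a zero count in at least one sample"
        )
    logs = np.log(mat[ref])
    log_geo_mean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample by its size factor (computed if not supplied)."""
    if factors is None:
        factors = size_factors_median_of_ratios(counts)
    return counts / factors


def compute_fpkm(
    counts: pd.DataFrame,
    feature_lengths: pd.Series,
    mapped_totals: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped reads.

    ``fpkm = count / (length_kb * mapped_millions)``.
    """
    lengths = feature_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("feature length missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    totals = mapped_totals.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("mapped totals must be positive for every sample")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def log2_fold_change(
    norm_counts: pd.DataFrame,
    samples: pd.DataFrame,
    group: str = "dKO",
    reference: str = "control",
    pseudocount: float = 0.5,
) -> pd.Series:
    """Plain log2 ratio of group-mean normalised counts with a pseudocount.

    No shrinkage is applied; externally shrunken fold changes can be fed to
    the z-score functions instead.
    """
    g_cols = samples.loc[samples["genotype"] == group, "sample_id"]
    r_cols = samples.loc[samples["genotype"] == reference, "sample_id"]
    if len(g_cols) == 0 or len(r_cols) == 0:
        raise ValueError(f"no samples for genotype {group!r} or {reference!r}")
    mg = norm_counts[list(g_cols)].mean(axis=1)
    mr = norm_counts[list(r_cols)].mean(axis=1)
    return np.log2((mg + pseudocount) / (mr + pseudocount)).rename("lfc")


def zscore_from_lfc(lfc: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Fold change divided by the overall SD of fold changes (ddof 1).

    The mean is *not* subtracted: the statistic expresses each gene's change
    on the scale of dataset-wide variability, preserving sign and zero.
    """
    arr = np.asarray(lfc, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("need at least two finite fold changes")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation across fold changes")
    z = arr / sd
    if isinstance(lfc, pd.Series):
        return pd.Series(z, index=lfc.index, name="z")
    return z


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagated)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _nearest_windows(expr_sorted: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Start index of the w-nearest contiguous window for each sorted position.

    For a sorted expression vector the w nearest neighbours of position ``i``
    (by absolute expression distance, including i itself) form a contiguous
    block.  Ties resolve toward the lower-expression side.
    """
    n = expr_sorted.size
    lo = np.empty(n, dtype=np.intp)
    hi = np.empty(n, dtype=np.intp)
    for i in range(n):
        l = r = i
        while r - l + 1 < w:
            if l == 0:
                r += 1
            elif r == n - 1:
                l -= 1
            elif expr_sorted[i] - expr_sorted[l - 1] <= expr_sorted[r + 1] - expr_sorted[i]:
                l -= 1
            else:
                r += 1
        lo[i], hi[i] = l, r
    return lo, hi


def intensity_diff(
    mean_expr: pd.Series,
    diff: pd.Series,
    window_fraction: float = 0.01,
    window_min: int = 200,
    contrasts: pd.Series | None = None,
) -> pd.DataFrame:
    """Expression-local z statistic for per-gene differences.

    For each gene ``g`` let ``W(g)`` be the ``w`` genes nearest to ``g`` in
    mean expression (``g`` included), with
    ``w = max(window_min, ceil(window_fraction * G))`` clamped to ``G``.  Then

        z_g = (diff_g - mean(diff over W)) / sd(diff over W, ddof 1)

    with a two-sided standard-normal p-value and BH-adjusted FDR.

    Parameters
    ----------
    mean_expr, diff
        Aligned per-gene series.  The expression axis defines neighbourhoods;
        the differences are the quantity being standardised (a raw log2 fold
        change, a standardised stability change, ...).
    window_fraction
        Window size as a proportion of the number of genes, in (0, 1].
    window_min
        Floor on the window size; keeps the local SD stable for small G.
    contrasts
        Optional per-gene contrast labels.  Windows are then formed over the
        union of all contrasts' (expression, difference) points, so z-scores
        are comparable across contrasts; the output carries the label.

    Returns
    -------
    DataFrame with columns ``gene_id, expression, diff, z, p, fdr`` (plus
    ``contrast`` when given), in the input order.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    expr = np.asarray(mean_expr, dtype=float)
    d = np.asarray(diff, dtype=float)
    if expr.shape != d.shape:
        raise ValueError("mean_expr and diff must be aligned")
    n = expr.size
    w = max(window_min, int(np.ceil(window_fraction * n)))
    w = min(w, n)
    if w < 3:
        raise ValueError("window of fewer than 3 genes")

    ids = np.asarray(mean_expr.index.astype(str))
    order = np.lexsort((ids, expr))  # expression ties broken by gene id
    expr_s, d_s = expr[order], d[order]
    lo, hi = _nearest_windows(expr_s, w)

    csum = np.concatenate(([0.0], np.cumsum(d_s)))
    csum2 = np.concatenate(([0.0], np.cumsum(d_s * d_s)))
    tot = csum[hi + 1] - csum[lo]
    tot2 = csum2[hi + 1] - csum2[lo]
    mean_w = tot / w
    var_w = (tot2 - tot * tot / w) / (w - 1)
    var_w = np.maximum(var_w, 0.0)
    sd_w = np.sqrt(var_w)
    if (sd_w == 0).any():
        raise ValueError("zero local standard deviation in at least one window")
    z_s = (d_s - mean_w) / sd_w

    z = np.empty(n)
    z[order] = z_s
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "gene_id": mean_expr.index,
            "expression": expr,
            "diff": d,
            "z": z,
            "p": p,
            "fdr": bh_fdr(p),
        }
    )
    if contrasts is not None:
        out["contrast"] = np.asarray(contrasts)
    return out


def diff_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    group: str = "dKO",
    reference: str = "control",
) -> pd.DataFrame:
    """Per-assay differential table: base mean, lfc, global z, p, BH fdr.

    The log2 fold change is the plain ratio of group-mean normalised counts
    (pseudocount 0.5); z is the fold change over the dataset-wide SD, and the
    p-value is two-sided standard normal on z.
    """
    cols = [c for c in samples["sample_id"] if c in counts.columns]
    counts = counts[cols]
    norm = normalize_counts(counts)
    base_mean = norm.mean(axis=1)
    lfc = log2_fold_change(norm, samples, group=group, reference=reference)
    z = zscore_from_lfc(lfc)
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z)))
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": base_mean.to_numpy(),
            "lfc": lfc.to_numpy(),
            "z": np.asarray(z),
            "p": p,
            "fdr": bh_fdr(p),
        }
    )


def filter_expressed(diff: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Keep rows with ``base_mean`` strictly above ``threshold``.

    FDR values are deliberately *not* recomputed on the filtered subset; the
    filter is applied post hoc for visualisation and downstream selection.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return diff.loc[diff["base_mean"] > threshold].copy()
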