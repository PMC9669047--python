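"""mRNA half-life estimation from 4sU three-fraction RNA-seq.

After a pulse of 4-thiouridine of length ``t`` hours, RNA is separated into
labelled (newly synthesised, L), unlabelled (pre-existing, U) and total (T)
fractions.  At steady state under first-order decay with rate ``delta`` the
labelled share of a transcript's pool is

    theta = 1 - exp(-delta * t)

so ``delta = -ln(1 - theta) / t`` and ``t_half = ln2 / delta``.  The labelled
and unlabelled libraries are sequenced separately, so their normalised counts
sit on arbitrary scales relative to total; per-sample correction factors
``(c_L, c_U)`` mapping them onto total are estimated by a no-intercept linear
regression ``T ~ c_L * L + c_U * U`` across genes, exploiting the fact that
the two fractions partition the total pool.

The downstream differential score standardises the per-batch log2 change in
half-life by the batch-wide SD before averaging across batches, which absorbs
batch-scale differences in labelling efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffstats import intensity_diff, normalize_counts, size_factors_median_of_ratios

__all__ = [
    "LabelingDesign",
    "CorrectionFactors",
    "estimate_correction_factors",
    "estimate_half_lives",
    "standardized_stability_change",
    "stability_significance",
    "run_stability_pipeline",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class LabelingDesign:
    """Labelling pulse parameters.

    t_label: pulse duration in hours (default 1.0 h).
    separation_purity: fraction of labelled molecules captured in the
        labelled fraction (1.0 = perfect separation).
    """

    t_label: float = 1.0
    separation_purity: float = 1.0

    def __post_init__(self) -> None:
        if self.t_label <= 0:
            raise ValueError("t_label must be positive")
        if not 0 < self.separation_purity <= 1:
            raise ValueError("separation_purity must be in (0, 1]")


@dataclass
class CorrectionFactors:
    """Per-sample (c_L, c_U) scalings of labelled/unlabelled onto total."""

    per_sample: pd.DataFrame  # columns: sample, c_l, c_u, valid, residual_rms
    mean_c_l: float = field(init=False)
    mean_c_u: float = field(init=False)

    def __post_init__(self) -> None:
        ok = self.per_sample.loc[self.per_sample["valid"]]
        if ok.empty:
            raise ValueError("no valid sample for correction-factor estimation")
        self.mean_c_l = float(ok["c_l"].mean())
        self.mean_c_u = float(ok["c_u"].mean())


def _estimate_dispersion(total: pd.DataFrame, floor: float = 50.0) -> float:
    """Moment estimate of a common NB dispersion from across-sample variance.

    ``var = mu + d * mu^2`` gives ``d = (var - mu) / mu^2`` per gene; the
    median over well-covered genes is robust to genotype-driven variance.
    Only used to shape regression weights, so bias is harmless.
    """
    if total.shape[1] < 2:
        return 0.0
    m = total.mean(axis=1).to_numpy(dtype=float)
    v = total.var(axis=1, ddof=1).to_numpy(dtype=float)
    ok = m > floor
    if not ok.any():
        return 0.0
    return float(max(np.median((v[ok] - m[ok]) / m[ok] ** 2), 0.0))


def estimate_correction_factors(
    total: pd.DataFrame,
    new: pd.DataFrame,
    pre: pd.DataFrame,
    min_total: float = 10.0,
    min_genes: int = 50,
    dispersion: float | None = None,
) -> CorrectionFactors:
    """Estimate (c_L, c_U) per biological sample by weighted regression.

    Per sample the no-intercept model ``T_g = c_L * L_g + c_U * U_g`` is fit
    across eligible genes.  Because L and U are themselves count estimates,
    a plain least-squares fit suffers errors-in-variables attenuation that
    is amplified by the strong collinearity of the two fractions (both scale
    with abundance).  When other samples are available, their mean labelled/
    unlabelled counts serve as instruments: the instrument is correlated
    with the true regressor but independent of the focal sample's count
    noise, removing the bias.  Weights are inverse NB variance
    ``1 / (mu + d * mu^2)`` with ``mu`` the mean normalised total over the
    *other* samples (so weights are independent of the focal sample's
    noise) and ``d`` a pooled moment estimate of dispersion.

    Parameters
    ----------
    total, new, pre
        *Normalised* count matrices sharing the gene index; columns are
        biological samples (the three fraction libraries of one sample must
        share a column name).
    min_total
        Eligibility floor on mean normalised total, suppressing
        zero-inflation leverage.
    min_genes
        Minimum number of eligible genes.
    dispersion
        NB dispersion used in the weights; estimated from the data when
        omitted.

    A sample whose fit is singular or yields a non-positive coefficient is
    flagged invalid and excluded from the means.
    """
    if not (total.index.equals(new.index) and total.index.equals(pre.index)):
        raise ValueError("the three matrices must share the gene index")
    for col in total.columns:
        if col not in new.columns or col not in pre.columns:
            raise ValueError(f"sample {col!r} missing from a fraction matrix")
    d = _estimate_dispersion(total) if dispersion is None else float(dispersion)
    cols = list(total.columns)
    rows = []
    for col in cols:
        others = [c for c in cols if c != col]
        ref = total[others].mean(axis=1) if others else total[col]
        mu = np.maximum(ref.to_numpy(dtype=float), 1.0)
        eligible = ref.to_numpy(dtype=float) >= min_total
        if eligible.sum() < min_genes:
            raise ValueError(
                f"sample {col!r}: only {int(eligible.sum())} genes with "
                f"normalised total >= {min_total} (need >= {min_genes})"
            )
        w = 1.0 / (mu + d * mu**2)
        y = total[col].to_numpy(dtype=float)
        X = np.column_stack([new[col].to_numpy(dtype=float), pre[col].to_numpy(dtype=float)])
        if others:
            Z = np.column_stack(
                [new[others].mean(axis=1).to_numpy(dtype=float),
                 pre[others].mean(axis=1).to_numpy(dtype=float)]
            )
        else:
            Z = X
        Zw = Z[eligible] * w[eligible, None]
        A = Zw.T @ X[eligible]
        b = Zw.T @ y[eligible]
        try:
            coef = np.linalg.solve(A, b)
            singular = False
        except np.linalg.LinAlgError:
            coef = np.array([np.nan, np.nan])
            singular = True
        valid = not singular and coef[0] > 0 and coef[1] > 0
        resid = y[eligible] - X[eligible] @ (coef if not singular else np.zeros(2))
        rows.append(
            {"sample": col, "c_l": float(coef[0]), "c_u": float(coef[1]),
             "valid": bool(valid), "residual_rms": float(np.sqrt(np.mean(resid**2)))}
        )
    return CorrectionFactors(per_sample=pd.DataFrame(rows))


def estimate_half_lives(
    total: pd.DataFrame,
    new: pd.DataFrame,
    pre: pd.DataFrame,
    samples: pd.DataFrame,
    factors: CorrectionFactors,
    design: LabelingDesign = LabelingDesign(),
    min_counts: float = 1.0,
    by: tuple[str, ...] = ("genotype", "batch"),
) -> pd.DataFrame:
    """Per-gene half-lives for every genotype x batch group.

    Group-mean normalised counts are formed first (variance reduction), then

        theta = c_L * Lbar / (c_L * Lbar + c_U * Ubar)

    using the across-sample mean correction factors.  The denominator is the
    reconstructed total, which guarantees theta in (0, 1) whenever both
    reconstructed components are positive.  Rows where theta falls on a
    boundary, or where the group-mean reconstructed total is below
    ``min_counts``, are flagged invalid with a reason code.

    Returns a long DataFrame: ``gene_id, genotype, batch, theta, decay_rate,
    half_life, valid, reason``.  ``by`` controls the grouping: the default
    estimates per genotype x batch (feeding the batch-standardised change);
    ``("genotype",)`` pools batches for a single per-genotype estimate
    (reported with batch ``"all"``).
    """
    c_l, c_u = factors.mean_c_l, factors.mean_c_u
    out = []
    sheet = samples.drop_duplicates(subset="sample_id")
    for keys, grp in sheet.groupby(list(by), sort=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        named = dict(zip(by, keys))
        genotype = named.get("genotype", "all")
        batch = named.get("batch", "all")
        cols = [c for c in grp["sample_id"] if c in total.columns]
        if not cols:
            continue
        lbar = new[cols].mean(axis=1).to_numpy(dtype=float) * c_l
        ubar = pre[cols].mean(axis=1).to_numpy(dtype=float) * c_u
        recon = lbar + ubar
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(recon > 0, lbar / recon, np.nan)
            delta = -np.log1p(-theta) / design.t_label
            half_life = LN2 / delta
        reason = np.full(total.shape[0], "", dtype=object)
        reason[recon < min_counts] = "insufficient_counts"
        low = (theta <= 0) | np.isnan(theta)
        high = theta >= 1
        reason[(reason == "") & low] = "theta<=0"
        reason[(reason == "") & high] = "theta>=1"
        valid = reason == ""
        df = pd.DataFrame(
            {
                "gene_id": total.index,
                "genotype": genotype,
                "batch": batch,
                "theta": theta,
                "decay_rate": delta,
                "half_life": half_life,
                "valid": valid,
                "reason": reason,
            }
        )
        df.loc[~valid, ["decay_rate", "half_life"]] = np.nan
        out.append(df)
    if not out:
        raise ValueError("no sample columns matched the count matrices")
    return pd.concat(out, ignore_index=True)


def standardized_stability_change(
    halflives: pd.DataFrame,
    group: str = "dKO",
    reference: str = "control",
) -> pd.DataFrame:
    """Batch-standardised log2 change in half-life.

    Within each batch ``b``, for genes with valid half-lives in both
    genotypes, ``d_b = log2(t_half[group] / t_half[reference])`` is divided by
    the batch-wide SD of ``d_b`` (ddof 1); the score is the mean of the
    standardised values over the batches where the gene is measurable.

    Returns ``gene_id, score, n_batches`` plus one ``z_<batch>`` column per
    batch.
    """
    batches = sorted(halflives["batch"].unique())
    per_batch: dict[str, pd.Series] = {}
    for b in batches:
        sub = halflives.loc[(halflives["batch"] == b) & halflives["valid"]]
        piv = sub.pivot_table(index="gene_id", columns="genotype", values="half_life",
                              aggfunc="first")
        if group not in piv.columns or reference not in piv.columns:
            continue
        piv = piv.dropna(subset=[group, reference])
        d = np.log2(piv[group] / piv[reference])
        if d.size < 2:
            raise ValueError(f"batch {b!r}: fewer than 2 valid genes")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError(f"batch {b!r}: zero SD of stability changes")
        per_batch[b] = d / sd
    if not per_batch:
        raise ValueError("no batch with both genotypes")
    z = pd.DataFrame({f"z_{b}": s for b, s in per_batch.items()})
    out = pd.DataFrame(
        {
            "gene_id": z.index,
            "score": z.mean(axis=1).to_numpy(),
            "n_batches": z.notna().sum(axis=1).to_numpy(),
        }
    )
    for c in z.columns:
        out[c] = z[c].to_numpy()
    return out.reset_index(drop=True)


def stability_significance(
    change: pd.DataFrame,
    expression: pd.Series,
    window_fraction: float = 0.01,
    window_min: int = 200,
) -> pd.DataFrame:
    """Attach local-SD z, p and FDR to the stability scores.

    ``expression`` should be the mean normalised read count across the total
    and newly-synthesised libraries, aligned on gene_id; genes without a
    score are dropped.
    """
    scored = change.dropna(subset=["score"]).set_index("gene_id")
    expr = expression.reindex(scored.index).dropna()
    scored = scored.loc[expr.index]
    res = intensity_diff(expr, scored["score"], window_fraction=window_fraction,
                         window_min=window_min)
    res = res.rename(columns={"diff": "score"})
    res["n_batches"] = scored["n_batches"].to_numpy()
    return res


def run_stability_pipeline(
    total_counts: pd.DataFrame,
    new_counts: pd.DataFrame,
    pre_counts: pd.DataFrame,
    samples: pd.DataFrame,
    design: LabelingDesign = LabelingDesign(),
    window_fraction: float = 0.01,
    window_min: int = 200,
) -> dict:
    """Counts-to-significance convenience wrapper.

    Normalises each fraction by median-of-ratios, maps the three libraries of
    each biological sample onto a common column name, estimates correction
    factors and half-lives, and returns the standardised change with local-SD
    significance.

    ``samples`` must carry ``sample_id, assay, genotype, batch, replicate``
    with assay in {total, new, pre}; libraries of one biological sample share
    (genotype, batch, replicate).
    """
    norm = {}
    bio_cols: dict[str, dict[str, str]] = {}
    for assay, counts in (("total", total_counts), ("new", new_counts), ("pre", pre_counts)):
        sub = samples.loc[samples["assay"] == assay]
        cols = [c for c in sub["sample_id"] if c in counts.columns]
        n = normalize_counts(counts[cols], size_factors_median_of_ratios(counts[cols]))
        rename = {}
        for _, row in sub.iterrows():
            bio = f"{row['genotype']}|{row['batch']}|{row['replicate']}"
            rename[row["sample_id"]] = bio
            bio_cols.setdefault(bio, {})[assay] = row["sample_id"]
        norm[assay] = n.rename(columns=rename)
    shared = [b for b, d in bio_cols.items() if len(d) == 3]
    total_n, new_n, pre_n = (norm[a][shared] for a in ("total", "new", "pre"))
    bio_sheet = pd.DataFrame(
        {
            "sample_id": shared,
            "genotype": [b.split("|")[0] for b in shared],
            "batch": [b.split("|")[1] for b in shared],
            "replicate": [b.split("|")[2] for b in shared],
        }
    )
    factors = estimate_correction_factors(total_n, new_n, pre_n)
    halflives = estimate_half_lives(total_n, new_n, pre_n, bio_sheet, factors, design)
    change = standardized_stability_change(halflives)
    expression = (total_n.mean(axis=1) + new_n.mean(axis=1)) / 2.0
    signif = stability_significance(change, expression, window_fraction=window_fraction,
                                    window_min=window_min)
    return {
        "factors": factors,
        "halflives": halflives,
        "change": change,
        "significance": signif,
        "expression": expression,
    }
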