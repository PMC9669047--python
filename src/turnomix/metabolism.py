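"""LC-MS metabolite table processing and 13C isotopologue correction.

A GC-MS isotopologue spectrum records ion counts at mass shifts
M+0 ... M+k for a derivatised metabolite fragment.  Natural heavy isotopes
of every atom in the fragment (C, H, N, O, Si, S) inflate the apparent
labelling, so the measured spectrum ``y`` relates to the true mass
isotopomer distribution (MID) ``m`` through a correction matrix ``C``:

    y = C m,   C[i][j] = P(mass shift i | j tracer carbons labelled)

``C`` is assembled by convolving the per-element natural-abundance mass-shift
distributions of all non-tracer atoms and, optionally, natural 13C at the
unlabelled tracer positions.  ``m`` is recovered by non-negative least
squares and renormalised; fractional labelling is the label-weighted mean
``FL = sum_j j*m_j / n_tracer``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .diffstats import bh_fdr
from .isotopes import NATURAL_ABUNDANCE, TRACER_ELEMENT

__all__ = [
    "IsotopologueSpectrum",
    "MIDResult",
    "natural_abundance_matrix",
    "correct_mid",
    "labelled_unlabelled_split",
    "normalize_metabolites",
    "metabolite_stats",
    "ratio_pairs",
    "row_log2_deviation",
]


@dataclass(frozen=True)
class IsotopologueSpectrum:
    """Raw ion counts at mass shifts M+0..M+k for one metabolite fragment.

    ``fragment_formula`` counts the atoms of the measured fragment
    *excluding* the tracer carbon positions; ``n_tracer`` is the number of
    carbon positions that can carry label.
    """

    metabolite: str
    fragment_formula: Mapping[str, int]
    n_tracer: int
    raw_counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_tracer < 1:
            raise ValueError("n_tracer must be >= 1")
        if any(v < 0 for v in self.fragment_formula.values()):
            raise ValueError("negative atom counts in fragment formula")
        if any(c < 0 for c in self.raw_counts):
            raise ValueError("negative ion counts")


@dataclass(frozen=True)
class MIDResult:
    metabolite: str
    mid: tuple[float, ...]
    fractional_labelling: float
    total_relative_ions: float


def _element_distribution(element: str, count: int,
                          abundances: Mapping[str, Mapping[int, float]]) -> np.ndarray:
    """Mass-shift distribution of ``count`` atoms of one element.

    Computed by exponentiation-by-squaring of the single-atom distribution
    under convolution.
    """
    freq = abundances[element]
    max_shift = max(freq)
    single = np.zeros(max_shift + 1)
    for shift, f in freq.items():
        single[shift] = f
    result = np.array([1.0])
    base = single
    n = count
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)
        base = np.convolve(base, base)
        n >>= 1
    return result


def natural_abundance_matrix(
    fragment_formula: Mapping[str, int],
    n_tracer: int,
    n_rows: int | None = None,
    abundances: Mapping[str, Mapping[int, float]] | None = None,
    correct_tracer_na: bool = True,
) -> np.ndarray:
    """Build the (n_rows x n_tracer+1) natural-abundance correction matrix.

    Column ``j`` is the mass-shift distribution of a molecule carrying ``j``
    tracer labels: the convolution of all non-tracer atoms' natural-isotope
    distributions, natural 13C at the ``n_tracer - j`` unlabelled tracer
    positions (disabled with ``correct_tracer_na=False``), shifted by ``j``.
    Consequently ``C[i][j] = 0`` for ``i < j`` and each column sums to <= 1,
    with equality when ``n_rows`` spans every reachable shift.
    """
    if n_tracer < 1:
        raise ValueError("n_tracer must be >= 1")
    if any(v < 0 for v in fragment_formula.values()):
        raise ValueError("negative atom counts in fragment formula")
    ab = abundances if abundances is not None else NATURAL_ABUNDANCE
    if n_rows is None:
        n_rows = n_tracer + 1
    base = np.array([1.0])
    for element, count in fragment_formula.items():
        if count == 0:
            continue
        if element not in ab:
            raise ValueError(f"no abundance data for element {element!r}")
        base = np.convolve(base, _element_distribution(element, int(count), ab))
    C = np.zeros((n_rows, n_tracer + 1))
    for j in range(n_tracer + 1):
        dist = base
        if correct_tracer_na and n_tracer - j > 0:
            dist = np.convolve(
                dist, _element_distribution(TRACER_ELEMENT, n_tracer - j, ab)
            )
        for i, p in enumerate(dist):
            row = i + j
            if row < n_rows:
                C[row, j] += p
    return C


def correct_mid(spectrum: IsotopologueSpectrum, matrix: np.ndarray,
                internal_standard: float | None = None) -> MIDResult:
    """Solve ``measured = C m`` for the MID by non-negative least squares.

    The solution is renormalised to sum to one.  ``total_relative_ions`` is
    the raw ion sum divided by ``internal_standard`` when given.
    """
    y = np.asarray(spectrum.raw_counts, dtype=float)
    if matrix.shape[0] != y.size:
        raise ValueError(
            f"matrix has {matrix.shape[0]} rows but spectrum has {y.size} bins"
        )
    if matrix.shape[1] != spectrum.n_tracer + 1:
        raise ValueError("matrix column count must equal n_tracer + 1")
    total = float(y.sum())
    if total == 0:
        raise ValueError("all-zero spectrum")
    m, _ = nnls(matrix, y / total)
    s = m.sum()
    if s == 0:
        raise ValueError("degenerate correction: NNLS returned the zero vector")
    m = m / s
    fl = float(np.dot(np.arange(m.size), m) / spectrum.n_tracer)
    rel = total / internal_standard if internal_standard else total
    return MIDResult(
        metabolite=spectrum.metabolite,
        mid=tuple(float(v) for v in m),
        fractional_labelling=fl,
        total_relative_ions=float(rel),
    )


def labelled_unlabelled_split(total_relative_ions: float, fl: float) -> tuple[float, float]:
    """Partition total relative ions into labelled/unlabelled parts.

    labelled = total * FL; unlabelled = total * (1 - FL).
    """
    if not 0 <= fl <= 1:
        raise ValueError("fractional labelling must be in [0, 1]")
    if total_relative_ions < 0:
        raise ValueError("total ions must be >= 0")
    return total_relative_ions * fl, total_relative_ions * (1.0 - fl)


def normalize_metabolites(
    raw: pd.DataFrame,
    internal_standard: pd.Series,
    tic: pd.Series | None = None,
    mode: str = "is",
) -> pd.DataFrame:
    """Normalise metabolite x sample peak areas.

    mode ``"is"`` divides each sample by its internal-standard signal;
    ``"is+tic"`` additionally divides by total ion content.  The returned
    frame carries the provenance in ``df.attrs["normalisation"]``.
    """
    if mode not in {"is", "is+tic"}:
        raise ValueError("mode must be 'is' or 'is+tic'")
    is_ = internal_standard.reindex(raw.columns)
    if is_.isna().any() or (is_ <= 0).any():
        raise ValueError("internal standard must be positive for every sample")
    out = raw.div(is_, axis=1)
    if mode == "is+tic":
        if tic is None:
            raise ValueError("mode 'is+tic' requires a TIC series")
        t = tic.reindex(raw.columns)
        if t.isna().any() or (t <= 0).any():
            raise ValueError("TIC must be positive for every sample")
        out = out.div(t, axis=1)
    out.attrs["normalisation"] = "IS-normalised" if mode == "is" else "IS+TIC-normalised"
    return out


def metabolite_stats(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    group: str = "dKO",
    reference: str = "control",
) -> pd.DataFrame:
    """Fold change of genotype means and unpaired t-test per metabolite."""
    g_cols = [c for c in samples.loc[samples["genotype"] == group, "sample_id"]
              if c in table.columns]
    r_cols = [c for c in samples.loc[samples["genotype"] == reference, "sample_id"]
              if c in table.columns]
    if len(g_cols) < 2 or len(r_cols) < 2:
        raise ValueError("need >= 2 samples per genotype")
    a = table[g_cols].to_numpy(dtype=float)
    b = table[r_cols].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    fold = a.mean(axis=1) / b.mean(axis=1)
    out = pd.DataFrame(
        {
            "metabolite": table.index,
            "fold_change": fold,
            "t": t,
            "p": p,
            "fdr": bh_fdr(p),
        }
    )
    return out


def ratio_pairs(table: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """Per-sample ratio of two metabolites (not a ratio of means)."""
    for m in (numerator, denominator):
        if m not in table.index:
            raise ValueError(f"metabolite {m!r} not in table")
    den = table.loc[denominator]
    if (den == 0).any():
        raise ValueError("zero denominator in at least one sample")
    return (table.loc[numerator] / den).rename(f"{numerator}/{denominator}")


def row_log2_deviation(matrix: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """log2 deviation of each entry from its row mean.

    ``v_ij = log2(x_ij / mean_i)``; row means must be positive.  ``floor``
    optionally clips entries below it before the transform (for zero-laden
    rows).
    """
    x = matrix.astype(float)
    if floor is not None:
        x = x.clip(lower=floor)
    if (x <= 0).to_numpy().any():
        raise ValueError("non-positive entries; supply a floor")
    means = x.mean(axis=1)
    if (means <= 0).any():
        raise ValueError("non-positive row mean")
    return np.log2(x.div(means, axis=0))
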