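"""Isotopologue correction, metabolite normalisation and statistics."""

import numpy as np
import pandas as pd
import pytest

from turnomix.isotopes import NATURAL_ABUNDANCE
from turnomix.metabolism import (
    IsotopologueSpectrum,
    correct_mid,
    labelled_unlabelled_split,
    metabolite_stats,
    natural_abundance_matrix,
    normalize_metabolites,
    ratio_pairs,
    row_log2_deviation,
)


def _atomwise_oracle(formula, n_tracer, j, abundances, n_rows):
    """Convolve per-atom shift distributions one atom at a time."""
    dist = np.array([1.0])
    for element, count in formula.items():
        freq = abundances[element]
        single = np.zeros(max(freq) + 1)
        for s, f in freq.items():
            single[s] = f
        for _ in range(count):
            dist = np.convolve(dist, single)
    freq = abundances["C"]
    single = np.zeros(max(freq) + 1)
    for s, f in freq.items():
        single[s] = f
    for _ in range(n_tracer - j):  # natural 13C at unlabelled tracer positions
        dist = np.convolve(dist, single)
    col = np.zeros(n_rows)
    for i, p in enumerate(dist):
        if i + j < n_rows:
            col[i + j] += p
    return col


class TestNaturalAbundanceMatrix:
    def test_identity_with_no_heavy_atoms(self):
        ab = {"C": {0: 1.0}}  # natural 13C switched off
        C = natural_abundance_matrix({}, 3, abundances=ab)
        assert np.allclose(C, np.eye(4))

    def test_single_extra_carbon_is_a_binomial_column(self):
        p = NATURAL_ABUNDANCE["C"][1]
        ab = {"C": NATURAL_ABUNDANCE["C"]}
        C = natural_abundance_matrix({"C": 1}, 2, n_rows=4, abundances=ab,
                                     correct_tracer_na=False)
        for j in range(3):
            expect = np.zeros(4)
            expect[j] = 1 - p
            if j + 1 < 4:
                expect[j + 1] = p
            assert np.allclose(C[:, j], expect)

    def test_matches_atomwise_convolution_oracle(self):
        formula = {"C": 14, "H": 34, "N": 1, "O": 4, "Si": 2}
        n_tracer, n_rows = 5, 9
        C = natural_abundance_matrix(formula, n_tracer, n_rows=n_rows)
        for j in range(n_tracer + 1):
            oracle = _atomwise_oracle(formula, n_tracer, j, NATURAL_ABUNDANCE, n_rows)
            assert np.allclose(C[:, j], oracle, atol=1e-12)

    def test_lower_triangular_and_column_sums(self):
        C = natural_abundance_matrix({"C": 6, "O": 3, "Si": 2}, 4, n_rows=30)
        for j in range(5):
            assert np.all(C[:j, j] == 0)
            assert C[:, j].sum() == pytest.approx(1.0, abs=1e-5)
        narrow = natural_abundance_matrix({"C": 6, "O": 3, "Si": 2}, 4, n_rows=5)
        assert (narrow.sum(axis=0) <= 1 + 1e-9).all()

    def test_negative_atom_count_rejected(self):
        with pytest.raises(ValueError, match="negative atom"):
            natural_abundance_matrix({"C": -1}, 2)


class TestCorrectMid:
    formula = {"C": 8, "H": 21, "O": 4, "Si": 2}

    def test_roundtrip_recovers_known_mid(self):
        C = natural_abundance_matrix(self.formula, 4, n_rows=8)
        m = np.array([0.3, 0.0, 0.0, 0.0, 0.7])
        spec = IsotopologueSpectrum("succinate", self.formula, 4,
                                    tuple(2e5 * (C @ m)))
        res = correct_mid(spec, C)
        assert np.abs(np.asarray(res.mid) - m).max() < 1e-8
        assert res.fractional_labelling == pytest.approx(0.7)

    def test_unlabelled_sample_corrects_to_pure_m0(self):
        C = natural_abundance_matrix(self.formula, 4, n_rows=8)
        m0 = np.array([1.0, 0, 0, 0, 0])
        spec = IsotopologueSpectrum("succinate", self.formula, 4,
                                    tuple(1e5 * (C @ m0)))
        res = correct_mid(spec, C)
        assert res.mid[0] >= 0.99
        assert res.fractional_labelling == pytest.approx(0.0, abs=1e-6)

    def test_fully_labelled_has_unit_fractional_labelling(self):
        C = natural_abundance_matrix(self.formula, 4, n_rows=9)
        m = np.array([0.0, 0, 0, 0, 1.0])
        spec = IsotopologueSpectrum("succinate", self.formula, 4,
                                    tuple(1e5 * (C @ m)))
        assert correct_mid(spec, C).fractional_labelling == pytest.approx(1.0)

    def test_mid_normalised_and_nonnegative_under_noise(self):
        rng = np.random.default_rng(0)
        C = natural_abundance_matrix(self.formula, 4, n_rows=8)
        m = np.array([0.5, 0.1, 0.1, 0.1, 0.2])
        y = (C @ m) * rng.lognormal(0, 0.1, 8)
        res = correct_mid(IsotopologueSpectrum("x", self.formula, 4, tuple(y)), C)
        assert min(res.mid) >= 0
        assert sum(res.mid) == pytest.approx(1.0, abs=1e-9)
        assert 0 <= res.fractional_labelling <= 1

    def test_zero_spectrum_rejected(self):
        C = natural_abundance_matrix(self.formula, 4, n_rows=5)
        with pytest.raises(ValueError, match="all-zero"):
            correct_mid(IsotopologueSpectrum("x", self.formula, 4, (0.0,) * 5), C)


class TestSplit:
    def test_quarter_fraction(self):
        assert labelled_unlabelled_split(100, 0.25) == (25, 75)

    def test_boundaries(self):
        assert labelled_unlabelled_split(40, 0.0) == (0, 40)
        assert labelled_unlabelled_split(40, 1.0) == (40, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            labelled_unlabelled_split(10, 1.5)


class TestNormalise:
    def test_is_only(self):
        raw = pd.DataFrame({"s1": [100.0]}, index=["m1"])
        out = normalize_metabolites(raw, pd.Series({"s1": 50.0}))
        assert out.loc["m1", "s1"] == pytest.approx(2.0)
        assert out.attrs["normalisation"] == "IS-normalised"

    def test_scaling_sample_is_absorbed(self):
        # a sample-wide instrument-response factor cancels against the
        # internal standard, which scales with it
        raw = pd.DataFrame({"s1": [100.0, 30.0], "s2": [300.0, 90.0]},
                           index=["m1", "m2"])
        is_ = pd.Series({"s1": 50.0, "s2": 150.0})
        out = normalize_metabolites(raw, is_)
        assert np.allclose(out["s1"], out["s2"])

    def test_is_tic_mode_divides_by_both(self):
        raw = pd.DataFrame({"s1": [100.0]}, index=["m1"])
        out = normalize_metabolites(raw, pd.Series({"s1": 50.0}),
                                    pd.Series({"s1": 4.0}), mode="is+tic")
        assert out.loc["m1", "s1"] == pytest.approx(0.5)
        assert out.attrs["normalisation"] == "IS+TIC-normalised"

    def test_two_by_two_hand_computation(self):
        raw = pd.DataFrame({"s1": [10.0, 20.0], "s2": [8.0, 4.0]},
                           index=["m1", "m2"])
        out = normalize_metabolites(raw, pd.Series({"s1": 2.0, "s2": 4.0}))
        assert np.allclose(out.to_numpy(), [[5.0, 2.0], [10.0, 1.0]])

    def test_zero_internal_standard_rejected(self):
        raw = pd.DataFrame({"s1": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            normalize_metabolites(raw, pd.Series({"s1": 0.0}))


class TestStatsAndRatios:
    def _sheet(self, n=3):
        rows = [{"sample_id": f"c{i}", "genotype": "control"} for i in range(n)]
        rows += [{"sample_id": f"k{i}", "genotype": "dKO"} for i in range(n)]
        return pd.DataFrame(rows)

    def test_noiseless_sevenfold(self):
        table = pd.DataFrame(
            {"c0": [1.0], "c1": [1.0], "c2": [1.0],
             "k0": [7.0], "k1": [7.0], "k2": [7.0]},
            index=["glutamine"],
        )
        out = metabolite_stats(table, self._sheet()).set_index("metabolite")
        assert out.loc["glutamine", "fold_change"] == pytest.approx(7.0)

    def test_identical_groups_p_one(self):
        table = pd.DataFrame(
            {"c0": [1.0], "c1": [2.0], "c2": [3.0],
             "k0": [1.0], "k1": [2.0], "k2": [3.0]},
            index=["m"],
        )
        out = metabolite_stats(table, self._sheet())
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_fold_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.lognormal(0, 1, size=(5, 6)),
            index=[f"m{i}" for i in range(5)],
            columns=[f"c{i}" for i in range(3)] + [f"k{i}" for i in range(3)],
        )
        a = metabolite_stats(table, self._sheet())["fold_change"]
        b = metabolite_stats(table * 17.3, self._sheet())["fold_change"]
        assert np.allclose(a, b)

    def test_ratio_pairs_elementwise(self):
        table = pd.DataFrame(
            {"s1": [6.0, 2.0], "s2": [0.0, 4.0], "s3": [9.0, 3.0], "s4": [1.0, 2.0]},
            index=["akg", "succinate"],
        )
        r = ratio_pairs(table, "akg", "succinate")
        assert np.allclose(r.to_numpy(), [3.0, 0.0, 3.0, 0.5])

    def test_ratio_zero_denominator_rejected(self):
        table = pd.DataFrame({"s1": [6.0, 0.0]}, index=["akg", "succinate"])
        with pytest.raises(ValueError, match="denominator"):
            ratio_pairs(table, "akg", "succinate")


class TestRowLog2Deviation:
    def test_two_entry_row(self):
        out = row_log2_deviation(pd.DataFrame({"a": [2.0], "b": [8.0]}, index=["m"]))
        assert np.allclose(out.to_numpy(), [[np.log2(0.4), np.log2(1.6)]])

    def test_constant_row_is_zero(self):
        out = row_log2_deviation(pd.DataFrame({"a": [3.0], "b": [3.0]}, index=["m"]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_mean_identity(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.lognormal(0, 1, (4, 6)))
        out = row_log2_deviation(mat)
        assert np.allclose((2.0 ** out).mean(axis=1), 1.0)

    def test_nonpositive_entries_need_floor(self):
        mat = pd.DataFrame({"a": [0.0], "b": [2.0]}, index=["m"])
        with pytest.raises(ValueError):
            row_log2_deviation(mat)
        out = row_log2_deviation(mat, floor=0.5)
        assert np.isfinite(out.to_numpy()).all()
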