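"""Ground-truth generator: determinism, planted structure, kinetic identities."""

import numpy as np
import pandas as pd
import pytest

from turnomix.clip import call_targets_hitsclip, scan_motif
from turnomix.metabolism import correct_mid, natural_abundance_matrix
from turnomix.stability import LabelingDesign
from turnomix.synthetic import (
    ARE_MOTIF_DNA,
    METABOLITES,
    SimulationConfig,
    build_sample_sheet,
    expected_fraction_means,
    simulate_fraction_counts,
    simulate_kinetics,
    simulate_metabolomics,
    simulate_ribo_counts,
    simulate_utrs_and_crosslinks,
)


class TestKinetics:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_genes=100, frac_direct=0.0, frac_indirect=0.0)
        a = simulate_kinetics(cfg, seed=7).table
        b = simulate_kinetics(cfg, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_exact_class_counts(self):
        cfg = SimulationConfig(n_genes=103, frac_direct=0.1, frac_indirect=0.25)
        t = simulate_kinetics(cfg, seed=1).table
        counts = t["effect_class"].value_counts()
        assert counts["direct_target"] == 10  # floor(0.1 * 103)
        assert counts["indirect_transcriptional"] == 25

    def test_half_life_median_near_target(self):
        cfg = SimulationConfig(n_genes=5000)
        t = simulate_kinetics(cfg, seed=2).table
        med = np.median(np.log(2) / t["delta"])
        assert abs(med / cfg.t_half_median - 1) < 0.1

    def test_direct_targets_are_stabilised_and_translated(self):
        cfg = SimulationConfig(n_genes=200)
        t = simulate_kinetics(cfg, seed=3).table
        direct = t[t["effect_class"] == "direct_target"]
        assert (direct["delta_mult_dKO"] < 1).all()
        assert (direct["te_mult_dKO"] > 1).all()
        indirect = t[t["effect_class"] == "indirect_transcriptional"]
        assert (indirect["alpha_mult_dKO"] > 1).all()

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            simulate_kinetics(SimulationConfig(n_genes=10, frac_direct=0.7,
                                               frac_indirect=0.5), seed=0)
        with pytest.raises(ValueError):
            simulate_kinetics(SimulationConfig(n_genes=0), seed=0)


class TestFractionCounts:
    def test_expected_means_partition_total_exactly(self):
        cfg = SimulationConfig(n_genes=50)
        truth = simulate_kinetics(cfg, seed=4)
        m = expected_fraction_means(truth, LabelingDesign(), "control", "b1",
                                    apply_fraction_scale=False)
        assert np.allclose(m["new"] + m["pre"], m["total"], rtol=1e-12)
        scaled = expected_fraction_means(truth, LabelingDesign(), "control", "b1")
        assert np.allclose(cfg.c_l_true * scaled["new"] + cfg.c_u_true * scaled["pre"],
                           scaled["total"], rtol=1e-12)

    def test_unit_decay_rate_gives_half_labelled_share(self):
        cfg = SimulationConfig(n_genes=5, c_l_true=1.0, c_u_true=1.0,
                               batch_log2_sd=0.0)
        truth = simulate_kinetics(cfg, seed=5)
        truth.table["delta"] = np.log(2.0)  # half-life of exactly 1 h
        m = expected_fraction_means(truth, LabelingDesign(t_label=1.0),
                                    "control", "b1")
        share = m["new"] / m["total"]
        assert np.allclose(share, 0.5)

    def test_fast_decay_limit_saturates_labelling(self):
        cfg = SimulationConfig(n_genes=3, c_l_true=1.0, c_u_true=1.0,
                               batch_log2_sd=0.0)
        truth = simulate_kinetics(cfg, seed=5)
        truth.table["delta"] = 50.0  # tiny half-life vs 1 h pulse
        m = expected_fraction_means(truth, LabelingDesign(), "control", "b1")
        assert np.allclose(m["new"] / m["total"], 1.0, atol=1e-12)
        assert np.allclose(m["pre"], 0.0, atol=1e-9)

    def test_zero_dispersion_counts_match_theta_closed_form(self):
        """Poisson draws at depth 1e6: new/total mean ratio ~ theta within 2%."""
        cfg = SimulationConfig(n_genes=200, dispersion=0.0, depth=1e6,
                               size_factor_log2_sd=0.0, c_l_true=1.0,
                               c_u_true=1.0, batch_log2_sd=0.0,
                               frac_direct=0.0, frac_indirect=0.0)
        truth = simulate_kinetics(cfg, seed=6)
        samples = build_sample_sheet(cfg)
        counts = simulate_fraction_counts(truth, LabelingDesign(), samples, seed=6)
        total = counts["total"].mean(axis=1)
        new = counts["new"].mean(axis=1)
        theta = -np.expm1(-truth.table["delta"] * 1.0)
        well_covered = total > 2000
        ratio = (new / total)[well_covered] / theta[well_covered]
        assert np.median(np.abs(ratio - 1)) < 0.02

    def test_counts_are_seed_deterministic(self):
        cfg = SimulationConfig(n_genes=40, depth=1e4)
        truth = simulate_kinetics(cfg, seed=8)
        samples = build_sample_sheet(cfg)
        a = simulate_fraction_counts(truth, LabelingDesign(), samples, seed=8)
        b = simulate_fraction_counts(truth, LabelingDesign(), samples, seed=8)
        for assay in a:
            pd.testing.assert_frame_equal(a[assay], b[assay])


class TestRiboCounts:
    def test_doubled_te_doubles_footprint_abundance_ratio(self):
        cfg = SimulationConfig(n_genes=300, depth=1e6, dispersion=0.0,
                               size_factor_log2_sd=0.0, batch_log2_sd=0.0,
                               frac_direct=0.1, frac_indirect=0.0)
        truth = simulate_kinetics(cfg, seed=9)
        # isolate the translation effect: no stability change in dKO
        truth.table["delta_mult_dKO"] = 1.0
        samples = build_sample_sheet(cfg)
        ribo = simulate_ribo_counts(truth, samples, seed=9)
        ctrl = ribo[[c for c in ribo if c.startswith("control")]].mean(axis=1)
        dko = ribo[[c for c in ribo if c.startswith("dKO")]].mean(axis=1)
        direct = truth.table["effect_class"] == "direct_target"
        covered = ctrl > 500
        # footprint depth is renormalised per library, so compare the
        # direct-target ratio with the null-gene ratio
        rel = (dko / ctrl)[direct & covered].median() / (dko / ctrl)[
            ~direct & covered
        ].median()
        assert rel == pytest.approx(2.0, rel=0.05)

    def test_footprints_track_abundance_when_te_constant(self):
        cfg = SimulationConfig(n_genes=300, depth=1e6, te_log_sigma=0.0,
                               frac_direct=0.0, frac_indirect=0.0)
        truth = simulate_kinetics(cfg, seed=10)
        samples = build_sample_sheet(cfg)
        ribo = simulate_ribo_counts(truth, samples, seed=10)
        col = "control_b1_r1_ribo"
        A = truth.table["alpha"] / truth.table["delta"]
        rho = pd.Series(ribo[col]).corr(A * truth.table[f"batch_b1"],
                                        method="spearman")
        assert rho > 0.95

    def test_zero_te_gives_zero_counts(self):
        cfg = SimulationConfig(n_genes=20, frac_direct=0.0, frac_indirect=0.0)
        truth = simulate_kinetics(cfg, seed=11)
        truth.table.loc[truth.gene_ids[0], "te"] = 0.0
        samples = build_sample_sheet(cfg)
        ribo = simulate_ribo_counts(truth, samples, seed=11)
        assert (ribo.loc[truth.gene_ids[0]] == 0).all()


class TestUtrsAndCrosslinks:
    def test_planted_motif_sits_at_recorded_offset(self):
        cfg = SimulationConfig(n_genes=60)
        truth = simulate_kinetics(cfg, seed=12)
        utrs = simulate_utrs_and_crosslinks(truth, seed=12)
        planted = utrs["planted"].set_index("gene_id")
        bound = planted[planted["bound"]]
        assert len(bound) > 0
        for gene, row in bound.iterrows():
            seq = utrs["sequences"][gene]
            off = int(row["motif_offset"])
            assert seq[off:off + len(ARE_MOTIF_DNA)] == ARE_MOTIF_DNA

    def test_bed_fasta_coordinates_consistent(self):
        cfg = SimulationConfig(n_genes=40)
        truth = simulate_kinetics(cfg, seed=13)
        utrs = simulate_utrs_and_crosslinks(truth, seed=13)
        ann = utrs["annotation"].set_index("gene_id")
        planted = utrs["planted"].set_index("gene_id")
        for gene, row in planted[planted["bound"]].iterrows():
            utr_start = ann.loc[gene, "start"]
            genomic = int(row["genomic_position"])
            assert genomic - utr_start == int(row["motif_offset"])
            assert ann.loc[gene, "start"] <= genomic < ann.loc[gene, "end"]
        # every UTR sequence length matches its interval
        for gene, row in ann.iterrows():
            assert len(utrs["sequences"][gene]) == row["end"] - row["start"]

    def test_replicated_planted_sites_are_called_targets(self):
        cfg = SimulationConfig(n_genes=120)
        truth = simulate_kinetics(cfg, seed=14)
        utrs = simulate_utrs_and_crosslinks(truth, seed=14)
        targets = call_targets_hitsclip(utrs["hitsclip"], utrs["annotation"])
        bound = set(utrs["planted"].loc[utrs["planted"]["bound"], "gene_id"])
        sensitivity = len(targets & bound) / len(bound)
        assert sensitivity >= 0.95
        false_calls = targets - bound
        assert len(false_calls) <= max(1, 0.05 * len(targets))

    def test_motif_scan_finds_all_bound_genes(self):
        cfg = SimulationConfig(n_genes=80)
        truth = simulate_kinetics(cfg, seed=15)
        utrs = simulate_utrs_and_crosslinks(truth, seed=15)
        hits = scan_motif(utrs["sequences"]).set_index("gene_id")
        bound = utrs["planted"].set_index("gene_id")["bound"]
        assert hits.loc[bound[bound].index, "contains"].all()


class TestMetabolomics:
    def test_noiseless_fold_is_exact(self):
        cfg = SimulationConfig()
        met = simulate_metabolomics(cfg, seed=16, noise_sd=0.0,
                                    folds={"glutamine": 7.0})
        table = met["table"] / met["internal_standard"]
        sheet = met["samples"].set_index("sample_id")
        ctrl = table.loc["glutamine", sheet["genotype"] == "control"].mean()
        dko = table.loc["glutamine", sheet["genotype"] == "dKO"].mean()
        assert dko / ctrl == pytest.approx(7.0, rel=1e-12)

    def test_fifty_two_metabolites_emitted(self):
        met = simulate_metabolomics(SimulationConfig(), seed=17)
        assert len(met["table"]) == len(METABOLITES) == 52

    def test_true_mids_roundtrip_through_correction(self):
        """Noiseless spectra corrected by the metabolism module return the
        planted MID to <= 1e-6."""
        met = simulate_metabolomics(SimulationConfig(tracing_replicates=1),
                                    seed=18, noise_sd=0.0)
        for spec in met["spectra"]:
            name, genotype, rep = spec.metabolite.split("|")
            true = np.asarray(met["true_mids"][(name, genotype, 1)])
            C = natural_abundance_matrix(spec.fragment_formula, spec.n_tracer,
                                         n_rows=len(spec.raw_counts))
            res = correct_mid(spec, C)
            assert np.abs(np.asarray(res.mid) - true).max() < 1e-6

    def test_spectra_nonnegative_and_seeded(self):
        a = simulate_metabolomics(SimulationConfig(), seed=19)
        b = simulate_metabolomics(SimulationConfig(), seed=19)
        assert all(min(s.raw_counts) >= 0 for s in a["spectra"])
        assert [s.raw_counts for s in a["spectra"]] == [
            s.raw_counts for s in b["spectra"]
        ]
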