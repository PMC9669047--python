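"""Synthetic multiomic data with known ground truth.

Generates every input the pipeline consumes — the four count-based assays
(total, newly-synthesised, pre-existing, ribosome-protected), 3'UTR
annotation and sequences with planted AU-rich elements, crosslink-site
tables, an LC-MS metabolite table and GC-MS isotopologue spectra — from a
single seeded configuration, so every downstream stage is testable without
any download.

The kinetic model is steady-state first-order turnover: a gene with
synthesis rate ``alpha`` (transcripts/h) and decay rate ``delta`` (1/h) has
abundance ``A = alpha / delta`` and, after a 4sU pulse of ``t`` hours, a
labelled share ``theta = 1 - exp(-delta * t)``.  Counts are negative
binomial around fraction-specific means; the labelled and unlabelled
libraries carry their own scale factors (``1/c_l``, ``1/c_u``) so that the
correction-factor regression has something real to estimate.

Perturbation classes mirror a double-knockout of an mRNA-destabilising
RNA-binding protein family: *direct targets* decay slower and/or translate
better in the knockout and carry an ARE with crosslink pileups in their
3'UTR; *indirect* genes are transcribed more; *null* genes are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _io
from .metabolism import IsotopologueSpectrum, natural_abundance_matrix
from .stability import LabelingDesign

__all__ = [
    "SimulationConfig",
    "KineticGroundTruth",
    "simulate_kinetics",
    "build_sample_sheet",
    "expected_fraction_means",
    "simulate_fraction_counts",
    "simulate_ribo_counts",
    "simulate_utrs_and_crosslinks",
    "simulate_conservation",
    "simulate_metabolomics",
    "mode_archetypes",
    "simulate_mode_zscores",
    "SyntheticBundle",
    "simulate_bundle",
    "write_bundle",
    "METABOLITES",
    "PLANTED_METABOLITE_FOLDS",
    "TRACING_FRAGMENTS",
]

ARE_MOTIF_DNA = "TATTTATT"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the study's data structure.

    Counts: ~1e6 expected reads per fraction library, NB dispersion 0.05,
    two batches with log-normal batch factors (sd 0.2 on log2), fraction
    scale factors (c_l, c_u) = (1.6, 0.8).  Effects: 5% direct targets
    (2x half-life and 2x translation efficiency in dKO), 10% indirect
    (2x transcription in dKO).  Half-lives log-normal with median 4 h.
    """

    n_genes: int = 2000
    frac_direct: float = 0.05
    frac_indirect: float = 0.10
    # kinetic parameter distributions (log-normal; medians + log-sigmas)
    t_half_median: float = 4.0  # hours
    t_half_log_sigma: float = 0.7
    alpha_median: float = 10.0
    alpha_log_sigma: float = 1.0
    te_median: float = 1.0
    te_log_sigma: float = 0.4
    dispersion: float = 0.05
    # effect sizes (dKO multipliers)
    direct_delta_mult: float = 0.5
    direct_te_mult: float = 2.0
    indirect_alpha_mult: float = 2.0
    # experimental design
    genotypes: tuple[str, ...] = ("control", "dKO")
    batches: tuple[str, ...] = ("b1", "b2")
    replicates_per_batch: int = 2
    batch_log2_sd: float = 0.2
    depth: float = 1e6
    size_factor_log2_sd: float = 0.1
    c_l_true: float = 1.6
    c_u_true: float = 0.8
    # CLIP / UTR structure
    utr_length_median: float = 800.0
    utr_length_log_sigma: float = 0.6
    utr_min_length: int = 60
    clip_replicates: int = 3
    background_sites_per_replicate: int | None = None  # default n_genes // 2
    planted_fdr_beta: tuple[float, float] = (1.0, 80.0)
    planted_reads_mean: float = 20.0
    background_reads_mean: float = 2.0
    # metabolomics
    metabolite_replicates: int = 6
    metabolite_log2_noise_sd: float = 0.15
    tracing_replicates: int = 4


@dataclass
class KineticGroundTruth:
    """Per-gene truth table plus the design-level constants that shaped it.

    The table holds ``alpha, delta, te, effect_class, dispersion``, dKO
    multipliers and one ``batch_<b>`` log-normal factor per batch.
    """

    table: pd.DataFrame
    config: SimulationConfig
    seed: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def simulate_kinetics(config: SimulationConfig, seed: int) -> KineticGroundTruth:
    """Draw per-gene kinetic parameters and effect classes.

    Class counts are exact: ``floor(frac * n_genes)`` genes per class,
    assigned by a seeded permutation.
    """
    G = config.n_genes
    if G <= 0:
        raise ValueError("n_genes must be positive")
    if config.frac_direct + config.frac_indirect > 1:
        raise ValueError("class fractions must sum to <= 1")
    rng = _rng(seed, 0)
    genes = pd.Index([f"g{i:05d}" for i in range(G)], name="gene_id")
    delta = np.log(2) / config.t_half_median * np.exp(
        rng.normal(0.0, config.t_half_log_sigma, G)
    )
    alpha = config.alpha_median * np.exp(rng.normal(0.0, config.alpha_log_sigma, G))
    te = config.te_median * np.exp(rng.normal(0.0, config.te_log_sigma, G))

    n_direct = int(np.floor(config.frac_direct * G))
    n_indirect = int(np.floor(config.frac_indirect * G))
    order = rng.permutation(G)
    effect = np.full(G, "null", dtype=object)
    effect[order[:n_direct]] = "direct_target"
    effect[order[n_direct:n_direct + n_indirect]] = "indirect_transcriptional"

    table = pd.DataFrame(
        {
            "alpha": alpha,
            "delta": delta,
            "te": te,
            "effect_class": effect,
            "dispersion": config.dispersion,
            "alpha_mult_dKO": np.where(
                effect == "indirect_transcriptional", config.indirect_alpha_mult, 1.0
            ),
            "delta_mult_dKO": np.where(
                effect == "direct_target", config.direct_delta_mult, 1.0
            ),
            "te_mult_dKO": np.where(
                effect == "direct_target", config.direct_te_mult, 1.0
            ),
        },
        index=genes,
    )
    for b in config.batches:
        table[f"batch_{b}"] = 2.0 ** rng.normal(0.0, config.batch_log2_sd, G)
    return KineticGroundTruth(table=table, config=config, seed=seed)


def build_sample_sheet(config: SimulationConfig,
                       assays: Sequence[str] = ("total", "new", "pre", "ribo")) -> pd.DataFrame:
    """One row per library: sample_id, assay, genotype, batch, replicate."""
    rows = []
    for genotype in config.genotypes:
        for batch in config.batches:
            for rep in range(1, config.replicates_per_batch + 1):
                for assay in assays:
                    rows.append(
                        {
                            "sample_id": f"{genotype}_{batch}_r{rep}_{assay}",
                            "assay": assay,
                            "genotype": genotype,
                            "batch": batch,
                            "replicate": f"r{rep}",
                        }
                    )
    return pd.DataFrame(rows)


def _gene_state(truth: KineticGroundTruth, genotype: str, batch: str):
    """Genotype/batch-adjusted (abundance, delta, te) vectors."""
    t = truth.table
    dko = genotype != "control"
    alpha = t["alpha"].to_numpy() * t[f"batch_{batch}"].to_numpy()
    delta = t["delta"].to_numpy().copy()
    te = t["te"].to_numpy().copy()
    if dko:
        alpha = alpha * t["alpha_mult_dKO"].to_numpy()
        delta = delta * t["delta_mult_dKO"].to_numpy()
        te = te * t["te_mult_dKO"].to_numpy()
    return alpha / delta, delta, te


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB with var = mu + d*mu^2; d = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    out = np.empty(mean.shape, dtype=np.int64)
    d = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    pois = d == 0
    out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / d[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


def expected_fraction_means(
    truth: KineticGroundTruth,
    design: LabelingDesign,
    genotype: str,
    batch: str,
    size_factor: float = 1.0,
    apply_fraction_scale: bool = True,
) -> pd.DataFrame:
    """Expected (total, new, pre) means for one biological sample.

    Before the fraction scale factors are applied,
    ``new + pre == total`` holds exactly for every gene; with them,
    ``c_l * new + c_u * pre == total``.
    """
    cfg = truth.config
    A, delta, _ = _gene_state(truth, genotype, batch)
    theta = -np.expm1(-delta * design.t_label)
    p = design.separation_purity
    s = size_factor * cfg.depth / A.sum()
    total = s * A
    new = s * A * theta * p
    pre = s * (A * (1 - theta) + A * theta * (1 - p))
    if apply_fraction_scale:
        new = new / cfg.c_l_true
        pre = pre / cfg.c_u_true
    return pd.DataFrame(
        {"total": total, "new": new, "pre": pre}, index=truth.gene_ids
    )


def simulate_fraction_counts(
    truth: KineticGroundTruth,
    design: LabelingDesign,
    samples: pd.DataFrame,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """NB count matrices for the total/new/pre fraction libraries."""
    cfg = truth.config
    rng = _rng(seed, 1)
    disp = truth.table["dispersion"].to_numpy()
    mats: dict[str, dict[str, np.ndarray]] = {"total": {}, "new": {}, "pre": {}}
    bio = samples.loc[samples["assay"].isin(["total", "new", "pre"])]
    for (genotype, batch, rep), grp in bio.groupby(["genotype", "batch", "replicate"],
                                                   sort=True):
        jitter = {a: 2.0 ** rng.normal(0.0, cfg.size_factor_log2_sd) for a in
                  ("total", "new", "pre")}
        means = expected_fraction_means(truth, design, genotype, batch)
        for _, row in grp.iterrows():
            assay = row["assay"]
            mu = means[assay].to_numpy() * jitter[assay]
            mats[assay][row["sample_id"]] = _nb_draw(rng, mu, disp)
    out = {}
    for assay, cols in mats.items():
        if not cols:
            raise ValueError(f"no samples for assay {assay!r}")
        df = pd.DataFrame(cols, index=truth.gene_ids)
        if (df.sum(axis=0) == 0).any():
            raise ValueError("a library drew zero total counts")
        out[assay] = df
    return out


def simulate_ribo_counts(
    truth: KineticGroundTruth,
    samples: pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """NB ribosome-footprint counts: mean proportional to abundance x TE."""
    cfg = truth.config
    rng = _rng(seed, 2)
    disp = truth.table["dispersion"].to_numpy()
    cols = {}
    ribo = samples.loc[samples["assay"] == "ribo"]
    for _, row in ribo.sort_values("sample_id").iterrows():
        A, _, te = _gene_state(truth, row["genotype"], row["batch"])
        load = A * te
        s = cfg.depth / load.sum() * 2.0 ** rng.normal(0.0, cfg.size_factor_log2_sd)
        cols[row["sample_id"]] = _nb_draw(rng, s * load, disp)
    return pd.DataFrame(cols, index=truth.gene_ids)


def simulate_utrs_and_crosslinks(
    truth: KineticGroundTruth,
    seed: int,
) -> dict:
    """3'UTR annotation + sequences with planted AREs, and crosslink tables.

    Direct-target genes carry one planted ``TATTTATT`` motif, wholly inside
    their 3'UTR, at a recorded offset; crosslink read pileups concentrate at
    the planted position (identical across replicates, site FDR ~
    Beta(1, 80)), while background sites land at random UTR positions with
    uniform FDR.  Returns annotation, sequences, per-replicate HITS-CLIP
    style tables, two antibody-grouped iCLIP style tables, and the planted
    truth.
    """
    cfg = truth.config
    rng = _rng(seed, 3)
    G = len(truth.gene_ids)
    lengths = np.maximum(
        cfg.utr_min_length,
        np.round(cfg.utr_length_median * np.exp(
            rng.normal(0.0, cfg.utr_length_log_sigma, G))).astype(int),
    )
    gap = 100
    starts = np.concatenate(([0], np.cumsum(lengths + gap)[:-1]))
    annotation = pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "chrom": "chrS",
            "start": starts,
            "end": starts + lengths,
            "strand": "+",
            "feature": "3UTR",
            "length": lengths,
        }
    )

    alphabet = np.array(list("ACGT"))
    bound = truth.table["effect_class"].to_numpy() == "direct_target"
    sequences: dict[str, str] = {}
    motif_offset = np.full(G, -1, dtype=int)
    m = len(ARE_MOTIF_DNA)
    for i, gene in enumerate(truth.gene_ids):
        seq = rng.integers(0, 4, lengths[i])
        s = "".join(alphabet[seq])
        if bound[i]:
            if lengths[i] < m:
                raise ValueError(f"UTR of {gene} shorter than the motif")
            off = int(rng.integers(0, lengths[i] - m + 1))
            s = s[:off] + ARE_MOTIF_DNA + s[off + m:]
            motif_offset[i] = off
        sequences[str(gene)] = s

    planted_pos = np.where(bound, starts + np.maximum(motif_offset, 0), -1)
    a, b = cfg.planted_fdr_beta
    n_bg = (cfg.background_sites_per_replicate
            if cfg.background_sites_per_replicate is not None else G // 2)

    def one_table() -> pd.DataFrame:
        rows_pos, rows_reads, rows_fdr = [], [], []
        for i in np.flatnonzero(bound):
            rows_pos.append(planted_pos[i])
            rows_reads.append(5 + rng.poisson(cfg.planted_reads_mean))
            rows_fdr.append(rng.beta(a, b))
        gene_pick = rng.integers(0, G, n_bg)
        for gi in gene_pick:
            rows_pos.append(int(starts[gi] + rng.integers(0, lengths[gi])))
            rows_reads.append(1 + rng.poisson(cfg.background_reads_mean))
            rows_fdr.append(rng.uniform())
        return pd.DataFrame(
            {
                "chrom": "chrS",
                "position": rows_pos,
                "strand": "+",
                "read_count": rows_reads,
                "fdr": rows_fdr,
            }
        )

    hitsclip = [one_table() for _ in range(cfg.clip_replicates)]
    iclip = {"antibody1": one_table(), "antibody2": one_table()}
    planted = pd.DataFrame(
        {
            "gene_id": truth.gene_ids,
            "bound": bound,
            "motif_offset": motif_offset,
            "genomic_position": planted_pos,
        }
    )
    return {
        "annotation": annotation,
        "sequences": sequences,
        "hitsclip": hitsclip,
        "iclip": iclip,
        "planted": planted,
    }


def simulate_conservation(utrs: dict, seed: int, motif_boost: float = 2.0) -> pd.DataFrame:
    """Per-base phyloP-like scores: N(0, 0.5) noise, elevated over AREs."""
    rng = _rng(seed, 4)
    ann = utrs["annotation"]
    planted = utrs["planted"].set_index("gene_id")
    rows = []
    for _, r in ann.iterrows():
        n = int(r["length"])
        score = rng.normal(0.0, 0.5, n)
        off = int(planted.loc[r["gene_id"], "motif_offset"])
        if off >= 0:
            score[off:off + len(ARE_MOTIF_DNA)] += motif_boost
        pos = np.arange(r["start"], r["end"])
        rows.append(pd.DataFrame(
            {"chrom": r["chrom"], "start": pos, "end": pos + 1, "score": score}
        ))
    return pd.concat(rows, ignore_index=True)


# 52 metabolites spanning the pathways profiled by LC-MS.
METABOLITES: tuple[str, ...] = (
    "glucose-6-phosphate", "fructose-6-phosphate", "fructose-1,6-bisphosphate",
    "dihydroxyacetone phosphate", "glyceraldehyde-3-phosphate",
    "3-phosphoglycerate", "phosphoenolpyruvate", "pyruvate", "lactate",
    "ribose-5-phosphate", "ribulose-5-phosphate", "sedoheptulose-7-phosphate",
    "erythrose-4-phosphate", "6-phosphogluconate",
    "citrate", "isocitrate", "alpha-ketoglutarate", "succinate", "fumarate",
    "malate", "oxaloacetate", "2-hydroxyglutarate",
    "acetyl-CoA", "ATP", "ADP", "AMP", "NAD+", "NADH", "GTP", "UTP", "CTP",
    "glutamine", "glutamate", "aspartate", "asparagine", "alanine", "serine",
    "glycine", "proline", "arginine", "lysine", "methionine", "threonine",
    "leucine", "isoleucine", "valine", "phenylalanine", "tyrosine",
    "tryptophan", "S-adenosylmethionine", "S-adenosylhomocysteine",
    "glutathione",
)

# dKO : control fold changes planted in the LC-MS table; glutamine shows the
# largest increase (over seven-fold), alpha-ketoglutarate about three-fold.
PLANTED_METABOLITE_FOLDS: Mapping[str, float] = {
    "glutamine": 7.5,
    "alpha-ketoglutarate": 3.0,
    "2-hydroxyglutarate": 1.8,
    "glutamate": 1.4,
    "citrate": 1.3,
    "isocitrate": 1.3,
    "malate": 1.3,
    "ribose-5-phosphate": 1.6,
    "sedoheptulose-7-phosphate": 1.6,
    "S-adenosylmethionine": 1.5,
}

# (fragment formula excluding tracer carbons, n tracer carbons); TBDMS-style
# derivative fragments, hence the Si and the large H/C payload.
TRACING_FRAGMENTS: Mapping[str, tuple[Mapping[str, int], int]] = {
    "pyruvate": ({"C": 6, "H": 15, "N": 1, "O": 3, "Si": 1}, 3),
    "lactate": ({"C": 8, "H": 21, "O": 3, "Si": 2}, 3),
    "serine": ({"C": 8, "H": 22, "N": 1, "O": 3, "Si": 2}, 3),
    "glutamate": ({"C": 14, "H": 34, "N": 1, "O": 4, "Si": 2}, 5),
    "alpha-ketoglutarate": ({"C": 7, "H": 17, "N": 1, "O": 5, "Si": 1}, 5),
    "succinate": ({"C": 8, "H": 21, "O": 4, "Si": 2}, 4),
    "fumarate": ({"C": 8, "H": 19, "O": 4, "Si": 2}, 4),
    "malate": ({"C": 14, "H": 35, "O": 5, "Si": 3}, 4),
    "citrate": ({"C": 14, "H": 33, "O": 7, "Si": 3}, 6),
}

# true MIDs by genotype for the glutamine-tracing simulation: dKO shows more
# label in glutamine-derived TCA intermediates (M+4/M+5 heavy species).
_TRACING_MIDS: Mapping[str, dict[str, tuple[float, ...]]] = {
    "glutamate": {
        "control": (0.55, 0.02, 0.03, 0.05, 0.05, 0.30),
        "dKO": (0.35, 0.02, 0.03, 0.05, 0.05, 0.50),
    },
    "alpha-ketoglutarate": {
        "control": (0.50, 0.02, 0.03, 0.05, 0.05, 0.35),
        "dKO": (0.30, 0.02, 0.03, 0.05, 0.05, 0.55),
    },
    "succinate": {
        "control": (0.60, 0.02, 0.03, 0.05, 0.30),
        "dKO": (0.45, 0.02, 0.03, 0.05, 0.45),
    },
    "fumarate": {
        "control": (0.62, 0.02, 0.03, 0.05, 0.28),
        "dKO": (0.47, 0.02, 0.03, 0.05, 0.43),
    },
    "malate": {
        "control": (0.60, 0.02, 0.04, 0.06, 0.28),
        "dKO": (0.45, 0.02, 0.04, 0.06, 0.43),
    },
    "citrate": {
        "control": (0.58, 0.02, 0.03, 0.04, 0.25, 0.05, 0.03),
        "dKO": (0.43, 0.02, 0.03, 0.04, 0.40, 0.05, 0.03),
    },
    "pyruvate": {
        "control": (0.90, 0.02, 0.03, 0.05),
        "dKO": (0.90, 0.02, 0.03, 0.05),
    },
    "lactate": {
        "control": (0.88, 0.02, 0.03, 0.07),
        "dKO": (0.88, 0.02, 0.03, 0.07),
    },
    "serine": {
        "control": (0.92, 0.02, 0.03, 0.03),
        "dKO": (0.92, 0.02, 0.03, 0.03),
    },
}


def simulate_metabolomics(
    config: SimulationConfig,
    seed: int,
    noise_sd: float | None = None,
    folds: Mapping[str, float] | None = None,
) -> dict:
    """LC-MS metabolite table and GC-MS isotopologue spectra with truth.

    The LC-MS table plants the configured dKO:control fold changes
    (glutamine 7x, alpha-ketoglutarate 3x by default) over log-normal
    replicate noise; raw areas include a per-sample internal-standard scale
    so that normalisation is exercised.  Tracing spectra are built by
    convolving genotype-specific true MIDs with the natural-abundance
    correction matrix of each fragment, plus multiplicative noise.
    """
    rng = _rng(seed, 5)
    planted = PLANTED_METABOLITE_FOLDS if folds is None else folds
    sd = config.metabolite_log2_noise_sd if noise_sd is None else noise_sd
    n_rep = config.metabolite_replicates
    samples = []
    for genotype in config.genotypes:
        for r in range(1, n_rep + 1):
            samples.append({"sample_id": f"{genotype}_m{r}", "genotype": genotype})
    sheet = pd.DataFrame(samples)

    base = pd.Series(
        np.exp(rng.normal(0.0, 1.0, len(METABOLITES))), index=pd.Index(METABOLITES,
                                                                       name="metabolite")
    )
    is_signal = pd.Series(
        1000.0 * 2.0 ** rng.normal(0.0, 0.2, len(sheet)),
        index=sheet["sample_id"],
    )
    cols = {}
    for _, row in sheet.iterrows():
        fold = np.array(
            [planted.get(m, 1.0) if row["genotype"] != "control" else 1.0
             for m in METABOLITES]
        )
        noise = 2.0 ** rng.normal(0.0, sd, len(METABOLITES)) if sd > 0 else 1.0
        cols[row["sample_id"]] = base.to_numpy() * fold * noise * is_signal[row["sample_id"]]
    raw = pd.DataFrame(cols, index=base.index)
    tic = raw.sum(axis=0)

    spectra: list[IsotopologueSpectrum] = []
    true_mids: dict[tuple[str, str, int], tuple[float, ...]] = {}
    for met, (formula, n_tracer) in TRACING_FRAGMENTS.items():
        mids = _TRACING_MIDS[met]
        buffer = 3
        C = natural_abundance_matrix(formula, n_tracer, n_rows=n_tracer + 1 + buffer)
        for genotype in config.genotypes:
            mid = np.asarray(mids[genotype], dtype=float)
            mid = mid / mid.sum()
            for r in range(1, config.tracing_replicates + 1):
                scale = 1e5 * 2.0 ** rng.normal(0.0, 0.3)
                counts = scale * (C @ mid)
                if sd > 0:
                    counts = counts * 2.0 ** rng.normal(0.0, sd, counts.size)
                spectra.append(
                    IsotopologueSpectrum(
                        metabolite=f"{met}|{genotype}|r{r}",
                        fragment_formula=formula,
                        n_tracer=n_tracer,
                        raw_counts=tuple(float(c) for c in counts),
                    )
                )
                true_mids[(met, genotype, r)] = tuple(float(v) for v in mid)
    return {
        "table": raw,
        "internal_standard": is_signal,
        "tic": tic,
        "samples": sheet,
        "spectra": spectra,
        "true_mids": true_mids,
    }


def mode_archetypes() -> dict[str, tuple[float, float, float]]:
    """Five regulatory-mode archetypes over (z_new, z_stability, z_ribo)."""
    return {
        "stability_only": (0.0, 2.5, 0.0),
        "stability_translation": (0.0, 2.0, 2.0),
        "translation_dominant": (0.0, 0.0, 2.5),
        "transcription_translation": (2.0, 0.0, 2.0),
        "transcription_dominant": (2.5, 0.0, 0.0),
    }


def simulate_mode_zscores(
    n_per_cluster: int = 40,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """z-score matrix with five planted archetypes plus Gaussian noise."""
    rng = _rng(seed, 6)
    arch = mode_archetypes()
    rows, labels, ids = [], [], []
    i = 0
    for name, vec in arch.items():
        for _ in range(n_per_cluster):
            rows.append(np.asarray(vec) + rng.normal(0.0, noise_sd, 3))
            labels.append(name)
            ids.append(f"g{i:05d}")
            i += 1
    z = pd.DataFrame(rows, columns=["z_new", "z_stability", "z_ribo"],
                     index=pd.Index(ids, name="gene_id"))
    z["z_total"] = z[["z_new", "z_stability", "z_ribo"]].mean(axis=1) + rng.normal(
        0.0, noise_sd, len(z)
    )
    return z, pd.Series(labels, index=z.index, name="mode")


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    truth: KineticGroundTruth
    samples: pd.DataFrame
    counts: dict[str, pd.DataFrame]  # total/new/pre/ribo
    utrs: dict
    metabolomics: dict
    design: LabelingDesign
    seed: int


def simulate_bundle(
    config: SimulationConfig | None = None,
    seed: int = 0,
    design: LabelingDesign | None = None,
) -> SyntheticBundle:
    """Generate the full multiomic bundle from one seed."""
    config = config if config is not None else SimulationConfig()
    design = design if design is not None else LabelingDesign()
    truth = simulate_kinetics(config, seed)
    samples = build_sample_sheet(config)
    counts = simulate_fraction_counts(truth, design, samples, seed)
    counts["ribo"] = simulate_ribo_counts(truth, samples, seed)
    utrs = simulate_utrs_and_crosslinks(truth, seed)
    metabolomics = simulate_metabolomics(config, seed)
    return SyntheticBundle(
        truth=truth, samples=samples, counts=counts, utrs=utrs,
        metabolomics=metabolomics, design=design, seed=seed,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Serialise a bundle to the plain-text file contracts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for assay, counts in bundle.counts.items():
        _io.write_counts_tsv(counts, outdir / f"counts_{assay}.tsv")
    _io.write_sample_sheet(bundle.samples, outdir / "samples.tsv")
    _io.write_utr_bed(bundle.utrs["annotation"], outdir / "utrs.bed")
    _io.write_fasta(bundle.utrs["sequences"], outdir / "utrs.fa")
    for i, tbl in enumerate(bundle.utrs["hitsclip"], start=1):
        _io.write_crosslinks(tbl, outdir / f"hitsclip_rep{i}.bed", name=f"hitsclip:rep{i}")
    for ab, tbl in bundle.utrs["iclip"].items():
        _io.write_crosslinks(tbl, outdir / f"iclip_{ab}.bed", name=f"iclip:{ab}")
    met = bundle.metabolomics
    _io.write_metabolite_csv(met["table"], met["internal_standard"], met["tic"],
                             outdir / "lcms.csv")
    _io.write_sample_sheet(met["samples"], outdir / "lcms_samples.tsv")
    _io.write_isotopologue_csv(met["spectra"], outdir / "isotopologues.csv")
    bundle.truth.table.to_csv(outdir / "truth_kinetics.tsv", sep="\t")
    bundle.utrs["planted"].to_csv(outdir / "truth_clip.tsv", sep="\t", index=False)
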