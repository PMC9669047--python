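"""CLIP crosslink-site annotation, 3'UTR target calling and summary scores.

Crosslink sites are single-nucleotide, strand-specific positions carrying a
read count and a per-site FDR (from an upstream peak caller).  Two target
rules are implemented:

* iCLIP: a gene is a target if each of the two antibody-grouped site tables
  contains at least one 3'UTR site with FDR below ``alpha``.
* HITS-CLIP: a gene is a target if an *identical* significant site
  (same chrom, position and strand; FDR below ``alpha``) occurs in its 3'UTR
  in at least ``min_replicates`` replicates.

The per-gene summary score sums 3'UTR reads over sites with FDR < 0.25,
normalises to the dataset's 90th percentile of sums over detected genes, and
log2-transforms.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FEATURE_PRIORITY",
    "annotate_sites",
    "call_targets_iclip",
    "call_targets_hitsclip",
    "summarize_crosslinks",
    "scan_motif",
    "smooth_conservation",
]

# 3'UTR first; the rest is a fixed artifact ordering.
FEATURE_PRIORITY = ("3UTR", "CDS", "5UTR", "intron", "non-coding")
_PRIORITY_RANK = {f: i for i, f in enumerate(FEATURE_PRIORITY)}

_SITE_COLS = {"chrom", "position", "strand", "read_count", "fdr"}


def _feature_trees(annotation: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    """One interval tree per (chrom, strand); payload (rank, gene_id, feature)."""
    need = {"gene_id", "chrom", "start", "end", "strand"}
    missing = need - set(annotation.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    feat = annotation["feature"] if "feature" in annotation.columns else pd.Series(
        "3UTR", index=annotation.index
    )
    trees: dict[tuple[str, str], IntervalTree] = {}
    for (chrom, strand), grp in annotation.assign(feature=feat).groupby(["chrom", "strand"]):
        t = IntervalTree()
        for _, row in grp.iterrows():
            if row["end"] <= row["start"]:
                raise ValueError(f"malformed interval for {row['gene_id']}")
            rank = _PRIORITY_RANK.get(row["feature"], len(FEATURE_PRIORITY))
            t[int(row["start"]):int(row["end"])] = (rank, str(row["gene_id"]), row["feature"])
        trees[(chrom, strand)] = t
    return trees


def annotate_sites(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign gene and feature to each crosslink site, 3'UTR first.

    A site overlapping multiple features takes the highest-priority one
    (3UTR > CDS > 5UTR > intron > non-coding); priority ties break by
    gene_id.  Sites overlapping nothing on their strand are ``intergenic``.
    """
    missing = _SITE_COLS - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    trees = _feature_trees(annotation)
    genes = np.full(len(sites), "", dtype=object)
    feats = np.full(len(sites), "intergenic", dtype=object)
    for i, (chrom, pos, strand) in enumerate(
        zip(sites["chrom"], sites["position"], sites["strand"])
    ):
        tree = trees.get((chrom, strand))
        if tree is None:
            continue
        hits = tree[int(pos)]
        if not hits:
            continue
        rank, gene, feature = min(h.data for h in hits)
        genes[i], feats[i] = gene, feature
    out = sites.copy()
    out["gene_id"] = genes
    out["feature"] = feats
    return out


def _utr_sites(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    annotated = sites if "feature" in sites.columns else annotate_sites(sites, annotation)
    return annotated.loc[annotated["feature"] == "3UTR"]


def call_targets_iclip(
    grouped_sites: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
) -> set[str]:
    """Targets supported by both antibody groups in the 3'UTR at FDR < alpha."""
    if len(grouped_sites) != 2:
        raise ValueError("iCLIP target calling requires exactly two antibody groups")
    per_group = []
    for _, tbl in grouped_sites.items():
        utr = _utr_sites(tbl, annotation)
        per_group.append(set(utr.loc[utr["fdr"] < alpha, "gene_id"]))
    return per_group[0] & per_group[1]


def call_targets_hitsclip(
    replicate_sites: Sequence[pd.DataFrame],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    min_replicates: int = 2,
) -> set[str]:
    """Targets with an identical significant 3'UTR site in >= min_replicates.

    Identity is exact (chrom, position, strand) equality; a site present in
    one replicate at position 100 and in another at 101 does not qualify.
    """
    seen: dict[tuple, set[int]] = {}
    site_gene: dict[tuple, str] = {}
    for r, tbl in enumerate(replicate_sites):
        utr = _utr_sites(tbl, annotation)
        sig = utr.loc[utr["fdr"] < alpha]
        for chrom, pos, strand, gene in zip(
            sig["chrom"], sig["position"], sig["strand"], sig["gene_id"]
        ):
            key = (chrom, int(pos), strand)
            seen.setdefault(key, set()).add(r)
            site_gene[key] = gene
    return {
        site_gene[k] for k, reps in seen.items() if len(reps) >= min_replicates
    }


def summarize_crosslinks(
    merged_sites: pd.DataFrame,
    annotation: pd.DataFrame,
    fdr_cap: float = 0.25,
) -> pd.DataFrame:
    """Per-gene 3'UTR crosslink summary score from replicate-pooled sites.

    Duplicate rows at one (chrom, position, strand) are first aggregated
    (reads summed, minimum FDR), making the score invariant to row order and
    to splitting a site's reads across rows.  Then

        S_g  = sum of read counts over the gene's 3'UTR sites with fdr < fdr_cap
        q90  = 90th percentile (linear interpolation) of {S_g : S_g > 0}
        score_g = log2(S_g / q90)   for detected genes only.

    Returns ``gene_id, read_sum, detected, summary_score``.
    """
    utr = _utr_sites(merged_sites, annotation)
    agg = (
        utr.groupby(["chrom", "position", "strand", "gene_id"], as_index=False)
        .agg(read_count=("read_count", "sum"), fdr=("fdr", "min"))
    )
    kept = agg.loc[agg["fdr"] < fdr_cap]
    sums = kept.groupby("gene_id")["read_count"].sum()
    genes = pd.Index(sorted(set(annotation["gene_id"])))
    read_sum = sums.reindex(genes, fill_value=0).astype(float)
    detected = read_sum > 0
    if not detected.any():
        raise ValueError("no gene with detected crosslinks below the FDR cap")
    q90 = float(np.percentile(read_sum[detected], 90))
    score = pd.Series(np.nan, index=genes)
    score[detected] = np.log2(read_sum[detected] / q90)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "read_sum": read_sum.to_numpy(),
            "detected": detected.to_numpy(),
            "summary_score": score.to_numpy(),
        }
    )


_VALID_NT = re.compile(r"^[ACGTUNacgtun]*$")


def _normalize_seq(seq: str, what: str) -> str:
    if not _VALID_NT.match(seq):
        raise ValueError(f"non-nucleotide characters in {what}")
    return seq.upper().replace("U", "T")


def scan_motif(
    sequences: Mapping[str, str],
    motif: str = "UAUUUAUU",
) -> pd.DataFrame:
    """Count (possibly overlapping) motif occurrences per sequence.

    DNA and RNA spellings are interchangeable: both motif and sequences are
    normalised T<->U before matching.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    m = _normalize_seq(motif, "motif")
    rows = []
    for gene, seq in sequences.items():
        s = _normalize_seq(str(seq), f"sequence of {gene}")
        count = 0
        start = s.find(m)
        while start != -1:
            count += 1
            start = s.find(m, start + 1)  # overlapping occurrences
        rows.append({"gene_id": gene, "count": count, "contains": count >= 1})
    return pd.DataFrame(rows)


def smooth_conservation(scores: Sequence[float], window: int = 7) -> np.ndarray:
    """Centred moving average of per-base scores; edges use shrunk windows."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score vector")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts
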