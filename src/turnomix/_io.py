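"""Plain-text readers and writers for the pipeline's file contracts.

Formats: counts TSV (first column ``gene_id``), sample sheet TSV, BED6 3'UTR
annotation (0-based half-open, name = gene_id), FASTA keyed by gene_id,
crosslink BED6+1 (single-nucleotide intervals, score = read count, extra
column = site FDR), bedGraph conservation, metabolite CSV and isotopologue
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"batch": str, "replicate": str})


def write_utr_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_utr_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLS)
    out = bed.rename(columns={"name": "gene_id"})[["gene_id", "chrom", "start", "end", "strand"]]
    out["feature"] = "3UTR"
    out["length"] = out["end"] - out["start"]
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_crosslinks(sites: pd.DataFrame, path: str | Path, name: str = "sites") -> None:
    bed = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["position"],
            "end": sites["position"] + 1,
            "name": name,
            "score": sites["read_count"],
            "strand": sites["strand"],
            "fdr": sites["fdr"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_crosslinks(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=BED6_COLS + ["fdr"])
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "position": bed["start"],
            "strand": bed["strand"],
            "read_count": bed["score"],
            "fdr": bed["fdr"],
        }
    )


def write_bedgraph(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks[["chrom", "start", "end", "score"]].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "score"])


def write_metabolite_csv(table: pd.DataFrame, internal_standard: pd.Series,
                         tic: pd.Series, path: str | Path) -> None:
    out = table.copy()
    out.loc["internal_standard"] = internal_standard.reindex(table.columns)
    out.loc["tic"] = tic.reindex(table.columns)
    out.to_csv(path, index_label="metabolite")


def read_metabolite_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    raw = pd.read_csv(path, index_col="metabolite")
    internal_standard = raw.loc["internal_standard"]
    tic = raw.loc["tic"]
    table = raw.drop(index=["internal_standard", "tic"])
    return table, internal_standard, tic


def write_isotopologue_csv(spectra, path: str | Path) -> None:
    """Serialise IsotopologueSpectrum objects (formula as JSON in one cell)."""
    k = max(len(s.raw_counts) for s in spectra)
    rows = []
    for s in spectra:
        row = {
            "metabolite": s.metabolite,
            "fragment_formula": json.dumps(dict(s.fragment_formula)),
            "n_tracer_carbons": s.n_tracer,
        }
        for i in range(k):
            row[f"M{i}"] = s.raw_counts[i] if i < len(s.raw_counts) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_isotopologue_csv(path: str | Path):
    from .metabolism import IsotopologueSpectrum

    df = pd.read_csv(path)
    mcols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]
    mcols.sort(key=lambda c: int(c[1:]))
    spectra = []
    for _, row in df.iterrows():
        counts = tuple(float(row[c]) for c in mcols if pd.notna(row[c]) and row[c] != "")
        spectra.append(
            IsotopologueSpectrum(
                metabolite=row["metabolite"],
                fragment_formula=json.loads(row["fragment_formula"]),
                n_tracer=int(row["n_tracer_carbons"]),
                raw_counts=counts,
            )
        )
    return spectra


def write_diff_table(diff: pd.DataFrame, path: str | Path) -> None:
    diff.to_csv(path, sep="\t", index=False)


def read_diff_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
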