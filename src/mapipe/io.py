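"""Readers and writers for the pipeline's on-disk formats.

FASTA via Biopython, VCF via pysam (plain-text VCF 4.2, one file per
lineage), BED/TSV via pandas.  In-memory the pipeline moves calls around as a
DataFrame with columns lineage_id, chrom, pos (0-based), ref, alt,
span_reads_sample, span_reads_ancestor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import MutationCall
from .repeats import RepeatCensus, RepeatLocus

CALL_IO_COLUMNS = ["lineage_id", "chrom", "pos", "ref", "alt",
                   "span_reads_sample", "span_reads_ancestor"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_vcf(calls: pd.DataFrame, sequences: dict[str, str],
              path: str | Path, lineage_id: str | None = None) -> None:
    """Write calls (one lineage) as an uncompressed VCF 4.2 file."""
    df = calls if lineage_id is None else calls[calls["lineage_id"] == lineage_id]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, r in df.sort_values(["chrom", "pos"]).iterrows():
            fh.write(f"{r['chrom']}\t{r['pos'] + 1}\t.\t{r['ref']}\t"
                     f"{r['alt']}\t.\tPASS\t.\n")


def read_vcf(path: str | Path, lineage_id: str) -> pd.DataFrame:
    """Read a single-lineage VCF into the calls DataFrame (pos 0-based)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                rows.append({"lineage_id": lineage_id, "chrom": rec.chrom,
                             "pos": rec.start, "ref": rec.ref, "alt": alt})
    df = pd.DataFrame(rows, columns=["lineage_id", "chrom", "pos", "ref", "alt"])
    df["span_reads_sample"] = pd.NA
    df["span_reads_ancestor"] = pd.NA
    return df


def write_bed(census: RepeatCensus, path: str | Path) -> None:
    census.to_bed().to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> RepeatCensus:
    """Read a repeats BED written by :func:`write_bed` back into a census.

    The unit is reconstructed as the canonical representative of the class
    (the phase/strand of the original tract is not kept in BED)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    loci = []
    for _, r in df.iterrows():
        cls, n_units = r["name"].rsplit(":", 1)
        unit_len = (r["end"] - r["start"]) // int(n_units)
        rep = cls.split("/")[0]
        if unit_len == 2 and cls in ("GT/CA", "GA/CT"):
            rep = {"GT/CA": "AC", "GA/CT": "AG"}[cls]
        loci.append(RepeatLocus(r["chrom"], int(r["start"]), int(r["end"]),
                                rep, cls))
    return RepeatCensus(loci)


def read_intervals_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def attach_spans(calls: pd.DataFrame, spans: pd.DataFrame) -> pd.DataFrame:
    """Join a (lineage_id, chrom, pos) -> span counts table onto calls."""
    out = calls.drop(columns=["span_reads_sample", "span_reads_ancestor"],
                     errors="ignore")
    return out.merge(spans, on=["lineage_id", "chrom", "pos"], how="left")


def calls_from_frame(df: pd.DataFrame) -> list[MutationCall]:
    def _int_or_none(v):
        return None if pd.isna(v) else int(v)

    return [
        MutationCall(
            lineage_id=str(r.lineage_id), chrom=str(r.chrom), pos=int(r.pos),
            ref=str(r.ref), alt=str(r.alt),
            span_reads_sample=_int_or_none(getattr(r, "span_reads_sample", None)),
            span_reads_ancestor=_int_or_none(getattr(r, "span_reads_ancestor", None)),
        )
        for r in df.itertuples(index=False)
    ]


def frame_from_calls(calls: Sequence[MutationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"lineage_id": c.lineage_id, "chrom": c.chrom, "pos": c.pos,
          "ref": c.ref, "alt": c.alt,
          "span_reads_sample": c.span_reads_sample,
          "span_reads_ancestor": c.span_reads_ancestor} for c in calls],
        columns=CALL_IO_COLUMNS)
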