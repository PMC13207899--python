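"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, VCF reading through cyvcf2, GFF3 reading
through gffutils; BED, bedGraph, Bismark-style cytosine reports, mutation
tables and COSMIC-style signature catalogs are plain TSV handled with
pandas.  All writers emit deterministic, uncompressed text.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Transcript, decode_seq, encode_seq
from .intervals import IntervalSet
from .variant_filter import MUTATION_COLUMNS, Mutation, VariantCall, mutations_to_frame

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(decode_seq(codes)), id=name, description="")
        for name, codes in sorted(sequences.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, np.ndarray]:
    return {rec.id: encode_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | os.PathLike) -> IntervalSet:
    triples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            triples.append((fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet.from_pairs(triples)


def write_bedgraph(windows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a windowed track; windows with missing values are skipped."""
    df = windows.dropna(subset=["value"])
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"], float_format="%.6g")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"],
                       dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Bismark-style cytosine report
# ---------------------------------------------------------------------------

_CYT_COLUMNS = ["chrom", "pos", "strand", "methylated", "unmethylated", "context"]


def write_cytosine_report(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    calls.to_csv(path, sep="\t", header=False, index=False, columns=_CYT_COLUMNS)


def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=_CYT_COLUMNS,
                       dtype={"chrom": str, "strand": str, "context": str})


# ---------------------------------------------------------------------------
# GFF3 (CDS gene models)
# ---------------------------------------------------------------------------


def write_gff3(transcripts: list[Transcript], path: str | os.PathLike,
               source: str = "azcma") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in transcripts:
            start = min(s for s, _ in tr.parts) + 1
            end = max(e for _, e in tr.parts)
            fh.write(
                f"{tr.chrom}\t{source}\tmRNA\t{start}\t{end}\t.\t{tr.strand}\t.\t"
                f"ID={tr.name};Name={tr.name}\n"
            )
            parts = tr.parts if tr.strand == "+" else tr.parts[::-1]
            coding = 0
            for s, e in parts:
                phase = (3 - coding % 3) % 3
                fh.write(
                    f"{tr.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{tr.strand}\t{phase}\t"
                    f"ID=cds-{tr.name};Parent={tr.name}\n"
                )
                coding += e - s


def read_gff3_cds(path: str | os.PathLike) -> list[Transcript]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    by_parent: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent", [feat.id])[0]
        entry = by_parent.setdefault(parent, {"chrom": feat.seqid, "strand": feat.strand,
                                              "parts": []})
        entry["parts"].append((feat.start - 1, feat.end))
    out = [
        Transcript(name=name, chrom=v["chrom"], strand=v["strand"], parts=v["parts"])
        for name, v in by_parent.items()
    ]
    out.sort(key=lambda t: (t.chrom, t.parts[0][0]))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    records: list[VariantCall],
    path: str | os.PathLike,
    sample: str,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write single-sample VCF 4.2 with DP/AD and per-allele strand counts.

    FORMAT fields: GT, DP (depth), AD (ref,alt depths), SAC (per-allele
    strand counts: ref+, ref-, alt+, alt-).
    """
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in sorted((chrom_lengths or {}).items()):
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=SAC,Number=.,Type=Integer,Description="Per-allele strand counts">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for v in sorted(records, key=lambda r: (r.chrom, r.pos)):
        ref_reads = v.depth - v.alt_reads
        ref_plus = ref_reads // 2
        sac = f"{ref_plus},{ref_reads - ref_plus},{v.alt_plus},{v.alt_minus}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{v.qual:.1f}\t.\t.\t"
            f"GT:DP:AD:SAC\t1:{v.depth}:{ref_reads},{v.alt_reads}:{sac}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike, line_id: str | None = None) -> list[VariantCall]:
    """Read candidate calls from a single-sample VCF with DP/AD/SAC fields."""
    from cyvcf2 import VCF

    out: list[VariantCall] = []
    vcf = VCF(str(path))
    for var in vcf:
        if not var.ALT:
            continue
        dp = int(var.format("DP")[0][0])
        ad = var.format("AD")[0]
        sac = var.format("SAC")[0]
        # multi-allelic records are split into per-allele calls
        for k, alt in enumerate(var.ALT):
            out.append(
                VariantCall(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=str(alt),
                    qual=float(var.QUAL if var.QUAL is not None else 0.0),
                    depth=dp,
                    alt_reads=int(ad[k + 1]),
                    alt_plus=int(sac[2 * (k + 1)]),
                    alt_minus=int(sac[2 * (k + 1) + 1]),
                    line_id=line_id,
                )
            )
    vcf.close()
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_mutation_table(mutations: list[Mutation] | pd.DataFrame,
                         path: str | os.PathLike) -> None:
    df = mutations if isinstance(mutations, pd.DataFrame) else mutations_to_frame(mutations)
    df.to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_signature_catalog(path: str | os.PathLike) -> pd.DataFrame:
    """Read a COSMIC-style SBS catalog: first column of 96 context labels
    (``A[C>A]A`` ...), one column per signature."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "context"
    return df


def write_line_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_line_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"line_id": str})
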