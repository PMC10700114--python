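"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA goes through Biopython, VCF reading through pysam. VCF writing is
done directly (the simulator emits small, fully specified VCF 4.2 files).
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .variant_filters import HET, HOM_ALT, HOM_REF, SiteCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_depth_track",
    "write_depth_track",
    "read_vcf_calls",
    "write_vcf",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["contig", "start", "end"],
    )


def write_bed(df: pd.DataFrame, path) -> None:
    df[["contig", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_depth_track(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_depth_track(df: pd.DataFrame, path) -> None:
    df[["contig", "start", "end", "depth"]].to_csv(path, sep="\t", index=False)


def read_vcf_calls(path) -> list[SiteCall]:
    """Load a single-sample VCF into SiteCall records, sorted as stored.

    Genotype is taken from the first sample's GT; depth from FORMAT DP
    (falling back to INFO DP); alt_fraction from FORMAT AD when present.
    Multiallelic records keep a comma-joined alt string, so downstream
    filters can reject them explicitly.
    """
    calls: list[SiteCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0] if rec.samples else None
            gt = sample["GT"] if sample is not None and "GT" in sample else None
            alts = [a for a in (rec.alts or ()) if a is not None]
            alt = ",".join(alts) if alts else "."
            if gt is None or all(a in (0, None) for a in gt):
                genotype = HOM_REF
            elif len(set(a for a in gt if a is not None)) > 1:
                genotype = HET
            else:
                genotype = HOM_ALT
            depth = None
            if sample is not None and "DP" in sample and sample["DP"] is not None:
                depth = int(sample["DP"])
            elif "DP" in rec.info:
                depth = int(rec.info["DP"])
            alt_fraction = None
            if sample is not None and "AD" in sample and sample["AD"] is not None:
                ad = [a for a in sample["AD"] if a is not None]
                if len(ad) >= 2 and sum(ad) > 0:
                    alt_fraction = ad[1] / sum(ad)
            calls.append(
                SiteCall(
                    contig=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref or ".",
                    alt=alt,
                    genotype=genotype,
                    depth=depth if depth is not None else 0,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    alt_fraction=alt_fraction,
                )
            )
    return calls


def write_vcf(
    path,
    records: Iterable[tuple],
    contig_lengths: Mapping[str, int],
    sample: str = "sample1",
    with_ad: bool = False,
) -> None:
    """Write a minimal single-sample VCF 4.2.

    ``records`` yields tuples ``(contig, pos1, ref, alt, qual, gt, dp, ad)``
    where ``ad`` is an (ref_count, alt_count) pair or None. ``pos1`` is
    1-based.
    """
    fmt = "GT:DP:AD" if with_ad else "GT:DP"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if with_ad:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic read depths">\n'
            )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for contig, pos1, ref, alt, qual, gt, dp, ad in records:
            fields = [gt, str(int(dp))]
            if with_ad:
                if ad is None:
                    fields.append(".")
                else:
                    fields.append(f"{int(ad[0])},{int(ad[1])}")
            fh.write(
                f"{contig}\t{int(pos1)}\t.\t{ref}\t{alt}\t{qual:.6g}\tPASS\t.\t"
                f"{fmt}\t{':'.join(fields)}\n"
            )
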