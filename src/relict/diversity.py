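"""Heterozygosity estimators: genome-wide, per contig, and by coding site class.

All estimates concern a single diploid individual: heterozygosity H is the
number of heterozygous biallelic SNVs divided by the number of callable
sites, and the coding-class statistics (pS, pN, 4-fold degenerate
diversity) partition het sites inside coding sequence by the effect of
swapping the two alleles in their codon context.

Synonymous/nonsynonymous site counting follows the Nei–Gojobori (1986)
fractional convention by default: each codon position contributes
``(# synonymous single-base changes)/3`` synonymous sites, so every codon
contributes exactly 3 sites in total. A stricter degeneracy-class mode is
available in which only 4-fold (fully synonymous) and 0-fold (fully
nonsynonymous) positions enter the denominators.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .intervals import CallableMask
from .variant_filters import HET, SiteCall

logger = logging.getLogger(__name__)

__all__ = [
    "DiversityEstimate",
    "CodingDiversity",
    "CodonDegeneracy",
    "heterozygosity",
    "codon_degeneracy",
    "coding_class_pi",
    "pairwise_alignment_pi",
]

_BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]
# Amino-acid lookup for all 64 codons; '*' marks stops.
CODON_TO_AA: dict[str, str] = {**_TABLE.forward_table, **{c: "*" for c in _TABLE.stop_codons}}
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))


@dataclass(frozen=True, slots=True)
class DiversityEstimate:
    n_het: int
    n_callable: int
    H: float
    scope: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise ValueError("H outside [0, 1]")


@dataclass(frozen=True, slots=True)
class CodonDegeneracy:
    """Per-position degeneracy class and fractional site counts of a codon."""

    degeneracy: tuple[int, int, int]        # each in {0, 2, 3, 4}
    syn_fraction: tuple[float, float, float]

    @property
    def nonsyn_fraction(self) -> tuple[float, float, float]:
        return tuple(1.0 - s for s in self.syn_fraction)  # type: ignore[return-value]

    @property
    def syn_sites(self) -> float:
        return sum(self.syn_fraction)

    @property
    def nonsyn_sites(self) -> float:
        return 3.0 - self.syn_sites


@dataclass(slots=True)
class CodingDiversity:
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    het_syn: int = 0
    het_nonsyn: int = 0
    fourfold_sites: int = 0
    het_fourfold: int = 0
    n_codons: int = 0
    n_codons_skipped: int = 0
    n_genes: int = 0
    n_genes_skipped: int = 0

    @property
    def pS(self) -> float:
        return self.het_syn / self.syn_sites if self.syn_sites > 0 else 0.0

    @property
    def pN(self) -> float:
        return self.het_nonsyn / self.nonsyn_sites if self.nonsyn_sites > 0 else 0.0

    @property
    def pi_fourfold(self) -> float:
        return self.het_fourfold / self.fourfold_sites if self.fourfold_sites > 0 else 0.0

    @property
    def pn_ps(self) -> float | None:
        """pN/pS, or None when pS = 0 (undefined, never inf)."""
        if self.pS == 0.0:
            return None
        return self.pN / self.pS


def heterozygosity(
    calls: Iterable[SiteCall],
    mask: CallableMask,
    contig_lengths: Mapping[str, int],
    min_contig_len: int = 30_000,
    excluded_contigs: Iterable[str] = (),
    per_contig_min_len: int = 200_000,
) -> tuple[DiversityEstimate, pd.DataFrame]:
    """Genome-wide H with a per-contig breakdown.

    Only heterozygous biallelic SNVs inside the (final, repeat-subtracted)
    mask are counted; the denominator is the mask size on retained contigs
    (length >= ``min_contig_len``, not in ``excluded_contigs``). The
    per-contig table is restricted to contigs >= ``per_contig_min_len``
    where single-contig estimates are stable.
    """
    excluded = set(excluded_contigs)
    retained = {
        c for c, ln in contig_lengths.items()
        if ln >= min_contig_len and c not in excluded
    }
    callable_by_contig = {c: mask.bp(c) for c in retained}
    total_callable = sum(callable_by_contig.values())
    if total_callable == 0:
        raise ValueError("zero callable bp on retained contigs; H is undefined")

    het_by_contig: dict[str, int] = {c: 0 for c in retained}
    for call in calls:
        if call.contig not in retained:
            continue
        if call.genotype == HET and call.is_biallelic_snv and mask.contains(call.contig, call.pos - 1):
            het_by_contig[call.contig] += 1

    n_het = sum(het_by_contig.values())
    estimate = DiversityEstimate(n_het, total_callable, n_het / total_callable, scope="genome")

    rows = []
    for contig in sorted(retained):
        if contig_lengths[contig] < per_contig_min_len:
            continue
        nc = callable_by_contig[contig]
        rows.append(
            {
                "contig": contig,
                "length": int(contig_lengths[contig]),
                "n_het": het_by_contig[contig],
                "n_callable": nc,
                "H": het_by_contig[contig] / nc if nc else float("nan"),
            }
        )
    return estimate, pd.DataFrame(rows, columns=["contig", "length", "n_het", "n_callable", "H"])


def codon_degeneracy(codon: str) -> CodonDegeneracy:
    """Degeneracy class and fractional synonymous site count per position.

    A position is k-fold degenerate when k of the four possible bases there
    encode the same amino acid (k = 1 is reported as 0-fold, the field's
    convention). Changes producing a stop codon count as nonsynonymous.
    Ambiguous bases and stop codons are rejected.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    if aa == "*":
        raise ValueError(f"stop codon: {codon}")
    degeneracy = []
    syn_fraction = []
    for i in range(3):
        same = sum(
            1 for b in _BASES if CODON_TO_AA[codon[:i] + b + codon[i + 1 :]] == aa
        )
        degeneracy.append({1: 0, 2: 2, 3: 3, 4: 4}[same])
        syn_fraction.append((same - 1) / 3.0)
    return CodonDegeneracy(tuple(degeneracy), tuple(syn_fraction))


def coding_class_pi(
    haplotype_pairs: Iterable[tuple[str, str]],
    site_mode: str = "ng86",
) -> CodingDiversity:
    """Classify within-individual het sites in coding sequence.

    ``haplotype_pairs`` yields the two in-frame haplotype CDS sequences of
    each gene. A het site is synonymous when swapping the two alleles in
    codon context (other positions held at the haplotype-A base) preserves
    the amino acid. Genes violating the reading frame are skipped with a
    log entry; codons containing gaps, ambiguity codes or stops are skipped
    individually.

    ``site_mode='ng86'`` accumulates fractional site counts; ``'degeneracy'``
    counts only 4-fold positions as synonymous sites and 0-fold positions
    as nonsynonymous sites (intermediate positions enter neither
    denominator; het classification is unchanged).
    """
    if site_mode not in ("ng86", "degeneracy"):
        raise ValueError(f"unknown site_mode: {site_mode!r}")
    result = CodingDiversity()
    for hap_a, hap_b in haplotype_pairs:
        if len(hap_a) != len(hap_b) or len(hap_a) % 3 != 0:
            result.n_genes_skipped += 1
            logger.warning("gene skipped: frame violation (lengths %d/%d)", len(hap_a), len(hap_b))
            continue
        result.n_genes += 1
        for i in range(0, len(hap_a), 3):
            ca = hap_a[i : i + 3].upper()
            cb = hap_b[i : i + 3].upper()
            try:
                dega = codon_degeneracy(ca)
                degb = codon_degeneracy(cb)
            except ValueError:
                result.n_codons_skipped += 1
                continue
            result.n_codons += 1
            if site_mode == "ng86":
                result.syn_sites += (dega.syn_sites + degb.syn_sites) / 2.0
                result.nonsyn_sites += (dega.nonsyn_sites + degb.nonsyn_sites) / 2.0
            else:
                for j in range(3):
                    if dega.degeneracy[j] == 4 and degb.degeneracy[j] == 4:
                        result.syn_sites += 1.0
                    elif dega.degeneracy[j] == 0 and degb.degeneracy[j] == 0:
                        result.nonsyn_sites += 1.0
            result.fourfold_sites += sum(1 for j in range(3) if dega.degeneracy[j] == 4)
            for j in range(3):
                if ca[j] == cb[j]:
                    continue
                swapped = ca[:j] + cb[j] + ca[j + 1 :]
                if CODON_TO_AA[swapped] == CODON_TO_AA[ca] and CODON_TO_AA[swapped] != "*":
                    result.het_syn += 1
                else:
                    result.het_nonsyn += 1
                if dega.degeneracy[j] == 4:
                    result.het_fourfold += 1
    return result


def pairwise_alignment_pi(seq_a: str, seq_b: str) -> tuple[int, int, float]:
    """Percent divergence between two aligned sequences, mismatches counted once.

    Columns where both bases are unambiguous nucleotides are the aligned
    positions; mismatching such columns are variable sites. Returns
    ``(variable_sites, aligned_positions, pi_percent)``. No multiple-hit
    correction is applied.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    bases = frozenset(_BASES)
    aligned = 0
    variable = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in bases and b in bases:
            aligned += 1
            if a != b:
                variable += 1
    if aligned == 0:
        raise ValueError("no aligned positions with unambiguous bases in both sequences")
    return variable, aligned, 100.0 * variable / aligned
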