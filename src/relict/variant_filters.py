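"""Platform-specific genotype-call filtering and callable-mask construction.

Single-individual heterozygosity is a ratio of het calls to callable sites,
so the filters here play two roles: they decide which genotype calls count
(depth, quality and allele-balance thresholds, applied inclusively), and
they build the :class:`~relict.intervals.CallableMask` that defines the
denominator (strict depth bounds, short-contig and sex-chromosome
exclusion, repeat subtraction).

Two built-in rule sets mirror common practice for short-read
(Freebayes-style) and long-read (Longshot-style) diploid calls. The
boundary semantics differ deliberately: calling filters exclude values
*below/above* the thresholds (bounds themselves are kept) whereas the
depth mask used for demographic inference keeps only strictly interior
depths.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CallableMask

__all__ = [
    "SiteCall",
    "FilterRuleSet",
    "Rejection",
    "builtin_rulesets",
    "apply_filters",
    "depth_mask",
    "subtract_regions",
]

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"

# Primary rejection reason codes, one per rejected record.
NOT_BIALLELIC_SNV = "NOT_BIALLELIC_SNV"
LOW_DEPTH = "LOW_DEPTH"
HIGH_DEPTH = "HIGH_DEPTH"
LOW_SITE_QUAL = "LOW_SITE_QUAL"
LOW_SNP_QUAL = "LOW_SNP_QUAL"
NO_ALLELE_SUPPORT = "NO_ALLELE_SUPPORT"

_BASES = frozenset("ACGT")


@dataclass(slots=True)
class SiteCall:
    """One genotyped position; the atom of all diversity estimates.

    ``pos`` is 1-based as in VCF. ``alt_fraction`` is the fraction of reads
    supporting the alternate allele, when the caller reports per-allele
    counts (long-read callers do; it is what the allele-balance window
    filters on).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str
    depth: int
    qual: float
    alt_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.alt_fraction is not None and not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")

    @property
    def is_biallelic_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
        )

    @property
    def is_snp(self) -> bool:
        """True for records carrying a non-reference allele call."""
        return self.genotype in (HET, HOM_ALT)


@dataclass(frozen=True, slots=True)
class FilterRuleSet:
    """Thresholds applied to genotype calls before counting heterozygotes."""

    min_depth: int
    max_depth: int
    min_site_qual: float | None
    min_snp_qual: float
    alt_fraction_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        if self.alt_fraction_window is not None:
            low, high = self.alt_fraction_window
            if not (0.0 <= low < high <= 1.0):
                raise ValueError("alt_fraction_window must satisfy 0 <= low < high <= 1")


@dataclass(frozen=True, slots=True)
class Rejection:
    contig: str
    pos: int
    reason: str


def builtin_rulesets() -> dict[str, FilterRuleSet]:
    """Named rule sets for short-read and long-read genotype calls.

    illumina: keep 15x <= DP <= 200x; SNPs need QUAL >= 200.
    ont: keep 10x <= DP <= 150x; all sites need QUAL >= 50, SNPs QUAL >= 300;
    heterozygotes additionally need the alternate allele supported by more
    than 20% and less than 80% of reads.
    """
    return {
        "illumina": FilterRuleSet(
            min_depth=15, max_depth=200, min_site_qual=None, min_snp_qual=200,
            alt_fraction_window=None,
        ),
        "ont": FilterRuleSet(
            min_depth=10, max_depth=150, min_site_qual=50, min_snp_qual=300,
            alt_fraction_window=(0.20, 0.80),
        ),
    }


def apply_filters(
    calls: Iterable[SiteCall], rules: FilterRuleSet
) -> tuple[list[SiteCall], list[Rejection]]:
    """Filter a (contig, pos)-sorted stream of calls.

    Returns the kept calls and a rejection log with exactly one primary
    reason per rejected record. Depth and quality bounds are inclusive
    (values *below* min / *above* max are rejected). Heterozygote calls
    whose allele balance falls outside the open window are not dropped:
    the site stays callable and is reclassified to the homozygous genotype
    of the majority allele. Long-read het calls without allele support
    information are rejected (fail closed).

    The operation is idempotent: re-filtering the kept stream changes
    nothing.
    """
    kept: list[SiteCall] = []
    rejected: list[Rejection] = []
    last: tuple[str, int] | None = None
    seen_contigs: set[str] = set()

    for call in calls:
        if last is not None:
            if call.contig == last[0]:
                if call.pos < last[1]:
                    raise ValueError(
                        f"input not sorted at {call.contig}:{call.pos}"
                    )
            elif call.contig in seen_contigs:
                raise ValueError(f"contig {call.contig} appears in multiple blocks")
        seen_contigs.add(call.contig)
        last = (call.contig, call.pos)

        reason = _primary_rejection(call, rules)
        if reason is not None:
            rejected.append(Rejection(call.contig, call.pos, reason))
            continue

        if (
            rules.alt_fraction_window is not None
            and call.genotype == HET
            and call.alt_fraction is not None
        ):
            low, high = rules.alt_fraction_window
            if call.alt_fraction <= low:
                call = dataclasses.replace(call, genotype=HOM_REF)
            elif call.alt_fraction >= high:
                call = dataclasses.replace(call, genotype=HOM_ALT)
        kept.append(call)
    return kept, rejected


def _primary_rejection(call: SiteCall, rules: FilterRuleSet) -> str | None:
    if call.is_snp and not call.is_biallelic_snv:
        return NOT_BIALLELIC_SNV
    if call.depth < rules.min_depth:
        return LOW_DEPTH
    if call.depth > rules.max_depth:
        return HIGH_DEPTH
    if rules.min_site_qual is not None and call.qual < rules.min_site_qual:
        return LOW_SITE_QUAL
    if call.is_snp and call.qual < rules.min_snp_qual:
        return LOW_SNP_QUAL
    if (
        rules.alt_fraction_window is not None
        and call.genotype == HET
        and call.alt_fraction is None
    ):
        return NO_ALLELE_SUPPORT
    return None


def depth_mask(
    depth_track: pd.DataFrame,
    min_exclusive: float,
    max_exclusive: float,
    min_contig_len: int = 0,
    excluded_contigs: Iterable[str] = (),
    contig_lengths: Mapping[str, int] | None = None,
) -> CallableMask:
    """Build a callable mask from a windowed or per-base depth track.

    ``depth_track`` needs columns contig/start/end/depth with 0-based
    half-open windows. Only positions with ``min_exclusive < depth <
    max_exclusive`` (strict, matching demographic-inference masking
    practice) on retained contigs enter the mask. Contigs shorter than
    ``min_contig_len`` or listed in ``excluded_contigs`` contribute
    nothing; contig length is taken from ``contig_lengths`` when given,
    otherwise from the track's extent.
    """
    if min_exclusive >= max_exclusive:
        raise ValueError("min_exclusive must be < max_exclusive")
    excluded = set(excluded_contigs)
    out: dict[str, list[tuple[int, int]]] = {}
    for contig, grp in depth_track.groupby("contig", sort=False):
        contig = str(contig)
        if contig in excluded:
            continue
        length = (
            int(contig_lengths[contig]) if contig_lengths is not None and contig in contig_lengths
            else int(grp["end"].max())
        )
        if length < min_contig_len:
            continue
        ok = grp[(grp["depth"] > min_exclusive) & (grp["depth"] < max_exclusive)]
        if len(ok):
            out[contig] = list(zip(ok["start"].astype(int), ok["end"].astype(int)))
    return CallableMask(out)


def subtract_regions(mask: CallableMask, regions: CallableMask | pd.DataFrame) -> CallableMask:
    """Remove regions (e.g. repeat annotations) from a callable mask."""
    if isinstance(regions, pd.DataFrame):
        regions = CallableMask.from_frame(regions)
    return mask.subtract(regions)


def read_rejections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_rejections(rejections: Sequence[Rejection], path) -> None:
    pd.DataFrame(
        [(r.contig, r.pos, r.reason) for r in rejections],
        columns=["contig", "pos", "reason"],
    ).to_csv(path, sep="\t", index=False)
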