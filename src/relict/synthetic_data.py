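"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the data a single-individual genome study produces:

* a diploid genome — contigs with configurable per-site heterozygosity,
  repeat intervals, GC-dependent sequencing depth, and hemizygous
  (Z-like) contigs at half depth with near-zero heterozygosity;
* platform-flavoured VCFs with injectable filter-fodder artifacts;
* TE copies mutated away from family consensus sequences to target K80
  divergences under a two-parameter (kappa) substitution process;
* codon alignments of orthologs evolving with fast third positions;
* a piecewise-constant-Ne pairwise coalescent (independent segments) whose
  heterozygous-site tracks feed the demographic-inference prep.

All randomness flows through one explicitly passed numpy Generator, so a
fixed seed reproduces every output byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .diversity import SENSE_CODONS, CODON_TO_AA
from .intervals import CallableMask
from .te_landscape import K2PResult, TECopyRecord, classify_family, k2p

__all__ = [
    "GenomeSpec",
    "GenomeTruth",
    "TEFamily",
    "TECopySpec",
    "TESimSpec",
    "CoalescentSpec",
    "CoalescentResult",
    "gen_diploid_genome",
    "write_genome",
    "emit_vcf",
    "gen_te_copies",
    "write_te_align",
    "gen_ortholog_alignments",
    "simulate_pairwise_coalescent",
    "gen_contig_profiles",
    "gen_coding_pairs",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
# K80 transition partner when bases are encoded A=0, C=1, G=2, T=3.
_TS_PARTNER = np.array([2, 3, 0, 1])


# ---------------------------------------------------------------------------
# diploid genome
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Study conditions for the synthetic diploid genome.

    Defaults reflect a Lepidoptera-like single-individual study: ~0.5%
    autosomal heterozygosity, hemizygous contigs at 3e-4, sequencing depth
    linear in GC with an autosomal expectation around 54x and hemizygous
    contigs at half that, and a modest repeat fraction.
    """

    n_autosomal_contigs: int = 8
    n_hemizygous_contigs: int = 2
    contig_length_bp: int = 500_000
    theta: float = 0.005
    theta_hemi: float = 3e-4
    gc_by_contig: Sequence[float] | None = None
    gc_range: tuple[float, float] = (0.30, 0.45)
    depth_intercept: float = 20.0
    depth_slope: float = 90.0
    hemi_depth_multiplier: float = 0.5
    depth_noise_sd: float = 3.0
    repeat_fraction: float = 0.10
    depth_window_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")
        if self.theta > 0 and not self.theta_hemi < self.theta:
            raise ValueError("theta_hemi must be < theta")
        if not 0.0 < self.hemi_depth_multiplier < 1.0:
            raise ValueError("hemizygous depth multiplier must lie in (0, 1)")
        if self.contig_length_bp <= 0:
            raise ValueError("contig length must be positive")
        if not 0.0 <= self.repeat_fraction < 1.0:
            raise ValueError("repeat_fraction must lie in [0, 1)")
        if self.gc_by_contig is not None:
            n = self.n_autosomal_contigs + self.n_hemizygous_contigs
            if len(self.gc_by_contig) != n:
                raise ValueError("gc_by_contig must list one GC per contig")
            if any(not 0.0 < g < 1.0 for g in self.gc_by_contig):
                raise ValueError("GC fractions must lie in (0, 1)")


@dataclass
class ContigTruth:
    name: str
    length: int
    gc: float
    is_hemizygous: bool
    expected_depth: float
    het_pos: np.ndarray          # 0-based planted het positions
    ref_alleles: np.ndarray      # S1 chars at het_pos (haplotype 1)
    alt_alleles: np.ndarray      # S1 chars at het_pos (haplotype 2)
    repeats: list[tuple[int, int]]


@dataclass
class GenomeTruth:
    spec: GenomeSpec
    contigs: list[ContigTruth]
    hap1: dict[str, str]
    hap2: dict[str, str]
    depth_track: pd.DataFrame    # contig, start, end, depth (windowed)
    repeat_bed: pd.DataFrame     # contig, start, end

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.contigs}

    def profile_table(self) -> pd.DataFrame:
        rows = []
        for c in self.contigs:
            depths = self.depth_track[self.depth_track.contig == c.name]["depth"]
            nonrepeat = c.length - sum(e - s for s, e in c.repeats)
            rows.append(
                {
                    "contig": c.name,
                    "length": c.length,
                    "gc": c.gc,
                    "median_depth": float(depths.median()),
                    "n_snp": len(c.het_pos),
                    "het": len(c.het_pos) / nonrepeat if nonrepeat else 0.0,
                    "is_hemizygous": c.is_hemizygous,
                    "expected_depth": c.expected_depth,
                }
            )
        return pd.DataFrame(rows)

    def nonrepeat_mask(self) -> CallableMask:
        full = CallableMask({c.name: [(0, c.length)] for c in self.contigs})
        return full.subtract(CallableMask({c.name: c.repeats for c in self.contigs if c.repeats}))


def gen_diploid_genome(spec: GenomeSpec, rng: np.random.Generator | None = None) -> GenomeTruth:
    """Generate a diploid genome with planted heterozygosity and depth.

    Heterozygous positions are independent Bernoulli(theta) draws over
    non-repeat sites; hemizygous contigs use theta_hemi and emit depth at
    ``hemi_depth_multiplier`` times the autosomal expectation at the same
    GC. Depth is ``intercept + slope*GC + N(0, sd)`` per window, truncated
    at zero.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_total = spec.n_autosomal_contigs + spec.n_hemizygous_contigs
    contigs: list[ContigTruth] = []
    hap1: dict[str, str] = {}
    hap2: dict[str, str] = {}
    depth_rows = []
    repeat_rows = []

    for i in range(n_total):
        name = f"ctg{i + 1:03d}"
        hemi = i >= spec.n_autosomal_contigs
        L = spec.contig_length_bp
        gc = (
            float(spec.gc_by_contig[i]) if spec.gc_by_contig is not None
            else float(rng.uniform(*spec.gc_range))
        )
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(4, size=L, p=p).astype(np.uint8)

        repeats = _place_repeats(L, spec.repeat_fraction, rng)
        nonrepeat = np.ones(L, dtype=bool)
        for s, e in repeats:
            nonrepeat[s:e] = False
            repeat_rows.append((name, s, e))

        theta = spec.theta_hemi if hemi else spec.theta
        het = (rng.random(L) < theta) & nonrepeat
        het_pos = np.flatnonzero(het)
        # alternate allele: one of the three other bases, uniformly
        offsets = rng.integers(1, 4, size=het_pos.size)
        alt_codes = (seq[het_pos] + offsets) % 4

        seq2 = seq.copy()
        seq2[het_pos] = alt_codes
        hap1[name] = _BASES[seq].tobytes().decode()
        hap2[name] = _BASES[seq2].tobytes().decode()

        expected = spec.depth_intercept + spec.depth_slope * gc
        if hemi:
            expected *= spec.hemi_depth_multiplier
        starts = np.arange(0, L, spec.depth_window_bp)
        depths = np.clip(
            rng.normal(expected, spec.depth_noise_sd, size=starts.size), 0.0, None
        )
        for s, d in zip(starts, depths):
            depth_rows.append((name, int(s), int(min(s + spec.depth_window_bp, L)), float(d)))

        contigs.append(
            ContigTruth(
                name=name, length=L, gc=gc, is_hemizygous=hemi,
                expected_depth=expected, het_pos=het_pos,
                ref_alleles=_BASES[seq[het_pos]], alt_alleles=_BASES[alt_codes],
                repeats=repeats,
            )
        )

    return GenomeTruth(
        spec=spec,
        contigs=contigs,
        hap1=hap1,
        hap2=hap2,
        depth_track=pd.DataFrame(depth_rows, columns=["contig", "start", "end", "depth"]),
        repeat_bed=pd.DataFrame(repeat_rows, columns=["contig", "start", "end"]),
    )


def _place_repeats(
    length: int, fraction: float, rng: np.random.Generator, block: int = 1_000
) -> list[tuple[int, int]]:
    """Non-overlapping repeat blocks covering ~fraction of the contig."""
    if fraction <= 0:
        return []
    grid = np.arange(0, max(length - block, 0) + 1, block)
    n_blocks = int(round(fraction * length / block))
    n_blocks = min(n_blocks, grid.size)
    if n_blocks == 0:
        return []
    starts = np.sort(rng.choice(grid, size=n_blocks, replace=False))
    return [(int(s), int(min(s + block, length))) for s in starts]


def write_genome(truth: GenomeTruth, outdir) -> dict[str, Path]:
    """Write haplotype FASTAs, truth VCF, repeat BED, depth track, profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hap1": outdir / "hap1.fa",
        "hap2": outdir / "hap2.fa",
        "truth_vcf": outdir / "truth.vcf",
        "repeats": outdir / "repeats.bed",
        "depth": outdir / "depth.tsv",
        "profiles": outdir / "contig_profiles.tsv",
    }
    rio.write_fasta(paths["hap1"], truth.hap1)
    rio.write_fasta(paths["hap2"], truth.hap2)
    records = (
        (c.name, int(p) + 1, r.decode(), a.decode(), 999.0, "0/1", 1, None)
        for c in truth.contigs
        for p, r, a in zip(c.het_pos, c.ref_alleles, c.alt_alleles)
    )
    rio.write_vcf(paths["truth_vcf"], records, truth.contig_lengths)
    rio.write_bed(truth.repeat_bed, paths["repeats"])
    rio.write_depth_track(truth.depth_track, paths["depth"])
    truth.profile_table().to_csv(paths["profiles"], sep="\t", index=False)
    return paths


def emit_vcf(
    truth: GenomeTruth,
    platform: str,
    out_vcf,
    artifacts_tsv=None,
    n_low_dp: int = 0,
    n_low_qual: int = 0,
    n_unbalanced: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write a platform-flavoured VCF of the planted het sites.

    illumina records carry DP and QUAL; ont records add per-allele read
    counts (AD) so the 20-80% allele-balance rule is exercisable.
    ``n_low_dp``/``n_low_qual``/``n_unbalanced`` (counts, or fractions of
    planted records when < 1) convert that many records into artifacts a
    correct filter must reject or reclassify; the returned sidecar table
    flags each as ``should_be_filtered`` or ``should_not_be_het``.
    """
    if platform not in ("illumina", "ont"):
        raise ValueError(f"unknown platform {platform!r}")
    rng = rng if rng is not None else np.random.default_rng(truth.spec.seed + 1)
    min_depth = 15 if platform == "illumina" else 10
    min_snp_qual = 200 if platform == "illumina" else 300

    sites = [
        (c, int(p), r.decode(), a.decode())
        for c in truth.contigs
        for p, r, a in zip(c.het_pos, c.ref_alleles, c.alt_alleles)
    ]
    n = len(sites)

    def _count(v) -> int:
        return int(round(v * n)) if 0 < v < 1 else int(v)

    n_low_dp, n_low_qual, n_unbalanced = map(_count, (n_low_dp, n_low_qual, n_unbalanced))
    if n_unbalanced and platform != "ont":
        raise ValueError("allele-balance artifacts require per-allele counts (ont)")
    n_art = n_low_dp + n_low_qual + n_unbalanced
    if n_art > n:
        raise ValueError("more artifacts requested than planted het sites")
    art_idx = rng.choice(n, size=n_art, replace=False) if n_art else np.array([], dtype=int)
    low_dp_idx = set(art_idx[:n_low_dp].tolist())
    low_qual_idx = set(art_idx[n_low_dp : n_low_dp + n_low_qual].tolist())
    unbal_idx = set(art_idx[n_low_dp + n_low_qual :].tolist())

    records = []
    sidecar = []
    for i, (contig, pos0, ref, alt) in enumerate(sites):
        dp = max(int(rng.poisson(contig.expected_depth)), 2)
        qual = float(rng.uniform(400, 1000))
        ad = None
        if i in low_dp_idx:
            dp = min_depth - 1
            sidecar.append((contig.name, pos0 + 1, "should_be_filtered", "low_depth"))
        if i in low_qual_idx:
            qual = min_snp_qual / 2.0
            sidecar.append((contig.name, pos0 + 1, "should_be_filtered", "low_qual"))
        if platform == "ont":
            if i in unbal_idx:
                alt_reads = max(int(np.floor(0.15 * dp)), 1)
                if alt_reads / dp >= 0.20:
                    alt_reads = max(int(np.floor(0.19 * dp)), 1)
                sidecar.append((contig.name, pos0 + 1, "should_not_be_het", "unbalanced"))
            else:
                alt_reads = int(np.clip(rng.binomial(dp, 0.5), 1, dp - 1))
            ad = (dp - alt_reads, alt_reads)
        records.append((contig.name, pos0 + 1, ref, alt, qual, "0/1", dp, ad))

    rio.write_vcf(out_vcf, records, truth.contig_lengths, with_ad=(platform == "ont"))
    sidecar_df = pd.DataFrame(sidecar, columns=["contig", "pos", "flag", "artifact"])
    if artifacts_tsv is not None:
        sidecar_df.to_csv(artifacts_tsv, sep="\t", index=False)
    return sidecar_df


# ---------------------------------------------------------------------------
# TE copies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEFamily:
    name: str
    te_class: str
    consensus: str

    def __post_init__(self) -> None:
        if any(b not in "ACGT" for b in self.consensus.upper()):
            raise ValueError("consensus must be ACGT-only")


@dataclass(frozen=True)
class TECopySpec:
    family: str
    target_divergence: float
    length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_divergence < 0.5:
            raise ValueError("target divergence must lie in [0, 0.5)")
        if self.length <= 0:
            raise ValueError("copy length must be positive")


@dataclass
class TESimSpec:
    families: Sequence[TEFamily]
    copies: Sequence[TECopySpec]
    ts_tv_ratio: float = 2.0
    tolerance: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        names = {f.name for f in self.families}
        for c in self.copies:
            if c.family not in names:
                raise ValueError(f"copy references unknown family {c.family!r}")


def _k2p_from_counts(ts: int, tv: int, n: int) -> float:
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return float("inf")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def gen_te_copies(
    spec: TESimSpec,
    host: GenomeTruth | Mapping[str, int],
    rng: np.random.Generator | None = None,
) -> tuple[list[TECopyRecord], pd.DataFrame, pd.DataFrame]:
    """Mutate consensus sequences into copies at target K80 divergences.

    Each copy accumulates single-base K80 substitutions (transition
    weighted kappa against 1 per transversion) until its realized distance
    to the consensus first reaches the target, which lands it within about
    1/length above the target. Returns the copy records (gap-free
    alignments), the insertion BED and the truth divergence table.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    fam_by_name = {f.name: f for f in spec.families}
    lengths = host.contig_lengths if isinstance(host, GenomeTruth) else dict(host)
    contig_names = sorted(lengths)
    cursors = {c: 100 for c in contig_names}
    kappa = spec.ts_tv_ratio

    records: list[TECopyRecord] = []
    bed_rows = []
    truth_rows = []
    which = 0
    for j, copy_spec in enumerate(spec.copies):
        fam = fam_by_name[copy_spec.family]
        cons = fam.consensus.upper()
        if copy_spec.length > len(cons):
            raise ValueError(
                f"copy length {copy_spec.length} exceeds consensus length {len(cons)}"
            )
        cons = cons[: copy_spec.length]
        cons_codes = np.frombuffer(cons.encode(), dtype="S1")
        enc = np.zeros(copy_spec.length, dtype=np.int8)
        for code, base in enumerate(b"ACGT"):
            enc[cons_codes == bytes([base])] = code
        copy_codes = enc.copy()

        n = copy_spec.length
        ts_count = tv_count = 0
        d = 0.0
        max_iter = 200 * n
        it = 0
        probs = np.array([kappa, 1.0, 1.0]) / (kappa + 2.0)
        while d < copy_spec.target_divergence:
            it += 1
            if it > max_iter:
                raise RuntimeError("target divergence not reached; check spec")
            site = int(rng.integers(n))
            cur = int(copy_codes[site])
            choice = rng.choice(3, p=probs)
            if choice == 0:
                new = int(_TS_PARTNER[cur])
            else:
                others = [b for b in range(4) if b != cur and b != _TS_PARTNER[cur]]
                new = others[choice - 1]
            ref = int(enc[site])
            # remove old pair class, add new
            if cur != ref:
                if cur == _TS_PARTNER[ref]:
                    ts_count -= 1
                else:
                    tv_count -= 1
            if new != ref:
                if new == _TS_PARTNER[ref]:
                    ts_count += 1
                else:
                    tv_count += 1
            copy_codes[site] = new
            d = _k2p_from_counts(ts_count, tv_count, n)

        copy_seq = _BASES[copy_codes.astype(np.intp)].tobytes().decode()
        realized = k2p(copy_seq, cons).d if copy_spec.target_divergence > 0 else 0.0

        contig = contig_names[which % len(contig_names)]
        which += 1
        start = cursors[contig]
        end = start + n
        if end > lengths[contig]:
            raise ValueError(f"host contig {contig} too short for TE insertions")
        cursors[contig] = end + 100

        copy_id = f"te_copy_{j + 1:04d}"
        records.append(
            TECopyRecord(
                copy_id=copy_id,
                family=f"{fam.name}#{fam.te_class}",
                te_class=classify_family(f"{fam.name}#{fam.te_class}"),
                contig=contig,
                start=start,
                end=end,
                copy_seq=copy_seq,
                cons_seq=cons,
                k2p_result=K2PResult(P=ts_count / n, Q=tv_count / n, n_sites=n, d=realized),
            )
        )
        bed_rows.append((contig, start, end, copy_id))
        truth_rows.append(
            {
                "copy_id": copy_id,
                "family": fam.name,
                "te_class": fam.te_class,
                "target_divergence": copy_spec.target_divergence,
                "realized_divergence": realized,
                "length": n,
            }
        )
    bed = pd.DataFrame(bed_rows, columns=["contig", "start", "end", "name"])
    truth = pd.DataFrame(truth_rows)
    return records, bed, truth


def write_te_align(records: Sequence[TECopyRecord], path, width: int = 50) -> None:
    """Write copy-vs-consensus alignments in the documented .align dialect."""
    with open(path, "w") as fh:
        for rec in records:
            assert rec.copy_seq is not None and rec.cons_seq is not None
            div = 100.0 * (rec.k2p_result.P + rec.k2p_result.Q) if rec.k2p_result else 0.0
            n = len(rec.copy_seq)
            fh.write(
                f"{max(int(2 * n), 1)} {div:.2f} 0.00 0.00 {rec.contig} "
                f"{rec.start + 1} {rec.end} (0) {rec.family} 1 {n} (0) {rec.copy_id}\n"
            )
            fam_name = rec.family.split("#")[0]
            for off in range(0, n, width):
                chunk_c = rec.copy_seq[off : off + width]
                chunk_f = rec.cons_seq[off : off + width]
                fh.write(f"  {rec.contig} {rec.start + 1 + off} {chunk_c} "
                         f"{rec.start + off + len(chunk_c)}\n")
                fh.write(f"  {fam_name} {off + 1} {chunk_f} {off + len(chunk_f)}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# ortholog codon alignments
# ---------------------------------------------------------------------------

def gen_ortholog_alignments(
    tree,
    n_genes: int,
    codons_per_gene: int = 200,
    third_position_rate: float = 1.0,
    first_second_rate: float = 0.1,
    kappa: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve codon alignments along a tree with fast third positions.

    Branch lengths are expected substitutions per third-position site when
    ``third_position_rate`` is 1; first/second positions evolve at
    ``first_second_rate`` times that. Substitutions follow K80 with the
    given kappa, so the expected pairwise third-position K80 distance
    between two tips equals their path length times the third-position
    rate. Returns {gene: {species: aligned CDS}} (no indels, hence already
    aligned).
    """
    import dendropy

    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if isinstance(tree, (str, Path)):
        text = str(tree)
        if "(" not in text:
            text = Path(tree).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
    rng = rng if rng is not None else np.random.default_rng(seed)

    sense = np.array(
        [[("ACGT".index(b)) for b in codon] for codon in SENSE_CODONS], dtype=np.int8
    )
    L = 3 * codons_per_gene
    rate_mult = np.tile([first_second_rate, first_second_rate, third_position_rate],
                        codons_per_gene)
    probs = np.array([kappa, 1.0, 1.0]) / (kappa + 2.0)

    out: dict[str, dict[str, str]] = {}
    for g in range(n_genes):
        codon_idx = rng.integers(len(sense), size=codons_per_gene)
        root = sense[codon_idx].reshape(-1)
        seqs: dict[int, np.ndarray] = {}
        gene: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                seq = root.copy()
            else:
                seq = seqs[id(parent)].copy()
                t = node.edge.length or 0.0
                if t > 0:
                    n_events = rng.poisson(rate_mult * t)
                    for site in np.flatnonzero(n_events):
                        for _ in range(int(n_events[site])):
                            cur = int(seq[site])
                            choice = rng.choice(3, p=probs)
                            if choice == 0:
                                seq[site] = _TS_PARTNER[cur]
                            else:
                                others = [b for b in range(4)
                                          if b != cur and b != _TS_PARTNER[cur]]
                                seq[site] = others[choice - 1]
            seqs[id(node)] = seq
            if node.is_leaf() and node.taxon is not None:
                gene[node.taxon.label] = _BASES[seq.astype(np.intp)].tobytes().decode()
        out[f"gene_{g + 1:04d}"] = gene
    return out


# ---------------------------------------------------------------------------
# pairwise coalescent
# ---------------------------------------------------------------------------

@dataclass
class CoalescentSpec:
    """Piecewise-constant-Ne pairwise coalescent, independent segments.

    ``epochs`` lists (start generation, Ne) from the present backwards;
    starts must begin at 0 and strictly increase. Within an epoch the
    two lineages coalesce at rate 1/(2 Ne) per generation.
    """

    epochs: Sequence[tuple[float, float]]
    mu: float = 1.3e-9
    seq_length_bp: int = 5_000_000
    n_segments: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("epochs must be non-empty")
        starts = [s for s, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch starts must strictly increase")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("Ne must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.n_segments < 1 or self.seq_length_bp < self.n_segments:
            raise ValueError("need >= 1 segment and seq length >= n_segments")


@dataclass
class CoalescentResult:
    spec: CoalescentSpec
    tmrca: np.ndarray            # generations, one per segment
    het_positions: np.ndarray    # 0-based, sorted, over the whole sequence
    contig: str = "sim_contig"

    @property
    def segment_length(self) -> int:
        return self.spec.seq_length_bp // self.spec.n_segments

    @property
    def total_length(self) -> int:
        return self.segment_length * self.spec.n_segments

    @property
    def het_rate(self) -> float:
        return self.het_positions.size / self.total_length

    def mask(self) -> CallableMask:
        return CallableMask({self.contig: [(0, self.total_length)]})

    def het_sites(self, genotype: str = "AC") -> dict[str, list[tuple[int, str]]]:
        return {self.contig: [(int(p), genotype) for p in self.het_positions]}


def simulate_pairwise_coalescent(
    spec: CoalescentSpec, rng: np.random.Generator | None = None
) -> CoalescentResult:
    """Draw per-segment TMRCAs and drop Poisson mutations on each segment.

    TMRCA per segment follows the piecewise-constant-Ne coalescent for two
    lineages (exponential with rate 1/(2 Ne) within each epoch); the
    heterozygous-site count per segment is Poisson(2 * TMRCA * mu * L_seg).
    At constant Ne the expected per-site heterozygosity is 4*Ne*mu.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_segments
    seg_len = spec.seq_length_bp // n
    tmrca = np.empty(n)
    remaining = np.arange(n)
    epochs = list(spec.epochs)
    for k, (start, ne) in enumerate(epochs):
        if remaining.size == 0:
            break
        span = (epochs[k + 1][0] - start) if k + 1 < len(epochs) else np.inf
        t = rng.exponential(2.0 * ne, size=remaining.size)
        done = (t < span) | np.isinf([span] * remaining.size)
        if k == len(epochs) - 1:
            done = np.ones(remaining.size, dtype=bool)
        tmrca[remaining[done]] = start + t[done]
        remaining = remaining[~done]

    n_mut = rng.poisson(2.0 * tmrca * spec.mu * seg_len)
    positions: list[np.ndarray] = []
    for i in np.flatnonzero(n_mut):
        k = min(int(n_mut[i]), seg_len)
        offs = rng.choice(seg_len, size=k, replace=False)
        positions.append(i * seg_len + np.sort(offs))
    het = np.concatenate(positions) if positions else np.array([], dtype=np.int64)
    return CoalescentResult(spec=spec, tmrca=tmrca, het_positions=np.sort(het))


# ---------------------------------------------------------------------------
# profile-level and coding-level shortcuts
# ---------------------------------------------------------------------------

def gen_contig_profiles(
    n_autosomal: int,
    n_hemizygous: int,
    rng: np.random.Generator,
    length_range: tuple[int, int] = (100_000, 1_000_000),
    gc_range: tuple[float, float] = (0.30, 0.45),
    depth_intercept: float = 20.0,
    depth_slope: float = 90.0,
    hemi_depth_multiplier: float = 0.5,
    depth_noise_sd: float = 3.0,
    theta: float = 0.005,
    theta_hemi: float = 3e-4,
    callable_fraction: float = 0.9,
) -> pd.DataFrame:
    """Per-contig profiles drawn from the depth/heterozygosity model only.

    Emulates the profile table of :func:`gen_diploid_genome` without
    materializing sequences — the input to sex-linkage classification at
    realistic contig counts.
    """
    rows = []
    for i in range(n_autosomal + n_hemizygous):
        hemi = i >= n_autosomal
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = float(rng.uniform(*gc_range))
        expected = depth_intercept + depth_slope * gc
        if hemi:
            expected *= hemi_depth_multiplier
        depth = max(float(rng.normal(expected, depth_noise_sd)), 0.0)
        n_callable = int(length * callable_fraction)
        th = theta_hemi if hemi else theta
        n_snp = int(rng.binomial(n_callable, th))
        rows.append(
            {
                "contig": f"ctg{i + 1:04d}",
                "length": length,
                "gc": gc,
                "median_depth": depth,
                "n_snp": n_snp,
                "het": n_snp / n_callable,
                "is_hemizygous": hemi,
            }
        )
    return pd.DataFrame(rows)


def gen_coding_pairs(
    n_codons: int,
    rng: np.random.Generator,
    het_syn_rate: float = 0.0078,
    pn_ps: float = 0.136,
    n_genes: int = 1,
) -> list[tuple[str, str]]:
    """Generate haplotype CDS pairs with a planted pN/pS ratio.

    Each synonymous single-base change occurs with probability
    ``het_syn_rate/3`` (so the synonymous per-site rate is
    ``het_syn_rate``) and each nonsynonymous change with that probability
    times ``pn_ps``; at most one change is applied per codon. Defaults
    plant a synonymous diversity of 0.78% and a pN/pS of 0.136.
    """
    if n_codons < 1 or n_genes < 1:
        raise ValueError("need at least one codon and one gene")
    q_syn = het_syn_rate / 3.0
    q_non = q_syn * pn_ps
    # precompute the nine single-base changes of every sense codon
    changes: dict[str, list[tuple[int, str, bool]]] = {}
    for codon in SENSE_CODONS:
        lst = []
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                mutant = codon[:i] + b + codon[i + 1 :]
                syn = CODON_TO_AA[mutant] == CODON_TO_AA[codon] and CODON_TO_AA[mutant] != "*"
                lst.append((i, b, syn))
        changes[codon] = lst

    per_gene = n_codons // n_genes
    genes: list[tuple[str, str]] = []
    codon_pool = list(SENSE_CODONS)
    for g in range(n_genes):
        count = per_gene if g < n_genes - 1 else n_codons - per_gene * (n_genes - 1)
        idx = rng.integers(len(codon_pool), size=count)
        a_parts: list[str] = []
        b_parts: list[str] = []
        us = rng.random(count)
        for k in range(count):
            codon = codon_pool[idx[k]]
            a_parts.append(codon)
            u = us[k]
            chosen = None
            acc = 0.0
            for i, b, syn in changes[codon]:
                acc += q_syn if syn else q_non
                if u < acc:
                    chosen = (i, b)
                    break
            if chosen is None:
                b_parts.append(codon)
            else:
                i, b = chosen
                b_parts.append(codon[:i] + b + codon[i + 1 :])
        genes.append(("".join(a_parts), "".join(b_parts)))
    return genes
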