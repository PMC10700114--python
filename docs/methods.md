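# Methods

This note documents the statistical models, conventions and design choices
behind each module, and what the synthetic-data tests do and do not
demonstrate about real data.

## Heterozygosity and the callable mask

Heterozygosity for a single diploid individual is estimated as
H = (heterozygous biallelic SNVs inside the mask) / (mask bp). Everything
therefore hinges on two filters with deliberately different boundary
semantics:

* **Calling filters** (`variant_filters.apply_filters`) are *inclusive*:
  a record is rejected only when its depth is below the minimum or above
  the maximum, or its quality below the threshold. Built-in rule sets:
  short-read calls keep 15× ≤ DP ≤ 200× with SNP QUAL ≥ 200; long-read
  calls keep 10× ≤ DP ≤ 150×, site QUAL ≥ 50, SNP QUAL ≥ 300, and require
  the alternate allele on strictly more than 20% and less than 80% of
  reads. A het call failing the balance window is *reclassified* to the
  homozygous genotype of its majority allele rather than dropped — the
  balance rule defines when a SNP is believed, not whether the site is
  callable. Long-read het calls without per-allele counts fail closed.
  Indels and multiallelic records never enter het counts
  (`NOT_BIALLELIC_SNV`); every rejection carries exactly one primary
  reason code, and filtering is idempotent.
* **The depth mask** used for demographic-inference input
  (`depth_mask`) is *strict* (min < depth < max), with short contigs
  (< 500 kb by convention for the coalescent HMM; < 30 kb for genome-wide
  H) and sex-linked contigs excluded, and repeat annotations subtracted
  exactly (interval-set difference, verified against per-base boolean
  arithmetic).

All interval arithmetic is 0-based half-open internally; VCF and
multihetsep conventions (1-based) are converted at I/O boundaries only.

## Coding site classes

Synonymous/nonsynonymous site counting defaults to the Nei–Gojobori
fractional convention: each codon position contributes
(#synonymous single-base changes)/3 synonymous sites, so syn + nonsyn = 3
per codon exactly; changes to stop codons count as nonsynonymous. A
degeneracy-class mode is available in which only 4-fold positions enter
the synonymous denominator and only 0-fold positions the nonsynonymous one
(2- and 3-fold positions enter neither); this changes pS's denominator and
is therefore reported explicitly. A het site is synonymous when swapping
the two alleles in codon context — other positions held at the
haplotype-A base — preserves the amino acid; codons het at several
positions are evaluated per site under that convention (pathway averaging
is out of scope; such codons are vanishingly rare at θ ≈ 0.5%). pN/pS
with pS = 0 is an explicit undefined marker, never 0 or ∞. Pairwise
alignment π (the mitogenome statistic) counts each mismatching
both-unambiguous column once, with no multiple-hit correction.

## Sex-linkage classification

Median depth is modelled as log-linear in GC; the fit is Huber-robust and
weighted by √(contig length), so a minority of hemizygous contigs cannot
drag the trend. On the log2 scale the hemizygous state is an additive
−1 residual, which motivates the default residual cut of −0.5 (midway
between the diploid and haploid states, ≈ 70% of expected depth). A
contig is Z-linked iff residual ≤ −0.5 AND (H ≤ 1e−3 or it has no SNPs);
autosomal iff residual > −0.5 AND H > 1e−3; otherwise ambiguous. Contigs
under 30 kb are excluded (unstable medians). Both cuts are parameters: the
residual criterion formalizes what is often done by visual inspection, so
the threshold is a package choice, documented rather than inherited. The
optional female:male depth ratio (normalized by each sample's autosomal
median) expects 0.5 on Z and 1.0 on autosomes, flagging contigs ≤ 0.65.

Note the generator draws sequencing depth linearly in GC
(depth = a + b·GC + noise, truncated at 0) while the classifier fits
log2(depth) on GC. Over realistic GC ranges (0.30–0.45) the log of an
affine function is almost exactly linear, so the residuals stay well
inside the ±0.5 decision band; the mismatch is intentional — the
classifier should not assume the generator's functional form.

## K80 distances and TE landscapes

The Kimura two-parameter distance d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) is
computed over columns free of gaps and ambiguity in both sequences
(pairwise deletion). Saturation (either log argument ≤ 0) raises a typed
error; saturated copies are tallied in an "unscorable" bucket, never
silently dropped. The plain K80 form is used, not the CpG-adjusted
variant some annotation pipelines apply. One `k2p` implementation serves
both TE copies and species distances — the single-source-of-truth that
makes the two scales comparable.

Landscapes bin copies by floor(100·d) into 1% bins over [0, 0.5); d ≥ 0.5
goes to an overflow bucket (beyond the annotation detection horizon). Bin
weight is aligned (non-gap) copy bp, falling back to genomic span when no
alignment is stored; the two coincide for the indel-free synthetic data.
"Other" (simple repeats, satellites, structural RNAs) is excluded from
landscapes but counted in totals. The `.align` reader parses a documented
dialect — one header line (score, divergence percentages, query
coordinates, `family#class/subfamily`, copy id) followed by paired,
possibly chunked aligned-sequence lines — plus a TSV fallback; malformed
blocks are skipped and counted.

The TE-content/genome-size correlation is reported both as ordinary
Pearson r and under phylogenetic generalized least squares with a
Brownian-motion covariance (shared root-to-MRCA branch length); on a star
tree with equal tip lengths PGLS reduces to OLS, which the tests verify.

## Divergence clock

Species distances are medians over genes of per-gene pairwise K80 at third
codon positions ("median pairwise"), with a concatenation mode offered as
an alternative; genes missing any species are dropped when `shared_only`.
Internal nodes are annotated with the median (and min) over all tip pairs
spanning the node. TE bp is partitioned at a node's divergence value with
linear apportioning inside the straddled bin; the partition carries a
caveat flag when ≥ 10% of bp is unscorable or beyond the horizon, and a
node beyond 0.5 triggers a warning. Raw K80 values are compared without
rate correction — a deliberate apples-to-apples approximation: TE
consensus distance and neutral interspecies distance are both absolute
substitution estimates, but rate variation between repeats and third
positions is not modelled.

## Demography preparation and scaling

The recombination argument: C chromosomes × x crossovers per tetrad per
male meiosis × 0.5 (a tetrad crossover recombines half the products) gives
the male map in Morgans; dividing by L gives the male-transmitted rate,
by 2L the sex-averaged rate when females are achiasmatic. Both conventions
are explicit parameters because published per-site rates often do not say
which was used. The `baronia` preset (30 chromosomes, 406 Mb, x = 1,
μ = 1.3e−9, generation time 1) yields r = 3.69e−8 male-only or 1.85e−8
sex-averaged, i.e. ρ/μ well above 10 either way; the preset stores the
value conventionally passed to the coalescent HMM (10) as a separate
constant rather than deriving it, since the ratio itself rounds to 28 or
14 depending on convention.

multihetsep rows are (contig, 1-based position, callable sites since the
previous row, genotype); the first row counts from the contig's first
masked position. Writing then parsing is the identity on site/count
structure, and per-contig count sums never exceed the contig's mask bp.
Scaled output conversion uses years = t/μ·g and Ne = 1/(2μλ) — stated in
output headers because these conventions differ across tools. Bootstraps
resample 5 Mb chunks with replacement.

## Synthetic data: what it does and does not emulate

* **Genome**: heterozygous sites are independent Bernoulli(θ) draws on
  non-repeat sites — no linkage, no mutation-rate heterogeneity, no
  clustering of SNVs; repeats are placed as 1 kb blocks on a grid. Depth
  is Gaussian per 1 kb window around a GC-linear expectation (defaults
  intercept 20, slope 90 → ≈ 54× at GC 0.37, the long-read scale of a
  typical single-specimen study), hemizygous contigs at multiplier 0.5.
  Defaults: θ = 0.005 (autosomes), θ_hemi = 3e−4 (residual caller noise on
  a hemizygous chromosome), repeat fraction 10%.
* **VCF emission**: DP ~ Poisson(expected depth), QUAL ~ U(400, 1000),
  long-read allele depths Binomial(DP, 0.5); injected artifacts (DP one
  below the platform minimum, QUAL at half the SNP threshold, alt
  fraction ≈ 0.15) are flagged in a truth sidecar. There is no
  genotype-likelihood model — only the VCF-level behaviour of a caller is
  emulated, since the upstream callers' internals are out of scope.
* **TE copies**: single-base K80 substitutions (transition weight κ = 2,
  matching the ts/tv prior commonly used for long-read calling) are
  applied until the realized copy-consensus K2P first reaches the target,
  which lands within ≈ 1.5/length above it; no indels (K2P is defined on
  substitutions). Realized distances are recorded as truth.
* **Orthologs**: codons evolve along the tree under K80 with third
  positions at the branch-length rate and positions 1–2 at 0.1× — no
  selection beyond that rate asymmetry, no indels, no stop-codon
  avoidance during evolution (alignments are used only for third-position
  distances).
* **Coalescent**: independent segments, TMRCA drawn from the
  piecewise-constant-Ne two-lineage coalescent (rate 1/(2Ne) per
  generation within an epoch), mutations Poisson(2·T·μ·L_seg). There is
  no recombination structure *within* the simulator, so it validates
  expectation-level statistics (E[H] = 4Neμ, stochastic ordering between
  demographic scenarios) and input-file plumbing — not the coalescent
  HMM's ability to recover a trajectory.
* **Coding pairs**: each synonymous single-base change occurs with
  probability p_syn/3 and each nonsynonymous change with that times the
  planted pN/pS; at most one change per codon. Defaults plant pS = 0.78%
  and pN/pS = 0.136.

Consequently, passing tests show the estimators are unbiased and the file
formats round-trip under the stated models; they do not probe mapping
artifacts, linked selection, indel errors, or assembly collapse, which
real data contain.

## Problem sizes and numerical choices

Parameter-recovery checks run on a 10 Mb genome (20 × 500 kb contigs,
≈ 45k planted SNVs), a 200,000-codon coding set (≈ 470 expected
nonsynonymous hets, giving ≈ 5% sampling error on pN/pS against the 15%
acceptance band), 200 contig profiles for sex linkage, 45 TE copies × 500
bp for landscape modes, and a 5 Mb / 500-segment coalescent run (3
analytic SE ≈ 14% of the expectation). These sizes were chosen so each
statistic's Monte-Carlo error is several-fold smaller than its tolerance.
All generators consume one explicitly passed `numpy.random.Generator`;
fixed seeds give byte-identical output files. Interval operations are
exact integer arithmetic; K80 saturation and zero-denominator cases
(empty masks, pS = 0, zero comparable columns) raise typed errors rather
than returning sentinel numbers.

## Known limitations

Single-individual statistics only (no Watterson/Tajima multi-sample
estimators, no divergence-based dN/dS); no phasing; no W-chromosome
detection; TE discovery and consensus building are upstream tools' jobs —
this package consumes their output formats; the coalescent HMM itself is
external (only its inputs and output scaling are handled here).
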