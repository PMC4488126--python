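# Methods

This note records the statistical models, default parameters and
numerical choices implemented in rrbskit, and their limitations.

## Reference preparation and digestion

Restriction sites are matched exactly (IUPAC degeneracy expanded to
character classes; `N` in the *sequence* never matches). Non-palindromic
sites are additionally searched on the reverse complement with the
mirrored cut offset `len(site) - offset`. Fragments are the intervals
between consecutive cut positions; the pre-filter fragment set tiles
each chromosome, and the target set keeps fragments whose length lies
in `[min_fragment, max_fragment]`.

Defaults: MspI `CCGG` with cut offset 1 (`C^CGG`); target window
40–220 bp for analysis of real libraries. The simulator examples use
90–220 bp so that every target fragment is at least as long as a read.

Bisulfite alignment operates on converted references: a C→T copy
(Watson) and a G→A copy (Crick), both written by `prepare-ref`.

## Methylation calling

A cytosine observation requires: mapped, primary, non-duplicate
alignment; mapping quality ≥ 20; base quality ≥ 13. Watson/Crick
assignment prefers the `XG` tag (`CT`/`GA`), falling back to the
reverse-strand flag. Only reference cytosines of the matching strand
are informative: C/T read bases on Watson, G/A on Crick; anything else
at such a site is ignored.

**Overlap deduplication.** Reads are grouped by query name; one
fragment contributes at most one observation per site. Conflicts
resolve by base quality; at equal quality an agreement keeps mate 1's
observation and a disagreement discards the site for that fragment
(counted in `discordant_overlaps`). Single-end data is unaffected:
dedup and naive counting coincide.

Contexts are CpG / CHG / CHH on both strands; cytosines whose context
window contains `N` or runs off the sequence end are excluded. Region
rates are observation-weighted by default (total methylated over total
observations); site weighting (mean of per-site rates) is available.

## Differential methylation

Each shared cytosine yields a 2×2 table of methylated/unmethylated
counts in the two samples. The test is Pearson's chi-square without
continuity correction; whenever **any cell is below 5** it switches to
Fisher's exact two-sided test. A DMC requires p < `alpha` (0.05) and
an absolute rate difference above `min_delta` (0.1). Benjamini–Hochberg
q-values are reported for transparency; thresholding uses raw p-values.

**Fisher implementation.** The exact test conditions on both margins
and sums hypergeometric probabilities of tables at most as probable as
the observed one. Table likelihoods are compared as exact integers
(`C(r1,k)·C(r2,n−k)`), so ties — which occur systematically in
symmetric tables — are resolved without a floating-point tolerance.
Degenerate margins return p = 1. The implementation is cross-checked in
the test suite against an independent hypergeometric enumeration and
against `scipy.stats.fisher_exact`.

**Seed and extension.** CpG counts are pooled across the two strands of
each dinucleotide and paired between samples where both have coverage
(`min_depth` 1). A window of `seed_size` (5) consecutive CpGs is a seed
when its pooled table passes the DMC gates and every CpG's rate
difference has the same nonzero sign. Seeds are scanned left to right
and never overlap. Extension adds one CpG at a time, alternating right
then left; a candidate is accepted while (i) its difference keeps the
seed's sign, (ii) the extended pooled table stays significant with
|Δ| > `min_delta`, and (iii) a paired two-sided t-test on per-CpG rates
stays below `alpha`. The t-test is waived when the per-CpG differences
are all equal (zero variance makes the statistic undefined); the pooled
test then governs. Regions from one pass never overlap: leftward growth
is floored at the end of the previous region. Region coordinates span
the first CpG's C to the last dinucleotide's G.

## Allele-specific methylation

Heterozygous biallelic SNVs come from a VCF, or from a built-in screen
over the alignments. The screen counts only bisulfite-unambiguous
evidence (C and T bases ignored on Watson reads, G and A on Crick) and
calls a site heterozygous when two alleles each reach 20% of at least
10 unambiguous observations; candidates involving a C or G allele are
flagged `confounded` because half their evidence is invisible. The
screen is a deliberately simple heuristic, not a genotyper.

Fragments are phased by the base observed at the SNP, after discarding
bases conversion could explain (T on Watson when a C allele is in play;
A on Crick when a G allele is). Mate overlaps at the SNP deduplicate by
quality, and an equal-quality disagreement discards the fragment for
that SNP. CpG observations are merged at the dinucleotide level. Each
linked SNP–CpG pair accumulates a 2×2 allele × methylation table over
fragments, tested with the same chi-square/Fisher rule and thresholds
as DMCs. The allele balance of contributing fragments is reported but
never filtered on.

## Simulator

The genome model is diploid: each SNP site maps to the bases carried by
haplotype 0 and 1 (heterozygous with probability `het_fraction`, 0.5).
Defaults: SNP rate 5×10⁻⁴ per base restricted to target fragments,
read length 90, paired-end, conversion rate 1.0, error rate 0.

Methylation is assigned per cytosine from non-overlapping segment
specifications (overlap is rejected); CpG rates are symmetric across
the two strands of a dinucleotide. Each molecule draws methylation
states independently per site (Bernoulli at the site rate), then
undergoes conversion, optional sequencing error, and read extraction
from both fragment ends.

**Coverage semantics.** `coverage` is fold coverage *per strand*: each
target fragment on each strand receives `round(coverage)` molecules,
and every sequenced position of a molecule is covered exactly once by
the fragment (mate overlap is double-read but single-molecule). At the
default 10-fold this yields per-strand site depth ≈ 10 and ≈ 20
observations per CpG dinucleotide after strand pooling.

Allele-specific segments carry `rate_ref`/`rate_alt` and an
`allele_fraction` (fraction of molecules from haplotype 0; 0.5 models a
monoclonal heterozygous sample). A segment without a usable
heterozygous anchor SNP gets one planted near its midpoint with an A/T
allele pair, which bisulfite chemistry cannot disguise on either
strand. Truth outputs: alignments with haplotype tags, FASTQ, VCF (with
a `BSC` flag for C/T and G/A confounded SNPs), per-site truth rates,
and the list of truth-linked SNP–CpG pairs with their allele rates.

**Realism limits.** Reads are uniformly laid at fragment ends (no
fragmentation noise, no adaptor read-through), base quality is
constant, errors are uniform substitutions, conversion failure is
site-independent, and alignment is bypassed entirely (truth SAM).
Consequences: error rates of downstream callers on real aligner output
are *not* predicted by these simulations; what the simulations do
establish is correctness of the counting, testing and phasing logic
under a known ground truth.

## Pipeline determinism and resume

Every stage is a pure function of its configuration, inputs and the
seed; outputs carry no timestamps and FASTQ is written uncompressed (or
gzip with a zeroed mtime), so fresh runs are byte-identical. A stage
marker stores a SHA-256 over the stage parameters and input file
contents; a stage re-runs only when its marker, checksum or outputs are
missing or stale. Per-sample simulation seeds derive as
`seed*1000 + sample_index`.

The coverage report computes, for each depth threshold (default 1, 4,
10, 20), the fraction of island CpG-context cytosines covered at least
that deeply; the denominator is all island CpGs of the reference, and
islands default to the target fragments when no BED is given. The QC
verdict is `warn` when any consecutive relative drop exceeds
`max_decay` (0.5) — a heuristic for uneven coverage, not a calibrated
statistic.

## Numerical and testing choices

- Chi-square uses `scipy.stats.chi2_contingency(correction=False)`;
  the suite checks it against the closed-form Pearson statistic
  `N(ad−bc)² / (r₁r₂c₁c₂)`.
- Fisher's test is the integer-weight implementation described above;
  the suite enumerates all tables with both row sums ≤ 30 (≈ 2.5×10⁵
  tables) against an independent hypergeometric oracle at 1e-12.
- BH q-values use `scipy.stats.false_discovery_control`.
- The paired t-test uses `scipy.stats.ttest_rel`, with the degenerate
  waiver above.
- Stochastic tests fix seeds and assert within 3σ binomial bounds or
  conservative type-I bounds; they are deterministic reruns, not
  flaky tolerances.

## Limitations

- No real aligner integration is bundled; external SAM/BAM can be
  supplied, but mapping-induced biases (multi-mapping in converted
  space, clipping) are out of scope.
- The DMR extension tests each candidate conditionally; no multiple-
  testing correction is applied at the region level.
- The het-SNP screen has no ploidy or error model and will miss C/T
  and G/A hets on the strand where they are invisible.
- CHG/CHH methylation is counted but all region logic (seeds, islands)
  is CpG-centric.
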