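# rrbskit

A toolkit for reduced-representation bisulfite sequencing (RRBS)
analysis on a diploid genome model: in-silico restriction digestion,
bisulfite read preparation, per-cytosine methylation calling with
paired-end overlap deduplication, differentially methylated cytosine
and region (DMC/DMR) detection by seed-and-extend, allele-specific
methylation (ASM) detection anchored on heterozygous SNPs, and a
bisulfite read simulator that emits complete ground truth. A single
YAML configuration drives a resume-able end-to-end pipeline.

## The scientific problem

Bisulfite treatment converts unmethylated cytosines to uracil (read as
T) while 5-methylcytosine is protected, so aligned reads reveal the
methylation state of each cytosine. RRBS enriches for CpG-dense regions
by sequencing only the restriction fragments (MspI, `C^CGG`) that fall
in a target length window, giving deep coverage of CpG islands at a
fraction of whole-genome cost.

Two pitfalls drive the design of this package:

1. **Paired-end overlap double counting.** Short RRBS fragments are
   often shorter than twice the read length, so the two mates of a pair
   overlap. Both mates observe the *same molecule*; counting a CpG in
   the overlap twice biases the methylation estimate toward whatever
   state that one fragment happened to carry, and the bias direction
   depends on which fragments were sequenced paired-end. The caller
   therefore counts at most one observation per fragment per site,
   resolving mate disagreements by base quality.
2. **Bisulfite/SNP confounding.** A C→T SNP is indistinguishable from
   an unmethylated cytosine on the converted strand. SNP-aware logic
   runs through the ASM caller and the built-in heterozygous-SNP
   screen: observations that conversion could explain are discarded
   rather than miscounted.

## Core model

- **Digestion** — exact in-silico scan for enzyme sites (IUPAC
  degeneracy supported, both strands for non-palindromic sites);
  fragments between consecutive cut sites are kept when their length
  falls in the target window (default 40–220 bp).
- **Methylation calling** — Watson-strand reads report C (methylated)
  vs T (unmethylated) at reference C; Crick-strand reads report G vs A
  at reference G. Strand comes from the Bismark-style `XG` tag with a
  flag-based fallback. Per fragment, overlapping mate observations are
  merged: higher base quality wins, quality-tied agreements defer to
  mate 1, quality-tied disagreements are discarded and counted.
- **DMC/DMR detection** — each shared cytosine is tested on a 2×2
  count table: Pearson chi-square without continuity correction, or
  Fisher's exact test whenever any cell is below 5; a DMC needs
  p < 0.05 and a rate difference above 0.1. DMRs grow from 5-CpG seed
  windows (pooled test, consistent per-CpG sign) extended one CpG at a
  time while the pooled test, a paired t-test on per-CpG rates, and the
  sign gate all hold. Benjamini–Hochberg q-values are reported.
- **ASM detection** — fragments observing both a heterozygous SNP and
  a CpG are phased to one allele; the resulting allele × methylation
  table is tested like a DMC. Allele balance is reported (monoclonal
  heterozygous ≈ 0.5; skew indicates mixtures or loss of
  heterozygosity) but never used as a filter.
- **Simulator** — diploid haplotypes with configurable SNP rate,
  per-molecule Bernoulli methylation from a per-cytosine rate map,
  strand-symmetric CpG rates, optional allele-specific segments with a
  planted unambiguous (A/T) anchor SNP, and per-strand fold coverage.
  Outputs: truth alignments (SAM), FASTQ, truth VCF, truth methylation
  rates, and in-memory linked ASM truth pairs.

## Worked example: the overlap bias

A target fragment carries three CpGs; one PE read pair covers it with
the mates overlapping over the middle CpG, which is methylated; the two
flanking CpGs are unmethylated and covered once each. The fragment's
true methylation rate is 1/3.

```python
from rrbskit.examples import pe_overlap_example

ex = pe_overlap_example()
print(ex["rate_dedup"], ex["rate_naive"])
# 0.3333333333333333 0.5
for s in ex["methylome_dedup"].sites():
    print(s.chrom, s.pos, s.strand, s.context, s.n_meth, s.n_unmeth)
# frag 2 + CpG 0 1
# frag 8 + CpG 1 0
# frag 14 + CpG 0 1
```

Deduplicated counting recovers 33% (1/3); naive counting sees the
overlapped CpG twice and reports 50% (2/4). With mixed layouts the
naive estimate even depends on *which* fragment was sequenced
paired-end (`mixed_layout_example`: 33% vs 66% naive, 50% either way
with deduplication).

## End-to-end pipeline

```bash
rrbskit init-config --out config.yaml   # fully populated defaults
rrbskit run-all --config config.yaml
```

The default configuration simulates two samples ("normal", "cancer",
each with random per-fragment methylation) on a 200 kb synthetic
chromosome and runs every stage. Representative output from that run:

- `ref/targets.bed` — 109 target fragments, e.g.
  `chrSim  674  877  fragment_0  203`
- `meth/normal.cytosine.tsv` — 5,238 called cytosines:

  ```
  chrom   pos  strand context n_meth n_unmeth rate
  chrSim  675  +      CpG     5      5        0.5
  chrSim  676  -      CpG     2      8        0.2
  chrSim  677  -      CHG     0      10       0.0
  ```

- `dmr/dmr.tsv` — 38 regions between the two random-rate samples, e.g.
  `chrSim 674 875 6 0.725 0.442 +0.283 8.5e-06 hyper`
- `asm/asm.tsv` — linked SNP–CpG tables plus summary counters
  (`n_pairs_tested`, `n_events`, discarded ambiguous observations).
- `report/summary.json` — mean depth 10.0 and the fraction of island
  CpGs covered at depths 1/4/10/20 per sample, with a QC verdict that
  flags steep coverage decay.

Every stage writes a checksum marker; re-running `run-all` skips intact
stages and reproduces deleted downstream outputs byte for byte, since
the whole pipeline is deterministic under the configured seed.

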