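"""Allele-specific methylation from heterozygous-SNP-anchored read phasing.

A heterozygous SNP whose base is visible on the same sequenced fragment
as a CpG ("linked SNP-CpG pair") phases that fragment's methylation
observation to one allele. Pooling fragments gives a 2x2 table of
allele x methylation state per linked pair, tested like a DMC
(chi-square, Fisher below 5 per cell); an event requires p < alpha and
an allele rate difference above min_delta. The allele balance of the
contributing fragments is reported — it separates monoclonal
heterozygous samples (~0.5) from polyclonal mixtures and loss of
heterozygosity (skewed) — but is never used as a filter.

Bisulfite chemistry hides some alleles: on a Watson-strand read an
observed T may be a converted C, and on a Crick-strand read an observed
A may be a converted (reverse-strand) C, so such observations are
discarded whenever a C (respectively G) allele is in play. The built-in
heterozygous-SNP screen applies the same logic genome-wide; it is a
deliberately simple heuristic for when no external VCF is available,
not a genotyper.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam

from rrbskit.dmr import test_2x2
from rrbskit.methylation import (WATSON, CRICK, Observation, bisulfite_strand_of,
                                 resolve_overlap, _read_site_calls,
                                 _effective_masks)
from rrbskit.reference import CytosineContextIndex, Genome, TargetFragment


@dataclass
class HetSNP:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    source: str = "vcf"  # vcf | screen
    allele_frequency: Optional[float] = None
    confounded: bool = False

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


def load_het_snps(vcf_path, sample: Optional[str] = None) -> list[HetSNP]:
    """Heterozygous biallelic SNVs from a VCF (first sample by default)."""
    snps: list[HetSNP] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        names = list(vf.header.samples)
        if not names:
            raise ValueError(f"VCF {vcf_path} has no sample genotypes")
        which = sample if sample is not None else names[0]
        for rec in vf:
            if len(rec.ref) != 1 or len(rec.alts or ()) != 1 \
                    or len(rec.alts[0]) != 1:
                continue
            gt = rec.samples[which].get("GT")
            if gt is None or len(set(a for a in gt if a is not None)) != 2:
                continue
            alleles = {rec.ref, rec.alts[0]}
            snps.append(HetSNP(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0],
                               "vcf", None,
                               alleles == {"C", "T"} or alleles == {"G", "A"}))
    return snps


def resolve_allele(ref: str, alt: str, base: str, bs_strand: str
                   ) -> Optional[str]:
    """Map an observed read base to an allele, or None when ambiguous.

    An observed T on a Watson read (or A on a Crick read) is discarded
    when a C (or G) allele is possible, since conversion could have
    produced it.
    """
    alleles = {ref, alt}
    if base not in alleles:
        return None
    if bs_strand == WATSON and base == "T" and "C" in alleles:
        return None
    if bs_strand == CRICK and base == "A" and "G" in alleles:
        return None
    return base


def _usable_reads(alignments: Union[str, Iterable[pysam.AlignedSegment]],
                  min_mapq: int) -> list[pysam.AlignedSegment]:
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
            reads = list(af)
    else:
        reads = list(alignments)
    return [r for r in reads
            if not (r.is_unmapped or r.is_secondary or r.is_supplementary
                    or r.is_duplicate or r.mapping_quality < min_mapq)]


def screen_het_snps(alignments, genome: Genome, min_depth: int = 10,
                    min_alt_frac: float = 0.2, min_mapq: int = 20,
                    min_baseq: int = 13) -> list[HetSNP]:
    """Heuristic heterozygous-SNP screen over bisulfite alignments.

    Counts only bisulfite-unambiguous evidence: C and T observations are
    ignored on Watson-strand reads, G and A on Crick-strand reads. A
    site is called heterozygous when two alleles each reach
    ``min_alt_frac`` of the unambiguous depth and that depth is at least
    ``min_depth``. Candidates with a C or G allele (evidence halved by
    the exclusion) are flagged confounded.
    """
    counts: dict[tuple[str, int], Counter] = defaultdict(Counter)
    for read in _usable_reads(alignments, min_mapq):
        bs = bisulfite_strand_of(read)
        excluded = "CT" if bs == WATSON else "GA"
        seq = read.query_sequence
        quals = read.query_qualities
        chrom = read.reference_name
        cig = read.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] == 0:
            pairs = enumerate(range(read.reference_start,
                                    read.reference_start + cig[0][1]))
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
        for qpos, rpos in pairs:
            base = seq[qpos]
            if base in excluded or base == "N":
                continue
            if quals is not None and quals[qpos] < min_baseq:
                continue
            counts[(chrom, rpos)][base] += 1
    snps: list[HetSNP] = []
    for (chrom, pos), ctr in sorted(counts.items()):
        depth = sum(ctr.values())
        if depth < min_depth:
            continue
        top = ctr.most_common(2)
        if len(top) < 2:
            continue
        (a1, n1), (a2, n2) = top
        if n1 / depth < min_alt_frac or n2 / depth < min_alt_frac:
            continue
        ref_base = genome[chrom][pos]
        if ref_base in (a1, a2):
            ref, alt = ref_base, a1 if a1 != ref_base else a2
            alt_n = n1 if alt == a1 else n2
        else:  # neither allele matches the reference; report the top two
            ref, alt, alt_n = a1, a2, n2
        snps.append(HetSNP(chrom, pos, ref, alt, "screen", alt_n / depth,
                           confounded=bool({"C", "G"} & {ref, alt})))
    return snps


@dataclass
class LinkedPairTable:
    """Allele x methylation counts for one linked SNP-CpG pair."""

    snp: HetSNP
    cpg_chrom: str
    cpg_pos: int  # + strand C position of the CpG dinucleotide
    counts: list  # [[ref_meth, ref_unmeth], [alt_meth, alt_unmeth]]


@dataclass
class ASMEvent:
    snp: HetSNP
    cpg_chrom: str
    cpg_pos: int
    counts: list
    rate_ref: float
    rate_alt: float
    delta: float
    p_value: float
    test_used: str
    allele_balance: float  # fraction of phased fragments carrying ref


def link_pairs(alignments, snps: Sequence[HetSNP],
               index: CytosineContextIndex,
               min_mapq: int = 20, min_baseq: int = 13,
               fragments: Optional[Sequence[TargetFragment]] = None
               ) -> tuple[list[LinkedPairTable], dict]:
    """Accumulate allele x methylation tables over sequenced fragments.

    PE mates are one fragment: both the SNP base and the CpG state are
    overlap-deduplicated before contributing, and a fragment whose SNP
    base matches neither allele (or is bisulfite-ambiguous) is discarded
    for that SNP and counted.
    """
    snp_by_pos = {(s.chrom, s.pos): s for s in snps}
    plus_mask, minus_mask = _effective_masks(index, fragments)
    by_fragment: dict[str, list[pysam.AlignedSegment]] = defaultdict(list)
    for read in _usable_reads(alignments, min_mapq):
        if read.reference_name not in index.lengths:
            raise ValueError(
                f"alignment references unknown chromosome {read.reference_name!r}")
        by_fragment[read.query_name].append(read)

    tables: dict[tuple, list] = {}
    discarded = 0
    for reads in by_fragment.values():
        # deduplicated SNP base and CpG observations for this fragment
        snp_obs: dict[tuple[str, int], tuple[str, int, int]] = {}
        cpg_obs: dict[tuple[str, int], Observation] = {}
        for read in reads:
            chrom = read.reference_name
            bs = bisulfite_strand_of(read)
            mate = 2 if (read.is_paired and read.is_read2) else 1
            seq = read.query_sequence
            quals = read.query_qualities
            cig = read.cigartuples
            if cig is not None and len(cig) == 1 and cig[0][0] == 0:
                pairs = list(enumerate(range(read.reference_start,
                                             read.reference_start + cig[0][1])))
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
            for qpos, rpos in pairs:
                snp = snp_by_pos.get((chrom, rpos))
                if snp is None:
                    continue
                qual = 40 if quals is None else quals[qpos]
                if qual < min_baseq:
                    continue
                allele = resolve_allele(snp.ref, snp.alt, seq[qpos], bs)
                key = (chrom, rpos)
                if key in snp_obs:
                    prev_allele, prev_qual, prev_mate = snp_obs[key]
                    if qual > prev_qual or (qual == prev_qual
                                            and allele != prev_allele):
                        # disagreement at equal quality poisons the call
                        if qual == prev_qual and allele != prev_allele:
                            allele = None
                        snp_obs[key] = (allele, qual, mate)
                else:
                    snp_obs[key] = (allele, qual, mate)
            mask = plus_mask[chrom] if bs == WATSON else minus_mask[chrom]
            strand = "+" if bs == WATSON else "-"
            for rpos, state, qual in _read_site_calls(read, mask, bs, min_baseq):
                if index.context[(chrom, rpos, strand)] != "CpG":
                    continue
                dinuc = rpos if strand == "+" else rpos - 1
                key = (chrom, dinuc)
                obs = Observation(state, qual, mate)
                cpg_obs[key] = resolve_overlap(cpg_obs[key], obs) \
                    if key in cpg_obs else obs
        for (chrom, spos), (allele, _q, _m) in snp_obs.items():
            snp = snp_by_pos[(chrom, spos)]
            if allele is None:
                discarded += 1
                continue
            row = 0 if allele == snp.ref else 1
            for (cchrom, cpos), obs in cpg_obs.items():
                if cchrom != chrom or obs.state is None:
                    continue
                tkey = (chrom, spos, cpos)
                tab = tables.setdefault(tkey, [[0, 0], [0, 0]])
                tab[row][0 if obs.state == "M" else 1] += 1

    out = [LinkedPairTable(snp_by_pos[(c, s)], c, p, tab)
           for (c, s, p), tab in sorted(tables.items())]
    return out, {"n_fragments": len(by_fragment),
                 "n_discarded_snp_observations": discarded}


def test_asm(table: LinkedPairTable, alpha: float = 0.05,
             min_delta: float = 0.1) -> Optional[ASMEvent]:
    """Test one linked pair; None when untestable or below thresholds."""
    (rm, ru), (am, au) = table.counts
    if rm + ru == 0 or am + au == 0:
        return None
    p, test = test_2x2(rm, ru, am, au)
    rate_ref = rm / (rm + ru)
    rate_alt = am / (am + au)
    delta = rate_ref - rate_alt
    if p < alpha and abs(delta) > min_delta:
        return ASMEvent(table.snp, table.cpg_chrom, table.cpg_pos,
                        table.counts, rate_ref, rate_alt, delta, p, test,
                        allele_balance=(rm + ru) / (rm + ru + am + au))
    return None


def call_asm(alignments, snps: Sequence[HetSNP], index: CytosineContextIndex,
             alpha: float = 0.05, min_delta: float = 0.1,
             min_mapq: int = 20, min_baseq: int = 13,
             fragments: Optional[Sequence[TargetFragment]] = None
             ) -> tuple[list[ASMEvent], dict]:
    """All ASM events over the linked SNP-CpG pairs, plus summary counts."""
    if not snps:
        warnings.warn("no heterozygous SNPs supplied; no ASM detectable")
        return [], {"n_snps": 0, "n_pairs_tested": 0, "n_events": 0,
                    "n_asm_snps": 0}
    tables, link_stats = link_pairs(alignments, snps, index, min_mapq,
                                    min_baseq, fragments)
    events: list[ASMEvent] = []
    n_tested = 0
    for tab in tables:
        (rm, ru), (am, au) = tab.counts
        if rm + ru > 0 and am + au > 0:
            n_tested += 1
        ev = test_asm(tab, alpha, min_delta)
        if ev is not None:
            events.append(ev)
    events.sort(key=lambda e: (e.cpg_chrom, e.snp.pos, e.cpg_pos))
    summary = {"n_snps": len(snps), "n_pairs_linked": len(tables),
               "n_pairs_tested": n_tested, "n_events": len(events),
               "n_asm_snps": len({(e.snp.chrom, e.snp.pos) for e in events}),
               **link_stats}
    return events, summary


def write_asm_tsv(events: Sequence[ASMEvent], summary: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in sorted(summary.items()):
            fh.write(f"# {k}={v}\n")
        fh.write("chrom\tsnp_pos\tref\talt\tcpg_pos\tref_meth\tref_unmeth\t"
                 "alt_meth\talt_unmeth\trate_ref\trate_alt\tdelta\tp_value\t"
                 "test\tallele_balance\n")
        for e in events:
            (rm, ru), (am, au) = e.counts
            fh.write(f"{e.snp.chrom}\t{e.snp.pos + 1}\t{e.snp.ref}\t"
                     f"{e.snp.alt}\t{e.cpg_pos + 1}\t{rm}\t{ru}\t{am}\t{au}\t"
                     f"{e.rate_ref:.6f}\t{e.rate_alt:.6f}\t{e.delta:+.6f}\t"
                     f"{e.p_value:.6g}\t{e.test_used}\t"
                     f"{e.allele_balance:.4f}\n")
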