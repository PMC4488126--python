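"""Bisulfite read simulator with full ground truth.

Emulates an RRBS experiment end to end: enzyme-digested target
fragments, randomly injected SNPs on a diploid genome model,
per-segment CpG methylation rates, per-molecule Bernoulli methylation
states, bisulfite chemistry (unmethylated C reads as T on Watson-strand
molecules, as A at the corresponding G on Crick-strand molecules),
optional sequencing error, and SE/PE reads sampled evenly from both
strands of every fragment. Reads are emitted both as FASTQ and as truth
alignments (SAM), so the downstream callers can be exercised without an
external aligner; truth SNPs (VCF) and assigned site rates (TSV) are
written alongside.

Allele-specific methylation is simulated by giving a segment two
methylation rates, one per haplotype, anchored on a heterozygous SNP
that identifies the haplotype on every fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from rrbskit.reference import (Genome, TargetFragment, CytosineContextIndex,
                               index_cytosines, reverse_complement)

_BASES = "ACGT"


@dataclass
class SegmentSpec:
    """A reference interval whose CpGs share one methylation rate."""

    chrom: str
    start: int
    end: int
    rate: float

    def __post_init__(self):
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError("methylation rate must be in [0, 1]")


@dataclass
class ASMSegmentSpec:
    """A segment with haplotype-specific CpG methylation rates.

    ``allele_fraction`` is the fraction of molecules carrying haplotype
    0 (the reference allele at the anchor SNP): 0.5 models a monoclonal
    heterozygous sample; skewed values model polyclonal mixtures or loss
    of heterozygosity.
    """

    chrom: str
    start: int
    end: int
    rate_ref: float
    rate_alt: float
    allele_fraction: float = 0.5

    def __post_init__(self):
        for r in (self.rate_ref, self.rate_alt, self.allele_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates and allele fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 1
    snp_rate: float = 0.0005
    het_fraction: float = 0.5
    read_length: int = 90
    coverage: float = 10.0  # fold per strand
    layout: str = "PE"  # PE or SE
    conversion_rate: float = 1.0
    error_rate: float = 0.0
    non_cpg_rate: float = 0.0
    default_cpg_rate: float = 0.0
    base_quality: int = 40

    def __post_init__(self):
        if self.layout not in ("PE", "SE"):
            raise ValueError("layout must be PE or SE")
        for r in (self.snp_rate, self.het_fraction, self.conversion_rate,
                  self.error_rate, self.non_cpg_rate, self.default_cpg_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class TruthSNP:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    confounded: bool = False  # C/T or G/A allele pair: hidden by bisulfite


@dataclass
class TruthSet:
    """Everything the simulator knows that a caller must recover."""

    snps: list[TruthSNP] = field(default_factory=list)
    site_rates: dict[tuple[str, int, str], float] = field(default_factory=dict)
    asm_pairs: list[dict] = field(default_factory=list)
    n_reads: int = 0
    n_bases: int = 0


def random_genome(length: int, seed: int, gc: float = 0.42,
                  name: str = "chrSim") -> Genome:
    """A single random chromosome with human-like GC content."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list(_BASES), size=length, p=p))
    return Genome({name: seq})


def _is_confounded(ref: str, alt: str) -> bool:
    alleles = {ref, alt}
    return alleles == {"C", "T"} or alleles == {"G", "A"}


def inject_snps(genome: Genome, snp_rate: float, rng: np.random.Generator,
                het_fraction: float = 0.5,
                fragments: Optional[Sequence[TargetFragment]] = None,
                ) -> tuple[dict[tuple[str, int], tuple[str, str]], list[TruthSNP]]:
    """Select random sites as SNPs on a diploid genome model.

    Returns ``(haplotype_bases, truth_snps)`` where ``haplotype_bases``
    maps (chrom, pos) to the bases carried by haplotype 0 and haplotype 1.
    Restricting to ``fragments`` mirrors placing SNPs "on the segments"
    the experiment sequences.
    """
    haplotypes: dict[tuple[str, int], tuple[str, str]] = {}
    snps: list[TruthSNP] = []
    if snp_rate == 0.0:
        return haplotypes, snps
    for chrom in genome.names():
        seq = genome[chrom]
        if fragments is None:
            candidate = np.arange(len(seq))
        else:
            candidate = np.concatenate([np.arange(f.start, f.end)
                                        for f in fragments if f.chrom == chrom]
                                       or [np.empty(0, dtype=int)])
        if candidate.size == 0:
            continue
        hits = candidate[rng.random(candidate.size) < snp_rate]
        for pos in hits:
            ref = seq[pos]
            if ref == "N":
                continue
            alt = _BASES.replace(ref, "")[rng.integers(3)]
            het = rng.random() < het_fraction
            if het:
                haplotypes[(chrom, int(pos))] = (ref, alt)
            else:
                haplotypes[(chrom, int(pos))] = (alt, alt)
            snps.append(TruthSNP(chrom, int(pos), ref, alt,
                                 "het" if het else "hom",
                                 _is_confounded(ref, alt)))
    snps.sort(key=lambda s: (s.chrom, s.pos))
    return haplotypes, snps


def assign_methylation(index: CytosineContextIndex,
                       segments: Sequence[SegmentSpec],
                       default_cpg_rate: float = 0.0,
                       non_cpg_rate: float = 0.0,
                       ) -> dict[tuple[str, int, str], float]:
    """Per-site theoretical methylation rates from segment assignments.

    Every CpG inside a segment carries that segment's rate; CpGs outside
    all segments carry ``default_cpg_rate`` and non-CpG cytosines
    ``non_cpg_rate``. The two strands of one CpG dinucleotide get the
    same rate (methylation is symmetric on a duplex). Overlapping
    segments are rejected.
    """
    by_chrom: dict[str, list[SegmentSpec]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError("overlapping methylation segments")
    rates: dict[tuple[str, int, str], float] = {}
    for chrom, pos, strand, ctx in index:
        if ctx != "CpG":
            rates[(chrom, pos, strand)] = non_cpg_rate
            continue
        dinuc = pos if strand == "+" else pos - 1
        rate = default_cpg_rate
        for seg in by_chrom.get(chrom, []):
            if seg.start <= dinuc < seg.end:
                rate = seg.rate
                break
        rates[(chrom, pos, strand)] = rate
    return rates


def _covered_intervals(frag: TargetFragment, read_length: int,
                       layout: str) -> list[tuple[int, int]]:
    L = min(read_length, frag.length)
    if layout == "SE" or 2 * L >= frag.length:
        if layout == "SE":
            return [(frag.start, frag.start + L)]  # per-strand 5' end differs
        return [(frag.start, frag.end)]
    return [(frag.start, frag.start + L), (frag.end - L, frag.end)]


class _SamWriter:
    def __init__(self, path, genome: Genome):
        header = {"HD": {"VN": "1.6", "SO": "unsorted"},
                  "SQ": [{"SN": n, "LN": len(genome[n])} for n in genome.names()]}
        self.af = pysam.AlignmentFile(str(path), "wh", header=header)
        self.tid = {n: i for i, n in enumerate(genome.names())}

    def write(self, qname, chrom, pos, seq, flag, baseq, mate_pos, tlen, xg, hap):
        a = pysam.AlignedSegment(self.af.header)
        a.query_name = qname
        a.query_sequence = seq
        a.flag = flag
        a.reference_id = self.tid[chrom]
        a.reference_start = pos
        a.mapping_quality = 60
        a.cigartuples = [(0, len(seq))]
        a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(seq))
        if mate_pos is not None:
            a.next_reference_id = self.tid[chrom]
            a.next_reference_start = mate_pos
            a.template_length = tlen
        a.set_tag("XG", xg)
        a.set_tag("XH", hap)
        self.af.write(a)

    def close(self):
        self.af.close()


def write_truth_vcf(snps: Sequence[TruthSNP], genome: Genome, path,
                    sample: str = "sim") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names():
            fh.write(f"##contig=<ID={name},length={len(genome[name])}>\n")
        fh.write('##INFO=<ID=BSC,Number=0,Type=Flag,'
                 'Description="Bisulfite-confounded allele pair">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for s in snps:
            info = "BSC" if s.confounded else "."
            gt = "0/1" if s.genotype == "het" else "1/1"
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                     f"{info}\tGT\t{gt}\n")


def write_truth_rates(rates: dict[tuple[str, int, str], float],
                      index: CytosineContextIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\trate\n")
        for chrom, pos, strand, ctx in index:
            fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{ctx}\t"
                     f"{rates[(chrom, pos, strand)]:.6f}\n")


def simulate_reads(genome: Genome,
                   fragments: Sequence[TargetFragment],
                   config: SimulationConfig,
                   out_prefix,
                   site_rates: Optional[dict] = None,
                   haplotypes: Optional[dict] = None,
                   snps: Optional[list[TruthSNP]] = None,
                   asm_segments: Sequence[ASMSegmentSpec] = (),
                   index: Optional[CytosineContextIndex] = None,
                   sample: str = "sim",
                   rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Simulate bisulfite reads over the target fragments.

    Writes ``<prefix>.truth.sam``, ``<prefix>_1.fastq`` (+ ``_2`` for
    PE), ``<prefix>.truth.vcf`` and ``<prefix>.truth_meth.tsv``; returns
    the in-memory truth set. Molecules are sampled evenly: each fragment
    on each strand receives enough molecules for the configured fold
    coverage of its sequenced bases.
    """
    if not fragments:
        raise ValueError("no target fragments to simulate from")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    index = index if index is not None else index_cytosines(genome)
    if site_rates is None:
        site_rates = assign_methylation(index, [], config.default_cpg_rate,
                                        config.non_cpg_rate)
    if haplotypes is None or snps is None:
        haplotypes, snps = inject_snps(genome, config.snp_rate, rng,
                                       config.het_fraction, fragments)
    truth = TruthSet(snps=snps, site_rates=dict(site_rates))

    # anchor het SNP per ASM segment: identifies the haplotype on a fragment
    asm_by_chrom: dict[str, list[tuple[ASMSegmentSpec, int]]] = {}
    for seg in asm_segments:
        anchors = [s for s in snps
                   if s.chrom == seg.chrom and seg.start <= s.pos < seg.end
                   and s.genotype == "het" and not s.confounded]
        if not anchors:
            warnings.warn(f"ASM segment {seg.chrom}:{seg.start}-{seg.end} "
                          "has no usable heterozygous SNP; no ASM simulated")
            continue
        asm_by_chrom.setdefault(seg.chrom, []).append((seg, anchors[0].pos))

    # sorted site position arrays per chromosome for fast fragment slicing
    site_pos: dict[str, np.ndarray] = {}
    for chrom in genome.names():
        site_pos[chrom] = np.array([p for p, _, _ in index.sites(chrom)],
                                   dtype=np.int64)

    L = config.read_length
    out_prefix = str(out_prefix)
    sam = _SamWriter(out_prefix + ".truth.sam", genome)
    fq1 = open(out_prefix + "_1.fastq", "w")
    fq2 = open(out_prefix + "_2.fastq", "w") if config.layout == "PE" else None
    qstr = chr(config.base_quality + 33)

    def fastq_write(fh, qname, seq):
        fh.write(f"@{qname}\n{seq}\n+\n{qstr * len(seq)}\n")

    for fi, frag in enumerate(fragments):
        seq0 = genome[frag.chrom][frag.start:frag.end]
        flen = frag.length
        rl = min(L, flen)
        # each molecule covers every sequenced position of the fragment
        # exactly once, so the per-strand fold equals the molecule count
        n_mol = max(1, int(round(config.coverage)))
        frag_snps = [(p - frag.start, haplotypes[(frag.chrom, p)])
                     for (c, p) in haplotypes
                     if c == frag.chrom and frag.start <= p < frag.end]
        # cytosine sites of each strand within the fragment
        sites = {"W": [], "C": []}
        pos_arr = site_pos[frag.chrom]
        lo = int(np.searchsorted(pos_arr, frag.start, side="left"))
        hi = int(np.searchsorted(pos_arr, frag.end, side="left"))
        chrom_sites = index.sites(frag.chrom)
        for si in range(lo, hi):
            pos, strand, ctx = chrom_sites[si]
            sites["W" if strand == "+" else "C"].append(
                (pos - frag.start, site_rates[(frag.chrom, pos, strand)]))
        asm_here = None
        for seg, anchor in asm_by_chrom.get(frag.chrom, []):
            if frag.start < seg.end and seg.start < frag.end and \
                    frag.start <= anchor < frag.end:
                asm_here = (seg, anchor)
                break

        for strand in ("W", "C"):
            for mi in range(n_mol):
                if asm_here is not None:
                    hap = 0 if rng.random() < asm_here[0].allele_fraction else 1
                else:
                    hap = int(rng.integers(2))
                bases = list(seq0)
                for off, alleles in frag_snps:
                    bases[off] = alleles[hap]
                # per-molecule methylation states at this strand's cytosines
                meth: dict[int, bool] = {}
                for off, rate in sites[strand]:
                    if asm_here is not None and \
                            asm_here[0].start <= frag.start + off < asm_here[0].end:
                        ctx = index.context.get(
                            (frag.chrom, frag.start + off,
                             "+" if strand == "W" else "-"))
                        if ctx == "CpG":
                            rate = (asm_here[0].rate_ref if hap == 0
                                    else asm_here[0].rate_alt)
                    meth[off] = bool(rng.random() < rate) if 0 < rate < 1 \
                        else rate >= 1.0
                # bisulfite chemistry in forward coordinates
                target, conv = ("C", "T") if strand == "W" else ("G", "A")
                for off, b in enumerate(bases):
                    if b != target:
                        continue
                    if meth.get(off, False):
                        continue
                    if config.conversion_rate >= 1.0 or \
                            rng.random() < config.conversion_rate:
                        bases[off] = conv
                if config.error_rate > 0.0:
                    for off in range(flen):
                        if rng.random() < config.error_rate:
                            bases[off] = _BASES.replace(bases[off], "")[
                                rng.integers(3)]
                mol = "".join(bases)
                qname = f"{sample}:{fi}:{strand}:{mi}"
                xg = "CT" if strand == "W" else "GA"
                if config.layout == "PE":
                    s1, s2 = mol[:rl], mol[flen - rl:]
                    p1, p2 = frag.start, frag.end - rl
                    if strand == "W":
                        sam.write(qname, frag.chrom, p1, s1, 99,
                                  config.base_quality, p2, flen, xg, hap)
                        sam.write(qname, frag.chrom, p2, s2, 147,
                                  config.base_quality, p1, -flen, xg, hap)
                        fastq_write(fq1, qname + "/1", s1)
                        fastq_write(fq2, qname + "/2", reverse_complement(s2))
                    else:
                        sam.write(qname, frag.chrom, p2, s2, 83,
                                  config.base_quality, p1, -flen, xg, hap)
                        sam.write(qname, frag.chrom, p1, s1, 163,
                                  config.base_quality, p2, flen, xg, hap)
                        fastq_write(fq1, qname + "/1", reverse_complement(s2))
                        fastq_write(fq2, qname + "/2", s1)
                    truth.n_reads += 2
                    truth.n_bases += 2 * rl
                else:
                    if strand == "W":
                        sam.write(qname, frag.chrom, frag.start, mol[:rl], 0,
                                  config.base_quality, None, 0, xg, hap)
                        fastq_write(fq1, qname, mol[:rl])
                    else:
                        sam.write(qname, frag.chrom, frag.end - rl,
                                  mol[flen - rl:], 16,
                                  config.base_quality, None, 0, xg, hap)
                        fastq_write(fq1, qname, reverse_complement(mol[flen - rl:]))
                    truth.n_reads += 1
                    truth.n_bases += rl

        if asm_here is not None:
            seg, anchor = asm_here
            if abs(seg.rate_ref - seg.rate_alt) > 0:
                cov = _covered_intervals(frag, L, config.layout)
                in_cov = lambda p: any(s <= p < e for s, e in cov)
                if in_cov(anchor):
                    seen = set()
                    for pos, strand, ctx in chrom_sites[lo:hi]:
                        if ctx != "CpG" or not (seg.start <= pos < seg.end):
                            continue
                        if not in_cov(pos):
                            continue
                        dinuc = pos if strand == "+" else pos - 1
                        if dinuc in seen:
                            continue
                        seen.add(dinuc)
                        truth.asm_pairs.append(
                            {"chrom": frag.chrom, "snp_pos": anchor,
                             "cpg_pos": dinuc, "rate_ref": seg.rate_ref,
                             "rate_alt": seg.rate_alt})

    sam.close()
    fq1.close()
    if fq2 is not None:
        fq2.close()
    write_truth_vcf(snps, genome, out_prefix + ".truth.vcf", sample)
    write_truth_rates(site_rates, index, out_prefix + ".truth_meth.tsv")
    return truth


def simulate_asm(genome: Genome,
                 fragments: Sequence[TargetFragment],
                 asm_segments: Sequence[ASMSegmentSpec],
                 config: SimulationConfig,
                 out_prefix,
                 index: Optional[CytosineContextIndex] = None,
                 sample: str = "sim",
                 background_rate: float = 0.5) -> TruthSet:
    """Simulate reads whose methylation depends on the allele at a het SNP.

    Background SNPs are injected at ``config.snp_rate`` as usual; on top,
    each ASM segment that lacks a usable heterozygous anchor gets one
    planted near its midpoint with an A/T allele pair, which bisulfite
    chemistry cannot disguise on either strand. CpGs outside ASM
    segments methylate at ``background_rate``.
    """
    rng = np.random.default_rng(config.seed)
    index = index if index is not None else index_cytosines(genome)
    haplotypes, snps = inject_snps(genome, config.snp_rate, rng,
                                   config.het_fraction, fragments)
    by_pos = {(s.chrom, s.pos): s for s in snps}
    for seg in asm_segments:
        usable = [s for s in snps
                  if s.chrom == seg.chrom and seg.start <= s.pos < seg.end
                  and s.genotype == "het" and not s.confounded]
        if usable:
            continue
        mid = (seg.start + seg.end) // 2
        planted = None
        for delta in range(0, (seg.end - seg.start) // 2):
            for pos in (mid - delta, mid + delta):
                if not (seg.start <= pos < seg.end) or (seg.chrom, pos) in by_pos:
                    continue
                ref = genome[seg.chrom][pos]
                if ref not in "AT":
                    continue
                # avoid destroying/creating a CpG with the planted allele
                alt = "T" if ref == "A" else "A"
                planted = TruthSNP(seg.chrom, pos, ref, alt, "het", False)
                break
            if planted:
                break
        if planted is None:
            warnings.warn(f"could not plant an anchor SNP in ASM segment "
                          f"{seg.chrom}:{seg.start}-{seg.end}")
            continue
        haplotypes[(planted.chrom, planted.pos)] = (planted.ref, planted.alt)
        snps.append(planted)
        by_pos[(planted.chrom, planted.pos)] = planted
    snps.sort(key=lambda s: (s.chrom, s.pos))
    site_rates = assign_methylation(
        index, [SegmentSpec(s.chrom, s.start, s.end, 0.0) for s in asm_segments],
        default_cpg_rate=background_rate, non_cpg_rate=config.non_cpg_rate)
    return simulate_reads(genome, fragments, config, out_prefix,
                          site_rates=site_rates, haplotypes=haplotypes,
                          snps=snps, asm_segments=asm_segments, index=index,
                          sample=sample, rng=rng)
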