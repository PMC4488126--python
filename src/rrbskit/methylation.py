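"""Per-cytosine methylation calling with paired-end overlap deduplication.

Bisulfite treatment converts unmethylated cytosine to uracil (sequenced
as T) while 5-methylcytosine is protected, so at a reference C a read C
means methylated and a read T unmethylated (mirrored as G/A for reads
from the Crick strand). When the two mates of a paired-end fragment
overlap, the overlap covers the same molecule twice; counting it twice
biases the methylation rate, so each fragment contributes at most one
observation per site. Within an overlap the higher-quality base wins,
ties go to mate 1, and a quality-tied disagreement makes the site
uninformative for that fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pysam

from rrbskit.reference import CytosineContextIndex, TargetFragment

WATSON = "W"
CRICK = "C"


def call_base_state(ref_base: str, bisulfite_strand: str,
                    read_base: str) -> Optional[str]:
    """Classify one aligned base as methylated ('M'), unmethylated ('U') or None.

    Watson-strand reads inform reference C positions (C = methylated,
    T = unmethylated); Crick-strand reads inform reference G positions
    (G = methylated, A = unmethylated). Everything else is uninformative.
    """
    if bisulfite_strand == WATSON and ref_base == "C":
        return {"C": "M", "T": "U"}.get(read_base)
    if bisulfite_strand == CRICK and ref_base == "G":
        return {"G": "M", "A": "U"}.get(read_base)
    return None


def bisulfite_strand_of(read: pysam.AlignedSegment) -> str:
    """Originating bisulfite strand of an alignment.

    Prefers the Bismark-style ``XG`` tag (``CT`` = Watson, ``GA`` =
    Crick); otherwise falls back to the directional-protocol convention
    that read 1 sequences the original strand.
    """
    if read.has_tag("XG"):
        tag = read.get_tag("XG")
        if tag == "CT":
            return WATSON
        if tag == "GA":
            return CRICK
        raise ValueError(f"unrecognized XG tag {tag!r}")
    if read.is_paired and read.is_read2:
        return WATSON if read.is_reverse else CRICK
    return CRICK if read.is_reverse else WATSON


@dataclass
class Observation:
    """One fragment's base call at one cytosine site."""

    state: Optional[str]  # 'M', 'U' or None (uninformative)
    qual: int
    mate: int  # 1 or 2 (SE reads count as mate 1)


def resolve_overlap(obs1: Observation, obs2: Observation) -> Observation:
    """Collapse the two mates' observations of one site into one.

    Higher base quality wins; on a quality tie mate 1 wins, unless the
    states disagree, in which case the site is uninformative for the
    fragment.
    """
    if obs1.qual > obs2.qual:
        return obs1
    if obs2.qual > obs1.qual:
        return obs2
    if obs1.state != obs2.state:
        return Observation(None, obs1.qual, obs1.mate)
    return obs1 if obs1.mate <= obs2.mate else obs2


@dataclass
class SiteMethylation:
    """Deduplicated methylated/unmethylated counts at one cytosine."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    context: str  # CpG / CHG / CHH
    n_meth: int = 0
    n_unmeth: int = 0

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def rate(self) -> Optional[float]:
        return self.n_meth / self.total if self.total else None


class Methylome:
    """Per-cytosine methylation counts for one sample."""

    def __init__(self, sample: str = "sample"):
        self.sample = sample
        self._sites: dict[tuple[str, int, str], SiteMethylation] = {}
        self.discordant_overlaps = 0

    def add(self, chrom: str, pos: int, strand: str, context: str,
            state: str) -> None:
        key = (chrom, pos, strand)
        site = self._sites.get(key)
        if site is None:
            site = self._sites[key] = SiteMethylation(chrom, pos, strand, context)
        if state == "M":
            site.n_meth += 1
        else:
            site.n_unmeth += 1

    def get(self, chrom: str, pos: int, strand: str) -> Optional[SiteMethylation]:
        return self._sites.get((chrom, pos, strand))

    def sites(self) -> list[SiteMethylation]:
        return [self._sites[k] for k in sorted(self._sites)]

    def __len__(self) -> int:
        return len(self._sites)

    def merged_cpg_counts(self) -> dict[tuple[str, int], tuple[int, int]]:
        """CpG counts merged across strands, keyed by the + strand C position.

        CpG methylation is symmetric on the two strands of a duplex, so
        the Watson C at p and the Crick C at p+1 report on the same CpG;
        merging them doubles the effective depth per CpG.
        """
        merged: dict[tuple[str, int], tuple[int, int]] = {}
        for (chrom, pos, strand), site in self._sites.items():
            if site.context != "CpG":
                continue
            start = pos if strand == "+" else pos - 1
            m, u = merged.get((chrom, start), (0, 0))
            merged[(chrom, start)] = (m + site.n_meth, u + site.n_unmeth)
        return merged

    def write_tsv(self, path) -> None:
        """chrom, 1-based pos, strand, context, counts, rate."""
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tstrand\tcontext\tn_meth\tn_unmeth\trate\n")
            for s in self.sites():
                fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.context}\t"
                         f"{s.n_meth}\t{s.n_unmeth}\t{s.rate:.6f}\n")

    def write_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sites():
                fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.rate:.6f}\n")

    @classmethod
    def from_tsv(cls, path, sample: str = "sample") -> "Methylome":
        meth = cls(sample)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom\t"):
                raise ValueError(f"unexpected methylation TSV header in {path}")
            for line in fh:
                chrom, pos, strand, ctx, nm, nu, _rate = line.rstrip("\n").split("\t")
                site = SiteMethylation(chrom, int(pos) - 1, strand, ctx,
                                       int(nm), int(nu))
                meth._sites[(site.chrom, site.pos, site.strand)] = site
        return meth


def _effective_masks(index: CytosineContextIndex,
                     fragments: Optional[Iterable[TargetFragment]]
                     ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    if fragments is None:
        return index.plus_mask, index.minus_mask
    allowed = {c: np.zeros(n, dtype=bool) for c, n in index.lengths.items()}
    for f in fragments:
        allowed[f.chrom][f.start:f.end] = True
    plus = {c: index.plus_mask[c] & allowed[c] for c in allowed}
    minus = {c: index.minus_mask[c] & allowed[c] for c in allowed}
    return plus, minus


def _read_site_calls(read: pysam.AlignedSegment, mask: np.ndarray,
                     bs_strand: str, min_baseq: int):
    """Yield (ref_pos, state, qual) for indexed cytosines under this read."""
    seq = read.query_sequence
    quals = read.query_qualities
    ref_base = "C" if bs_strand == WATSON else "G"
    cig = read.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        start = read.reference_start
        offsets = np.nonzero(mask[start:start + cig[0][1]])[0]
        pairs = ((int(off), start + int(off)) for off in offsets)
    else:
        pairs = ((q, r) for q, r in read.get_aligned_pairs(matches_only=True)
                 if mask[r])
    for qpos, rpos in pairs:
        qual = 40 if quals is None else quals[qpos]
        if qual < min_baseq:
            continue
        state = call_base_state(ref_base, bs_strand, seq[qpos])
        if state is not None:
            yield rpos, state, qual


def pileup_methylation(alignments: Union[str, Iterable[pysam.AlignedSegment]],
                       index: CytosineContextIndex,
                       dedup: bool = True,
                       min_mapq: int = 20,
                       min_baseq: int = 13,
                       fragments: Optional[Iterable[TargetFragment]] = None,
                       sample: str = "sample") -> Methylome:
    """Accumulate per-cytosine methylation counts from alignments.

    With ``dedup=True`` (the default, and the correct setting for paired
    data) each fragment contributes at most one observation per site;
    ``dedup=False`` counts every informative aligned base, double-counting
    mate overlaps — useful only to demonstrate the bias it causes.
    ``fragments`` restricts counting to digested target regions (RRBS
    semantics); pass None for genome-wide (Bis-seq) counting.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
            return pileup_methylation(list(af), index, dedup, min_mapq,
                                      min_baseq, fragments, sample)
    plus_mask, minus_mask = _effective_masks(index, fragments)
    meth = Methylome(sample)
    # per-fragment pending observations, flushed when the pair completes
    pending: dict[str, dict[tuple[str, int, str], Observation]] = {}
    seen_once: set[str] = set()

    def flush(qname: str) -> None:
        for (chrom, pos, strand), obs in pending.pop(qname).items():
            if obs.state is None:
                meth.discordant_overlaps += 1
                continue
            meth.add(chrom, pos, strand,
                     index.context[(chrom, pos, strand)], obs.state)

    for read in alignments:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.is_duplicate or read.mapping_quality < min_mapq):
            continue
        chrom = read.reference_name
        if chrom not in index.lengths:
            raise ValueError(f"alignment references unknown chromosome {chrom!r}")
        bs = bisulfite_strand_of(read)
        mask = plus_mask[chrom] if bs == WATSON else minus_mask[chrom]
        strand = "+" if bs == WATSON else "-"
        mate = 2 if (read.is_paired and read.is_read2) else 1
        if not dedup:
            for rpos, state, _q in _read_site_calls(read, mask, bs, min_baseq):
                meth.add(chrom, rpos, strand,
                         index.context[(chrom, rpos, strand)], state)
            continue
        frag = pending.setdefault(read.query_name, {})
        for rpos, state, qual in _read_site_calls(read, mask, bs, min_baseq):
            key = (chrom, rpos, strand)
            obs = Observation(state, qual, mate)
            frag[key] = resolve_overlap(frag[key], obs) if key in frag else obs
        if not read.is_paired or read.query_name in seen_once:
            seen_once.discard(read.query_name)
            flush(read.query_name)
        else:
            seen_once.add(read.query_name)
    for qname in list(pending):  # unpaired leftovers (orphaned mates)
        flush(qname)
    return meth


def region_rate(methylome: Methylome, chrom: str, start: int, end: int,
                weighting: str = "observation",
                context: Optional[str] = None) -> Optional[float]:
    """Aggregate methylation rate over [start, end).

    ``observation`` weighting pools counts (sum meth / sum total);
    ``site`` weighting averages per-site rates. Returns None when no
    covered site falls in the interval.
    """
    if weighting not in ("observation", "site"):
        raise ValueError("weighting must be 'observation' or 'site'")
    rates, n_meth, n_total = [], 0, 0
    for site in methylome.sites():
        if site.chrom != chrom or not (start <= site.pos < end):
            continue
        if context is not None and site.context != context:
            continue
        if site.total == 0:
            continue
        rates.append(site.rate)
        n_meth += site.n_meth
        n_total += site.total
    if not rates:
        return None
    if weighting == "observation":
        return n_meth / n_total
    return float(np.mean(rates))
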