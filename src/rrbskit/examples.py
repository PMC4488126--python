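"""Worked examples of the paired-end overlap bias, built in memory.

These tiny fixtures reproduce the canonical schematic for why mate
overlaps must be counted once. A target fragment holds three CpGs; a PE
read pair covers it with the mates overlapping over the middle CpG,
which is methylated, while the two flanking CpGs are unmethylated and
covered once each. The fragment's true methylation rate is 1/3; naive
counting sees the overlapped CpG twice and reports 2/4.

A second pair of fixtures mixes sequencing layouts: one methylated and
one unmethylated single-CpG fragment, one sequenced PE with its CpG in
the mate overlap, the other SE. The true pooled rate is 1/2, but
without overlap deduplication the PE fragment's CpG is counted twice,
dragging the estimate to 1/3 or 2/3 depending on which fragment got the
PE layout.
"""

from __future__ import annotations

import pysam

from rrbskit.methylation import Methylome, pileup_methylation, region_rate
from rrbskit.reference import Genome, index_cytosines

# three CpGs at positions 2, 8 and 14; mates overlap over [6, 12)
THREE_CPG_REF = "TTCGTTTTCGTTTTCGTT"
# a single CpG at position 8 of each 18 bp fragment
ONE_CPG_FRAG = "TTTTTTTTCGTTTTTTTT"


def _header(length: int, name: str = "frag") -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": name, "LN": length}]})


def make_read(header: pysam.AlignmentHeader, qname: str, pos: int, seq: str,
              mate: int = 0, qual: int = 40, xg: str = "CT",
              quals: list[int] | None = None) -> pysam.AlignedSegment:
    """An ungapped alignment; ``mate`` 0 means single-end, ``xg`` the
    bisulfite strand tag (CT = Watson, GA = Crick)."""
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigartuples = [(0, len(seq))]
    if quals is None:
        quals = [qual] * len(seq)
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals))
    if mate:
        a.flag = 99 if mate == 1 else 147
    a.set_tag("XG", xg)
    return a


def pe_overlap_example() -> dict:
    """The three-CpG fragment covered by one overlapping PE pair.

    Returns the deduplicated and naive fragment methylation rates
    (0.333... and 0.5) along with the objects used to compute them.
    """
    genome = Genome({"frag": THREE_CPG_REF})
    index = index_cytosines(genome)
    header = _header(len(THREE_CPG_REF))
    # mate 1 covers [0,12): flanking CpG unmethylated (T), middle kept C
    # mate 2 covers [6,18): middle kept C, flanking CpG unmethylated (T)
    reads = [
        make_read(header, "pair1", 0, "TTTGTTTTCGTT", mate=1),
        make_read(header, "pair1", 6, "TTCGTTTTTGTT", mate=2),
    ]
    dedup = pileup_methylation(reads, index, dedup=True)
    naive = pileup_methylation(
        [make_read(header, "pair1", 0, "TTTGTTTTCGTT", mate=1),
         make_read(header, "pair1", 6, "TTCGTTTTTGTT", mate=2)],
        index, dedup=False)
    return {
        "rate_dedup": region_rate(dedup, "frag", 0, 18),
        "rate_naive": region_rate(naive, "frag", 0, 18),
        "methylome_dedup": dedup,
        "methylome_naive": naive,
    }


def mixed_layout_example(pe_fragment_methylated: bool) -> dict:
    """One methylated and one unmethylated single-CpG fragment, PE vs SE.

    ``pe_fragment_methylated=False``: the unmethylated fragment is
    sequenced PE with its CpG inside the mate overlap and the methylated
    one SE (naive rate 1/3). ``True`` mirrors the layouts (naive rate
    2/3). Deduplication recovers 1/2 either way.
    """
    ref = ONE_CPG_FRAG + "T" * 32 + ONE_CPG_FRAG  # fragments at 0 and 50
    genome = Genome({"frag": ref})
    index = index_cytosines(genome)
    header = _header(len(ref))

    def fragment_reads(start: int, methylated: bool, paired: bool):
        base = "C" if methylated else "T"
        seq1 = ONE_CPG_FRAG[:12].replace("CG", base + "G")
        seq2 = ONE_CPG_FRAG[6:].replace("CG", base + "G")
        if paired:
            return [make_read(header, f"pe{start}", start, seq1, mate=1),
                    make_read(header, f"pe{start}", start + 6, seq2, mate=2)]
        return [make_read(header, f"se{start}", start, seq1)]

    def build():
        return (fragment_reads(0, pe_fragment_methylated, paired=True)
                + fragment_reads(50, not pe_fragment_methylated, paired=False))

    dedup = pileup_methylation(build(), index, dedup=True)
    naive = pileup_methylation(build(), index, dedup=False)
    return {
        "rate_dedup": region_rate(dedup, "frag", 0, len(ref)),
        "rate_naive": region_rate(naive, "frag", 0, len(ref)),
        "methylome_dedup": dedup,
        "methylome_naive": naive,
    }
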