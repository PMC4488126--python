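"""Reference preparation: bisulfite conversion, in-silico digestion, cytosine index.

RRBS enriches CpG-dense regions by digesting genomic DNA with a
methylation-insensitive restriction enzyme (classically MspI, C^CGG) and
size-selecting the fragments. The same digestion is applied in silico to
the reference so that downstream analysis is restricted to the fragments
("target regions") the protocol can actually sequence. Bisulfite-converted
reference copies (C->T and G->A) are what three-letter aligners index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Uppercase DNA sequences over {A,C,G,T,N}, keyed by unique names."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("Genome requires at least one sequence")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            if set(seq) - VALID_BASES:
                bad = sorted(set(seq) - VALID_BASES)
                raise ValueError(f"sequence {name!r} has invalid characters: {bad}")
            self.sequences[name] = seq

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def names(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme given by its recognition site and cut offset.

    ``cut_offset`` is the 0-based position within the recognition site at
    which the enzyme cuts the top strand (MspI C^CGG has offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self):
        site = self.recognition_site.upper()
        object.__setattr__(self, "recognition_site", site)
        if len(site) < 2:
            raise ValueError("recognition site must be at least 2 bases")
        if any(b not in IUPAC for b in site):
            raise ValueError(f"invalid IUPAC code in site {site!r}")
        if all(len(IUPAC[b]) == 4 for b in site):
            raise ValueError(f"site {site!r} is fully degenerate (matches everywhere)")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError("cut offset outside recognition site")

    @classmethod
    def from_string(cls, spec: str) -> "RestrictionEnzyme":
        """Parse a ``name:site:offset`` triple, e.g. ``"MspI:CCGG:1"``."""
        parts = spec.split(":")
        if len(parts) != 3:
            raise ValueError(f"enzyme spec must be name:site:offset, got {spec!r}")
        return cls(parts[0], parts[1], int(parts[2]))

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_site) == self.recognition_site

    def _site_regex(self, site: str) -> re.Pattern:
        # character classes exclude N in the target so N never matches
        pattern = "".join(f"[{IUPAC[b]}]" for b in site)
        return re.compile(f"(?=({pattern}))")

    def cut_positions(self, seq: str) -> set[int]:
        """0-based cut positions on the forward strand of ``seq``.

        Palindromic sites are matched on the forward strand only (the
        reverse-strand match is the same locus). Non-palindromic sites are
        additionally matched on the reverse complement, with the offset
        mirrored back into forward coordinates.
        """
        cuts = {m.start() + self.cut_offset
                for m in self._site_regex(self.recognition_site).finditer(seq)}
        if not self.is_palindromic:
            rc_site = reverse_complement(self.recognition_site)
            mirrored = len(self.recognition_site) - self.cut_offset
            cuts |= {m.start() + mirrored
                     for m in self._site_regex(rc_site).finditer(seq)}
        return cuts


MSPI = RestrictionEnzyme("MspI", "CCGG", 1)


@dataclass(frozen=True)
class TargetFragment:
    """An enzyme-digested reference interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    flanked_by_cuts: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid fragment interval")


def fragment_intervals(genome: Genome,
                       enzymes: Iterable[RestrictionEnzyme]) -> list[TargetFragment]:
    """All digestion fragments, unfiltered: they tile each chromosome."""
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("at least one enzyme required")
    frags: list[TargetFragment] = []
    for chrom, seq in genome.sequences.items():
        cuts: set[int] = set()
        for enz in enzymes:
            cuts |= enz.cut_positions(seq)
        cuts.discard(0)
        cuts.discard(len(seq))
        bounds = [0] + sorted(cuts) + [len(seq)]
        n_inner = len(bounds) - 2
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            flanked = 0 < i <= n_inner - 1 if n_inner else False
            frags.append(TargetFragment(chrom, s, e, flanked_by_cuts=flanked))
    return frags


def digest(genome: Genome, enzymes: Iterable[RestrictionEnzyme],
           min_len: int = 40, max_len: int = 220) -> list[TargetFragment]:
    """Digest the reference and keep fragments within the size window.

    Size selection mimics the RRBS library preparation: only fragments in
    ``[min_len, max_len]`` are sequenced, so only those are analysed.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    return [f for f in fragment_intervals(genome, enzymes)
            if min_len <= f.length <= max_len]


def write_fragments_bed(fragments: Iterable[TargetFragment], path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(fragments):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\tfragment_{i}\t{f.length}\n")


class CytosineContextIndex:
    """Per-chromosome index of cytosines with strand and sequence context.

    A ``+`` entry at position p is a C on the forward strand; a ``-`` entry
    at p is a G on the forward strand, i.e. a C on the reverse strand.
    Context (CpG/CHG/CHH) is read from the strand-local downstream bases;
    positions whose context window runs off the sequence or contains N are
    excluded.
    """

    def __init__(self, entries: dict[str, list[tuple[int, str, str]]],
                 lengths: dict[str, int]):
        self.entries = entries
        self.lengths = lengths
        self.context: dict[tuple[str, int, str], str] = {}
        # boolean masks for fast pileup lookup
        self.plus_mask: dict[str, np.ndarray] = {}
        self.minus_mask: dict[str, np.ndarray] = {}
        for chrom, ents in entries.items():
            plus = np.zeros(lengths[chrom], dtype=bool)
            minus = np.zeros(lengths[chrom], dtype=bool)
            for pos, strand, ctx in ents:
                self.context[(chrom, pos, strand)] = ctx
                (plus if strand == "+" else minus)[pos] = True
            self.plus_mask[chrom] = plus
            self.minus_mask[chrom] = minus

    def __iter__(self) -> Iterator[tuple[str, int, str, str]]:
        for chrom, ents in self.entries.items():
            for pos, strand, ctx in ents:
                yield chrom, pos, strand, ctx

    def sites(self, chrom: str) -> list[tuple[int, str, str]]:
        return self.entries.get(chrom, [])

    def cpg_dinucleotide_start(self, chrom: str, pos: int, strand: str) -> int:
        """+ strand position of the C of the CpG containing this entry."""
        return pos if strand == "+" else pos - 1


def _context_plus(seq: str, i: int) -> str | None:
    n = len(seq)
    if i + 1 >= n or seq[i + 1] == "N":
        return None
    if seq[i + 1] == "G":
        return "CpG"
    if i + 2 >= n or seq[i + 2] == "N":
        return None
    return "CHG" if seq[i + 2] == "G" else "CHH"


def _context_minus(seq: str, i: int) -> str | None:
    # reverse-strand cytosine at forward G; downstream on - is upstream on +
    if i - 1 < 0 or seq[i - 1] == "N":
        return None
    if seq[i - 1] == "C":
        return "CpG"
    if i - 2 < 0 or seq[i - 2] == "N":
        return None
    return "CHG" if seq[i - 2] == "C" else "CHH"


def index_cytosines(genome: Genome) -> CytosineContextIndex:
    """Index every cytosine on both strands with its CpG/CHG/CHH context."""
    entries: dict[str, list[tuple[int, str, str]]] = {}
    lengths: dict[str, int] = {}
    for chrom, seq in genome.sequences.items():
        ents: list[tuple[int, str, str]] = []
        for i, base in enumerate(seq):
            if base == "C":
                ctx = _context_plus(seq, i)
                if ctx is not None:
                    ents.append((i, "+", ctx))
            elif base == "G":
                ctx = _context_minus(seq, i)
                if ctx is not None:
                    ents.append((i, "-", ctx))
        entries[chrom] = ents
        lengths[chrom] = len(seq)
    return CytosineContextIndex(entries, lengths)


def convert_reference(genome: Genome) -> tuple[Genome, Genome]:
    """Bisulfite-converted reference copies: (C->T genome, G->A genome).

    The C->T copy is what fully converted Watson-strand reads align to;
    the G->A copy serves Crick-strand reads. Three-letter aligners index
    both.
    """
    ct = {name: seq.replace("C", "T") for name, seq in genome.sequences.items()}
    ga = {name: seq.replace("G", "A") for name, seq in genome.sequences.items()}
    return Genome(ct), Genome(ga)
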