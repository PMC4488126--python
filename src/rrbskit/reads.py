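"""Read preparation: adaptor and quality trimming of raw bisulfite reads.

Rather than discarding whole reads that contain adaptor sequence, the
3' ends carrying adaptor or low-quality tails are clipped, which keeps
the maximal amount of usable ("clean") data. Trimming only ever removes
a suffix: the retained bases are untouched.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO


@dataclass
class SequenceRead:
    """A FASTQ read with per-base Phred qualities."""

    id: str
    bases: str
    quals: list[int]
    mate: str = "SE"  # "1", "2" or "SE"

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and qualities differ in length")
        if any(q < 0 for q in self.quals):
            raise ValueError("negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def truncate(self, n: int) -> "SequenceRead":
        return SequenceRead(self.id, self.bases[:n], self.quals[:n], self.mate)


def trim_adaptor(read: SequenceRead, adaptor: str, min_overlap: int = 3,
                 max_mismatch_rate: float = 0.1) -> SequenceRead:
    """Clip the read at the leftmost adaptor occurrence.

    The adaptor may appear internally (full match) or run off the 3' end
    (a prefix of the adaptor matching a suffix of the read). The leftmost
    position where a prefix of the adaptor matches with at least
    ``min_overlap`` aligned bases and a mismatch fraction at most
    ``max_mismatch_rate`` wins; everything from that position on is
    removed. Reads with no such match are returned unchanged.
    """
    adaptor = adaptor.upper()
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    if not (1 <= min_overlap <= len(adaptor)):
        raise ValueError("min_overlap out of range")
    bases = read.bases.upper()
    n = len(bases)
    for p in range(0, n - min_overlap + 1):
        overlap = min(len(adaptor), n - p)
        mismatches = sum(1 for a, b in zip(bases[p : p + overlap], adaptor)
                         if a != b)
        if mismatches <= max_mismatch_rate * overlap:
            return read.truncate(p)
    return read


def quality_trim(read: SequenceRead, q_threshold: int = 20) -> SequenceRead:
    """Trim the low-quality 3' tail by the running-sum rule.

    Accumulates ``q - q_threshold`` from the 3' end and cuts at the
    position of the minimal (negative) running sum — the same rule BWA
    and cutadapt apply. Reads whose running sum never dips below zero
    are untouched.
    """
    if q_threshold < 0:
        raise ValueError("threshold must be >= 0")
    s = 0
    min_s = 0
    cut = len(read)
    for i in range(len(read) - 1, -1, -1):
        s += read.quals[i] - q_threshold
        if s < min_s:
            min_s = s
            cut = i
    return read.truncate(cut)


@dataclass
class ReadFilterStats:
    """Counters for the length filter over trimmed reads."""

    input_reads: int = 0
    kept_reads: int = 0
    orphaned_reads: int = 0
    dropped_reads: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_reads(units: Iterable[tuple[SequenceRead, Optional[SequenceRead]]],
                 min_len: int = 20,
                 stats: ReadFilterStats | None = None,
                 ) -> Iterator[tuple[SequenceRead, Optional[SequenceRead]]]:
    """Drop reads shorter than ``min_len``; orphan PE survivors become SE.

    ``units`` are ``(read, None)`` for SE or ``(mate1, mate2)`` for PE.
    Emitted units follow the same convention; a pair whose single
    surviving mate is emitted alone counts as orphaned.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if stats is None:
        stats = ReadFilterStats()
    for r1, r2 in units:
        if r2 is None:
            stats.input_reads += 1
            if len(r1) >= min_len:
                stats.kept_reads += 1
                yield r1, None
            else:
                stats.dropped_reads += 1
        else:
            stats.input_reads += 2
            ok1, ok2 = len(r1) >= min_len, len(r2) >= min_len
            if ok1 and ok2:
                stats.kept_reads += 2
                yield r1, r2
            elif ok1 or ok2:
                survivor = r1 if ok1 else r2
                survivor = SequenceRead(survivor.id, survivor.bases,
                                        survivor.quals, "SE")
                stats.orphaned_reads += 1
                stats.dropped_reads += 1
                yield survivor, None
            else:
                stats.dropped_reads += 2


# --- FASTQ I/O (plain or gzip, Phred+33) ---------------------------------

def _open_text(path, mode: str) -> TextIO:
    if str(path).endswith(".gz"):
        # mtime=0 keeps gzip output byte-reproducible
        return gzip.open(path, mode + "t", mtime=0) if "w" in mode \
            else gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path, mate: str = "SE", offset: int = 33) -> Iterator[SequenceRead]:
    with _open_text(path, "r") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            bases = fh.readline().strip()
            fh.readline()  # '+'
            quals = fh.readline().strip()
            if not header.startswith("@") or len(bases) != len(quals):
                raise ValueError(f"malformed FASTQ record in {path}")
            yield SequenceRead(header[1:].strip().split()[0], bases,
                               [ord(c) - offset for c in quals], mate)


def write_fastq(reads: Iterable[SequenceRead], path, offset: int = 33) -> int:
    n = 0
    with _open_text(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n"
                     + "".join(chr(q + offset) for q in r.quals) + "\n")
            n += 1
    return n


def clean_reads(in1, out1, in2=None, out2=None, adaptor: str | None = None,
                q_threshold: int = 20, min_len: int = 20,
                min_overlap: int = 3, max_mismatch_rate: float = 0.1,
                orphan_out=None) -> ReadFilterStats:
    """Trim and filter FASTQ file(s); returns the filter counters.

    For PE input the two files must have equal read counts; orphaned
    survivors go to ``orphan_out`` when given, else are dropped silently
    from the paired outputs (still counted).
    """

    def trimmed(read: SequenceRead) -> SequenceRead:
        if adaptor:
            read = trim_adaptor(read, adaptor, min_overlap, max_mismatch_rate)
        return quality_trim(read, q_threshold)

    stats = ReadFilterStats()
    if in2 is None:
        units = ((trimmed(r), None) for r in read_fastq(in1, "SE"))
        write_fastq((r for r, _ in filter_reads(units, min_len, stats)), out1)
        return stats

    def paired_units():
        it1, it2 = read_fastq(in1, "1"), read_fastq(in2, "2")
        while True:
            r1, r2 = next(it1, None), next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError("paired FASTQ files have unequal read counts")
            yield trimmed(r1), trimmed(r2)

    orphans: list[SequenceRead] = []
    with _open_text(out1, "w") as fh1, _open_text(out2, "w") as fh2:
        for r1, r2 in filter_reads(paired_units(), min_len, stats):
            if r2 is None:
                orphans.append(r1)
            else:
                fh1.write(f"@{r1.id}\n{r1.bases}\n+\n"
                          + "".join(chr(q + 33) for q in r1.quals) + "\n")
                fh2.write(f"@{r2.id}\n{r2.bases}\n+\n"
                          + "".join(chr(q + 33) for q in r2.quals) + "\n")
    if orphan_out is not None:
        write_fastq(orphans, orphan_out)
    return stats
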