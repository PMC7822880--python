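"""Read cleaning for degraded single-end libraries.

The cleaning order used throughout the package is: adapter trimming with a
1-bp minimum overlap, 3'-end quality trimming at Q30, discarding reads
shorter than 30 bp, and (on the assembly/consensus path) duplicate removal
by exact sequence identity.  Nothing here ever lengthens a read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .simdata import DEFAULT_ADAPTER


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases vs {len(self.quals)} qualities"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")

    @classmethod
    def from_fastq(cls, rid: str, bases: str, qual_string: str) -> "Read":
        return cls(rid, bases, tuple(ord(c) - 33 for c in qual_string))

    def qual_string(self) -> str:
        return "".join(chr(q + 33) for q in self.quals)

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "Read":
        return Read(self.id, self.bases[:n], self.quals[:n])


def trim_adapter(read: Read, adapter: str = DEFAULT_ADAPTER,
                 min_overlap: int = 1, max_error_rate: float = 0.1) -> Read:
    """Remove the longest 3' suffix of the read matching a prefix of the
    adapter.

    An overlap of length ``o`` qualifies when it has at most
    ``floor(max_error_rate * o)`` mismatches and ``o >= min_overlap``; the
    longest qualifying overlap wins.  A single terminal base equal to the
    adapter's first base is trimmed (1-bp overlap semantics).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(read)
    for o in range(min(n, len(adapter)), min_overlap - 1, -1):
        allowed = int(max_error_rate * o)
        mism = 0
        tail = read.bases[n - o:]
        for x, y in zip(tail, adapter):
            if x != y:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return read.prefix(n - o)
    return read


def quality_trim_3p(read: Read, threshold: int = 30) -> Read:
    """BWA-style running-sum 3' quality trimming.

    Accumulate (threshold - q) from the 3' end and cut at the position where
    the partial sum is maximal (equivalently, where the sum of q relative to
    the threshold is minimal).  Reads whose qualities never dip below the
    threshold are unchanged.
    """
    best = 0
    cut = len(read)
    running = 0
    for i in range(len(read) - 1, -1, -1):
        running += threshold - read.quals[i]
        if running > best:
            best = running
            cut = i
    return read.prefix(cut) if cut < len(read) else read


def filter_min_length(reads: Iterable[Read], min_len: int = 30) -> list[Read]:
    """Keep reads of length >= min_len (inclusive boundary); order preserved."""
    return [r for r in reads if len(r) >= min_len]


def dedupe_by_sequence(reads: Iterable[Read]) -> list[Read]:
    """Keep the first occurrence of each exact base string (PCR duplicate
    removal by sequence identity).  Idempotent."""
    seen: set[str] = set()
    out: list[Read] = []
    for r in reads:
        if r.bases not in seen:
            seen.add(r.bases)
            out.append(r)
    return out


def prep_reads(reads: Sequence[Read], adapter: str = DEFAULT_ADAPTER,
               quality_threshold: int = 30, min_len: int = 30,
               dedup_seq: bool = False, trim_quality: bool = True) -> list[Read]:
    """The full cleaning pipeline in canonical order:
    adapter -> quality -> length -> (optional) sequence dedup."""
    out = [trim_adapter(r, adapter) for r in reads]
    if trim_quality:
        out = [quality_trim_3p(r, quality_threshold) for r in out]
    out = filter_min_length(out, min_len)
    if dedup_seq:
        out = dedupe_by_sequence(out)
    return out
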