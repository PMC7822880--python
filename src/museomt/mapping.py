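"""Read mapping to small circular references.

A deterministic seed-and-extend mapper sized for mitogenome work: 13-mer
seeds locate candidate loci, candidates are scored gaplessly with numpy, and
a full affine-gap (Gotoh) glocal alignment is run only when the gapless
score suggests an indel.  The read is always aligned end-to-end (glocal);
the reference is consumed locally.

Circularity is handled at indexing time: the reference is extended by
``max_read_length - 1`` wraparound bases so origin-spanning reads align
contiguously, with coordinates reported on the original circle (``end`` may
exceed L to denote wraparound).  A linear (non-extended) mode exists for the
consensus path, whose two-pass 100-bp rotation rescue then recovers the
origin — mirroring pipelines built on linear aligners.

Mapping quality is a uniqueness indicator: 37 when the best-scoring
placement is unique, 0 when two distinct placements tie.  Downstream the
only use of MQ is the >= 30 filter, so only uniqueness matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .readprep import Read
from .simdata import CircularReference, revcomp

MQ_UNIQUE = 37


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class ReadAlignment:
    """Placement of one read on one reference.

    ``start``/``end`` are 0-based half-open on the original circle; ``end``
    may exceed the reference length to denote wraparound.  ``query`` holds
    the read bases oriented to the forward reference strand.  ``edits`` is a
    run-length list of (op, length) with op in {M, X, I, D} (M match,
    X mismatch, I insertion to the reference, D deletion from it).
    """

    read_id: str
    ref_id: str
    start: int
    end: int
    strand: str
    aligned_bases: int
    score: int
    mq: int
    edits: tuple[tuple[str, int], ...]
    query: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start must precede end")
        if self.aligned_bases > len(self.query):
            raise ValueError("aligned_bases exceeds read length")

    def cigar(self) -> str:
        """CIGAR with M covering both match and mismatch columns."""
        merged: list[tuple[str, int]] = []
        for op, ln in self.edits:
            op = "M" if op in "MX" else op
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return "".join(f"{ln}{op}" for op, ln in merged)


class ReferenceIndex:
    """Exact k-mer index over a (possibly circularly extended) reference."""

    def __init__(self, ref: CircularReference, k: int = 13,
                 circular: bool = True, max_read_length: int = 300) -> None:
        if k < 4:
            raise ValueError("k must be >= 4")
        self.ref = ref
        self.ref_id = ref.id
        self.k = k
        self.length = len(ref)
        self.circular = circular
        self.extension = min(max_read_length - 1, self.length) if circular else 0
        self.extended = ref.sequence + ref.sequence[: self.extension]
        self._arr = np.frombuffer(self.extended.encode("ascii"), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        for i in range(len(self.extended) - k + 1):
            index.setdefault(self.extended[i : i + k], []).append(i)
        self._index = {kmer: np.asarray(pos, dtype=np.int64)
                       for kmer, pos in index.items()}

    def seed_hits(self, seq: str) -> np.ndarray:
        """Candidate start positions (extended coordinates) for a gapless
        placement of ``seq``, from every overlapping k-mer."""
        k = self.k
        cands: list[np.ndarray] = []
        for off in range(0, len(seq) - k + 1):
            hits = self._index.get(seq[off : off + k])
            if hits is not None:
                cands.append(hits - off)
        if not cands:
            return np.empty(0, dtype=np.int64)
        starts = np.unique(np.concatenate(cands))
        hi = len(self.extended) - len(seq)
        starts = starts[(starts >= 0) & (starts <= hi)]
        if self.circular:
            # placements starting in the extension duplicate mod-L ones
            starts = np.unique(starts % self.length)
            starts = starts[starts <= hi]
        return starts

    def gapless_scores(self, seq: str, starts: np.ndarray,
                       scoring: Scoring = DEFAULT_SCORING) -> np.ndarray:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        idx = starts[:, None] + np.arange(len(seq))[None, :]
        matches = (self._arr[idx] == arr[None, :]).sum(axis=1)
        return (matches * (scoring.match - scoring.mismatch)
                + len(seq) * scoring.mismatch)


def _gapless_edits(query: str, ref_window: str) -> tuple[tuple[str, int], ...]:
    edits: list[tuple[str, int]] = []
    for q, r in zip(query, ref_window):
        op = "M" if q == r else "X"
        if edits and edits[-1][0] == op:
            edits[-1] = (op, edits[-1][1] + 1)
        else:
            edits.append((op, 1))
    return tuple(edits)


def _gotoh_glocal(query: str, window: str, scoring: Scoring
                  ) -> tuple[int, int, int, tuple[tuple[str, int], ...]]:
    """Affine-gap alignment of the whole query against a local stretch of
    ``window`` (free leading/trailing reference gaps).

    Returns (score, ref_start_in_window, ref_end_in_window, edits).
    Small inputs only; quadratic DP with traceback.
    """
    n, m = len(query), len(window)
    NEG = -(10 ** 9)
    go, ge, ma, mi = scoring.gap_open, scoring.gap_extend, scoring.match, scoring.mismatch
    # M[i][j]: query[:i] vs window[:j] ending in match/mismatch
    # X[i][j]: ending in gap in reference (query base consumed, I op)
    # Y[i][j]: ending in gap in query (reference base consumed, D op)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptrM = [[0] * (m + 1) for _ in range(n + 1)]
    ptrX = [[0] * (m + 1) for _ in range(n + 1)]
    ptrY = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0  # free leading reference gap
    for i in range(1, n + 1):
        X[i][0] = go + ge * (i - 1)
        ptrX[i][0] = 1 if i == 1 else 2
        qi = query[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = ma if qi == window[j - 1] else mi
            best_prev = Mp[j - 1]
            ptr = 1
            if Xp[j - 1] > best_prev:
                best_prev, ptr = Xp[j - 1], 2
            if Yp[j - 1] > best_prev:
                best_prev, ptr = Yp[j - 1], 3
            Mi[j] = best_prev + s
            ptrM[i][j] = ptr
            # gap in reference (I): consume query base
            a, b = Mp[j] + go, Xp[j] + ge
            if a >= b:
                Xi[j], ptrX[i][j] = a, 1
            else:
                Xi[j], ptrX[i][j] = b, 2
            # gap in query (D): consume reference base
            a, b = Mi[j - 1] + go, Yi[j - 1] + ge
            if a >= b:
                Yi[j], ptrY[i][j] = a, 1
            else:
                Yi[j], ptrY[i][j] = b, 3
    # free trailing reference gap: best over last row (M or X states)
    best_j, best_score, best_state = 0, NEG, 1
    for j in range(m + 1):
        for state, val in ((1, M[n][j]), (2, X[n][j])):
            if val > best_score:
                best_score, best_j, best_state = val, j, state
    # traceback
    ops: list[str] = []
    i, j, state = n, best_j, best_state
    while i > 0:
        if state == 1:
            op = "M" if query[i - 1] == window[j - 1] else "X"
            nxt = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == 2:
            op = "I"
            nxt = ptrX[i][j]
            i = i - 1
        else:
            op = "D"
            nxt = ptrY[i][j]
            j = j - 1
        ops.append(op)
        state = nxt
    ops.reverse()
    edits: list[tuple[str, int]] = []
    for op in ops:
        if edits and edits[-1][0] == op:
            edits[-1] = (op, edits[-1][1] + 1)
        else:
            edits.append((op, 1))
    ref_start = best_j - sum(ln for op, ln in edits if op in "MXD")
    return best_score, ref_start, best_j, tuple(edits)


def map_read(read: Read, index: ReferenceIndex,
             scoring: Scoring = DEFAULT_SCORING, band: int = 16,
             min_score_fraction: float = 0.89) -> ReadAlignment | None:
    """Best placement of ``read`` on the indexed reference, or None.

    Candidate loci come from seed hits on both strands and are scored
    gaplessly.  When the best gapless score misses the acceptance
    threshold *and* the seed hits cluster on two nearby diagonals (the
    signature of a small indel), the affine-gap DP refines that locus.
    The read is rejected (None) when the final score stays below
    ``min_score_fraction * read_length * match`` — the stringency that
    makes divergent reads fail to map, which is what the downstream
    mapping-success statistic measures (on default scoring, roughly 4
    mismatches on a 75-mer, comparable to short-read aligner defaults).
    """
    seq = read.bases
    if len(seq) < index.k:
        return None
    threshold = min_score_fraction * len(seq) * scoring.match
    placements: list[tuple[int, int, str, str]] = []  # (score, start_ext, strand, oriented)
    all_starts: dict[str, np.ndarray] = {}
    oriented_by_strand: dict[str, str] = {}
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        starts = index.seed_hits(oriented)
        if starts.size == 0:
            continue
        all_starts[strand] = starts
        oriented_by_strand[strand] = oriented
        scores = index.gapless_scores(oriented, starts, scoring)
        order = np.argsort(scores)[::-1][: 8]
        for r in order:
            placements.append((int(scores[r]), int(starts[r]), strand, oriented))
    if not placements:
        return None
    placements.sort(key=lambda p: (-p[0], p[1], p[2]))
    best_score, best_start, best_strand, best_query = placements[0]

    gapped = None
    if best_score < threshold:
        # candidate loci where two seed diagonals sit within the band:
        # run the affine DP there (small-indel rescue)
        for strand, starts in all_starts.items():
            ss = np.sort(starts)
            close = np.nonzero((np.diff(ss) > 0) & (np.diff(ss) <= band))[0]
            loci = list(ss[close][:2])
            if not loci and best_score >= 0.6 * len(seq) * scoring.match:
                loci = [best_start] if strand == best_strand else []
            for start in loci:
                lo = max(0, int(start) - band)
                hi = min(len(index.extended), int(start) + len(seq) + band)
                g = _gotoh_glocal(oriented_by_strand[strand],
                                  index.extended[lo:hi], scoring)
                if gapped is None or g[0] > gapped[0]:
                    gapped = (g[0], lo + g[1], lo + g[2], g[3], strand,
                              oriented_by_strand[strand])
    if gapped is not None and gapped[0] > best_score:
        score, s, _e, edits, strand, oriented = gapped
    else:
        score, s, strand, oriented = (best_score, best_start, best_strand,
                                      best_query)
        edits = _gapless_edits(oriented, index.extended[s : s + len(seq)])

    if score < threshold:
        return None
    # uniqueness: another placement at a distinct (start mod L, strand)
    # reaching the same score means ambiguity
    L = index.length
    tie = any(
        p_score >= score and (p_start % L, p_strand) != (s % L, strand)
        for p_score, p_start, p_strand, _ in placements
    )
    mq = 0 if tie else MQ_UNIQUE
    aligned = sum(ln for op, ln in edits if op in "MX")
    return ReadAlignment(
        read_id=read.id, ref_id=index.ref_id, start=s % L,
        end=s % L + sum(ln for op, ln in edits if op in "MXD"),
        strand=strand, aligned_bases=aligned, score=int(score), mq=mq,
        edits=edits, query=oriented,
    )


def map_reads(reads: Iterable[Read], index: ReferenceIndex,
              scoring: Scoring = DEFAULT_SCORING, band: int = 16
              ) -> list[ReadAlignment]:
    out = []
    for r in reads:
        aln = map_read(r, index, scoring, band)
        if aln is not None:
            out.append(aln)
    return out


def filter_mq(alignments: Iterable[ReadAlignment],
              min_mq: int = 30) -> list[ReadAlignment]:
    """Keep alignments with mapping quality >= min_mq (inclusive)."""
    return [a for a in alignments if a.mq >= min_mq]


DedupMode = Literal["both-ends", "5p", "off"]


def remove_duplicates_start_end(alignments: Sequence[ReadAlignment],
                                mode: DedupMode = "both-ends"
                                ) -> list[ReadAlignment]:
    """Collapse presumed PCR duplicates on one reference.

    "both-ends" keys on (start, end, strand) — reads sharing only the 5'
    coordinate survive; "5p" keys on (start, strand) as in classic rmdup.
    The representative is the highest-scoring alignment, ties broken by
    lexicographically smallest read id.  Output is sorted by
    (start, end, strand); the operation is idempotent.
    """
    if mode == "off":
        return list(alignments)
    if alignments:
        ref_ids = {a.ref_id for a in alignments}
        if len(ref_ids) > 1:
            raise ValueError(f"alignments span multiple references: {ref_ids}")
    best: dict[tuple, ReadAlignment] = {}
    for a in alignments:
        key = (a.start, a.end, a.strand) if mode == "both-ends" else (a.start, a.strand)
        cur = best.get(key)
        if cur is None or a.score > cur.score or (
                a.score == cur.score and a.read_id < cur.read_id):
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.start, a.end, a.strand))


def mapped_bases(alignments: Iterable[ReadAlignment]) -> int:
    """Total read bases in match/mismatch columns (the per-reference
    mapping-success statistic)."""
    return sum(a.aligned_bases for a in alignments)
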