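"""Reference-coordinate consensus calling for circular mitogenomes.

The calling rules follow common archival-DNA practice: a 75% majority rule
with a minimum coverage of 3 reads (below which the position is N);
sub-threshold columns emit the smallest IUPAC code covering the
highest-frequency bases (a strict-N alternative is a switch); insertions
relative to the reference are kept only when supported by at least three
reads; columns where a deletion is the plurality winner are omitted from
the output sequence ("trim to reference" semantics).

Because the consensus path maps reads linearly, coverage collapses at the
linearization point of the circle.  ``edge_rescue`` runs a second mapping
pass against the reference rotated by 100 bp (its last 100 bp moved to the
front), rotates that consensus back, and combines the two calls per
position at a 50% rule: agreeing calls stand, an N yields to the other
call, and conflicting base calls take the IUPAC union.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .mapping import (ReadAlignment, ReferenceIndex, Scoring, DEFAULT_SCORING,
                      filter_mq, map_reads, remove_duplicates_start_end)
from .readprep import Read
from .simdata import CircularReference

_BASE_ORDER = "ACGT"
_IUPAC_FROM_SET = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}
_SET_FROM_IUPAC = {v: set(k) for k, v in _IUPAC_FROM_SET.items()}
_SET_FROM_IUPAC["N"] = set("ACGT")


def iupac_code(bases: Iterable[str]) -> str:
    return _IUPAC_FROM_SET[frozenset(bases)]


def iupac_union(a: str, b: str) -> str:
    return iupac_code(_SET_FROM_IUPAC[a] | _SET_FROM_IUPAC[b])


@dataclass(frozen=True)
class ConsensusParams:
    majority: float = 0.75
    min_depth: int = 3
    min_insertion_support: int = 3
    edge_window: int = 100
    combine_majority: float = 0.50
    ambiguity_codes: bool = True  # False: strict N below the majority rule

    def __post_init__(self) -> None:
        if not 0.5 <= self.majority <= 1.0:
            raise ValueError("majority must be in [0.5, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class Pileup:
    """Per-position base/deletion counts plus an insertion table.

    ``counts`` is (L, 5) over A, C, G, T, deletion.  ``insertions`` maps a
    0-based reference position to counts of the sequences inserted *before*
    that position.
    """

    ref_id: str
    length: int
    counts: np.ndarray
    insertions: dict[int, dict[str, int]]

    def depth(self, pos: int) -> int:
        return int(self.counts[pos].sum())


def build_pileup(alignments: Iterable[ReadAlignment],
                 reference: CircularReference) -> Pileup:
    """Accumulate aligned columns of every alignment (positions mod L;
    no columns outside reference coordinates)."""
    L = len(reference)
    counts = np.zeros((L, 5), dtype=np.int64)
    insertions: dict[int, dict[str, int]] = {}
    base_idx = {b: i for i, b in enumerate(_BASE_ORDER)}
    for aln in alignments:
        if aln.ref_id != reference.id:
            raise ValueError(
                f"alignment on {aln.ref_id!r} given pileup for {reference.id!r}")
        rpos = aln.start
        qpos = 0
        for op, ln in aln.edits:
            if op in "MX":
                for j in range(ln):
                    b = aln.query[qpos + j]
                    if b in base_idx:
                        counts[(rpos + j) % L, base_idx[b]] += 1
                rpos += ln
                qpos += ln
            elif op == "D":
                for j in range(ln):
                    counts[(rpos + j) % L, 4] += 1
                rpos += ln
            elif op == "I":
                ins = aln.query[qpos : qpos + ln]
                tab = insertions.setdefault(rpos % L, {})
                tab[ins] = tab.get(ins, 0) + 1
                qpos += ln
            else:  # pragma: no cover - edits are validated upstream
                raise ValueError(f"unknown edit op {op!r}")
    return Pileup(reference.id, L, counts, insertions)


@dataclass(frozen=True)
class PositionCall:
    call: str  # IUPAC base/code, "N", or "" when the column is omitted
    cls: str  # one of {"call", "ambiguity", "N", "omitted"}
    depth: int


@dataclass
class ConsensusResult:
    ref_id: str
    positions: list[PositionCall]  # one per reference position
    insertions: dict[int, str]  # included insertions, keyed by position

    @property
    def sequence(self) -> str:
        """Flattened consensus: omitted columns dropped, included
        insertions spliced in before their reference position."""
        parts: list[str] = []
        for pos, rec in enumerate(self.positions):
            if pos in self.insertions:
                parts.append(self.insertions[pos])
            if rec.cls != "omitted":
                parts.append(rec.call)
        return "".join(parts)

    @property
    def called_bases(self) -> int:
        return sum(1 for r in self.positions
                   if r.cls in ("call", "ambiguity"))

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [{"position": i, "depth": r.depth, "call": r.call or "-",
              "class": r.cls} for i, r in enumerate(self.positions)])


def _call_column(col: np.ndarray, params: ConsensusParams) -> PositionCall:
    depth = int(col.sum())
    if depth < params.min_depth:
        return PositionCall("N", "N", depth)
    # deletion as plurality winner -> column omitted
    if col[4] >= col[:4].max() and col[4] > 0:
        return PositionCall("", "omitted", depth)
    ranked = sorted(range(4), key=lambda i: (-col[i], i))
    top = ranked[0]
    if col[top] / depth >= params.majority:
        return PositionCall(_BASE_ORDER[top], "call", depth)
    if not params.ambiguity_codes:
        return PositionCall("N", "N", depth)
    chosen: list[str] = []
    cum = 0
    for i in ranked:
        if col[i] == 0:
            break
        chosen.append(_BASE_ORDER[i])
        cum += int(col[i])
        if cum / depth >= params.majority:
            break
    code = iupac_code(chosen) if len(chosen) > 1 else chosen[0]
    cls = "ambiguity" if len(chosen) > 1 else "call"
    return PositionCall(code, cls, depth)


def call_consensus(pileup: Pileup,
                   params: ConsensusParams = ConsensusParams()
                   ) -> ConsensusResult:
    positions = [_call_column(pileup.counts[p], params)
                 for p in range(pileup.length)]
    insertions: dict[int, str] = {}
    for pos, tab in pileup.insertions.items():
        support = sum(tab.values())
        if support >= params.min_insertion_support:
            seq = sorted(tab.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            insertions[pos] = seq
    return ConsensusResult(pileup.ref_id, positions, insertions)


def combine_consensuses(first: ConsensusResult, second: ConsensusResult,
                        params: ConsensusParams = ConsensusParams()
                        ) -> ConsensusResult:
    """50% combine of two reference-coordinate consensuses.

    Agreeing calls stand; an N yields to any other state; conflicting base
    calls take the IUPAC union; a deletion (omitted) conflicting with a base
    call keeps the base.  Insertions are the union, first pass preferred.
    """
    if len(first.positions) != len(second.positions):
        raise ValueError("consensus lengths differ")
    out: list[PositionCall] = []
    for a, b in zip(first.positions, second.positions):
        depth = max(a.depth, b.depth)
        if a.cls == "N" and b.cls == "N":
            out.append(PositionCall("N", "N", depth))
        elif a.cls == "N":
            out.append(replace(b, depth=depth))
        elif b.cls == "N":
            out.append(replace(a, depth=depth))
        elif a.cls == "omitted" and b.cls == "omitted":
            out.append(PositionCall("", "omitted", depth))
        elif a.cls == "omitted":
            out.append(replace(b, depth=depth))
        elif b.cls == "omitted":
            out.append(replace(a, depth=depth))
        elif a.call == b.call:
            out.append(replace(a, depth=depth))
        else:
            code = iupac_union(a.call, b.call)
            out.append(PositionCall(code, "ambiguity", depth))
    insertions = dict(second.insertions)
    insertions.update(first.insertions)
    return ConsensusResult(first.ref_id, out, insertions)


def _rotate_back(result: ConsensusResult, window: int, L: int
                 ) -> ConsensusResult:
    """Map a consensus computed on the rotated reference (last ``window``
    bases moved to the front) back onto original coordinates."""
    positions = [result.positions[(q + window) % L] for q in range(L)]
    insertions = {(p - window) % L: seq
                  for p, seq in result.insertions.items()}
    return ConsensusResult(result.ref_id, positions, insertions)


def consensus_from_reads(reads: Sequence[Read], reference: CircularReference,
                         params: ConsensusParams = ConsensusParams(),
                         min_mq: int = 30, dedup: str = "both-ends",
                         scoring: Scoring = DEFAULT_SCORING,
                         circular_mapping: bool = False) -> ConsensusResult:
    """Single-pass consensus: linear mapping, MQ filter, endpoint dedup,
    pileup, majority-rule calling."""
    index = ReferenceIndex(reference, circular=circular_mapping)
    alns = remove_duplicates_start_end(
        filter_mq(map_reads(reads, index, scoring), min_mq), dedup)
    return call_consensus(build_pileup(alns, reference), params)


def edge_rescue(reads: Sequence[Read], reference: CircularReference,
                params: ConsensusParams = ConsensusParams(),
                min_mq: int = 30, dedup: str = "both-ends",
                scoring: Scoring = DEFAULT_SCORING) -> ConsensusResult:
    """Two-pass circular rescue around the linearization point.

    Pass 1 maps to the reference as-is; pass 2 maps to the reference with
    its last ``edge_window`` bases moved to the front, so reads spanning the
    origin align contiguously.  The second consensus is rotated back and
    the two are combined; the combined call never has fewer called bases
    than either input.
    """
    L = len(reference)
    W = params.edge_window
    if not 0 < W < L:
        raise ValueError("edge_window must be in (0, reference length)")
    cons1 = consensus_from_reads(reads, reference, params, min_mq, dedup,
                                 scoring)
    rotated_seq = reference.sequence[-W:] + reference.sequence[:-W]
    rotated = CircularReference(reference.id, rotated_seq, (0, 0), 0)
    cons2_rot = consensus_from_reads(reads, rotated, params, min_mq, dedup,
                                     scoring)
    cons2 = _rotate_back(cons2_rot, W, L)
    return combine_consensuses(cons1, cons2, params)


def rotate_to_anchor(sequence: str, anchor: int) -> str:
    """Rotate a circular sequence so position ``anchor`` comes first."""
    if not 0 <= anchor < max(len(sequence), 1):
        raise ValueError("anchor outside sequence")
    return sequence[anchor:] + sequence[:anchor]


def excise_span(sequence: str, span: tuple[int, int]) -> str:
    """Remove a half-open span (e.g. the control region) from a sequence."""
    lo, hi = span
    if not 0 <= lo <= hi <= len(sequence):
        raise ValueError(f"span {span} outside sequence of length {len(sequence)}")
    return sequence[:lo] + sequence[hi:]
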