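"""Species assignment by normalized relative mapping success.

Each specimen's cleaned reads are mapped independently to every candidate
reference mitogenome (a read may count for several references), filtered at
MQ >= 30, deduplicated by both alignment endpoints, and the per-reference
mapped-base totals are normalized by the best total: the best reference
scores 1 and the others score their fraction of it.  The species call is
the argmax reference; an exact tie is an explicit no-call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mapping import (ReadAlignment, ReferenceIndex, filter_mq, map_reads,
                      mapped_bases, remove_duplicates_start_end)
from .readprep import Read
from .simdata import CircularReference


class UnclassifiableError(ValueError):
    """Raised when no reads map to any candidate reference."""


@dataclass(frozen=True)
class MappingReport:
    specimen_id: str
    mapped: dict[str, int]  # per-reference mapped bases
    normalized: dict[str, float]
    call: str | None  # None on exact tie (no-call)
    runner_up: str | None
    margin: float
    ambiguous: bool

    def as_row(self) -> dict:
        row: dict = {"specimen": self.specimen_id}
        for ref, bases in sorted(self.mapped.items()):
            row[f"bases_{ref}"] = bases
        for ref, s in sorted(self.normalized.items()):
            row[f"norm_{ref}"] = s
        row.update(call=self.call if self.call is not None else "no-call",
                   runner_up=self.runner_up, margin=self.margin,
                   ambiguous=self.ambiguous)
        return row


def competitive_map(reads: Sequence[Read],
                    indexes: Mapping[str, ReferenceIndex],
                    min_mq: int = 30,
                    dedup: str = "both-ends"
                    ) -> dict[str, list[ReadAlignment]]:
    """Map one specimen's reads to each reference independently, then
    MQ-filter and deduplicate per reference."""
    if len(indexes) < 2:
        raise ValueError("competitive mapping needs >= 2 references")
    out: dict[str, list[ReadAlignment]] = {}
    for ref_id, index in indexes.items():
        alns = map_reads(reads, index)
        alns = filter_mq(alns, min_mq)
        alns = remove_duplicates_start_end(alns, dedup)
        out[ref_id] = alns
    return out


def normalize_success(mapped: Mapping[str, int]) -> dict[str, float]:
    """Divide every per-reference mapped-base total by the best total."""
    best = max(mapped.values(), default=0)
    if best <= 0:
        raise UnclassifiableError(
            "no bases mapped to any reference; specimen unclassifiable")
    return {ref: bases / best for ref, bases in mapped.items()}


def call_species(specimen_id: str, mapped: Mapping[str, int]) -> MappingReport:
    """Build the full report: normalized scores, call, runner-up, margin.

    All-zero totals yield an ambiguous report with no call rather than an
    exception (the pipeline treats it as an explicit no-call).
    """
    if not mapped or max(mapped.values()) <= 0:
        return MappingReport(specimen_id, dict(mapped),
                             {r: 0.0 for r in mapped}, None, None, 0.0, True)
    normalized = normalize_success(mapped)
    ranked = sorted(normalized.items(), key=lambda kv: (-kv[1], kv[0]))
    best_ref, best_score = ranked[0]
    runner_up, second = (ranked[1] if len(ranked) > 1 else (None, 0.0))
    tie = second == best_score
    return MappingReport(
        specimen_id=specimen_id, mapped=dict(mapped), normalized=normalized,
        call=None if tie else best_ref, runner_up=runner_up,
        margin=best_score - second, ambiguous=tie,
    )


def classify_specimen(specimen_id: str, reads: Sequence[Read],
                      indexes: Mapping[str, ReferenceIndex],
                      min_mq: int = 30, dedup: str = "both-ends"
                      ) -> tuple[MappingReport, dict[str, list[ReadAlignment]]]:
    """competitive_map + mapped_bases + call_species in one step."""
    per_ref = competitive_map(reads, indexes, min_mq, dedup)
    totals = {ref: mapped_bases(alns) for ref, alns in per_ref.items()}
    return call_species(specimen_id, totals), per_ref


def shred_sequence(sequence: str, piece: int = 75, seq_id: str = "shred",
                   quality: int = 37) -> list[Read]:
    """Cut an assembled sequence into non-overlapping ``piece``-mers so it
    can be pushed through the identical read-based classifier (used when
    only consensus sequences, not raw reads, are available)."""
    reads = []
    q = quality
    for i, s in enumerate(range(0, len(sequence) - piece + 1, piece)):
        bases = sequence[s : s + piece]
        reads.append(Read(f"{seq_id}:{i}", bases, (q,) * len(bases)))
    return reads


def report_table(reports: Sequence[MappingReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def long_format_table(reports: Sequence[MappingReport]) -> pd.DataFrame:
    """Bar-chart-ready long format: one row per (specimen, reference)."""
    rows = []
    for r in reports:
        for ref in sorted(r.normalized):
            rows.append({"specimen": r.specimen_id, "reference": ref,
                         "mapped_bases": r.mapped[ref],
                         "normalized": r.normalized[ref]})
    return pd.DataFrame(rows)


def build_indexes(references: Sequence[CircularReference], k: int = 13,
                  circular: bool = True) -> dict[str, ReferenceIndex]:
    return {ref.id: ReferenceIndex(ref, k=k, circular=circular)
            for ref in references}
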