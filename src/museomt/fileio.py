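"""File formats and pipeline configuration.

FASTA/FASTQ reading and writing is gzip-transparent (by ``.gz`` suffix)
and built on Biopython's SeqIO, with a light structural pre-check so that
malformed records are reported with a line number.  SAM output is minimal
but valid: @HD/@SQ headers, 1-based POS, CIGAR consistent with the read;
wraparound alignments are emitted either as one soft-clipped primary line
or as a primary + supplementary pair.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .mapping import ReadAlignment
from .readprep import Read


class FormatError(ValueError):
    """Malformed sequence file; message carries the line number."""


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, newline=None)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read (multi-line, possibly CRLF, possibly gzipped) FASTA into an
    ordered id -> sequence mapping."""
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected '>' header, got "
                    f"{line[:20]!r}")
            break
    out: dict[str, str] = {}
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: Mapping[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path) -> list[Read]:
    """Read FASTQ (Phred+33) into Read records, validating structure."""
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    # drop trailing blank lines only
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: truncated FASTQ: {len(lines)} lines "
            f"(error near line {len(lines)})")
    reads: list[Read] = []
    for i in range(0, len(lines), 4):
        head, bases, plus, quals = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}: line {i + 1}: header must start with '@'")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {i + 3}: separator must start with '+'")
        if len(bases) != len(quals):
            raise FormatError(
                f"{path}: line {i + 4}: quality length {len(quals)} != "
                f"sequence length {len(bases)}")
        reads.append(Read.from_fastq(head[1:].split()[0], bases.strip().upper(),
                                     quals.strip()))
    return reads


def write_fastq(path, reads: Iterable) -> None:
    """Write Read objects or (id, bases, qual-string) tuples."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            if isinstance(r, Read):
                rid, bases, qual = r.id, r.bases, r.qual_string()
            else:
                rid, bases, qual = r
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _cigar_read_length(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MISX=":
                total += int(num)
            num = ""
    return total


def write_sam(path, alignments: Sequence[ReadAlignment],
              references: Mapping[str, int],
              wraparound: str = "softclip") -> None:
    """Write alignments as SAM.

    ``references`` maps reference id -> length.  Alignments whose ``end``
    exceeds the reference length (origin-spanning) are emitted per
    ``wraparound``: "softclip" writes one primary line with the wrapped
    tail soft-clipped; "split" additionally writes the tail as a
    supplementary line at position 1.
    """
    if wraparound not in ("softclip", "split"):
        raise ValueError(f"unknown wraparound mode {wraparound!r}")
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for rid, length in references.items():
        lines.append(f"@SQ\tSN:{rid}\tLN:{length}")
    for a in alignments:
        L = references[a.ref_id]
        flag = 16 if a.strand == "-" else 0
        if a.end <= L:
            cigar = a.cigar()
            if _cigar_read_length(cigar) != len(a.query):
                raise ValueError(
                    f"CIGAR {cigar} inconsistent with read length "
                    f"{len(a.query)} for {a.read_id}")
            lines.append("\t".join([
                a.read_id, str(flag), a.ref_id, str(a.start + 1),
                str(a.mq), cigar, "*", "0", "0", a.query, "*"]))
            continue
        # origin-spanning: split edits at the reference boundary
        head_ref = L - a.start
        head_ops, tail_ops = _split_edits(a.edits, head_ref)
        head_q = sum(ln for op, ln in head_ops if op in "MXI")
        tail_q = len(a.query) - head_q
        head_cigar = _ops_to_cigar(head_ops) + (f"{tail_q}S" if tail_q else "")
        lines.append("\t".join([
            a.read_id, str(flag), a.ref_id, str(a.start + 1), str(a.mq),
            head_cigar, "*", "0", "0", a.query, "*"]))
        if wraparound == "split" and tail_q:
            tail_cigar = (f"{head_q}S" if head_q else "") + _ops_to_cigar(tail_ops)
            lines.append("\t".join([
                a.read_id, str(flag | 2048), a.ref_id, "1", str(a.mq),
                tail_cigar, "*", "0", "0", a.query, "*"]))
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def _ops_to_cigar(ops: Sequence[tuple[str, int]]) -> str:
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        op = "M" if op in "MX" else op
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return "".join(f"{ln}{op}" for op, ln in merged)


def _split_edits(edits, ref_budget: int):
    head, tail = [], []
    remaining = ref_budget
    for op, ln in edits:
        consumes_ref = op in "MXD"
        if not consumes_ref:
            (head if remaining > 0 else tail).append((op, ln))
            continue
        if remaining >= ln:
            head.append((op, ln))
            remaining -= ln
        elif remaining > 0:
            head.append((op, remaining))
            tail.append((op, ln - remaining))
            remaining = 0
        else:
            tail.append((op, ln))
    return head, tail


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the end-to-end driver.

    ``references`` are FASTA paths (one record each); ``specimens`` maps a
    specimen id to its FASTQ path.  All stage parameters default to the
    pipeline's canonical values.
    """

    references: dict[str, str] = field(default_factory=dict)
    specimens: dict[str, str] = field(default_factory=dict)
    control_regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    outdir: str = "museomt_out"
    seed: int = 0
    adapter: str = ("AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
                    "ACAGTGATCTCGTATGCCGTCTTCTGCTTG")
    min_len: int = 30
    quality_threshold: int = 30
    trim_quality: bool = True
    min_mq: int = 30
    dedup: str = "both-ends"
    majority: float = 0.75
    min_depth: int = 3
    min_insertion_support: int = 3
    edge_window: int = 100
    bootstrap: int = 100
    outgroup: str | None = None
    log_level: str = "INFO"

    _SIMPLE = {"outdir", "seed", "adapter", "min_len", "quality_threshold",
               "trim_quality", "min_mq", "dedup", "majority", "min_depth",
               "min_insertion_support", "edge_window", "bootstrap",
               "outgroup", "log_level"}

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cfg = cls()
        types = {f.name: f.type for f in dc_fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key.startswith("reference."):
                    cfg.references[key.split(".", 1)[1]] = value
                elif key.startswith("specimen."):
                    cfg.specimens[key.split(".", 1)[1]] = value
                elif key.startswith("control_region."):
                    lo, hi = value.split(",")
                    cfg.control_regions[key.split(".", 1)[1]] = (int(lo), int(hi))
                elif key in cls._SIMPLE:
                    cur = getattr(cfg, key)
                    if key == "outgroup":
                        setattr(cfg, key, value or None)
                    elif isinstance(cur, bool):
                        setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                    elif isinstance(cur, int):
                        setattr(cfg, key, int(value))
                    elif isinstance(cur, float):
                        setattr(cfg, key, float(value))
                    else:
                        setattr(cfg, key, value)
                else:
                    raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        del types
        return cfg

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for rid, p in self.references.items():
                fh.write(f"reference.{rid} = {p}\n")
            for sid, p in self.specimens.items():
                fh.write(f"specimen.{sid} = {p}\n")
            for rid, (lo, hi) in self.control_regions.items():
                fh.write(f"control_region.{rid} = {lo},{hi}\n")
            for key in sorted(self._SIMPLE):
                val = getattr(self, key)
                if val is None:
                    val = ""
                fh.write(f"{key} = {val}\n")
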