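"""End-to-end driver: prep -> map -> classify -> consensus -> diversity -> tree.

Each stage writes its artifacts under the configured output directory and a
machine-readable JSON summary records versions, seed, parameters and the
headline numbers, sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .consensus import ConsensusParams, edge_rescue, excise_span, rotate_to_anchor
from .fileio import PipelineConfig, read_fasta, read_fastq, write_fasta
from .phylo import bootstrap_support, progressive_align, support_table
from .popstats import (EmptyMatrixError, complete_deletion,
                       diversity, median_joining_network)
from .readprep import prep_reads
from .simdata import CircularReference
from .speciesid import (build_indexes, classify_specimen, report_table)

log = logging.getLogger("museomt")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_references(config: PipelineConfig) -> dict[str, CircularReference]:
    refs: dict[str, CircularReference] = {}
    for rid, path in config.references.items():
        records = read_fasta(path)
        if not records:
            raise FileNotFoundError(f"reference {rid}: no records in {path}")
        seq = next(iter(records.values()))
        span = config.control_regions.get(rid, (len(seq), len(seq)))
        refs[rid] = CircularReference(rid, seq, span, 0)
    if len(refs) < 2:
        raise ValueError("pipeline needs >= 2 references")
    return refs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the JSON-ready summary dict."""
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool": "museomt", "version": __version__, "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("references", "specimens")},
    }

    stage = "load"
    try:
        references = _load_references(config)
        cons_params = ConsensusParams(
            majority=config.majority, min_depth=config.min_depth,
            min_insertion_support=config.min_insertion_support,
            edge_window=config.edge_window)
        circular_indexes = build_indexes(list(references.values()),
                                         circular=True)

        stage = "prep+classify+consensus"
        reports = []
        consensus_seqs: dict[str, str] = {}
        calls: dict[str, str | None] = {}
        for sid, fastq in config.specimens.items():
            raw = read_fastq(fastq)
            reads = prep_reads(raw, adapter=config.adapter,
                               quality_threshold=config.quality_threshold,
                               min_len=config.min_len,
                               trim_quality=config.trim_quality)
            log.info("%s: %d raw reads, %d after cleaning", sid, len(raw),
                     len(reads))
            report, _ = classify_specimen(sid, reads, circular_indexes,
                                          config.min_mq, config.dedup)
            reports.append(report)
            calls[sid] = report.call
            if report.call is None:
                log.warning("%s: ambiguous, no species call", sid)
                continue
            best_ref = references[report.call]
            cons = edge_rescue(reads, best_ref, cons_params,
                               config.min_mq, config.dedup)
            seq = rotate_to_anchor(cons.sequence, 0)
            consensus_seqs[sid] = seq
        report_df = report_table(reports)
        report_df.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        write_fasta(outdir / "consensus.fasta", consensus_seqs)
        summary["classification"] = {
            r.specimen_id: (r.call or "no-call") for r in reports}

        stage = "diversity"
        groups: dict[str, list[str]] = {}
        for sid, call in calls.items():
            if call is not None and sid in consensus_seqs:
                groups.setdefault(call, []).append(sid)
        diversity_rows = []
        for species, members in sorted(groups.items()):
            if len(members) < 2:
                continue
            aln = progressive_align({m: consensus_seqs[m] for m in members})
            try:
                res = diversity(aln)
            except EmptyMatrixError:
                log.warning("%s: no clean columns, diversity skipped", species)
                continue
            diversity_rows.append({
                "species": species, "n": len(members),
                "retained_length": res.retained_length,
                "segregating_sites": res.segregating_sites,
                "pi": res.pi, "k": res.k})
            filtered, _ = complete_deletion(aln)
            net = median_joining_network(
                {i: r for i, r in zip(filtered.ids, filtered.rows)})
            nodes = pd.DataFrame(
                [{"node": n.name, "is_median": n.is_median,
                  "multiplicity": n.multiplicity,
                  "members": ",".join(n.members)} for n in net.nodes])
            edges = pd.DataFrame(net.edges,
                                 columns=["node_a", "node_b", "steps"])
            nodes.to_csv(outdir / f"network_{species}_nodes.tsv", sep="\t",
                         index=False)
            edges.to_csv(outdir / f"network_{species}_edges.tsv", sep="\t",
                         index=False)
        if diversity_rows:
            pd.DataFrame(diversity_rows).to_csv(
                outdir / "diversity.tsv", sep="\t", index=False)
            summary["diversity"] = diversity_rows

        stage = "tree"
        tree_seqs: dict[str, str] = {}
        for sid, seq in consensus_seqs.items():
            ref = references[calls[sid]]
            tree_seqs[sid] = _excise_cr(seq, ref)
        for rid, ref in references.items():
            tree_seqs[f"ref_{rid}"] = _excise_cr(ref.sequence, ref)
        if len(tree_seqs) >= 4:
            aln = progressive_align(tree_seqs)
            tree = bootstrap_support(aln, B=config.bootstrap,
                                     seed=config.seed,
                                     outgroup=config.outgroup)
            (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
            support_table(tree).to_csv(outdir / "tree_support.tsv",
                                       sep="\t", index=False)
            summary["tree_supports"] = {
                "|".join(sorted(p)): v for p, v in tree.supports.items()}
    except Exception as exc:  # noqa: BLE001 - halt with stage name and cause
        raise StageError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def _excise_cr(seq: str, ref: CircularReference) -> str:
    lo, hi = ref.control_region
    lo = min(lo, len(seq))
    hi = min(hi, len(seq))
    return excise_span(seq, (lo, hi))
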