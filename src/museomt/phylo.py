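"""Cross-specimen phylogeny: distances, neighbor-joining, bootstrap.

The hypervariable control region is excised before tree building (it is
hard to align across divergent species), distances are p-distances or
their Jukes-Cantor correction on complete-deletion columns, the topology
comes from neighbor-joining with deterministic tie-breaking, and clade
support is the percentage of nonparametric bootstrap replicates (column
resampling) containing each original bipartition.

Neighbor-joining with bootstrap is used as the tree stand-in for full
maximum-likelihood inference: the species involved are deeply divergent
with shallow within-species structure, where clade recovery is
method-insensitive.  Multi-sequence alignment of unequal-length inputs is
delegated to the MAFFT binary; same-length inputs (already on shared
coordinates) pass through unchanged.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .popstats import SiteMatrix, complete_deletion


def excise_control_region(sequences: Mapping[str, str],
                          span: tuple[int, int]) -> dict[str, str]:
    """Remove the half-open control-region span from every sequence.

    All sequences must share the coordinate frame of ``span`` (i.e. be
    aligned or unaligned-but-homologous); the span must fit each sequence.
    """
    lo, hi = span
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid span {span}")
    out = {}
    for sid, seq in sequences.items():
        if hi > len(seq):
            raise ValueError(
                f"span {span} outside sequence {sid!r} (length {len(seq)})")
        out[sid] = seq[:lo] + seq[hi:]
    return out


def progressive_align(sequences: Mapping[str, str]) -> SiteMatrix:
    """Multiple alignment of >= 2 sequences.

    Equal-length inputs are taken as already sharing coordinates and pass
    through unchanged; otherwise the sequences are aligned with MAFFT
    (default parameters), which must be on PATH.
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    ids = list(sequences)
    for sid in ids:
        if not sequences[sid]:
            raise ValueError(f"empty sequence {sid!r}")
    lengths = {len(sequences[sid]) for sid in ids}
    if len(lengths) == 1:
        return SiteMatrix(ids, [sequences[sid] for sid in ids])
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH; cannot align "
                           "unequal-length sequences")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for i, sid in enumerate(ids):
                fh.write(f">s{i}\n{sequences[sid]}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", str(fasta)],
            capture_output=True, text=True, check=True)
    aligned: dict[str, list[str]] = {}
    current = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].strip()
            aligned[current] = []
        elif current is not None:
            aligned[current].append(line.strip())
    rows = ["".join(aligned[f"s{i}"]).upper() for i in range(len(ids))]
    return SiteMatrix(ids, rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str  # "p" or "jc69"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


def jc69_distance(p: float) -> float:
    """JC69 correction d = -3/4 ln(1 - 4p/3); defined for p < 0.75."""
    if p >= 0.75:
        raise ValueError(f"p-distance {p} >= 0.75: JC69 distance undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def distance_matrix(matrix: SiteMatrix, model: str = "p",
                    apply_complete_deletion: bool = True) -> DistanceMatrix:
    """Pairwise p or JC69 distances over the clean columns."""
    if matrix.n < 2:
        raise ValueError("need >= 2 sequences")
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    work = complete_deletion(matrix)[0] if apply_complete_deletion else matrix
    enc = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in work.rows])
    n, L = enc.shape
    d = np.zeros((n, n))
    for i in range(n):
        p = (enc[i + 1:] != enc[i]).sum(axis=1) / L
        if model == "jc69":
            d[i, i + 1:] = [jc69_distance(float(x)) for x in p]
        else:
            d[i, i + 1:] = p
    return DistanceMatrix(list(work.ids), d + d.T, model)


@dataclass
class Tree:
    """Unrooted tree as a graph with branch lengths; optional per-edge
    bootstrap support (percent, keyed by the leaf set of one side)."""

    graph: nx.Graph
    taxa: list[str]
    supports: dict[frozenset, float] | None = None
    outgroup: str | None = None

    def bipartitions(self) -> set[frozenset]:
        """Leaf sets induced by internal edges, canonicalized as the side
        not containing the alphabetically first taxon."""
        first = min(self.taxa)
        out = set()
        for u, v in self.graph.edges:
            g = self.graph.copy()
            g.remove_edge(u, v)
            side = {n for n in nx.node_connected_component(g, u)
                    if n in set(self.taxa)}
            other = set(self.taxa) - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(frozenset(other if first in side else side))
        return out

    def to_newick(self) -> str:
        taxa_set = set(self.taxa)
        first = min(self.taxa)
        if self.outgroup is not None and self.outgroup in taxa_set:
            og = self.outgroup
            root = next(iter(self.graph.neighbors(og)))
        else:
            og = None
            root = next(n for n in self.graph.nodes if n not in taxa_set) \
                if len(self.taxa) > 2 else self.taxa[0]

        def support_label(node, parent) -> str:
            if self.supports is None:
                return ""
            g = self.graph.copy()
            g.remove_edge(node, parent)
            side = {n for n in nx.node_connected_component(g, node)
                    if n in taxa_set}
            other = taxa_set - side
            if len(side) < 2 or len(other) < 2:
                return ""
            key = frozenset(other if first in side else side)
            val = self.supports.get(key)
            return "" if val is None else f"{val:g}"

        def rec(node, parent) -> str:
            nbrs = [n for n in self.graph.neighbors(node) if n != parent]
            if not nbrs:
                return str(node)
            inner = ",".join(
                rec(c, node)
                + f":{self.graph.edges[node, c].get('length', 0.0):.6g}"
                for c in sorted(nbrs, key=str))
            label = support_label(node, parent) if parent is not None else ""
            return f"({inner}){label}"

        return rec(root, None) + ";"


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Standard neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the sorted pair of cluster
    labels (smallest leaf name in each cluster), so output is independent
    of input order.  Negative branch lengths are clamped to zero.
    """
    n0 = len(D.ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    g = nx.Graph()
    labels = list(D.ids)
    dist = {
        (a, b): float(D.matrix[i, j])
        for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j
    }

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    clusters = sorted(labels)
    rep = {c: c for c in clusters}  # smallest-leaf representative
    next_internal = 0
    while len(clusters) > 2:
        m = len(clusters)
        r = {a: sum(d(a, b) for b in clusters if b != a) for a in clusters}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = clusters[i], clusters[j]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                key = (q, tuple(sorted((rep[a], rep[b]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d(a, b)
        la = dab / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        new = f"__int{next_internal}"
        next_internal += 1
        g.add_edge(a, new, length=max(la, 0.0))
        g.add_edge(b, new, length=max(lb, 0.0))
        for c in clusters:
            if c in (a, b):
                continue
            dist[(c, new)] = max((d(c, a) + d(c, b) - dab) / 2, 0.0)
        rep[new] = min(rep[a], rep[b])
        clusters = sorted(c for c in clusters if c not in (a, b)) + [new]
        clusters.sort()
    a, b = clusters
    g.add_edge(a, b, length=max(d(a, b), 0.0))
    return Tree(graph=g, taxa=list(D.ids))


def bootstrap_support(matrix: SiteMatrix, B: int = 100, seed: int = 0,
                      model: str = "p", outgroup: str | None = None
                      ) -> Tree:
    """NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement per replicate (RNG stream
    (seed, replicate)); each original internal bipartition's support is
    the percentage of replicates containing it.  Taxon input order does
    not affect the supports.
    """
    if matrix.n < 4:
        raise ValueError("need >= 4 taxa for meaningful supports")
    order = sorted(matrix.ids)
    work = matrix.subset(order)
    work, _ = complete_deletion(work)
    tree = neighbor_joining(distance_matrix(work, model,
                                            apply_complete_deletion=False))
    parts = tree.bipartitions()
    counts = {p: 0 for p in parts}
    L = work.length
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[j] for j in cols) for r in work.rows]
        rep_tree = neighbor_joining(
            distance_matrix(SiteMatrix(list(work.ids), rows), model,
                            apply_complete_deletion=False))
        rep_parts = rep_tree.bipartitions()
        for p in counts:
            if p in rep_parts:
                counts[p] += 1
    tree.supports = {p: 100.0 * c / B for p, c in counts.items()}
    tree.outgroup = outgroup
    return tree


def support_table(tree: Tree):
    import pandas as pd

    rows = []
    if tree.supports:
        for part, val in sorted(tree.supports.items(),
                                key=lambda kv: sorted(kv[0])):
            rows.append({"bipartition": "|".join(sorted(part)),
                         "support_pct": val})
    return pd.DataFrame(rows)
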