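"""Mitochondrial diversity statistics and the haplotype network.

All statistics operate on a ``SiteMatrix`` (aligned, equal-length rows) and
use raw pairwise mismatch counts ("number of substitutions", no
multiple-hit correction), after "complete deletion": every column
containing a gap, an N, or an IUPAC ambiguity in any row is discarded
before anything is computed.  With d_ij the pairwise mismatch count over
the L retained columns and n sequences:

    k  = sum_{i<j} d_ij / C(n, 2)      (mean pairwise distance)
    pi = k / L                          (nucleotide diversity)
    S  = #columns with >= 2 states      (segregating sites)

``resample_k`` reproduces the cross-species comparison design: draw m
sequences without replacement from a species' pool, compute k, repeat B
times on a frozen column set; a pool of exactly m sequences yields the one
deterministic k.

``median_joining_network`` builds a haplotype network from observed
haplotypes plus inferred unsampled intermediates (quasi-medians of node
triples), accepted while they reduce the cost of connecting the network;
median nodes that end up as simple pass-throughs (degree <= 2) are pruned.
Edges carry mutational-step weights (Hamming distances).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

_CLEAN = set("ACGT")


class EmptyMatrixError(ValueError):
    """All columns were removed by complete deletion."""


@dataclass
class SiteMatrix:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("rows are not equal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column_classes(self) -> list[str]:
        """Per-column class: gapped beats ambiguous beats clean."""
        classes = []
        for j in range(self.length):
            col = [r[j] for r in self.rows]
            if any(c == "-" for c in col):
                classes.append("gapped")
            elif any(c not in _CLEAN for c in col):
                classes.append("ambiguous")
            else:
                classes.append("clean")
        return classes

    def subset(self, ids: list[str]) -> "SiteMatrix":
        keep = {i: r for i, r in zip(self.ids, self.rows)}
        return SiteMatrix(list(ids), [keep[i] for i in ids])


def complete_deletion(matrix: SiteMatrix, drop_ambiguous: bool = True,
                      drop_gaps: bool = True) -> tuple[SiteMatrix, int]:
    """Retain exactly the clean columns; returns (matrix, retained length)."""
    if matrix.n == 0:
        raise ValueError("empty matrix")
    drop = set()
    if drop_gaps:
        drop.add("gapped")
    if drop_ambiguous:
        drop.add("ambiguous")
    classes = matrix.column_classes()
    keep = [j for j, c in enumerate(classes) if c not in drop]
    if not keep:
        raise EmptyMatrixError("complete deletion removed every column")
    rows = ["".join(r[j] for j in keep) for r in matrix.rows]
    return SiteMatrix(list(matrix.ids), rows), len(keep)


def _pair_diffs(matrix: SiteMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise mismatch counts."""
    enc = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in matrix.rows])
    n = matrix.n
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i, i + 1:] = (enc[i + 1:] != enc[i]).sum(axis=1)
    return d + d.T


def segregating_sites(matrix: SiteMatrix) -> int:
    """Number of columns with more than one state."""
    if matrix.n == 0:
        return 0
    enc = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in matrix.rows])
    return int((enc != enc[0]).any(axis=0).sum())


def mean_pairwise_k(matrix: SiteMatrix) -> float:
    """Average number of substitutions per sequence pair."""
    if matrix.n < 2:
        raise ValueError("need >= 2 sequences")
    d = _pair_diffs(matrix)
    n = matrix.n
    return float(d[np.triu_indices(n, 1)].mean())


def nucleotide_diversity(matrix: SiteMatrix) -> float:
    """pi = k / L, the mean per-site pairwise difference."""
    if matrix.length == 0:
        raise ValueError("zero-length matrix")
    return mean_pairwise_k(matrix) / matrix.length


@dataclass(frozen=True)
class DiversityResult:
    retained_length: int
    segregating_sites: int
    pi: float
    k: float


def diversity(matrix: SiteMatrix, drop_ambiguous: bool = True,
              drop_gaps: bool = True) -> DiversityResult:
    """Complete deletion followed by S, pi and k on the retained columns."""
    filtered, L = complete_deletion(matrix, drop_ambiguous, drop_gaps)
    k = mean_pairwise_k(filtered)
    return DiversityResult(L, segregating_sites(filtered), k / L, k)


def resample_k(matrix: SiteMatrix, m: int = 4, B: int = 1000,
               seed: int = 0, species: str | None = None) -> np.ndarray:
    """Distribution of k over B without-replacement draws of m sequences.

    The column set must already be frozen (complete deletion applied on the
    joint alignment before drawing).  Replicate b uses the RNG stream
    (seed, b), so values are independent of execution order.  A pool of
    exactly m sequences yields the single deterministic k.
    """
    n = matrix.n
    label = species or "input"
    if n < m:
        raise ValueError(f"species {label!r} has {n} < m={m} sequences")
    d = _pair_diffs(matrix)
    iu = np.triu_indices(m, 1)
    if n == m:
        return np.array([float(d[np.triu_indices(n, 1)].mean())])
    out = np.empty(B)
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        pick = rng.choice(n, size=m, replace=False)
        sub = d[np.ix_(pick, pick)]
        out[b] = sub[iu].mean()
    return out


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkNode:
    name: str
    sequence: str
    members: tuple[str, ...]  # observed haplotype ids collapsed here
    is_median: bool

    @property
    def multiplicity(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeNetwork:
    nodes: list[NetworkNode]
    edges: list[tuple[str, str, int]]  # (node, node, mutational steps)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node.name, sequence=node.sequence,
                       members=node.members, is_median=node.is_median)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    @property
    def total_cost(self) -> int:
        """Mutational steps needed to connect all nodes (MST weight)."""
        g = self.graph()
        return int(sum(d["weight"]
                       for _, _, d in nx.minimum_spanning_edges(g, data=True)))

    @property
    def median_count(self) -> int:
        return sum(1 for n in self.nodes if n.is_median)


def _hamming(a: tuple, b: tuple) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_union_of_msts(vectors: list[tuple],
                       epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Minimum spanning network: an edge of weight w is kept iff its
    endpoints are not already connected using only edges of weight
    < w - epsilon.  With epsilon = 0 this is exactly the union of all
    minimum spanning trees."""
    n = len(vectors)
    pairs = sorted(
        ((_hamming(vectors[i], vectors[j]), i, j)
         for i in range(n) for j in range(i + 1, n)),
    )
    edges = []
    for w, i, j in pairs:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from((a, b) for ww, a, b in pairs if ww < w - epsilon)
        if not nx.has_path(g, i, j):
            edges.append((i, j, w))
    return edges


def _mst_cost(vectors: list[tuple]) -> int:
    g = nx.Graph()
    g.add_nodes_from(range(len(vectors)))
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            g.add_edge(i, j, weight=_hamming(vectors[i], vectors[j]))
    if len(vectors) < 2:
        return 0
    return int(sum(d["weight"]
                   for _, _, d in nx.minimum_spanning_edges(g, data=True)))


def _quasi_medians(u: tuple, v: tuple, w: tuple) -> list[tuple]:
    """Coordinate-wise majority; coordinates where all three states differ
    branch over the three states."""
    fixed: list = []
    branch_sites: list[int] = []
    options: list[tuple] = []
    for idx, (a, b, c) in enumerate(zip(u, v, w)):
        if a == b or a == c:
            fixed.append(a)
        elif b == c:
            fixed.append(b)
        else:
            fixed.append(None)
            branch_sites.append(idx)
            options.append((a, b, c))
    if not branch_sites:
        return [tuple(fixed)]
    results = []
    for combo in itertools.product(*options):
        vec = list(fixed)
        for site, state in zip(branch_sites, combo):
            vec[site] = state
        results.append(tuple(vec))
    return results


def median_joining_network(haplotypes: dict[str, str],
                           epsilon: int = 0) -> HaplotypeNetwork:
    """Build the haplotype network for aligned, gap/ambiguity-free
    sequences.

    Identical sequences collapse into one node.  Quasi-medians of node
    triples are added while they strictly reduce the cost of connecting
    the node set (best reduction first, canonical tie-breaks); afterwards
    median nodes of degree <= 2 whose removal does not raise the cost are
    pruned.  Edges are the union of all minimum spanning trees over the
    final node set (tolerance ``epsilon``; 0 keeps only MST-feasible
    links).
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    lengths = {len(s) for s in haplotypes.values()}
    if len(lengths) != 1:
        raise ValueError("sequences of unequal length")
    ids = sorted(haplotypes)
    seqs = {i: haplotypes[i].upper() for i in ids}
    for i, s in seqs.items():
        if set(s) - _CLEAN:
            raise ValueError(f"haplotype {i!r} contains non-ACGT characters")

    # collapse identical sequences; condense to segregating sites
    by_seq: dict[str, list[str]] = {}
    for i in ids:
        by_seq.setdefault(seqs[i], []).append(i)
    full_seqs = sorted(by_seq)
    L = len(full_seqs[0])
    seg = [j for j in range(L)
           if len({s[j] for s in full_seqs}) > 1]
    template = full_seqs[0]

    def condense(s: str) -> tuple:
        return tuple(s[j] for j in seg)

    def expand(vec: tuple) -> str:
        out = list(template)
        for j, state in zip(seg, vec):
            out[j] = state
        return "".join(out)

    observed = [condense(s) for s in full_seqs]
    vectors = list(dict.fromkeys(observed))

    # iterative quasi-median addition: accept the single median giving the
    # largest cost reduction; when no single median helps, look ahead one
    # level (pairs over the two-level quasi-median closure) — some optimal
    # configurations only pay off once both intermediates are present
    def candidate_medians(current: list[tuple], levels: int) -> list[tuple]:
        have = set(current)
        found: set[tuple] = set()
        pool = list(current)
        for _ in range(levels):
            new = set()
            for u, v, w in itertools.combinations(pool, 3):
                for med in _quasi_medians(u, v, w):
                    if med not in have and med not in found:
                        new.add(med)
            if not new:
                break
            found |= new
            pool = list(current) + sorted(found)
        return sorted(found)

    if len(vectors) >= 3:
        while True:
            base_cost = _mst_cost(vectors)
            best: list[tuple] | None = None
            best_cost = base_cost
            for med in candidate_medians(vectors, 1):
                cost = _mst_cost(vectors + [med])
                if cost < best_cost:
                    best, best_cost = [med], cost
            if best is None:
                pool = candidate_medians(vectors, 2)
                if len(pool) <= 64:
                    for pair in itertools.combinations(pool, 2):
                        cost = _mst_cost(vectors + list(pair))
                        if cost < best_cost:
                            best, best_cost = list(pair), cost
            if best is None:
                break
            vectors.extend(best)

    # prune pass-through medians (degree <= 2 in the MSN, removal does not
    # raise the connection cost)
    observed_set = set(observed)
    while True:
        edges = _msn_union_of_msts(vectors, epsilon)
        degree = {i: 0 for i in range(len(vectors))}
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        cost = _mst_cost(vectors)
        removable = None
        for i in sorted(range(len(vectors)),
                        key=lambda i: (degree[i], vectors[i])):
            if vectors[i] in observed_set or degree[i] > 2:
                continue
            rest = vectors[:i] + vectors[i + 1:]
            if _mst_cost(rest) <= cost:
                removable = i
                break
        if removable is None:
            break
        vectors.pop(removable)

    # canonical node naming and final edge set
    vectors.sort(key=lambda v: (v not in observed_set, v))
    nodes: list[NetworkNode] = []
    names: dict[tuple, str] = {}
    median_idx = 0
    for vec in vectors:
        seq = expand(vec)
        if vec in observed_set:
            members = tuple(sorted(by_seq[seq]))
            name = "+".join(members)
            nodes.append(NetworkNode(name, seq, members, False))
        else:
            median_idx += 1
            name = f"median{median_idx}"
            nodes.append(NetworkNode(name, seq, (), True))
        names[vec] = name
    edges = [(names[vectors[i]], names[vectors[j]], w)
             for i, j, w in _msn_union_of_msts(vectors, epsilon)]
    edges.sort()
    return HaplotypeNetwork(nodes, edges)
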