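"""Diversity statistics and the median-joining network, including the
brute-force Steiner oracle for small networks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from museomt.popstats import (EmptyMatrixError, SiteMatrix, complete_deletion, mean_pairwise_k,
                              median_joining_network, nucleotide_diversity,
                              resample_k, segregating_sites)
from museomt.simdata import sample_haplotypes


class TestCompleteDeletion:
    def test_clean_matrix_unchanged(self):
        m = SiteMatrix(["a", "b"], ["ACGT", "ACGT"])
        out, L = complete_deletion(m)
        assert out.rows == m.rows and L == 4

    def test_column_with_n_dropped(self):
        m = SiteMatrix(["a", "b"], ["ACGTAN", "ACNTAA"])
        out, L = complete_deletion(m)
        assert L == 4
        assert out.rows == ["ACTA", "ACTA"]

    def test_gap_and_iupac_columns_dropped(self):
        m = SiteMatrix(["a", "b"], ["A-GR", "ACGT"])
        out, L = complete_deletion(m)
        assert L == 2 and out.rows == ["AG", "AG"]

    def test_all_columns_removed_is_explicit(self):
        m = SiteMatrix(["a", "b"], ["N-", "AC"])
        with pytest.raises(EmptyMatrixError):
            complete_deletion(m)


class TestStatistics:
    def test_identical_rows(self):
        m = SiteMatrix(list("abc"), ["ACGT"] * 3)
        assert segregating_sites(m) == 0
        assert mean_pairwise_k(m) == 0.0
        assert nucleotide_diversity(m) == 0.0

    def test_hand_counted_examples(self):
        m = SiteMatrix(list("abc"), ["AAAA", "AAAT", "AATT"])
        assert segregating_sites(m) == 2
        # pairwise diffs 1, 2, 1 -> k = 4/3
        assert mean_pairwise_k(m) == pytest.approx(4 / 3)
        m2 = SiteMatrix(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAT"])
        assert nucleotide_diversity(m2) == pytest.approx(0.1)

    def test_three_rows_mean_of_pairs(self):
        # pairwise diffs {1, 2, 3} -> k = 2.0
        m = SiteMatrix(list("abc"), ["AAAA", "AAAT", "ATTA"])
        assert mean_pairwise_k(m) == pytest.approx(2.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_k(SiteMatrix(["a"], ["ACGT"]))

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.text(alphabet="ACGT", min_size=12, max_size=12),
                    min_size=2, max_size=6))
    def test_pi_times_length_equals_k(self, rows):
        m = SiteMatrix([f"s{i}" for i in range(len(rows))], rows)
        assert nucleotide_diversity(m) * m.length == \
            pytest.approx(mean_pairwise_k(m))

    def test_recovery_from_simulated_variant_lists(self, small_trio):
        """S and pi computed on generated haplotypes equal the values
        implied by the emitted variant lists."""
        ref = small_trio.references["A"]
        haps, variants = sample_haplotypes(ref, 4, 2, seed=21)
        m = SiteMatrix(list(haps), list(haps.values()))
        mutated_sites = {v.position for v in variants}
        states = {}
        for v in variants:
            states.setdefault(v.position, set()).add(v.alt_base)
        # a site segregates unless every haplotype carries the same change
        expected_s = sum(
            1 for p in mutated_sites
            if not (len(states[p]) == 1
                    and sum(v.position == p for v in variants) == 4))
        assert segregating_sites(m) == expected_s
        d = {}
        ids = list(haps)
        for i, j in itertools.combinations(range(4), 2):
            d[(i, j)] = sum(a != b for a, b in zip(haps[ids[i]],
                                                   haps[ids[j]]))
        k_expected = sum(d.values()) / 6
        assert mean_pairwise_k(m) == pytest.approx(k_expected)
        assert nucleotide_diversity(m) == pytest.approx(k_expected / len(ref))


class TestResampleK:
    def test_identical_sequences_all_zero(self):
        m = SiteMatrix(list("abcde"), ["ACGTACGT"] * 5)
        values = resample_k(m, m=4, B=100, seed=1)
        assert np.all(values == 0)

    def test_pool_equal_to_m_is_deterministic(self):
        m = SiteMatrix(list("abcd"),
                       ["AAAA", "AAAT", "AATT", "ATTT"])
        values = resample_k(m, m=4, B=1000, seed=3)
        assert values.shape == (1,)
        assert values[0] == pytest.approx(mean_pairwise_k(m))

    def test_too_few_sequences_names_species(self):
        m = SiteMatrix(list("abc"), ["AAAA"] * 3)
        with pytest.raises(ValueError, match="oryx"):
            resample_k(m, m=4, species="oryx")

    def test_draw_distribution_matches_enumeration(self):
        """5 sequences, one 10 steps from four identical others: draws of 4
        give k in {0, 5.0}, with P(5.0) = C(4,3)/C(5,4) = 0.8."""
        base = "A" * 20
        outlier = "T" * 10 + "A" * 10
        m = SiteMatrix(list("abcde"), [base] * 4 + [outlier])
        values = resample_k(m, m=4, B=1000, seed=11)
        assert set(np.unique(values)) == {0.0, 5.0}
        p_obs = float(np.mean(values == 5.0))
        sigma = np.sqrt(0.8 * 0.2 / 1000)
        assert abs(p_obs - 0.8) < 3 * sigma

    def test_seeded_reproducibility(self):
        m = SiteMatrix(list("abcde"),
                       ["AAAA", "AAAT", "AATT", "ATTT", "TTTT"])
        v1 = resample_k(m, m=4, B=50, seed=5)
        v2 = resample_k(m, m=4, B=50, seed=5)
        assert np.array_equal(v1, v2)


# ---------------------------------------------------------------------------
# median-joining network
# ---------------------------------------------------------------------------


def oracle_steiner_cost(seqs: list[str]) -> int:
    """Independent brute force: minimum over subsets (size <= n-2) of the
    quasi-median closure of the MST weight, with Prim's algorithm written
    out by hand."""

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    def prim(nodes):
        if len(nodes) < 2:
            return 0
        in_tree = {0}
        cost = 0
        while len(in_tree) < len(nodes):
            best = None
            for i in in_tree:
                for j in range(len(nodes)):
                    if j in in_tree:
                        continue
                    d = ham(nodes[i], nodes[j])
                    if best is None or d < best[0]:
                        best = (d, j)
            cost += best[0]
            in_tree.add(best[1])
        return cost

    def quasi_medians(u, v, w):
        sites = []
        for a, b, c in zip(u, v, w):
            if a == b or a == c:
                sites.append((a,))
            elif b == c:
                sites.append((b,))
            else:
                sites.append((a, b, c))
        return {"".join(combo) for combo in itertools.product(*sites)}

    observed = list(dict.fromkeys(seqs))
    closure = set(observed)
    frontier = set(observed)
    for _ in range(4):  # closure levels; tiny instances converge fast
        new = set()
        pool = sorted(closure)
        for u, v, w in itertools.combinations(pool, 3):
            new |= quasi_medians(u, v, w) - closure
        if not new:
            break
        closure |= new
        frontier = new
    candidates = sorted(closure - set(observed))
    max_extra = max(len(observed) - 2, 0)
    best = prim(observed)
    for size in range(1, max_extra + 1):
        for combo in itertools.combinations(candidates, size):
            best = min(best, prim(observed + list(combo)))
    return best


class TestMedianJoiningNetwork:
    def test_two_haplotypes_single_edge(self):
        net = median_joining_network({"a": "AAAA", "b": "AAAT"})
        assert len(net.nodes) == 2
        assert net.edges == [("a", "b", 1)]
        assert net.total_cost == 1

    def test_star_median_inferred(self):
        net = median_joining_network(
            {"x": "AATT", "y": "TAAT", "z": "ATAT"})
        medians = [n for n in net.nodes if n.is_median]
        assert len(medians) == 1
        assert sorted(w for _, _, w in net.edges) == [1, 1, 1]
        assert net.total_cost == 3

    def test_identical_haplotypes_collapse(self):
        net = median_joining_network(
            {"s": "AAAA", "u": "AAAA", "v": "AAAT"})
        names = {n.name: n for n in net.nodes}
        assert "s+u" in names
        assert names["s+u"].multiplicity == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            median_joining_network({"a": "AAA", "b": "AAAA"})

    def test_path_weights_bound_hamming_distance(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        haps = {f"h{i}": "".join("ACGT"[b]
                                 for b in rng.integers(0, 2, 10))
                for i in range(4)}
        net = median_joining_network(haps)
        g = net.graph()
        seq = {n.name: n.sequence for n in net.nodes}
        for u, v in itertools.combinations([n.name for n in net.nodes], 2):
            direct = sum(a != b for a, b in zip(seq[u], seq[v]))
            path = nx.shortest_path_length(g, u, v, weight="weight")
            assert path >= direct

    def test_total_cost_matches_steiner_oracle(self):
        """200 random instances with <= 4 haplotypes and <= 8 segregating
        sites: the constructed network connects at brute-force minimum
        Steiner cost."""
        rng = np.random.default_rng(42)
        for trial in range(200):
            n = int(rng.integers(2, 5))
            sites = int(rng.integers(1, 9))
            rows = ["".join("ACGT"[b] for b in rng.integers(0, 2, sites))
                    for _ in range(n)]
            haps = {f"h{i}": r for i, r in enumerate(rows)}
            net = median_joining_network(haps)
            assert net.total_cost == oracle_steiner_cost(rows), \
                f"trial {trial}: {rows}"

    def test_canonical_under_input_order(self):
        haps = {"a": "AATT", "b": "TAAT", "c": "ATAT", "d": "TTTA"}
        n1 = median_joining_network(dict(sorted(haps.items())))
        n2 = median_joining_network(dict(sorted(haps.items(),
                                                reverse=True)))
        assert n1.edges == n2.edges
        assert [n.name for n in n1.nodes] == [n.name for n in n2.nodes]
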