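"""Generator correctness: trio divergence calibration, haplotype variant
bookkeeping, read construction, probe tiling, determinism."""

import math
import re

import numpy as np
import pytest

from museomt.simdata import (CircularReference, IndelEvent, ReadSimParams,
                             TrioModel, design_tiling_probes,
                             expected_p_distance, generate_reference_trio,
                             revcomp, sample_haplotypes, simulate_reads,
                             with_seed)


def p_distance(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestReferenceTrio:
    def test_zero_divergence_gives_identical_gapfree_trio(self):
        model = TrioModel(genome_length=2000, ab_to_a=0, ab_to_b=0,
                          root_to_ab=0, root_to_c=0, seed=4)
        trio = generate_reference_trio(model)
        seqs = [r.sequence for r in trio]
        assert seqs[0] == seqs[1] == seqs[2]
        assert all("-" not in a for a in trio.alignment.values())

    def test_pairwise_divergence_matches_jukes_cantor(self):
        # branch sums: d(A,B) = 0.06, d(A,C) = d(B,C) = 0.09
        model = TrioModel(genome_length=16000, ab_to_a=0.03, ab_to_b=0.03,
                          root_to_ab=0.015, root_to_c=0.045, seed=7)
        trio = generate_reference_trio(model)
        aln = trio.alignment
        for pair, d_sum in (("AB", 0.06), ("AC", 0.09), ("BC", 0.09)):
            a, b = aln[pair[0]], aln[pair[1]]
            p_exp = expected_p_distance(d_sum)
            p_obs = p_distance(a, b)
            sigma = math.sqrt(p_exp * (1 - p_exp) / len(a))
            assert abs(p_obs - p_exp) < 3 * sigma

    def test_control_region_insertion_appears_as_gap_block(self, small_trio):
        aln = small_trio.alignment
        assert [len(g) for g in re.findall("-+", aln["A"])] == [78]
        assert [len(g) for g in re.findall("-+", aln["C"])] == [78]
        assert "-" not in aln["B"]
        # the insertion falls inside B's annotated control region
        b = small_trio.references["B"]
        gap_start = aln["A"].index("-")
        b_pos = len(aln["B"][:gap_start].replace("-", ""))
        lo, hi = b.control_region
        assert lo <= b_pos < hi

    def test_oversized_indel_rejected(self):
        model = TrioModel(genome_length=1000,
                          indel_events=(IndelEvent("b", "control_region",
                                                   900, "insertion"),))
        with pytest.raises(ValueError, match="does not fit"):
            generate_reference_trio(model)

    def test_same_seed_is_bit_identical(self):
        m = TrioModel(genome_length=1500, seed=9)
        t1 = generate_reference_trio(m)
        t2 = generate_reference_trio(m)
        assert [r.sequence for r in t1] == [r.sequence for r in t2]
        assert t1.alignment == t2.alignment


class TestHaplotypes:
    def test_zero_mutations_gives_identical_haplotypes(self, small_trio):
        ref = small_trio.references["A"]
        haps, variants = sample_haplotypes(ref, 4, 0, seed=1)
        assert len(haps) == 4
        assert all(h == ref.sequence for h in haps.values())
        assert variants == []

    def test_hamming_distances_follow_variant_list(self, small_trio):
        ref = small_trio.references["A"]
        haps, variants = sample_haplotypes(ref, 4, 2, seed=3)
        by_hap = {}
        for v in variants:
            by_hap.setdefault(v.haplotype_id, set()).add(v.position)
            assert ref.sequence[v.position] == v.ref_base
            assert haps[v.haplotype_id][v.position] == v.alt_base
        ids = list(haps)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                si, sj = by_hap.get(ids[i], set()), by_hap.get(ids[j], set())
                # sites mutated in both could coincide (rare at these sizes)
                expected = len(si ^ sj) + sum(
                    1 for p in si & sj
                    if haps[ids[i]][p] != haps[ids[j]][p])
                observed = sum(a != b for a, b in zip(haps[ids[i]],
                                                      haps[ids[j]]))
                assert observed == expected

    def test_too_many_mutations_rejected(self, small_trio):
        with pytest.raises(ValueError):
            sample_haplotypes(small_trio.references["A"], 1, 10**6)


class TestReadSimulation:
    def test_error_free_reads_are_substrings_of_doubled_circle(self,
                                                               specimen_a):
        hap = specimen_a["haplotype"]
        doubled = hap + hap
        doubled_rc = revcomp(doubled)
        truth = {t.read_id: t for t in specimen_a["sim"].truth}
        for rid, bases, _ in specimen_a["sim"].reads:
            t = truth[rid]
            flen = t.end - t.start
            if flen >= len(bases):  # no adapter read-through
                assert bases in doubled or bases in doubled_rc

    def test_adapter_readthrough_matches_construction(self):
        hap = "ACGT" * 300
        params = ReadSimParams(fragment_mean_log=math.log(40),
                               fragment_sd_log=1e-9, mean_depth=1.0,
                               seed=2)
        sim = simulate_reads(hap, params)
        truth = {t.read_id: t for t in sim.truth}
        checked = 0
        for rid, bases, _ in sim.reads:
            t = truth[rid]
            if t.end - t.start == 40:
                assert len(bases) == 75
                assert bases[40:] == params.adapter[:35]
                checked += 1
        assert checked > 0

    def test_deamination_rate_at_terminal_base(self):
        rng_hap = np.random.default_rng(0)
        hap = "".join("ACGT"[i] for i in rng_hap.integers(0, 4, 20000))
        params = ReadSimParams(deamination_rate=0.3, mean_depth=3.0, seed=5)
        sim = simulate_reads(hap, params)
        doubled = hap + hap
        truth = {t.read_id: t for t in sim.truth}
        c_start, converted = 0, 0
        for rid, bases, _ in sim.reads:
            t = truth[rid]
            if t.is_duplicate or t.is_exogenous:
                continue
            frag = doubled[t.start % 20000:][: t.end - t.start]
            if t.strand == "-":
                frag = revcomp(frag)
            if frag[0] == "C":
                c_start += 1
                converted += bases[0] == "T"
        p_obs = converted / c_start
        sigma = math.sqrt(0.3 * 0.7 / c_start)
        assert abs(p_obs - 0.3) < 3 * sigma

    def test_duplicates_are_byte_identical(self):
        hap = "ACGT" * 1000
        params = ReadSimParams(duplicate_rate=0.5, mean_depth=2.0, seed=8)
        sim = simulate_reads(hap, params)
        by_id = {rid: bases for rid, bases, _ in sim.reads}
        dups = [t for t in sim.truth if t.is_duplicate]
        assert dups
        for t in dups:
            # duplicate ids are emitted immediately after their original
            orig_id = f"{t.haplotype_id}:{int(t.read_id.split(':')[1]) - 1}"
            assert by_id[t.read_id] == by_id[orig_id]

    def test_realized_depth_within_ten_percent(self, specimen_a):
        L = len(specimen_a["haplotype"])
        total = sum(min(t.end - t.start, 75)
                    for t in specimen_a["sim"].truth
                    if not (t.is_duplicate or t.is_exogenous))
        assert abs(total / L - 5.0) / 5.0 < 0.10

    def test_exogenous_fraction_and_flags(self):
        hap = "ACGT" * 1000
        params = ReadSimParams(endogenous_fraction=0.5, mean_depth=2.0,
                               seed=3)
        sim = simulate_reads(hap, params)
        exo = [t for t in sim.truth if t.is_exogenous]
        endo = [t for t in sim.truth if not t.is_exogenous]
        assert abs(len(exo) - len(endo)) <= 1
        assert all(t.start == -1 and t.strand == "." for t in exo)

    def test_same_seed_gives_identical_fastq(self):
        hap = "ACGT" * 500
        params = ReadSimParams(error_rate=0.01, deamination_rate=0.1,
                               duplicate_rate=0.2, endogenous_fraction=0.8,
                               mean_depth=2.0, seed=13)
        assert simulate_reads(hap, params).reads == \
            simulate_reads(hap, with_seed(params, 13)).reads


class TestProbeTiling:
    def test_single_probe_is_the_sequence(self):
        ref = CircularReference("r", "ACGT" * 15, (60, 60))
        probes = design_tiling_probes(ref, probe_len=60, tile=3,
                                      wrap_extension=0)
        assert probes == [(0, ref.sequence)]

    def test_tiling_starts_are_multiples_of_tile(self):
        ref = CircularReference("r", "A" * 66, (66, 66))
        probes = design_tiling_probes(ref, probe_len=60, tile=3,
                                      wrap_extension=0)
        assert [s for s, _ in probes] == [0, 3, 6]

    def test_probe_count_on_full_length_mitogenome(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 16514))
        ref = CircularReference("mt", seq, (15450, 16514))
        probes = design_tiling_probes(ref)
        assert len(probes) == 5505

    def test_wrap_extension_covers_every_position(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        ref = CircularReference("r", seq, (450, 500))
        probes = design_tiling_probes(ref, probe_len=60, tile=3,
                                      wrap_extension=59)
        covered = set()
        for s, p in probes:
            assert p == (seq + seq[:59])[s : s + 60]
            covered.update((s + i) % 500 for i in range(60))
        assert covered == set(range(500))

    def test_too_short_sequence_rejected(self):
        ref = CircularReference("r", "ACGT" * 10, (40, 40))
        with pytest.raises(ValueError):
            design_tiling_probes(ref, probe_len=60, tile=3, wrap_extension=0)
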