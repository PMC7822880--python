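# museomt

Species identification and mitochondrial-diversity analysis for degraded
museum-specimen sequencing data.

Natural history collections hold specimens whose species identity is
contentious — skins, skulls and horns labeled long ago, often without
provenance. Shotgun or capture sequencing of such material yields short
(~75 bp single-end), damaged, contamination-rich reads, but even a few
thousand endogenous reads are enough to assign a specimen to a species by
its mitogenome and to say something about the maternal diversity of the
sampled "museum population". `museomt` implements that workflow end to
end, together with a synthetic ancient-DNA read generator so the whole
pipeline is testable without any external data.

## What it computes

**Competitive mapping classifier.** Each specimen's cleaned reads are
mapped independently to every candidate reference mitogenome (circular,
~16.5 kb), filtered at mapping quality ≥ 30 and deduplicated on both
alignment endpoints. With `b_r` the total bases mapped to reference `r`,
the *normalized relative mapping success* is

    s_r = b_r / max_r' b_r'

so the best reference scores 1 and the call is `argmax_r s_r` (an exact
tie is an explicit no-call). On a sister-pair topology ((A,B),C), reads
from A map second-best to B, so the runner-up identifies the sister
species.

**Circular consensus.** Reference-coordinate consensus with a 75%
majority rule and minimum coverage 3× (below: N); sub-threshold columns
emit the minimal covering IUPAC code; insertions relative to the
reference need ≥ 3 supporting reads; deletion-majority columns are
omitted. Because linear mapping loses coverage at the linearization
point of the circle, a second pass maps against the reference rotated by
100 bp and the two consensuses are combined per position at a 50% rule.

**Diversity.** After *complete deletion* (every column containing a gap,
N or ambiguity in any sequence is discarded, leaving L columns), with
`d_ij` pairwise mismatch counts over n sequences:

    k  = Σ_{i<j} d_ij / C(n,2)        mean pairwise substitutions
    π  = k / L                        nucleotide diversity
    S  = # columns with ≥ 2 states    segregating sites

`resample_k` draws m = 4 sequences without replacement B = 1000 times
from a species' pool to make k comparable across species with different
sample sizes. A median-joining network connects observed haplotypes
through inferred unsampled intermediates (quasi-medians), with edges
weighted in mutational steps.

**Tree.** Control-region excision, p or JC69 distances
(`d = −(3/4)·ln(1 − 4p/3)`), neighbor-joining, and nonparametric
bootstrap (column resampling) clade supports. Unequal-length inputs are
aligned with MAFFT.

**Simulator.** A Jukes–Cantor trio generator (((A,B),C) with
configurable branch lengths and a lineage-specific control-region indel),
within-species haplotype sampling with exact variant lists, and an
ancient-DNA read simulator (truncated-lognormal fragments ≥ 30 bp,
adapter read-through, flat sequencing error, optional 5′ C→T
deamination, PCR duplicates, tunable endogenous fraction) with per-read
truth tables. Capture-probe tiling (60-mers, 3-bp step, 59-bp wraparound
extension) is included for bait design.

## Worked example

```python
from museomt.simdata import (default_study_trio, generate_reference_trio,
                             sample_haplotypes, simulate_reads,
                             uniform_coverage_params)
from museomt.readprep import Read, prep_reads
from museomt.speciesid import build_indexes, classify_specimen
from museomt.consensus import edge_rescue
from museomt.popstats import SiteMatrix, diversity, median_joining_network

trio = generate_reference_trio(default_study_trio(genome_length=16500, seed=1))
indexes = build_indexes(list(trio.references.values()))

haps, _ = sample_haplotypes(trio.references["A"], 4, 2, seed=11)
for i, (hap_id, hap) in enumerate(haps.items()):
    sim = simulate_reads(hap, uniform_coverage_params(5.0, seed=100 + i),
                         haplotype_id=hap_id)
    reads = prep_reads([Read.from_fastq(*r) for r in sim.reads])
    report, _ = classify_specimen(hap_id, reads, indexes)
    print(hap_id, report.call, report.normalized)
```

prints (abridged):

```
A_hap0: call=A margin=0.11 normalized={'A': 1.0, 'B': 0.89, 'C': 0.29}
  consensus: 16500 bp, 0 N, exact=True
A_hap1: call=A margin=0.11 normalized={'A': 1.0, 'B': 0.89, 'C': 0.29}
...
diversity: L=16500 S=8 pi=0.000242 k=4.000
network: 5 nodes (1 inferred), total steps 8
```

Every specimen is called as species A with normalized success 1.0, the
sister reference B scores ≈ 0.89 (it absorbs most A reads at ~3%
divergence) and the deeper outgroup C only ≈ 0.29. The edge-rescued
consensus of the first specimen reconstructs its haplotype exactly
(0 N over 16,500 bp). The four haplotypes carry 2 private substitutions
each, hence S = 8 segregating sites, k = 4 mean pairwise substitutions,
π = k/L ≈ 2.4 × 10⁻⁴, and a star-like network with one inferred
(unsampled) central haplotype.

A command-line interface mirrors the library
(`museomt simulate|prep|map|classify|consensus|diversity|network|tree|probes|run`);
`museomt run config.txt` drives the whole pipeline from a plain
key-value config.

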