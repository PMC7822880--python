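# Methods

This note documents the models, rules and numerical choices behind
`museomt`, in the order the pipeline applies them.

## Synthetic data model

**Reference trio.** Three circular mitogenome-scale references related as
((A,B),C) are simulated from a random ancestor under Jukes–Cantor
substitution. Branch lengths are expected substitutions/site; because JC
transition matrices compose (two branches of lengths d₁, d₂ equal one of
d₁+d₂), per-branch endpoint sampling gives exact distributions on the
whole tree, and the realized p-distance between two leaves with branch
sum d has mean `3/4·(1 − e^(−4d/3))` with binomial variance — the
calibration asserted in the tests. JC was chosen because the pipeline
consumes only distances; branch lengths stay interpretable without rate
parameters. Indel events (branch, region, length, insertion/deletion)
are applied to the stated lineage inside the coding or control region;
the generator returns the true gapped alignment alongside the ungapped
references. The default study trio uses sister branches summing to 3%
divergence, an outgroup at ~8%, and a 78-bp insertion in the control
region of lineage B, mirroring the structure of a bovid sister-species
panel in which one reference carries a control-region block the others
lack. The control region occupies the final 7% of the genome
(bovid-like proportion); the tRNA-Phe anchor is position 0 by the usual
linearization convention.

**Within-species haplotypes** differ from their reference at exactly the
drawn substitution sites; the emitted variant list is exact, so
diversity statistics can be checked against hand-computed truth.

**Reads.** Fragments are placed on the circle (wraparound allowed) with
truncated-lognormal lengths, minimum 30 bp (the pipeline's own length
filter), maximum 300 bp. The read is the first `read_length` bases of
the fragment strand; shorter fragments run into the sequencing adapter
(read-through), which the adapter trimmer must remove. Deamination (5′
C→T with geometric decay into the fragment) is off by default, the
appropriate setting for USER-treated single-stranded libraries; flat
per-base substitution error and byte-identical PCR duplicates are
applied after truncation. Exogenous contamination is i.i.d. uniform
random sequence at rate 1 − endogenous_fraction: only the
endogenous-fraction mechanic matters downstream, so no real contaminant
genome is modeled. Depth is defined as endogenous aligned bases over
genome length; fragment lengths are drawn until the target is met, so
realized depth tracks the request within a few percent.

Two start-placement modes exist. `uniform` (default) scatters fragment
starts i.i.d.; per-position coverage is then essentially Poisson, so at
5× mean roughly an eighth of positions fall below a 3-read minimum —
realistic for shotgun data, but incompatible with exact reconstruction.
`systematic` stratifies starts (one jittered start per equal arc of the
circle), and `uniform_coverage_params()` combines it with fragment
lengths tightly around the read length; this is the uniform-coverage
regime used for exact-recovery demonstrations. What passing
exact-recovery tests show is therefore a property of the consensus
machinery under adequate uniform coverage, not a claim that 5× shotgun
data yields complete genomes.

The generator does not model capture efficiency biases, quality-score
error profiles, index hopping, or real contaminant genomes; per-position
coverage in real capture data is far more uneven than either mode.

## Read cleaning

Order: adapter → 3′ quality → length ≥ 30 → (consensus path only)
dedup-by-sequence. Adapter trimming removes the longest 3′ suffix
matching an adapter prefix with ≤ ⌊0.10·overlap⌋ mismatches, minimum
overlap 1 bp — so a read whose last base equals the adapter's first base
loses it; with 1-bp overlap this is deliberately aggressive and costs
roughly a quarter of reads one terminal base. Quality trimming is the
BWA-style running-sum rule at Q30: accumulate (threshold − q) from the
3′ end and cut at the maximum of the partial sums; all-good reads and
empty reads pass unchanged. Duplicate removal by exact sequence identity
keeps first occurrences and is idempotent. The mapping path instead
deduplicates after alignment by both endpoints (below); applying Q30
trimming on that path too is the default, switchable off.

## Mapping

A deterministic seed-and-extend mapper over an exact 13-mer index.
Circularity is handled at indexing time by extending the reference with
`max_read_length − 1 = 299` wraparound bases; coordinates are reported
on the original circle with `end > L` denoting wraparound. A linear
(non-extended) mode exists for the consensus path so that the two-pass
edge rescue below remains load-bearing, as in pipelines built on linear
aligners.

Candidates come from every overlapping read 13-mer on both strands and
are scored gaplessly (match +1, mismatch −1) with vectorized
comparisons. A full affine-gap DP (gap open −2, extend −1; read global,
reference local) refines a locus only when the gapless best misses the
acceptance threshold *and* seed hits fall on two diagonals within the
16-column band — the signature of a small indel. Acceptance requires
score ≥ 0.89 × read length, i.e. about 4 mismatches on a 75-mer,
matching the default stringency of the short-read aligners this mapper
stands in for. That stringency is what gives the classifier its signal:
reads from the sequenced species nearly always map to their own
reference, map to a ~3%-divergent sister with probability ≈ 0.9, and
mostly fail on an ~8%-divergent outgroup.

Mapping quality is a pure uniqueness indicator — 37 for a unique best
placement, 0 when two distinct placements tie — because the only
downstream use is the MQ ≥ 30 filter. Duplicate removal keys on
(start, end, strand) ("both-ends"; a "5p" mode keys on (start, strand));
the representative is the highest score, then the lexicographically
smallest read id, and output is sorted by coordinates, making the
operation deterministic and idempotent. `mapped_bases` sums read bases
in match/mismatch columns only (insertions to the reference excluded).

## Species classification

Each specimen is mapped independently to every reference (a read may
count for several), then filtered and deduplicated per reference.
Normalized success divides each per-reference mapped-base total by the
best total; the call is the argmax, an exact tie is an explicit no-call,
and the margin (best − second normalized score) is reported so users can
impose their own threshold — only exact ties are refused here, since the
statistic itself defines no margin cutoff. Normalization makes the call
scale-invariant. For already-assembled sequences a shred-and-map mode
cuts the input into non-overlapping 75-mers and runs the identical
pipeline.

## Consensus

Pileups count every aligned column once (positions mod L, trim-to-
reference: nothing outside reference coordinates); insertions accumulate
in a side table keyed by the position they precede. Per column with
depth < 3: N. Deletion as plurality winner: the column is omitted from
the output (reference-coordinate FASTA loses that base). Otherwise the
top base is called if its frequency (relative to bases + deletions)
reaches 75%; below that, the smallest set of highest-frequency bases
whose cumulative frequency reaches 75% is emitted as an IUPAC code
(count ties broken in A<C<G<T order; a strict-N switch is available).
Insertions are included when supported by ≥ 3 reads, taking the most
common inserted sequence. Base qualities are not weighted — counts
only.

Edge rescue maps the reads a second time against the reference with its
last 100 bp moved to the front, rotates that consensus back, and
combines the two per position at a 50% rule: agreement stands, N yields
to any other state, conflicting base calls take the IUPAC union (any
base present in 1 of 2 calls qualifies at 50%), and a deletion
conflicting with a base call keeps the base — the definition of conflict
handling at the combine step was an open choice; the union reading is
used because it never discards observed evidence. The combined call
never has fewer called bases than either input. Monotonicity holds by
construction: raising min_depth can only turn calls into Ns.

## Diversity statistics

All statistics run on complete-deletion columns (any gap, N or IUPAC in
any row removes the column), computed once on the joint alignment and
frozen before any resampling. Distances are raw mismatch counts — the
quantities are defined as observed substitution counts, so no
multiple-hit correction is applied. π·L = k is an exact identity on any
matrix and is asserted as such. `resample_k` uses one RNG stream per
replicate, (seed, b), so results are independent of execution order; a
pool of exactly m sequences returns the single deterministic k. Since
all draws come from one frozen column set, per-draw realignment would be
a no-op and is skipped.

## Median-joining network

Identical haplotypes collapse into one node (members recorded); work
happens on segregating-site vectors. The network is built by iterative
quasi-median addition: candidate medians are coordinate-wise majorities
of node triples (coordinates where all three states differ branch over
the three); in each round the candidate giving the largest reduction in
connection cost (MST weight over the node set) is added, with a
pairwise lookahead over the two-level quasi-median closure when no
single candidate helps — some two-intermediate configurations only pay
off jointly. Afterwards, unsampled nodes of degree ≤ 2 whose removal
does not raise the connection cost are pruned (canonical, smallest-
vector-first order). Final edges are the union of all minimum spanning
trees over the surviving nodes (an edge of weight w is kept iff its
endpoints are not connected by strictly lighter edges; tolerance ε
relaxes this, default 0). Node naming and iteration order are
canonical, so the result is independent of input order. On small
instances (≤ 4 haplotypes, ≤ 8 segregating sites) the construction is
validated in the tests against a brute-force Steiner oracle that
enumerates subsets of the quasi-median closure. The exact internal
variant of published median-joining tools is unspecified detail; this
construction is the package's definition.

## Phylogeny

The control region is excised before tree building (unalignable across
divergent species). Unequal-length sequences are aligned with MAFFT
(the field-standard aligner; default parameters); equal-length inputs
pass through unchanged as already sharing coordinates. Distances are
p-distances or the JC69 correction (undefined at p ≥ 3/4, rejected
explicitly) on complete-deletion columns. Neighbor-joining uses the
standard Q-criterion agglomeration with ties broken by the sorted pair
of smallest-leaf labels, making output independent of input order;
negative branch lengths are clamped to zero. On additive matrices NJ
provably recovers the generating topology, asserted in the tests over
all 4- and 5-taxon shapes. Bootstrap resamples columns with replacement
(stream (seed, replicate)) and reports the percentage of replicates
containing each original internal bipartition, encoded canonically (the
side not containing the alphabetically first taxon). NJ + bootstrap
stands in for full maximum-likelihood inference: the species involved
are deeply divergent with shallow within-species structure, where clade
recovery is method-insensitive; the supports the acceptance run
computes are produced by this method, not by ML. Newick output carries
supports as internal node labels, with outgroup rooting for display
only.

## Problem sizes and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| read_length | 75 | bp | single-end short-read archival sequencing |
| fragment min/max | 30 / 300 | bp | ≥ 30 matches the length filter; aDNA fragments are short |
| error_rate | 0 (sim), 0.002 in sweeps | /base | flat proxy for post-filter error |
| deamination_rate | 0 | /fragment 5′ | USER-treated libraries |
| majority / min_depth | 0.75 / 3 | — / reads | consensus calling rules |
| min_insertion_support | 3 | reads | insertion acceptance |
| edge_window / combine | 100 bp / 0.50 | | circular rescue |
| min_mq | 30 | — | uniqueness filter |
| k (seed) | 13 | bp | exact-match seeds on 16.5-kb targets |
| min_score_fraction | 0.89 | — | ≈ 4 mismatches / 75 bp, aligner-default stringency |
| m / B (resampling) | 4 / 1000 | draws | cross-species comparison design |
| bootstrap B | 100 | replicates | standard support resolution |

The test suite and acceptance script use 16.5-kb genomes where the
full-scale behaviour is the point (exact reconstruction, the museum
panel, probes) and 4-kb genomes for the 100-simulation classifier sweep,
where the per-simulation mapped-base totals are already decisive at a
few hundred reads; these sizes are the package's own defaults for its
demonstration study.

## Known limitations

- The mapper is exact-seed based: reads with no clean 13-mer against the
  target (possible at very high divergence or error) are dropped rather
  than rescued; paired-end, spliced and local-only alignment are out of
  scope, as is a probabilistic MAPQ model.
- The consensus has no base-quality weighting and no diploid genotype
  model; it is a haploid mitogenome caller.
- mtDNA-only identification cannot detect hybrids; the classifier
  reports maternal ancestry only.
- The simulator's exogenous reads are random sequence, so endogenous
  fraction estimates derived from it are optimistic relative to real
  microbial contamination, which shares k-mers with the target.
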