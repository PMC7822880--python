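"""Synthetic data generation for the whole pipeline.

Everything downstream (read cleaning, competitive mapping, consensus,
diversity statistics, trees) is exercised against data produced here, so
this module emulates the salient features of a museum-specimen mitogenome
study: a trio of circular ~16.5 kb references related as ((A,B),C) with a
lineage-specific control-region indel, within-species haplotypes carrying a
handful of substitutions, and short single-end reads with ancient-DNA
characteristics (short fragments, adapter read-through, sequencing error,
optional 5' C->T deamination, PCR duplicates, exogenous contamination).

All coordinates are 0-based, half-open; circular positions reduce mod L.
Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Illumina TruSeq/smallRNA-style adapter used when a fragment is shorter
#: than the read length (read-through).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACACAGTGATCTCGTATGCCGTCTTCTGCTTG"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (keeps N)."""
    return seq.translate(COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Encode A/C/G/T as uint8 0..3 (anything else becomes 4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_INT.items():
        out[arr == ord(base)] = code
    return out


def array_to_seq(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircularReference:
    """An annotated circular mitogenome.

    ``control_region`` is a 0-based half-open span; ``anchor`` is the start
    of tRNA-Phe (by convention position 0 for generated references, matching
    the usual linearization of bovid mitogenomes, which start with tRNA-Phe
    and end with the control region).
    """

    id: str
    sequence: str
    control_region: tuple[int, int]
    anchor: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        lo, hi = self.control_region
        if not (0 <= lo <= hi <= len(self.sequence)):
            raise ValueError(
                f"control region {self.control_region} outside [0, {len(self.sequence)})"
            )
        if not (0 <= self.anchor < len(self.sequence)):
            raise ValueError("anchor outside sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IndelEvent:
    """A single indel placed on one branch of the trio.

    branch in {"a", "b", "c", "ab"}; region in {"control_region", "coding"};
    kind in {"insertion", "deletion"}.
    """

    branch: str
    region: str
    length: int
    kind: str

    def __post_init__(self) -> None:
        if self.branch not in {"a", "b", "c", "ab"}:
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.region not in {"control_region", "coding"}:
            raise ValueError(f"unknown region {self.region!r}")
        if self.kind not in {"insertion", "deletion"}:
            raise ValueError(f"unknown indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


@dataclass(frozen=True)
class TrioModel:
    """Parameters for the three-species reference panel ((A,B),C).

    Branch lengths are expected substitutions/site under Jukes-Cantor on the
    four branches: AB-ancestor->A, AB-ancestor->B, root->AB, root->C.  The
    control region occupies the final ``control_region_fraction`` of the
    genome, mirroring a tRNA-Phe-anchored mitogenome.
    """

    genome_length: int = 16_500
    ab_to_a: float = 0.01
    ab_to_b: float = 0.01
    root_to_ab: float = 0.02
    root_to_c: float = 0.04
    indel_events: tuple[IndelEvent, ...] = ()
    control_region_fraction: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for d in (self.ab_to_a, self.ab_to_b, self.root_to_ab, self.root_to_c):
            if d < 0:
                raise ValueError("branch lengths must be >= 0")
        if not 0 < self.control_region_fraction < 0.5:
            raise ValueError("control_region_fraction must be in (0, 0.5)")


@dataclass(frozen=True)
class ReadSimParams:
    """Knobs of the ancient-DNA read simulator.

    Fragment lengths are lognormal (on the log scale: ``fragment_mean_log``,
    ``fragment_sd_log``) truncated to [fragment_min, fragment_max]; the
    default law centres fragments around ~60-90 bp, typical for archival
    skin/bone extracts.  Deamination is off by default, as appropriate for
    USER-treated single-stranded libraries.
    """

    read_length: int = 75
    fragment_mean_log: float = 4.3
    fragment_sd_log: float = 0.35
    fragment_min: int = 30
    fragment_max: int = 300
    error_rate: float = 0.0
    deamination_rate: float = 0.0
    deamination_decay: float = 0.5
    duplicate_rate: float = 0.0
    endogenous_fraction: float = 1.0
    adapter: str = DEFAULT_ADAPTER
    mean_depth: float = 5.0
    base_quality: int = 37
    start_mode: str = "uniform"  # "uniform" or "systematic" (stratified)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_mode not in ("uniform", "systematic"):
            raise ValueError("start_mode must be 'uniform' or 'systematic'")
        for name in ("error_rate", "deamination_rate", "deamination_decay",
                     "duplicate_rate", "endogenous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fragment_min < 30:
            raise ValueError("fragment_min must be >= 30")
        if self.fragment_max < self.fragment_min:
            raise ValueError("fragment_max < fragment_min")
        if self.read_length < 1 or self.mean_depth <= 0:
            raise ValueError("read_length and mean_depth must be positive")


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    haplotype_id: str
    start: int  # 0-based on the circle; -1 for exogenous reads
    end: int  # may exceed L to denote wraparound; -1 for exogenous
    strand: str  # "+", "-" or "." for exogenous
    is_duplicate: bool
    is_exogenous: bool


@dataclass
class SimulatedReads:
    """FASTQ-ready reads plus their per-read truth table."""

    reads: list[tuple[str, str, str]]  # (id, bases, quality string)
    truth: list[TruthRecord]

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(t) for t in self.truth])


# ---------------------------------------------------------------------------
# reference trio
# ---------------------------------------------------------------------------


def _jc_substitute(states: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve base states along a Jukes-Cantor branch of length d.

    Under JC the endpoint differs from the start with probability
    3/4 (1 - exp(-4d/3)), uniformly among the three other bases; composing
    two branches equals one branch of summed length, so per-branch
    application yields exact endpoint distributions on any tree.
    """
    if d == 0:
        return states.copy()
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    hit = rng.random(states.shape[0]) < p_diff
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out = states.copy()
    out[hit] = (out[hit] + shift) % 4
    return out


def expected_p_distance(d: float) -> float:
    """Jukes-Cantor expected proportion of differing sites for branch sum d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class ReferenceTrio:
    references: dict[str, CircularReference]  # keys "A", "B", "C"
    alignment: dict[str, str]  # true gapped alignment, same keys

    def __iter__(self):
        return iter(self.references.values())


def generate_reference_trio(model: TrioModel) -> ReferenceTrio:
    """Simulate three circular references related as ((A,B),C).

    Substitutions follow Jukes-Cantor along the four branches; the listed
    indel events are applied to the stated lineage inside the stated region.
    Returns the references together with the true gapped alignment.
    """
    rng = np.random.default_rng(model.seed)
    L = model.genome_length
    root = rng.integers(0, 4, size=L).astype(np.uint8)

    ab = _jc_substitute(root, model.root_to_ab, rng)
    leaves = {
        "A": _jc_substitute(ab, model.ab_to_a, rng),
        "B": _jc_substitute(ab, model.ab_to_b, rng),
        "C": _jc_substitute(root, model.root_to_c, rng),
    }

    # Column-based representation for the true alignment: start from the
    # ancestral L columns, then apply indels as gap/insert columns.
    cols = {k: [BASES[s] for s in leaves[k]] for k in leaves}
    # per-leaf membership of named branches
    branch_leaves = {"a": {"A"}, "b": {"B"}, "c": {"C"}, "ab": {"A", "B"}}

    # ancestral-column index -> current column index offset bookkeeping:
    # we apply indels sequentially on the current column lists.
    def region_span(n_cols: int) -> tuple[int, int]:
        # Control region / coding spans in *current* column coordinates,
        # taken proportionally; adequate because indels are few and small.
        s = int(round(n_cols * (1.0 - model.control_region_fraction)))
        return s, n_cols

    for ev in model.indel_events:
        n_cols = len(cols["A"])
        if ev.region == "control_region":
            lo, hi = region_span(n_cols)
        else:
            lo, hi = 0, region_span(n_cols)[0]
        if hi - lo < ev.length + 1:
            raise ValueError(
                f"indel of length {ev.length} does not fit in region "
                f"{ev.region} ({hi - lo} columns)"
            )
        affected = branch_leaves[ev.branch]
        if ev.kind == "insertion":
            pos = int(rng.integers(lo, hi))
            block = [BASES[i] for i in rng.integers(0, 4, size=ev.length)]
            for k in cols:
                ins = block if k in affected else ["-"] * ev.length
                cols[k] = cols[k][:pos] + list(ins) + cols[k][pos:]
        else:  # deletion: affected lineages lose a span present in the rest
            pos = int(rng.integers(lo, hi - ev.length))
            for k in cols:
                if k in affected:
                    for j in range(pos, pos + ev.length):
                        cols[k][j] = "-"

    alignment = {k: "".join(v) for k, v in cols.items()}
    refs = {}
    for k, aln in alignment.items():
        seq = aln.replace("-", "")
        n = len(seq)
        s = int(round(n * (1.0 - model.control_region_fraction)))
        refs[k] = CircularReference(
            id=k, sequence=seq, control_region=(s, n), anchor=0
        )
    return ReferenceTrio(references=refs, alignment=alignment)


# ---------------------------------------------------------------------------
# within-species haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    haplotype_id: str
    position: int
    ref_base: str
    alt_base: str


def sample_haplotypes(
    ref: CircularReference,
    n: int,
    mutations_per_haplotype: int,
    seed: int = 0,
) -> tuple[dict[str, str], list[Variant]]:
    """Draw ``n`` haplotypes, each differing from ``ref`` at exactly
    ``mutations_per_haplotype`` random substitution sites.

    Returns the haplotypes (id -> sequence) and the exact variant list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    L = len(ref)
    if mutations_per_haplotype > L:
        raise ValueError("more mutations than genome positions")
    rng = np.random.default_rng(seed)
    haplotypes: dict[str, str] = {}
    variants: list[Variant] = []
    for i in range(n):
        hap_id = f"{ref.id}_hap{i}"
        positions = rng.choice(L, size=mutations_per_haplotype, replace=False)
        seq = list(ref.sequence)
        for pos in sorted(int(p) for p in positions):
            old = seq[pos]
            alt = BASES[(_BASE_TO_INT[old] + int(rng.integers(1, 4))) % 4]
            seq[pos] = alt
            variants.append(Variant(hap_id, pos, old, alt))
        haplotypes[hap_id] = "".join(seq)
    return haplotypes, variants


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _apply_deamination(frag: list[str], rate: float, decay: float,
                       rng: np.random.Generator) -> None:
    """5' C->T damage: probability ``rate`` at the terminal base, decaying
    geometrically (factor ``decay``) into the fragment."""
    p = rate
    for i in range(len(frag)):
        if p < 1e-9:
            break
        if frag[i] == "C" and rng.random() < p:
            frag[i] = "T"
        p *= decay


def simulate_reads(
    haplotype: str,
    params: ReadSimParams,
    haplotype_id: str = "hap",
    read_prefix: str | None = None,
) -> SimulatedReads:
    """Simulate single-end reads from one circular haplotype.

    Fragments are drawn uniformly on the circle (wraparound allowed) with
    truncated-lognormal lengths; the read is the first ``read_length`` bases
    of the fragment strand, with adapter read-through when the fragment is
    shorter.  Deamination and flat sequencing error are applied after
    truncation; duplicates are byte-identical re-emissions; exogenous reads
    are i.i.d. random sequence added at rate 1 - endogenous_fraction.
    """
    rng = np.random.default_rng(params.seed)
    L = len(haplotype)
    doubled = haplotype + haplotype
    prefix = read_prefix if read_prefix is not None else haplotype_id
    qual = chr(33 + params.base_quality) * params.read_length

    reads: list[tuple[str, str, str]] = []
    truth: list[TruthRecord] = []
    target_bases = params.mean_depth * L

    # draw fragment lengths until the depth target is met, then place them:
    # uniform mode scatters starts i.i.d. on the circle; systematic mode
    # stratifies them (one jittered start per equal arc), which evens out
    # coverage for deep-coverage reconstructions
    flens: list[int] = []
    total = 0.0
    while total < target_bases:
        flen = int(round(float(rng.lognormal(params.fragment_mean_log,
                                             params.fragment_sd_log))))
        flen = min(max(flen, params.fragment_min), min(params.fragment_max, L))
        flens.append(flen)
        total += min(flen, params.read_length)
    n_frag = len(flens)
    if params.start_mode == "systematic":
        jitter = rng.random(n_frag)
        starts = [int((i + u) * L / n_frag) % L
                  for i, u in enumerate(jitter)]
    else:
        starts = [int(s) for s in rng.integers(0, L, size=n_frag)]

    idx = 0
    for flen, start in zip(flens, starts):
        strand = "+" if rng.random() < 0.5 else "-"
        frag = doubled[start : start + flen]
        if strand == "-":
            frag = revcomp(frag)
        frag_list = list(frag)
        if params.deamination_rate > 0:
            _apply_deamination(frag_list, params.deamination_rate,
                               params.deamination_decay, rng)
        if flen >= params.read_length:
            read = frag_list[: params.read_length]
        else:
            read = frag_list + list(params.adapter)
            read = read[: params.read_length]
        if params.error_rate > 0:
            err = rng.random(len(read)) < params.error_rate
            for j in np.nonzero(err)[0]:
                read[j] = BASES[(_BASE_TO_INT.get(read[j], 0)
                                 + int(rng.integers(1, 4))) % 4]
        bases = "".join(read)
        rid = f"{prefix}:{idx}"
        reads.append((rid, bases, qual[: len(bases)]))
        truth.append(TruthRecord(rid, haplotype_id, start, start + flen,
                                 strand, False, False))
        idx += 1
        if params.duplicate_rate > 0 and rng.random() < params.duplicate_rate:
            dup_id = f"{prefix}:{idx}"
            reads.append((dup_id, bases, qual[: len(bases)]))
            truth.append(TruthRecord(dup_id, haplotype_id, start, start + flen,
                                     strand, True, False))
            idx += 1

    if params.endogenous_fraction < 1.0:
        n_endo = len(reads)
        f = params.endogenous_fraction
        n_exo = int(round(n_endo * (1.0 - f) / f)) if f > 0 else 0
        for _ in range(n_exo):
            bases = "".join(BASES[i] for i in rng.integers(0, 4,
                                                           size=params.read_length))
            rid = f"{prefix}:{idx}"
            reads.append((rid, bases, qual))
            truth.append(TruthRecord(rid, "exogenous", -1, -1, ".",
                                     False, True))
            idx += 1
    return SimulatedReads(reads=reads, truth=truth)


# ---------------------------------------------------------------------------
# capture probe tiling
# ---------------------------------------------------------------------------


def design_tiling_probes(
    ref: CircularReference,
    probe_len: int = 60,
    tile: int = 3,
    wrap_extension: int = 59,
) -> list[tuple[int, str]]:
    """Tile ``probe_len``-mer capture probes at ``tile``-bp steps.

    The first ``wrap_extension`` bases of the circular genome are appended
    to its end before tiling so the linearization point is not
    under-represented; with wrap_extension = probe_len - 1 every position of
    the circle is covered.  Returns (start, probe sequence) pairs.
    """
    if not (1 <= tile <= probe_len):
        raise ValueError("need probe_len >= tile >= 1")
    if wrap_extension < 0:
        raise ValueError("wrap_extension must be >= 0")
    seq = ref.sequence + ref.sequence[:wrap_extension]
    if len(seq) < probe_len:
        raise ValueError("sequence shorter than probe length")
    return [(s, seq[s : s + probe_len])
            for s in range(0, len(seq) - probe_len + 1, tile)]


# ---------------------------------------------------------------------------
# convenience: a whole simulated study
# ---------------------------------------------------------------------------


def default_study_trio(genome_length: int = 16_500, seed: int = 0,
                       insertion_length: int = 78) -> TrioModel:
    """Trio model emulating the study panel: sister species A and B at ~3%
    divergence, C at ~8%, with a B-specific control-region insertion
    (78 bp by default, mirroring the sable-specific control-region block)."""
    return TrioModel(
        genome_length=genome_length,
        ab_to_a=0.015,
        ab_to_b=0.015,
        root_to_ab=0.025,
        root_to_c=0.04,
        indel_events=(IndelEvent("b", "control_region", insertion_length,
                                 "insertion"),),
        seed=seed,
    )


def with_seed(params: ReadSimParams, seed: int) -> ReadSimParams:
    return replace(params, seed=seed)


def uniform_coverage_params(mean_depth: float = 5.0, seed: int = 0,
                            **overrides) -> ReadSimParams:
    """Parameters for the uniform-coverage regime: stratified fragment
    starts and fragment lengths tightly around the read length, so that
    realized per-position depth stays at or above the consensus minimum
    whenever mean_depth comfortably exceeds it.  Used for exact-recovery
    reconstructions; the plain defaults model scattered aDNA coverage."""
    return ReadSimParams(mean_depth=mean_depth, start_mode="systematic",
                         fragment_mean_log=4.32, fragment_sd_log=0.05,
                         seed=seed, **overrides)
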