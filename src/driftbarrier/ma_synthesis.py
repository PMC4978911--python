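"""Synthetic mutation-accumulation (MA) experiments and population samples.

Generators with the statistical structure the downstream estimators assume:

* an MA experiment is a set of independently bottlenecked lines descending
  from one founder; per line, mutation counts accrue as Poisson with mean
  ``u * n * T`` (rate x sites x generations), sites drawn uniformly, since
  single-organism bottlenecking makes selection negligible;
* sequencing is summarised per line and per site as eight read counts
  (forward/reverse for A,C,G,T) with Poisson coverage (~100x in the studies
  emulated), an even strand split in expectation, and independent per-read
  errors to a uniform other base;
* indels are reported by two emulated aligners as per-base gap calls, with
  optional positional jitter and aligner-specific false calls, so the
  dual-callset concordance filter has something to do;
* population allele samples come from a standard neutral (Kingman)
  coalescent with infinite-sites mutation, supporting Watterson's theta and
  pairwise heterozygosity;
* transfer logs are lognormally scattered viable-colony cell counts used to
  estimate generations per transfer.

All generators are deterministic per seed, and every experiment retains its
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus_calling import (
    BASES,
    DELETION,
    INSERTION,
    SUBSTITUTION,
    MutationEvent,
    RawIndelCall,
)

__all__ = [
    "ReferenceGenome",
    "MALine",
    "MAExperiment",
    "PopulationSample",
    "default_indel_size_dist",
    "simulate_reference",
    "simulate_ma_experiment",
    "simulate_site_counts",
    "simulate_population_sample",
    "simulate_transfer_log",
    "line_true_bases",
]


@dataclass
class ReferenceGenome:
    """A reference sequence over {A,C,G,T}."""

    sequence: str
    label: str = "chr1"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("reference length must be >= 1")
        if set(self.sequence) - set(BASES):
            raise ValueError("reference alphabet restricted to A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)

    def base_codes(self) -> np.ndarray:
        """Sequence as int8 codes (A=0, C=1, G=2, T=3)."""
        lut = np.full(128, -1, dtype=np.int8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        return lut[np.frombuffer(self.sequence.encode(), dtype=np.uint8)]


@dataclass
class MALine:
    """One MA line: ground-truth events plus emulated sequencing output."""

    line_id: str
    true_events: list[MutationEvent] = field(default_factory=list)
    site_counts: np.ndarray | None = None  # (n_sites, 8) A,a,C,c,G,g,T,t
    indel_callsets: tuple[list[RawIndelCall], list[RawIndelCall]] = field(
        default_factory=lambda: ([], [])
    )


@dataclass
class MAExperiment:
    """A set of MA lines with shared reference, generations, and truth."""

    reference: ReferenceGenome
    lines: list[MALine]
    T: float
    true_u_bs: float
    true_u_id: float
    seed: int
    # ancestral variants present in several lines (not mutations; used to
    # exercise the shared-variant screen of the caller)
    shared_variants: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class PopulationSample:
    """Alleles x segregating-sites 0/1 matrix from L surveyed silent sites."""

    n_alleles: int
    L: int
    genotypes: np.ndarray  # (n_alleles, S) 0 = ancestral, 1 = derived
    true_theta: float

    def __post_init__(self) -> None:
        if self.n_alleles < 2:
            raise ValueError("need at least 2 alleles")
        g = np.asarray(self.genotypes)
        if g.size and (g.min(initial=1) < 0 or g.max(initial=0) > 1):
            raise ValueError("genotypes must be 0/1")

    @property
    def n_segregating(self) -> int:
        return int(self.genotypes.shape[1])


# ---------------------------------------------------------------------------
# reference and MA experiment

def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> ReferenceGenome:
    """I.i.d. random reference with the given expected GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs)
    seq = "".join(BASES[c] for c in codes)
    return ReferenceGenome(sequence=seq)


def default_indel_size_dist() -> list[tuple[int, float]]:
    """Stylized signed indel-length distribution.

    85% short events (1-9 bp, truncated geometric, p=0.5) and 15% large
    (10-200 bp, uniform), mirroring the short/large split observed in
    bacterial MA data; insertions and deletions equiprobable.
    """
    short_p = 0.5
    short_w = np.array([short_p * (1 - short_p) ** (k - 1) for k in range(1, 10)])
    short_w = 0.85 * short_w / short_w.sum()
    large_lengths = list(range(10, 201))
    large_w = 0.15 / len(large_lengths)
    dist: list[tuple[int, float]] = []
    for k, w in zip(range(1, 10), short_w):
        dist.append((k, w / 2))
        dist.append((-k, w / 2))
    for k in large_lengths:
        dist.append((k, large_w / 2))
        dist.append((-k, large_w / 2))
    return dist


def _place_events(
    rng: np.random.Generator,
    n_sites: int,
    line_id: str,
    n_sub: int,
    n_indel: int,
    ref_codes: np.ndarray,
    sizes: np.ndarray,
    size_probs: np.ndarray,
) -> list[MutationEvent]:
    """Uniform placement with rejection of overlaps (events are sparse)."""
    events: list[MutationEvent] = []
    occupied: set[int] = set()

    def free(lo: int, hi: int) -> bool:
        return all(p not in occupied for p in range(lo, hi))

    for _ in range(n_sub):
        for _attempt in range(1000):
            pos = int(rng.integers(0, n_sites))
            if free(pos, pos + 1):
                break
        else:  # pragma: no cover - genome saturated
            raise RuntimeError("could not place substitution without overlap")
        occupied.add(pos)
        ref_b = int(ref_codes[pos])
        alt_b = int((ref_b + rng.integers(1, 4)) % 4)
        events.append(
            MutationEvent(
                line_id=line_id,
                position=pos,
                kind=SUBSTITUTION,
                ref_base=BASES[ref_b],
                alt_base=BASES[alt_b],
            )
        )
    for _ in range(n_indel):
        for _attempt in range(1000):
            signed = int(sizes[rng.choice(len(sizes), p=size_probs)])
            length = abs(signed)
            if signed < 0:
                # deletion occupies [pos, pos+length); avoid position 0 so the
                # truth VCF can left-anchor the record
                if n_sites - length < 1:
                    continue
                pos = int(rng.integers(1, n_sites - length + 1))
                lo, hi = pos, pos + length
                kind = DELETION
            else:
                pos = int(rng.integers(1, n_sites))
                lo, hi = pos, pos + 1
                kind = INSERTION
            if free(lo - 1, hi + 1):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place indel without overlap")
        occupied.update(range(lo, hi))
        events.append(
            MutationEvent(line_id=line_id, position=pos, kind=kind, length=length)
        )
    events.sort(key=lambda e: e.position)
    return events


def _gap_calls_for_events(
    events: Sequence[MutationEvent],
    rng: np.random.Generator,
    n_sites: int,
    jitter: int,
    fp_rate: float,
) -> list[RawIndelCall]:
    """Per-base gap calls one aligner would report for the true indels."""
    calls: list[RawIndelCall] = []
    for e in events:
        if e.kind == SUBSTITUTION:
            continue
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        start = min(max(e.position + shift, 0), n_sites - 1)
        for k in range(e.length):
            calls.append(RawIndelCall(position=start + k, kind=e.kind))
    if fp_rate > 0:
        n_fp = rng.poisson(fp_rate * n_sites)
        truth_spans = {
            p
            for e in events
            if e.kind != SUBSTITUTION
            for p in range(e.position - jitter - 1, e.position + (e.length or 1) + jitter + 1)
        }
        for _ in range(n_fp):
            pos = int(rng.integers(0, n_sites))
            if pos in truth_spans:
                continue
            kind = DELETION if rng.random() < 0.5 else INSERTION
            calls.append(RawIndelCall(position=pos, kind=kind))
    calls.sort()
    return calls


def simulate_ma_experiment(
    ref: ReferenceGenome,
    n_lines: int,
    T: float,
    u_bs: float,
    u_id: float,
    indel_size_dist: Sequence[tuple[int, float]] | None = None,
    seed: int = 0,
    aligner_jitter: int = 1,
    aligner_fp_rate: float = 0.0,
    shared_variant_count: int = 0,
) -> MAExperiment:
    """Simulate an MA experiment with ground truth.

    Per line, the substitution count is Poisson(u_bs * n * T) and the
    indel-event count Poisson(u_id * n * T); sites are uniform and signed
    indel lengths follow ``indel_size_dist`` (default:
    :func:`default_indel_size_dist`).  Mutations are drawn as a single
    Poisson aggregate over n*T rather than per transfer — the estimators
    only see totals.  ``shared_variant_count`` ancestral variants (present
    in every line, absent from the truth) exercise the caller's
    shared-variant screen.  Each line also carries two raw indel callsets
    emulating independent aligners (callset B with positional jitter; both
    with optional aligner-specific false calls).
    """
    if u_bs < 0 or u_id < 0:
        raise ValueError("mutation rates must be non-negative")
    if n_lines < 1:
        raise ValueError("need at least one line")
    if T <= 0:
        raise ValueError("T must be positive")
    dist = list(indel_size_dist) if indel_size_dist is not None else default_indel_size_dist()
    if not dist:
        raise ValueError("indel size distribution must be non-empty")
    sizes = np.array([s for s, _ in dist], dtype=np.int64)
    if (sizes == 0).any():
        raise ValueError("signed indel lengths must be non-zero")
    probs = np.array([p for _, p in dist], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("invalid indel size probabilities")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    n = len(ref)
    ref_codes = ref.base_codes()

    shared: list[tuple[int, str]] = []
    for _ in range(shared_variant_count):
        pos = int(rng.integers(0, n))
        alt = BASES[int((ref_codes[pos] + rng.integers(1, 4)) % 4)]
        shared.append((pos, alt))

    lines: list[MALine] = []
    width = len(str(n_lines))
    for i in range(n_lines):
        line_id = f"L{i + 1:0{width}d}"
        n_sub = int(rng.poisson(u_bs * n * T))
        n_indel = int(rng.poisson(u_id * n * T))
        events = _place_events(
            rng, n, line_id, n_sub, n_indel, ref_codes, sizes, probs
        )
        indels = [e for e in events if e.kind != SUBSTITUTION]
        callset_a = _gap_calls_for_events(indels, rng, n, jitter=0, fp_rate=aligner_fp_rate)
        callset_b = _gap_calls_for_events(
            indels, rng, n, jitter=aligner_jitter, fp_rate=aligner_fp_rate
        )
        lines.append(
            MALine(line_id=line_id, true_events=events, indel_callsets=(callset_a, callset_b))
        )
    return MAExperiment(
        reference=ref,
        lines=lines,
        T=T,
        true_u_bs=u_bs,
        true_u_id=u_id,
        seed=seed,
        shared_variants=shared,
    )


def line_true_bases(
    line: MALine,
    ref: ReferenceGenome,
    shared_variants: Sequence[tuple[int, str]] = (),
) -> np.ndarray:
    """The line's true base code at every reference site.

    Reference, overlaid with shared ancestral variants and the line's fixed
    substitutions.  Indels do not alter per-site base identity here: site
    counts emulate the substitution channel only, while indels are observed
    through the aligner gap callsets.
    """
    codes = ref.base_codes().copy()
    lut = {b: i for i, b in enumerate(BASES)}
    for pos, alt in shared_variants:
        codes[pos] = lut[alt]
    for e in line.true_events:
        if e.kind == SUBSTITUTION:
            codes[e.position] = lut[e.alt_base]
    return codes


def simulate_site_counts(
    line: MALine,
    ref: ReferenceGenome,
    mean_coverage: float = 100.0,
    error_rate: float = 1e-3,
    seed: int = 0,
    shared_variants: Sequence[tuple[int, str]] = (),
) -> np.ndarray:
    """Emulate per-site read-count configurations for one line.

    Coverage per site is Poisson(``mean_coverage``) split binomially between
    strands; each read reports the line's true base with probability
    ``1 - error_rate``, otherwise a uniformly chosen other base.  Returns an
    ``(n_sites, 8)`` uint16 array (A,a,C,c,G,g,T,t) and stores it on the
    line.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(ref)
    tb = line_true_bases(line, ref, shared_variants).astype(np.int64)

    cov = rng.poisson(mean_coverage, size=n)
    fwd = rng.binomial(cov, 0.5)
    rev = cov - fwd
    err_f = rng.binomial(fwd, error_rate) if error_rate > 0 else np.zeros(n, dtype=np.int64)
    err_r = rng.binomial(rev, error_rate) if error_rate > 0 else np.zeros(n, dtype=np.int64)

    counts = np.zeros((n, 8), dtype=np.int64)
    idx = np.arange(n)
    counts[idx, 2 * tb] = fwd - err_f
    counts[idx, 2 * tb + 1] = rev - err_r
    if error_rate > 0:
        # distribute error reads uniformly over the three other bases
        ef3 = rng.multinomial(err_f, [1 / 3] * 3)
        er3 = rng.multinomial(err_r, [1 / 3] * 3)
        for k in range(1, 4):
            other = (tb + k) % 4
            np.add.at(counts, (idx, 2 * other), ef3[:, k - 1])
            np.add.at(counts, (idx, 2 * other + 1), er3[:, k - 1])
    counts = counts.astype(np.uint16)
    line.site_counts = counts
    return counts


# ---------------------------------------------------------------------------
# neutral coalescent population sample

def simulate_population_sample(
    n_alleles: int, L: int, theta: float, seed: int = 0
) -> PopulationSample:
    """Sample alleles under the standard neutral coalescent, infinite sites.

    Coalescence times for k lineages are exponential with rate k(k-1)/2 (in
    units of 2N generations for haploids / 4N for diploids); mutations fall
    on branches as Poisson with rate ``theta * L / 2`` per unit coalescent
    time, each creating one segregating 0/1 column.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    mut_rate = theta * L / 2.0

    # active lineages: boolean leaf masks and accumulated branch time
    masks = [np.zeros(n_alleles, dtype=bool) for _ in range(n_alleles)]
    for i in range(n_alleles):
        masks[i][i] = True
    elapsed = [0.0] * n_alleles
    columns: list[np.ndarray] = []

    k = n_alleles
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for i in range(k):
            elapsed[i] += t
        i, j = sorted(rng.choice(k, size=2, replace=False))
        for idx in (i, j):
            n_mut = rng.poisson(mut_rate * elapsed[idx]) if mut_rate > 0 else 0
            for _ in range(n_mut):
                columns.append(masks[idx].copy())
        merged = masks[i] | masks[j]
        # replace i with merged lineage, drop j
        masks[i] = merged
        elapsed[i] = 0.0
        del masks[j], elapsed[j]
        k -= 1

    if columns:
        genotypes = np.stack(columns, axis=1).astype(np.int8)
    else:
        genotypes = np.zeros((n_alleles, 0), dtype=np.int8)
    return PopulationSample(
        n_alleles=n_alleles, L=L, genotypes=genotypes, true_theta=theta
    )


# ---------------------------------------------------------------------------
# transfer log

def simulate_transfer_log(
    n_transfers: int,
    mean_colony_cells: float,
    seed: int = 0,
    log2_sd: float = 0.5,
) -> np.ndarray:
    """Viable-colony cell counts, lognormally scattered per transfer.

    ``log2(count)`` is Normal(log2(mean_colony_cells), log2_sd), so the
    geometric mean — which is what the divisions-per-transfer estimate
    uses — equals ``mean_colony_cells``.  ``log2_sd = 0`` gives a noiseless
    log.
    """
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    if mean_colony_cells <= 0:
        raise ValueError("mean_colony_cells must be positive")
    rng = np.random.default_rng(seed)
    logs = math.log2(mean_colony_cells) + rng.normal(0.0, log2_sd, size=n_transfers)
    return np.exp2(logs)
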