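"""Consensus mutation calling from per-site read-count configurations.

Mutation-accumulation (MA) lines are sequenced to high depth and summarised,
per line and per genomic site, as eight read counts (forward/reverse for each
of A, C, G, T).  A base substitution is called for a line when its consensus
base at a site differs from the consensus shared by the other MA lines, and
the variant is not shared by more than a configurable number of lines
(shared variants are treated as putative ancestral polymorphisms or
systematic false calls and excluded from the mutation count).

Indels are handled as *events*: per-base gap calls emitted by an aligner are
merged into maximal contiguous runs, and only events reported concordantly
by two independent aligners (within a small positional slop) are retained.
Counting events rather than affected base pairs reflects that a 1-bp and a
50-bp frameshift are comparably disruptive to a coding region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: indel events strictly longer than this many bp are classed "large"
LARGE_INDEL_THRESHOLD = 9

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
_KINDS = (SUBSTITUTION, INSERTION, DELETION)


class IndelConflictError(ValueError):
    """Contradictory (insertion and deletion) gap calls at one position."""


@dataclass(frozen=True)
class MutationEvent:
    """A single called or simulated mutation.

    ``position`` is 0-based on the reference.  Substitutions carry
    ``ref_base``/``alt_base`` and no length; indel events carry a positive
    ``length`` in bp (deletions occupy ``[position, position + length)``).
    """

    line_id: str
    position: int
    kind: str
    ref_base: str | None = None
    alt_base: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown mutation kind: {self.kind!r}")
        if self.position < 0:
            raise ValueError("position must be non-negative")
        if self.kind == SUBSTITUTION:
            if self.length is not None:
                raise ValueError("substitutions carry no length")
        else:
            if self.length is None or self.length < 1:
                raise ValueError("indel events require length >= 1")

    @property
    def size_class(self) -> str | None:
        """``short``/``large`` for indels (large iff length > 9 bp)."""
        if self.kind == SUBSTITUTION:
            return None
        return "large" if self.length > LARGE_INDEL_THRESHOLD else "short"


class RawIndelCall(NamedTuple):
    """A per-base gap call from one aligner, before event merging."""

    position: int
    kind: str  # insertion | deletion
    length: int = 1


@dataclass
class CallingConfig:
    """Thresholds of the consensus caller.

    ``min_consensus_fraction`` must exceed 0.5 so at most one base can be
    consensus; ``max_lines_sharing`` caps how many lines may carry an
    identical variant before it is flagged as shared (ancestral/false).
    """

    min_coverage: int = 10
    min_consensus_fraction: float = 0.8
    min_forward: int = 2
    min_reverse: int = 2
    max_lines_sharing: int = 1

    def __post_init__(self) -> None:
        if not 0.5 < self.min_consensus_fraction <= 1.0:
            raise ValueError("min_consensus_fraction must be in (0.5, 1]")
        if self.min_coverage < 0 or self.min_forward < 0 or self.min_reverse < 0:
            raise ValueError("count thresholds must be non-negative")


class SharedVariant(NamedTuple):
    """A variant carried by more lines than ``max_lines_sharing`` allows."""

    position: int
    base: str
    line_ids: tuple[str, ...]


@dataclass
class SubstitutionCalls:
    """Result of cross-line substitution calling."""

    events: list[MutationEvent]
    shared: list[SharedVariant] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-site consensus

def consensus_matrix(counts: np.ndarray, cfg: CallingConfig) -> np.ndarray:
    """Vector consensus over an ``(n_sites, 8)`` count array.

    Columns are ordered A,a,C,c,G,g,T,t (capital = forward strand).  Returns
    an int8 array with the consensus base index (0..3) or -1 for no-call.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != 8:
        raise ValueError("counts must have shape (n_sites, 8)")
    fwd = counts[:, 0::2].astype(np.int64)
    rev = counts[:, 1::2].astype(np.int64)
    pooled = fwd + rev
    total = pooled.sum(axis=1)
    best = np.argmax(pooled, axis=1)
    idx = np.arange(counts.shape[0])
    best_pooled = pooled[idx, best]
    ok = (
        (total >= cfg.min_coverage)
        & (total > 0)
        & (best_pooled >= cfg.min_consensus_fraction * total)
        & (fwd[idx, best] >= cfg.min_forward)
        & (rev[idx, best] >= cfg.min_reverse)
    )
    out = np.where(ok, best, -1).astype(np.int8)
    return out


def consensus_base(counts: Sequence[int], cfg: CallingConfig | None = None) -> str | None:
    """Consensus base for a single eight-number count configuration.

    Returns one of ``"A"/"C"/"G"/"T"`` or ``None`` (no-call) when coverage,
    consensus fraction, or per-strand support fall below the thresholds.
    """
    cfg = cfg or CallingConfig()
    arr = np.asarray(counts, dtype=np.int64).reshape(1, 8)
    if (arr < 0).any():
        raise ValueError("read counts must be non-negative")
    code = consensus_matrix(arr, cfg)[0]
    return None if code < 0 else BASES[code]


def callable_sites(
    counts_by_line: Mapping[str, np.ndarray], cfg: CallingConfig | None = None
) -> dict[str, int]:
    """Number of sites per line passing the consensus thresholds.

    This is the denominator *n* ("number of nucleotide sites analyzed") of
    the per-line mutation-rate estimate.
    """
    cfg = cfg or CallingConfig()
    return {
        line_id: int((consensus_matrix(counts, cfg) >= 0).sum())
        for line_id, counts in counts_by_line.items()
    }


# ---------------------------------------------------------------------------
# cross-line substitution calling

def call_line_substitutions(
    counts_by_line: Mapping[str, np.ndarray],
    cfg: CallingConfig | None = None,
) -> SubstitutionCalls:
    """Call substitutions for every line against the other lines' consensus.

    A substitution is called for line *i* at a site when line *i* has a
    consensus base, the other lines share a (majority) consensus base, the
    two differ, and no more than ``cfg.max_lines_sharing`` lines carry the
    identical variant.  Variants shared by more lines are reported in
    ``shared`` and excluded from the events (the across-line frequency
    screen for ancestral polymorphism and systematic artefacts).

    Results are invariant to the ordering of lines; events are returned
    sorted by (position, line_id).
    """
    cfg = cfg or CallingConfig()
    if len(counts_by_line) < 2:
        raise ValueError("substitution calling requires at least 2 lines")
    line_ids = sorted(counts_by_line)
    cons = np.vstack(
        [consensus_matrix(counts_by_line[lid], cfg) for lid in line_ids]
    )  # (L, n)
    n_lines, n_sites = cons.shape
    if any(counts_by_line[lid].shape[0] != n_sites for lid in line_ids):
        raise ValueError("all lines must cover the same number of sites")

    # candidate sites: any two callable lines disagree
    base_counts = np.zeros((4, n_sites), dtype=np.int32)
    for b in range(4):
        base_counts[b] = (cons == b).sum(axis=0)
    n_callable = base_counts.sum(axis=0)
    top = base_counts.max(axis=0)
    cand = np.flatnonzero((n_callable >= 2) & (top < n_callable))

    events: list[MutationEvent] = []
    shared: dict[tuple[int, int], list[str]] = {}
    for s in cand:
        col = cons[:, s]
        for i, lid in enumerate(line_ids):
            b = col[i]
            if b < 0:
                continue
            others = col[(np.arange(n_lines) != i) & (col >= 0)]
            if others.size == 0:
                continue
            oc = np.bincount(others, minlength=4)
            maj = int(np.argmax(oc))
            # if the line's own base ties for the others' majority the site is
            # ambiguous rather than mutant: no call
            if b == maj or oc[b] == oc[maj]:
                continue
            carriers = int((col == b).sum())
            if carriers <= cfg.max_lines_sharing:
                events.append(
                    MutationEvent(
                        line_id=lid,
                        position=int(s),
                        kind=SUBSTITUTION,
                        ref_base=BASES[maj],
                        alt_base=BASES[int(b)],
                    )
                )
            else:
                shared.setdefault((int(s), int(b)), []).append(lid)
    events.sort(key=lambda e: (e.position, e.line_id))
    shared_list = [
        SharedVariant(pos, BASES[b], tuple(sorted(lids)))
        for (pos, b), lids in sorted(shared.items())
    ]
    return SubstitutionCalls(events=events, shared=shared_list)


# ---------------------------------------------------------------------------
# indel event handling

def _as_gap_tuples(calls: Iterable) -> list[tuple[int, str, int]]:
    out = []
    for c in calls:
        if isinstance(c, MutationEvent):
            if c.kind == SUBSTITUTION:
                raise ValueError("substitutions are not gap calls")
            out.append((c.position, c.kind, int(c.length)))
        else:
            pos, kind = c[0], c[1]
            length = c[2] if len(c) > 2 else 1
            if kind not in (INSERTION, DELETION):
                raise ValueError(f"unknown gap kind: {kind!r}")
            out.append((int(pos), kind, int(length)))
    return out


def merge_indel_events(
    raw_calls: Iterable, line_id: str = ""
) -> list[MutationEvent]:
    """Merge contiguous same-kind gap calls into indel events.

    Maximal runs of adjacent positions with the same sign become one event
    whose length is the summed gap length.  The operation is idempotent:
    merged events are separated by construction, so re-merging them is a
    no-op.  Contradictory calls (insertion and deletion covering the same
    position) raise :class:`IndelConflictError`.
    """
    calls = sorted(_as_gap_tuples(raw_calls))
    # conflict check: overlapping opposite-sign spans
    occupied: dict[int, str] = {}
    for pos, kind, length in calls:
        for p in range(pos, pos + length):
            prev = occupied.get(p)
            if prev is not None and prev != kind:
                raise IndelConflictError(f"conflicting gap calls at position {p}")
            occupied[p] = kind
    events: list[MutationEvent] = []
    cur: list[int | str] | None = None  # [start, kind, length]
    for pos, kind, length in calls:
        if cur is not None and kind == cur[1] and pos <= cur[0] + cur[2]:
            # adjacent or duplicated run of the same sign: extend
            cur[2] = max(cur[2], pos + length - cur[0])
        else:
            if cur is not None:
                events.append(
                    MutationEvent(line_id=line_id, position=cur[0], kind=cur[1], length=cur[2])
                )
            cur = [pos, kind, length]
    if cur is not None:
        events.append(
            MutationEvent(line_id=line_id, position=cur[0], kind=cur[1], length=cur[2])
        )
    return events


def intersect_indel_callsets(
    callset_a: Sequence[MutationEvent],
    callset_b: Sequence[MutationEvent],
    position_slop: int = 3,
) -> list[MutationEvent]:
    """Events supported by both aligners' callsets.

    An event from callset A is retained when callset B contains an unused
    event of the same kind within ``position_slop`` bp; short events (<= 9
    bp) must additionally match in length exactly.  The A-side coordinates
    are kept.  Greedy nearest-position matching; each B event matches at
    most once.
    """
    used = [False] * len(callset_b)
    b_sorted = sorted(range(len(callset_b)), key=lambda j: callset_b[j].position)
    kept: list[MutationEvent] = []
    for a in sorted(callset_a, key=lambda e: e.position):
        best_j, best_d = None, None
        for j in b_sorted:
            if used[j]:
                continue
            b = callset_b[j]
            if b.kind != a.kind:
                continue
            d = abs(b.position - a.position)
            if d > position_slop:
                continue
            if a.size_class == "short" or b.size_class == "short":
                if a.length != b.length:
                    continue
            if best_d is None or d < best_d:
                best_j, best_d = j, d
        if best_j is not None:
            used[best_j] = True
            kept.append(a)
    return kept


def call_line_indels(
    raw_callset_a: Iterable,
    raw_callset_b: Iterable,
    line_id: str = "",
    position_slop: int = 3,
) -> list[MutationEvent]:
    """Merge both aligners' gap calls into events, then intersect them."""
    a = merge_indel_events(raw_callset_a, line_id=line_id)
    b = merge_indel_events(raw_callset_b, line_id=line_id)
    return intersect_indel_callsets(a, b, position_slop=position_slop)
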