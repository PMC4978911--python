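"""Mutation-rate estimation from called mutations and generation counts.

Per line, the rate is u = m / (n T): m observed mutations, n callable
nucleotide sites, T generations of accumulation, with the Poisson-based
per-line standard error sqrt(u / (n T)).  The pooled rate over lines is the
unweighted mean of per-line rates with SE_pooled = s / sqrt(N), s the SD of
the per-line rates and N the number of lines.  The identical machinery
serves the base-substitution rate (m = substitution count) and the indel
rate (m = number of merged indel *events*, irrespective of their lengths).

Generations are estimated from transfer logs: divisions per transfer is the
mean of log2(viable colony cell count), and T is divisions per transfer
times the number of transfers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus_calling import SUBSTITUTION, MutationEvent

__all__ = [
    "LineRate",
    "PooledRate",
    "GenerationEstimate",
    "line_rate",
    "pooled_rate",
    "generations_from_colonies",
    "split_rates",
    "rates_by_line",
]


@dataclass
class LineRate:
    line_id: str
    m: int
    n: int
    T: float
    u: float
    se: float


@dataclass
class PooledRate:
    mean_u: float
    sd_across_lines: float
    n_lines: int
    se_pooled: float


@dataclass
class GenerationEstimate:
    divisions_per_transfer: float
    n_transfers: int
    T: float


def line_rate(m: int, n: int, T: float, line_id: str = "") -> LineRate:
    """Per-line rate u = m/(nT) with SE sqrt(u/(nT))."""
    if n <= 0:
        raise ValueError("n (callable sites) must be positive")
    if T <= 0:
        raise ValueError("T (generations) must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    u = m / (n * T)
    se = math.sqrt(u / (n * T))
    return LineRate(line_id=line_id, m=m, n=n, T=T, u=u, se=se)


def pooled_rate(rates: Sequence[LineRate]) -> PooledRate:
    """Unweighted mean of per-line rates; SE = SD across lines / sqrt(N)."""
    if len(rates) < 2:
        raise ValueError("pooling requires at least 2 lines")
    us = np.array([r.u for r in rates], dtype=float)
    s = float(np.std(us, ddof=1))
    return PooledRate(
        mean_u=float(us.mean()),
        sd_across_lines=s,
        n_lines=len(rates),
        se_pooled=s / math.sqrt(len(rates)),
    )


def generations_from_colonies(
    cell_counts: Sequence[float], n_transfers: int
) -> GenerationEstimate:
    """T = mean(log2 cells per colony) x number of transfers."""
    counts = np.asarray(cell_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("cell_counts must be non-empty")
    if (counts < 1).any():
        raise ValueError("colony cell counts must be >= 1")
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    divisions = float(np.mean(np.log2(counts)))
    return GenerationEstimate(
        divisions_per_transfer=divisions,
        n_transfers=n_transfers,
        T=divisions * n_transfers,
    )


def split_rates(
    events: Iterable[MutationEvent], n: int, T: float, line_id: str = ""
) -> tuple[LineRate, LineRate]:
    """(u_bs, u_id) from one line's classified events.

    The indel m counts merged *events* (a 50-bp deletion contributes one),
    never affected base pairs.
    """
    m_bs = m_id = 0
    for e in events:
        if e.kind == SUBSTITUTION:
            m_bs += 1
        elif e.kind in ("insertion", "deletion"):
            m_id += 1
        else:  # pragma: no cover - MutationEvent validates kinds
            raise ValueError(f"unclassified event kind: {e.kind!r}")
    return (
        line_rate(m_bs, n, T, line_id=line_id),
        line_rate(m_id, n, T, line_id=line_id),
    )


def rates_by_line(
    events_by_line: Mapping[str, Sequence[MutationEvent]],
    callable_by_line: Mapping[str, int],
    T: float | Mapping[str, float],
) -> tuple[list[LineRate], list[LineRate], PooledRate, PooledRate]:
    """Per-line and pooled (u_bs, u_id) across an experiment.

    ``T`` may be shared or per-line.  Lines with zero callable sites are
    dropped with a warning rather than propagating NaN.
    """
    bs: list[LineRate] = []
    idl: list[LineRate] = []
    for line_id in sorted(callable_by_line):
        n = callable_by_line[line_id]
        if n <= 0:
            warnings.warn(f"line {line_id} has no callable sites; dropped")
            continue
        t = T[line_id] if isinstance(T, Mapping) else T
        r_bs, r_id = split_rates(
            events_by_line.get(line_id, ()), n, t, line_id=line_id
        )
        bs.append(r_bs)
        idl.append(r_id)
    return bs, idl, pooled_rate(bs), pooled_rate(idl)
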