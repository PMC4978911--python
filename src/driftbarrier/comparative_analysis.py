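"""Drift-barrier comparative tests across species.

The drift-barrier hypothesis predicts that selection lowers the genome-wide
deleterious mutation rate only until its marginal advantage drops below the
power of drift, ~1/N_e, so the per-generation indel burden u_id * G_e
should decline with effective population size.  This module computes the
burden, fits the log10-log10 ordinary least-squares regressions of burden
on N_e (for G_e and for G_c + G_nc), of u_id on u_bs, and of the
unicellular subset; removes phylogenetic non-independence with
Felsenstein's standardized independent contrasts fitted through the origin;
and solves s * t * delta_u_id * G_e = 1/N_e (1/(2 N_e) in diploids) for the
smallest antimutator effect selection can see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .popgen_diversity import DiversityEstimate

__all__ = [
    "SpeciesRecord",
    "RegressionFit",
    "ContrastSet",
    "BarrierEstimate",
    "mutational_burden",
    "loglog_regression",
    "subset_regression",
    "pic_contrasts",
    "origin_regression",
    "antimutator_threshold",
    "reproduce_paper",
    "load_expected_fits",
    "UNICELLULAR_GROUPS",
]

UNICELLULAR_GROUPS = frozenset({"bacteria", "unicellular_eukaryote"})
_GROUPS = frozenset(
    {"bacteria", "unicellular_eukaryote", "multicellular_eukaryote"}
)


@dataclass
class SpeciesRecord:
    """One species row: rates, genome sizes, diversity, and N_e.

    All quantities in absolute units: sites, per-site per-generation rates,
    individuals.  ``Ge`` is the effective (proteome-approximated) genome
    size; ``Gc_plus_Gnc`` adds constrained noncoding sites.
    """

    name: str
    label: str
    Ge: float
    Gc_plus_Gnc: float
    u_id: float
    u_bs: float
    diversity: DiversityEstimate
    Ne: float
    ploidy: str
    group: str
    ne_flagged: bool = False

    def __post_init__(self) -> None:
        for fname in ("Ge", "Gc_plus_Gnc", "u_id", "u_bs", "Ne"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{self.label}: {fname} must be positive")
        if self.Gc_plus_Gnc < self.Ge:
            raise ValueError(f"{self.label}: Gc_plus_Gnc must be >= Ge")
        if self.group not in _GROUPS:
            raise ValueError(f"{self.label}: unknown group {self.group!r}")


@dataclass
class RegressionFit:
    slope: float
    intercept: float | None
    se_slope: float
    se_intercept: float | None
    r2: float
    p_value: float
    df: int
    n: int


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait on a tree."""

    trait: str
    contrasts: list[tuple[str, float]]  # (internal node id, contrast)
    tree: dendropy.Tree = field(repr=False)

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.contrasts], dtype=float)


@dataclass
class BarrierEstimate:
    label: str
    s_coeff: float
    t_link: float
    delta_u_id: float
    fraction_of_u_id: float


def mutational_burden(rec: SpeciesRecord, genome: str = "Ge") -> float:
    """Indel events per (effective) genome per generation: u_id x G."""
    if genome == "Ge":
        return rec.u_id * rec.Ge
    if genome == "Gc_plus_Gnc":
        return rec.u_id * rec.Gc_plus_Gnc
    raise ValueError("genome must be 'Ge' or 'Gc_plus_Gnc'")


# ---------------------------------------------------------------------------
# regressions

def loglog_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """OLS of log10(y) on log10(x) with SEs and a two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("log-log regression requires positive values")
    res = stats.linregress(np.log10(x), np.log10(y))
    n = x.size
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        df=n - 2,
        n=n,
    )


def subset_regression(
    records: Sequence[SpeciesRecord],
    group_filter: Callable[[SpeciesRecord], bool] | Sequence[str] | None = None,
    response: str = "burden_ge",
) -> RegressionFit:
    """Log-log regression against N_e on a filtered subset of species.

    ``group_filter`` is a predicate or a collection of group names (default:
    all records).  ``response`` selects u_id*Ge (default), u_id*(Gc+Gnc),
    or u_id alone.
    """
    if group_filter is None:
        keep = list(records)
    elif callable(group_filter):
        keep = [r for r in records if group_filter(r)]
    else:
        groups = set(group_filter)
        keep = [r for r in records if r.group in groups]
    if len(keep) < 3:
        raise ValueError("subset must retain >= 3 records")
    resp = {
        "burden_ge": lambda r: mutational_burden(r, "Ge"),
        "burden_gcnc": lambda r: mutational_burden(r, "Gc_plus_Gnc"),
        "u_id": lambda r: r.u_id,
    }
    if response not in resp:
        raise ValueError(f"unknown response {response!r}")
    x = [r.Ne for r in keep]
    y = [resp[response](r) for r in keep]
    return loglog_regression(x, y)


# ---------------------------------------------------------------------------
# phylogenetically independent contrasts

def pic_contrasts(
    tree: dendropy.Tree, trait: Mapping[str, float], trait_name: str = "trait"
) -> ContrastSet:
    """Felsenstein's standardized contrasts on a rooted bifurcating tree.

    At each internal node joining subtrees with values x_i, x_j and
    (adjusted) branch lengths b_i, b_j: contrast = (x_i - x_j) /
    sqrt(b_i + b_j); the node's value is the 1/b-weighted average and its
    parent branch is extended by b_i b_j / (b_i + b_j).  Missing branch
    lengths default to 1.  Contrasts are returned in postorder, so two
    traits computed on the same tree pair up node by node.
    """
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_labels)) != len(leaf_labels):
        raise ValueError("leaf labels must be unique")
    missing = [lb for lb in leaf_labels if lb not in trait]
    if missing:
        raise ValueError(f"missing trait values for: {', '.join(sorted(missing))}")

    node_val: dict[dendropy.Node, float] = {}
    node_bl: dict[dendropy.Node, float] = {}
    contrasts: list[tuple[str, float]] = []
    counter = 0
    for nd in tree.postorder_node_iter():
        edge_len = nd.edge.length if nd.edge.length is not None else 1.0
        if nd.is_leaf():
            node_val[nd] = float(trait[nd.taxon.label])
            node_bl[nd] = edge_len
            continue
        children = nd.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"tree must be bifurcating; node has {len(children)} children"
            )
        c1, c2 = children
        b1, b2 = node_bl[c1], node_bl[c2]
        x1, x2 = node_val[c1], node_val[c2]
        counter += 1
        node_id = nd.label or f"node{counter}"
        contrasts.append((node_id, (x1 - x2) / np.sqrt(b1 + b2)))
        node_val[nd] = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
        parent_edge = edge_len if nd.parent_node is not None else 0.0
        node_bl[nd] = parent_edge + b1 * b2 / (b1 + b2)
    return ContrastSet(trait=trait_name, contrasts=contrasts, tree=tree)


def origin_regression(
    cx: ContrastSet | Sequence[float], cy: ContrastSet | Sequence[float]
) -> RegressionFit:
    """No-intercept least squares of contrasts, df = n - 1.

    Each contrast pair is oriented so the predictor contrast is >= 0 (the
    orientation of a contrast is arbitrary; the through-origin fit is
    invariant to flipping any pair's sign).  Zero predictor contrasts
    contribute nothing to the sums but stay in the df.
    """
    x = cx.values() if isinstance(cx, ContrastSet) else np.asarray(cx, float)
    y = cy.values() if isinstance(cy, ContrastSet) else np.asarray(cy, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired contrasts")
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all predictor contrasts are zero")
    sxy = float(x @ y)
    syy = float(y @ y)
    slope = sxy / sxx
    n = x.size
    df = n - 1
    resid = y - slope * x
    sse = float(resid @ resid)
    se_slope = np.sqrt(sse / (df * sxx)) if df > 0 else np.nan
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 1.0
    if df > 0 and se_slope > 0:
        tval = slope / se_slope
        p = 2 * stats.t.sf(abs(tval), df)
    else:
        p = np.nan
    return RegressionFit(
        slope=slope,
        intercept=None,
        se_slope=float(se_slope),
        se_intercept=None,
        r2=float(r2),
        p_value=float(p),
        df=df,
        n=n,
    )


# ---------------------------------------------------------------------------
# antimutator threshold

def antimutator_threshold(
    rec: SpeciesRecord, s_coeff: float = 0.01, t_link: float = 2.0
) -> BarrierEstimate:
    """Smallest indel-rate reduction selection can promote against drift.

    Solves s * t * delta_u_id * G_e = 1/N_e (haploids; 1/(2 N_e) diploids)
    for delta_u_id.  ``s_coeff`` is the mean fitness cost per mutation and
    ``t_link`` the generations a modifier stays linked to its background.
    """
    if s_coeff <= 0 or t_link <= 0:
        raise ValueError("s_coeff and t_link must be positive")
    drift = 1.0 / rec.Ne if rec.ploidy == "haploid" else 1.0 / (2.0 * rec.Ne)
    delta = drift / (s_coeff * t_link * rec.Ge)
    return BarrierEstimate(
        label=rec.label,
        s_coeff=s_coeff,
        t_link=t_link,
        delta_u_id=delta,
        fraction_of_u_id=delta / rec.u_id,
    )


def plot_burden_vs_ne(
    records: Sequence[SpeciesRecord],
    fit: RegressionFit,
    path: str,
    genome: str = "Ge",
) -> None:
    """Scatter of log10 burden against log10 N_e with the fitted line.

    Colour-codes bacteria / unicellular / multicellular eukaryotes.
    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "bacteria": "tab:blue",
        "unicellular_eukaryote": "black",
        "multicellular_eukaryote": "tab:red",
    }
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, col in colors.items():
        xs = [np.log10(r.Ne) for r in records if r.group == grp]
        ys = [
            np.log10(mutational_burden(r, genome))
            for r in records
            if r.group == grp
        ]
        ax.scatter(xs, ys, c=col, label=grp.replace("_", " "))
    grid = np.linspace(
        min(np.log10(r.Ne) for r in records),
        max(np.log10(r.Ne) for r in records),
        50,
    )
    ax.plot(grid, fit.intercept + fit.slope * grid, "k--", lw=1)
    ax.set_xlabel(r"$\log_{10} N_e$")
    ax.set_ylabel(r"$\log_{10}(u_{id} G)$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# one-shot reproduction driver

def load_expected_fits() -> dict:
    """Packaged expected slopes/intercepts/r2 with their tolerances."""
    with resources.files("driftbarrier.data").joinpath("expected_fits.json").open() as fh:
        return json.load(fh)


def _fit_row(name: str, fit: RegressionFit, expected: dict | None) -> dict:
    row = {
        "fit": name,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "se_slope": fit.se_slope,
        "se_intercept": fit.se_intercept,
        "r2": fit.r2,
        "p_value": fit.p_value,
        "df": fit.df,
        "n": fit.n,
    }
    if expected is not None:
        ok = True
        for key in ("slope", "intercept", "r2"):
            if key in expected:
                ok &= abs(row[key] - expected[key]) <= expected[f"tol_{key}"]
        row["within_expected"] = bool(ok)
    else:
        row["within_expected"] = None
    return row


def reproduce_paper(
    records: Sequence[SpeciesRecord],
    tree: dendropy.Tree,
    s_coeff: float = 0.01,
    t_link: float = 2.0,
    expected: dict | None = None,
) -> dict:
    """Recompute every comparative result from the species table and tree.

    Returns a dict with the five regression fits (burden vs N_e for Ge and
    Gc+Gnc, u_id vs u_bs, the unicellular subset, and the through-origin
    PIC fit), the per-species antimutator table, the u_id/u_bs ratio range,
    and per-fit pass/fail against the packaged expectations.
    """
    from .popgen_diversity import ne_consistency_report

    if expected is None:
        expected = load_expected_fits()
    by_label = {r.label: r for r in records}
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(leaf_labels ^ set(by_label))
    if missing:
        raise ValueError(f"tree/table label mismatch: {', '.join(missing)}")

    fits: dict[str, RegressionFit] = {
        "fig1a": subset_regression(records, None, "burden_ge"),
        "fig1b": subset_regression(records, None, "burden_gcnc"),
        "fig3": loglog_regression(
            [r.u_bs for r in records], [r.u_id for r in records]
        ),
        "unicellular": subset_regression(records, UNICELLULAR_GROUPS, "burden_ge"),
    }
    log_ne = {r.label: np.log10(r.Ne) for r in records}
    log_burden = {
        r.label: np.log10(mutational_burden(r, "Ge")) for r in records
    }
    cx = pic_contrasts(tree, log_ne, "log10_Ne")
    cy = pic_contrasts(tree, log_burden, "log10_uid_Ge")
    fits["pic"] = origin_regression(cx, cy)

    fits_table = pd.DataFrame(
        [_fit_row(name, fit, expected.get(name)) for name, fit in fits.items()]
    )
    barrier_table = pd.DataFrame(
        [vars(antimutator_threshold(r, s_coeff, t_link)) for r in records]
    )
    contrasts_table = pd.DataFrame(
        {
            "node_id": [nid for nid, _ in cx.contrasts],
            "contrast_log10_Ne": cx.values(),
            "contrast_log10_uid_Ge": cy.values(),
        }
    )
    ratios = np.array([r.u_id / r.u_bs for r in records])
    return {
        "fits": fits,
        "fits_table": fits_table,
        "barrier_table": barrier_table,
        "contrasts_table": contrasts_table,
        "ne_report": ne_consistency_report(records),
        "uid_over_ubs_range": (float(ratios.min()), float(ratios.max())),
    }
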