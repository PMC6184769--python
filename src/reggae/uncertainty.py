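"""Bootstrap robustness for the enrichment ranking.

Technical noise in the expression measurements propagates through the
correlation coefficients into the order of L.  To stabilise the ranking,
B bootstrap matrices are drawn by resampling the m sample columns i.i.d.
with replacement (not stratified by group: group labels play no role in
Steps 2-4), Steps 2-4 are repeated on each, and every regulator's adjusted
p-values across replicates are summarised by their median (the new ranking
score), standard deviation, mean absolute deviation and a BCa confidence
interval.  The gene list itself stays fixed from the original matrix.

A pair-swap trace - the number of regulator pairs whose relative order flips
between consecutive cumulative rankings - serves as the convergence
diagnostic for choosing B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, ResultTable, RTICollection
from .diffexp import GeneScoreList
from .enrichment import ReggaeConfig, _frame_to_table, _single_run

__all__ = [
    "BootstrapSummary",
    "bootstrap_reggae",
    "bca_interval",
    "pair_swap_count",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapSummary:
    """Per-regulator summary of the bootstrap p-value distribution."""

    regulator_id: str
    p_median: float
    p_sd: float
    p_mad: float
    ci: tuple[float, float]
    B: int


def bca_interval(
    replicate_values,
    theta_hat: float,
    jackknife_values,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Efron's bias-corrected and accelerated bootstrap interval.

    z0 is the normal quantile of the fraction of replicates below the point
    estimate; the acceleration a comes from the jackknife skewness.  When all
    replicates fall on one side of theta_hat (z0 infinite) the interval is
    clamped to the plain percentile interval with a warning.
    """
    reps = np.asarray(replicate_values, dtype=float)
    if reps.size == 0:
        raise ValueError("no replicate values")
    if np.all(reps == reps[0]):
        return float(reps[0]), float(reps[0])
    frac = float(np.mean(reps < theta_hat))
    q_lo, q_hi = alpha / 2.0, 1.0 - alpha / 2.0
    if frac in (0.0, 1.0):
        warnings.warn(
            "all bootstrap replicates on one side of the estimate; "
            "falling back to the percentile interval"
        )
        lo, hi = np.quantile(reps, [q_lo, q_hi])
        return float(lo), float(hi)
    z0 = stats.norm.ppf(frac)
    jack = np.asarray(jackknife_values, dtype=float)
    if jack.size:
        d = jack.mean() - jack
        denom = 6.0 * (np.sum(d**2)) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
    else:
        a = 0.0
    out = []
    for z in (stats.norm.ppf(q_lo), stats.norm.ppf(q_hi)):
        adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
        out.append(float(np.quantile(reps, stats.norm.cdf(adj))))
    return out[0], out[1]


def pair_swap_count(rank_prev: dict[str, int], rank_curr: dict[str, int]) -> int:
    """Number of regulator pairs whose relative order differs between two
    rankings (the discordant-pair count of Kendall's tau)."""
    if set(rank_prev) != set(rank_curr):
        raise ValueError("rankings cover different regulator sets")
    keys = list(rank_prev)
    a = np.array([rank_prev[k] for k in keys], dtype=float)
    b = np.array([rank_curr[k] for k in keys], dtype=float)
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    discordant = (sa * sb) < 0
    return int(np.triu(discordant, k=1).sum())


def _ranking_from_scores(scores: dict[str, float]) -> dict[str, int]:
    """Ranks 1..R by ascending score, ties broken by regulator id."""
    order = sorted(scores, key=lambda r: (scores[r], r))
    return {r: i for i, r in enumerate(order, start=1)}


def bootstrap_reggae(
    expr: ExpressionMatrix,
    gene_list: GeneScoreList,
    rti: RTICollection,
    config: ReggaeConfig | None = None,
    B: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
    ci_method: str | None = "bca",
    median_on: str = "adjusted",
    swap_trace: bool = False,
) -> ResultTable:
    """Bootstrap the enrichment analysis and rank by the median p-value.

    Parameters
    ----------
    B : number of bootstrap replicates (B = 0 falls back to the single
        non-bootstrap run, flagged in the metadata).
    seed : master seed; each replicate draws from its own spawned substream,
        so increasing B leaves earlier replicates unchanged.
    ci_method : "bca" (adds m jackknife leave-one-column-out runs),
        "percentile", or None to skip intervals.
    median_on : summarise "adjusted" (default) or "raw" p-values.
    swap_trace : also record the pair-swap convergence diagnostic; the trace
        (one count per replicate from the second on) lands in
        ``metadata["swap_trace"]``.  The trace ranks regulators by the
        cumulative median of their *raw* p-values: the step-up adjustment
        flattens most null regulators onto p = 1, which would hide the
        order fluctuations the diagnostic is meant to expose.
    """
    config = config or ReggaeConfig()
    if median_on not in ("adjusted", "raw"):
        raise ValueError("median_on must be 'adjusted' or 'raw'")
    if ci_method not in ("bca", "percentile", None):
        raise ValueError("ci_method must be 'bca', 'percentile' or None")
    pcol = "p_adjusted" if median_on == "adjusted" else "p_raw"

    base = _single_run(expr, gene_list, rti, config)
    if B == 0:
        log.warning("B=0: returning the single non-bootstrap run")
        return _frame_to_table(base, config, gene_list,
                               extra_meta={"B": 0, "bootstrap_skipped": True})

    m = expr.n_samples
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    regs = list(base["regulator"])
    reg_pos = {r: i for i, r in enumerate(regs)}
    pmat = np.ones((len(regs), B))  # untested-in-replicate regulators keep p=1
    praw = np.ones((len(regs), B))
    trace: list[int] = []
    prev_ranks: dict[str, int] | None = None
    for b in range(B):
        rng = np.random.default_rng(children[b])
        cols = rng.integers(0, m, size=m)
        rep = _single_run(expr, gene_list, rti, config, cols=cols)
        for reg, p, p_r in zip(rep["regulator"], rep[pcol], rep["p_raw"]):
            if reg in reg_pos:  # regulators absent from the original run are ignored
                pmat[reg_pos[reg], b] = p
                praw[reg_pos[reg], b] = p_r
        if swap_trace:
            med = np.median(praw[:, : b + 1], axis=1)
            ranks = _ranking_from_scores({r: med[i] for i, r in enumerate(regs)})
            if prev_ranks is not None:
                trace.append(pair_swap_count(prev_ranks, ranks))
            prev_ranks = ranks

    p_median = np.median(pmat, axis=1)
    p_sd = pmat.std(axis=1, ddof=1) if B > 1 else np.zeros(len(regs))
    p_mad = np.abs(pmat - pmat.mean(axis=1, keepdims=True)).mean(axis=1)

    ci_low = np.full(len(regs), np.nan)
    ci_high = np.full(len(regs), np.nan)
    if ci_method is not None:
        theta = base.set_index("regulator")[pcol]
        jack = None
        if ci_method == "bca":
            jack = np.ones((len(regs), m))
            for j in range(m):
                cols = np.array([c for c in range(m) if c != j])
                rep = _single_run(expr, gene_list, rti, config, cols=cols)
                for reg, p in zip(rep["regulator"], rep[pcol]):
                    if reg in reg_pos:
                        jack[reg_pos[reg], j] = p
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, reg in enumerate(regs):
                jk = jack[i] if jack is not None else np.array([])
                ci_low[i], ci_high[i] = bca_interval(
                    pmat[i], float(theta[reg]), jk, alpha=alpha
                )

    out = base.copy()
    out["p_median"] = p_median
    out["p_sd"] = p_sd
    out["p_mad"] = p_mad
    out["ci_low"] = ci_low
    out["ci_high"] = ci_high
    out = out.sort_values(
        by=["p_median", "p_adjusted", "statistic", "regulator"],
        ascending=True,
        kind="mergesort",
    ).reset_index(drop=True)
    out.attrs.update(base.attrs)
    meta = {
        "B": B,
        "seed": seed,
        "ci_level": 1.0 - alpha,
        "ci_method": ci_method,
        "median_on": median_on,
    }
    if swap_trace:
        meta["swap_trace"] = trace
    return _frame_to_table(out, config, gene_list, extra_meta=meta)


def plot_swap_trace(trace, ax=None):
    """Plot the pair-swap convergence diagnostic (replicate index vs swaps)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(2, len(trace) + 2), trace, lw=1)
    ax.set_xlabel("bootstrap replicate")
    ax.set_ylabel("pair swaps vs previous cumulative ranking")
    return ax
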