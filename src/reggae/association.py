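"""Step 2: regulator-target correlations and per-gene regulator rankings.

Correlations are computed across *all* samples (both groups).  Each
deregulated gene's regulator list is sorted by absolute (default) or signed
correlation, ties broken by regulator id.  Zero-variance vectors - possible
in bootstrap resamples - yield correlation 0, which places the regulator last
in absolute mode instead of aborting the resample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionMatrix, RTICollection
from .diffexp import GeneScoreList

__all__ = [
    "PerGeneRegulatorRanking",
    "RegulatorDirection",
    "correlate",
    "correlation_matrix",
    "rank_regulators",
    "regulator_direction",
]

log = logging.getLogger(__name__)


@dataclass
class PerGeneRegulatorRanking:
    """One gene's regulators ordered by correlation strength."""

    gene_id: str
    entries: list[tuple[str, float]]  # (regulator_id, correlation), best first
    sort_mode: str

    @property
    def regulators(self) -> list[str]:
        return [r for r, _ in self.entries]


@dataclass
class RegulatorDirection:
    """Activator/repressor call from the mean signed target correlation."""

    regulator_id: str
    mean_signed_correlation: float
    direction: str  # "activator" | "repressor" | "ambiguous"


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation of two equal-length vectors.

    Spearman uses average ranks for ties.  If either vector has zero
    variance the coefficient is defined as 0 (logged, not raised).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        log.debug("zero-variance vector in correlate; coefficient set to 0")
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_matrix(a: np.ndarray, b: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Row-wise correlation of every row of ``a`` against every row of ``b``.

    Returns shape (a_rows, b_rows); rows with zero variance produce 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "spearman":
        a = stats.rankdata(a, axis=1)
        b = stats.rankdata(b, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac**2).sum(axis=1))
    nb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac @ bc.T) / np.outer(na, nb)
    corr[~np.isfinite(corr)] = 0.0
    return np.clip(corr, -1.0, 1.0)


def rank_regulators(
    expr: ExpressionMatrix,
    gene_list: GeneScoreList,
    rti: RTICollection,
    corr_method: str = "pearson",
    sort_mode: str = "absolute",
    cols: np.ndarray | None = None,
) -> list[PerGeneRegulatorRanking]:
    """Build each listed gene's sorted regulator ranking (in gene-list order).

    Regulators without an expression row are dropped from the per-gene lists
    (counted in the log as untestable RTIs); genes with no testable regulator
    are omitted.  ``cols`` optionally selects/reorders sample columns, which
    is how bootstrap resampling re-runs this step.
    """
    if sort_mode not in ("absolute", "signed"):
        raise ValueError(f"unknown sort mode {sort_mode!r}")
    if not len(gene_list):
        raise ValueError("empty gene list")

    genes = [g for g in gene_list.gene_ids if expr.has_gene(g)]
    # regulators needed anywhere in the list, insertion-ordered
    reg_seen: dict[str, None] = {}
    untestable = 0
    per_gene_regs: dict[str, list[str]] = {}
    for g in genes:
        regs = []
        for r in rti.regulators_of(g):
            if expr.has_gene(r):
                regs.append(r)
                reg_seen[r] = None
            else:
                untestable += 1
        if regs:
            per_gene_regs[g] = regs
    if untestable:
        log.info("dropped %d untestable RTIs (regulator lacks an expression row)", untestable)
    kept_genes = [g for g in gene_list.gene_ids if g in per_gene_regs]
    skipped = len(gene_list) - len(kept_genes)
    if skipped:
        log.info("%d gene(s) without testable regulators omitted from rankings", skipped)
    if not kept_genes:
        return []

    reg_ids = list(reg_seen)
    reg_idx = {r: i for i, r in enumerate(reg_ids)}
    gene_idx = {g: i for i, g in enumerate(kept_genes)}
    reg_rows = expr.rows(reg_ids)
    gene_rows = expr.rows(kept_genes)
    if cols is not None:
        reg_rows = reg_rows[:, cols]
        gene_rows = gene_rows[:, cols]
    corr = correlation_matrix(reg_rows, gene_rows, method=corr_method)

    rankings = []
    for g in kept_genes:
        gi = gene_idx[g]
        entries = [(r, float(corr[reg_idx[r], gi])) for r in per_gene_regs[g]]
        if sort_mode == "absolute":
            entries.sort(key=lambda t: (-abs(t[1]), t[0]))
        else:
            entries.sort(key=lambda t: (-t[1], t[0]))
        rankings.append(PerGeneRegulatorRanking(gene_id=g, entries=entries, sort_mode=sort_mode))
    return rankings


def regulator_direction(
    rti: RTICollection,
    expr: ExpressionMatrix,
    gene_list: GeneScoreList,
    regulator_id: str,
    corr_method: str = "pearson",
    tau: float = 0.0,
) -> RegulatorDirection:
    """Mean signed correlation of a regulator with its listed targets.

    Direction is "activator" if the mean exceeds +tau, "repressor" if below
    -tau, otherwise "ambiguous" (tau defaults to 0).
    """
    if not expr.has_gene(regulator_id):
        raise ValueError(f"regulator {regulator_id!r} has no expression row")
    targets = [
        g for g in gene_list.gene_ids
        if g in set(rti.targets_of(regulator_id)) and expr.has_gene(g)
    ]
    if not targets:
        raise ValueError(f"regulator {regulator_id!r} has no targets in the gene list")
    reg_row = expr.rows([regulator_id])
    corr = correlation_matrix(reg_row, expr.rows(targets), method=corr_method)[0]
    return _direction_from_mean(regulator_id, float(corr.mean()), tau)


def _direction_from_mean(regulator_id: str, msc: float, tau: float = 0.0) -> RegulatorDirection:
    if msc > tau:
        call = "activator"
    elif msc < -tau:
        call = "repressor"
    else:
        call = "ambiguous"
    return RegulatorDirection(regulator_id=regulator_id, mean_signed_correlation=msc, direction=call)
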