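"""Step 1: per-gene differential-expression scoring and gene-list selection.

Every method signs its statistic so that positive means "higher in the case
group".  Scores feed only an ordering downstream, so infinities from
zero-variance genes are demoted to the largest finite magnitude plus one,
preserving the rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix

__all__ = ["GeneScoreList", "score_genes", "shrinkage_t", "select_gene_list", "SCORE_METHODS"]


@dataclass
class GeneScoreList:
    """A sorted list of up- or down-regulated genes with their scores.

    ``entries`` is ordered best-first: most positive scores for direction
    "up", most negative for "down".  ``p`` entries are ``None`` for methods
    that do not define a p-value.
    """

    entries: list[tuple[str, float, float | None]]
    direction: str
    method: str

    def __post_init__(self) -> None:
        ids = [g for g, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene id in gene list")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def _group_arrays(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    return expr.values[:, expr.case_indices], expr.values[:, expr.control_indices]


def _demote_infinite(score: np.ndarray) -> np.ndarray:
    """Map +-inf statistics to (max finite |score| + 1), keeping their sign."""
    bad = ~np.isfinite(score)
    if bad.any():
        finite = np.abs(score[~bad])
        cap = (finite.max() if finite.size else 0.0) + 1.0
        score = score.copy()
        score[bad] = np.sign(score[bad]) * cap
        # sign of inf is +-1; NaN (0/0) becomes 0
        score[np.isnan(score)] = 0.0
    return score


def _fold_change(expr: ExpressionMatrix, log: bool) -> pd.DataFrame:
    case, ctrl = _group_arrays(expr)
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    keep = m2 != 0
    if log:
        keep &= (m1 > 0) & (m2 > 0)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} gene(s) with undefined fold change"
        )
    ratio = np.where(keep, m1 / np.where(m2 == 0, np.nan, m2), np.nan)
    score = np.log2(ratio) if log else ratio
    frame = pd.DataFrame({"score": score, "p": np.nan}, index=expr.gene_ids)
    return frame.loc[keep]


def _signal_to_noise(expr: ExpressionMatrix) -> pd.DataFrame:
    case, ctrl = _group_arrays(expr)
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    s1 = case.std(axis=1, ddof=1)
    s2 = ctrl.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (m1 - m2) / (s1 + s2)
    score = _demote_infinite(score)
    return pd.DataFrame({"score": score, "p": np.nan}, index=expr.gene_ids)


def _t_test(expr: ExpressionMatrix, equal_var: bool) -> pd.DataFrame:
    case, ctrl = _group_arrays(expr)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
    score = _demote_infinite(np.asarray(res.statistic, dtype=float))
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 0.0
    return pd.DataFrame({"score": score, "p": p}, index=expr.gene_ids)


def _wilcoxon(expr: ExpressionMatrix) -> pd.DataFrame:
    case, ctrl = _group_arrays(expr)
    n1, n2 = case.shape[1], ctrl.shape[1]
    both = np.concatenate([case, ctrl], axis=1)
    ranks = stats.rankdata(both, axis=1)
    w = ranks[:, :n1].sum(axis=1)
    mean = n1 * (n1 + n2 + 1) / 2.0
    # tie-corrected variance of the rank sum
    n = n1 + n2
    var = np.empty(both.shape[0])
    for i in range(both.shape[0]):
        _, counts = np.unique(both[i], return_counts=True)
        tie = (counts**3 - counts).sum()
        var[i] = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (w - mean) / np.sqrt(var)
    z = _demote_infinite(z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"score": z, "p": p}, index=expr.gene_ids)


def _label_correlation(expr: ExpressionMatrix, method: str) -> pd.DataFrame:
    label = np.array(
        [1.0 if expr.groups[s] == expr.case_group else 0.0 for s in expr.sample_ids]
    )
    x = expr.values
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
        label = stats.rankdata(label)
    xc = x - x.mean(axis=1, keepdims=True)
    lc = label - label.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (lc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ lc) / denom
    r = np.where(np.isfinite(r), r, 0.0)
    m = x.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    return pd.DataFrame({"score": r, "p": p}, index=expr.gene_ids)


def shrinkage_t(expr: ExpressionMatrix) -> pd.DataFrame:
    """t-like statistic with a James-Stein-type shrunken pooled variance.

    The per-gene pooled variance v_g (two-group-centred residuals, n-2 df) is
    shrunk toward the median variance v_med with data-driven intensity

        lambda* = min(1, sum_g Var-hat(v_g) / sum_g (v_g - v_med)^2),

    where Var-hat(v_g) = n/(n-1)^3 * sum_i (w_i - w_bar)^2 and w_i are the
    squared centred residuals.  The statistic is the mean difference over
    sqrt(v*_g (1/n1 + 1/n2)); p-values come from the standard normal.
    """
    case, ctrl = _group_arrays(expr)
    n1, n2 = case.shape[1], ctrl.shape[1]
    n = n1 + n2
    resid = np.concatenate(
        [case - case.mean(axis=1, keepdims=True), ctrl - ctrl.mean(axis=1, keepdims=True)],
        axis=1,
    )
    v = (resid**2).sum(axis=1) / (n - 2)
    if len(v) < 2:
        warnings.warn("single-gene matrix: shrinkage target degenerate, using lambda*=0")
        lam = 0.0
        v_med = float(v[0]) if len(v) else 0.0
    else:
        w = resid**2
        var_v = n / (n - 1) ** 3 * ((w - w.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        v_med = float(np.median(v))
        denom = float(((v - v_med) ** 2).sum())
        lam = 1.0 if denom == 0.0 else min(1.0, float(var_v.sum()) / denom)
    v_star = lam * v_med + (1.0 - lam) * v
    se = np.sqrt(v_star * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (case.mean(axis=1) - ctrl.mean(axis=1)) / se
    score = _demote_infinite(score)
    p = 2.0 * stats.norm.sf(np.abs(score))
    return pd.DataFrame({"score": score, "p": p}, index=expr.gene_ids)


SCORE_METHODS = {
    "fold_change": lambda e: _fold_change(e, log=False),
    "log_fold_change": lambda e: _fold_change(e, log=True),
    "signal_to_noise": _signal_to_noise,
    "t_test": lambda e: _t_test(e, equal_var=True),
    "welch_t": lambda e: _t_test(e, equal_var=False),
    "shrinkage_t": shrinkage_t,
    "wilcoxon_rank_sum": _wilcoxon,
    "pearson_vs_label": lambda e: _label_correlation(e, "pearson"),
    "spearman_vs_label": lambda e: _label_correlation(e, "spearman"),
}

# score value meaning "no difference"; 1 for the ratio-based fold change
_NULL_SCORE = {m: 0.0 for m in SCORE_METHODS}
_NULL_SCORE["fold_change"] = 1.0


def score_genes(expr: ExpressionMatrix, method: str = "shrinkage_t") -> pd.DataFrame:
    """Score each gene for differential expression between the two groups.

    Returns a DataFrame indexed by gene id with columns ``score`` and ``p``
    (``p`` is NaN for methods without a p-value).
    """
    if method not in SCORE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(SCORE_METHODS)}"
        )
    return SCORE_METHODS[method](expr)


def select_gene_list(
    scores: pd.DataFrame,
    direction: str = "up",
    top_k: int | None = None,
    p_threshold: float | None = None,
    method: str = "shrinkage_t",
) -> GeneScoreList:
    """Select the best genes in one direction, sorted by score.

    Exactly one of ``top_k`` (positive integer) or ``p_threshold`` (alpha in
    (0,1); requires p-values) must be given.  Direction "up" keeps genes with
    scores above the method's neutral value sorted descending; "down" keeps
    those below it sorted ascending (most extreme first).  Ties break on gene
    id.
    """
    if (top_k is None) == (p_threshold is None):
        raise ValueError("specify exactly one of top_k or p_threshold")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    null = _NULL_SCORE.get(method, 0.0)
    score = scores["score"]
    mask = score > null if direction == "up" else score < null
    if p_threshold is not None:
        if not 0.0 < p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if scores["p"].isna().all():
            raise ValueError(f"method {method!r} provides no p-values for thresholding")
        mask &= scores["p"] < p_threshold
    sub = scores.loc[mask].copy()
    if sub.empty:
        raise ValueError(f"no genes match direction {direction!r}")
    order = sorted(
        sub.itertuples(),
        key=lambda t: (-t.score if direction == "up" else t.score, t.Index),
    )
    if top_k is not None:
        if top_k <= 0:
            raise ValueError("top_k must be a positive integer")
        if top_k > len(order):
            warnings.warn(
                f"requested top {top_k} {direction}-regulated genes, only "
                f"{len(order)} available"
            )
        order = order[:top_k]
    entries = [
        (str(t.Index), float(t.score), None if np.isnan(t.p) else float(t.p))
        for t in order
    ]
    return GeneScoreList(entries=entries, direction=direction, method=method)
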