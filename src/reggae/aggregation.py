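"""Consensus over result lists computed for gene lists of different sizes.

Running the analysis for several list lengths and aggregating stabilises the
ranking: per regulator we take the sum of its per-list ranks and the maximum
of its per-list p-values (worst-case imputation - rank = list length + 1 and
p = 1 - where a regulator is missing from a list), then apply a final
Benjamini-Yekutieli adjustment to the max-p vector.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .data import ResultTable
from .enrichment import adjust_benjamini_yekutieli

__all__ = ["aggregate", "significant_overlaps"]


def aggregate(tables: list[ResultTable], alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate >=2 result tables into one consensus ranking.

    Per-list p-values are the ranking scores (``p_median``, which equals the
    adjusted p when no bootstrap ran).  Output is ordered by adjusted max-p,
    ties by rank sum then regulator id; per-list ranks and p-values are kept
    in ``rank_<i>`` / ``p_<i>`` columns.  The frame's ``attrs`` carry the
    significant-set overlap report.
    """
    if not tables:
        raise ValueError("no tables to aggregate")
    if len(tables) == 1:
        warnings.warn("single result table: aggregation is an identity pass-through")
    union: dict[str, None] = {}
    for t in tables:
        for r in t.regulators:
            union[r] = None
    regs = list(union)
    n_lists = len(tables)

    ranks = np.zeros((len(regs), n_lists))
    pvals = np.ones((len(regs), n_lists))
    present = np.zeros((len(regs), n_lists), dtype=bool)
    for j, t in enumerate(tables):
        idx = t.table.set_index("regulator")
        worst = len(t) + 1
        for i, reg in enumerate(regs):
            if reg in idx.index:
                ranks[i, j] = idx.loc[reg, "rank"]
                pvals[i, j] = idx.loc[reg, "p_median"]
                present[i, j] = True
            else:
                ranks[i, j] = worst
    rank_sum = ranks.sum(axis=1)
    p_max = pvals.max(axis=1)
    p_max_adjusted = adjust_benjamini_yekutieli(p_max)

    frame = pd.DataFrame(
        {
            "regulator": regs,
            "rank_sum": rank_sum.astype(int),
            "p_max": p_max,
            "p_max_adjusted": p_max_adjusted,
            "n_lists_present": present.sum(axis=1),
        }
    )
    for j in range(n_lists):
        frame[f"rank_{j + 1}"] = ranks[:, j].astype(int)
        frame[f"p_{j + 1}"] = pvals[:, j]
    frame = frame.sort_values(
        by=["p_max_adjusted", "rank_sum", "regulator"], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame.attrs["overlaps"] = significant_overlaps(tables, alpha=alpha)
    return frame


def significant_overlaps(tables: list[ResultTable], alpha: float = 0.05) -> dict:
    """Pairwise and all-way intersection sizes of the per-list significant
    sets (adjusted/median p below alpha)."""
    sig = [
        set(t.table.loc[t.table["p_median"] < alpha, "regulator"]) for t in tables
    ]
    report: dict = {
        "sizes": [len(s) for s in sig],
        "pairwise": {
            (i + 1, j + 1): len(sig[i] & sig[j])
            for i, j in combinations(range(len(sig)), 2)
        },
    }
    if sig:
        inter = set(sig[0])
        for s in sig[1:]:
            inter &= s
        report["all"] = len(inter)
    return report
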