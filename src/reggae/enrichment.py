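"""Steps 3-4: the column-merged regulator list L and enrichment tests on it.

Step 3 merges the per-gene regulator rankings column by column: every gene's
best regulator first (in gene order), then every gene's second-best, and so
on, skipping genes whose lists are exhausted.  A regulator occupying k of the
N entries of L is then tested for enrichment toward the top with a one-sided
Wilcoxon rank-sum (WRS) test on its positions, or with the unweighted
Kolmogorov-Smirnov (KS) running-sum statistic.  Raw p-values are adjusted
with the Benjamini-Yekutieli step-up, which controls the FDR under arbitrary
dependence among the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import _direction_from_mean, rank_regulators, PerGeneRegulatorRanking
from .data import ExpressionMatrix, ResultTable, RTICollection
from .diffexp import GeneScoreList

__all__ = [
    "CombinedList",
    "ReggaeConfig",
    "build_combined_list",
    "occurrence_positions",
    "wrs_enrichment",
    "ks_enrichment",
    "ks_running_sum",
    "adjust_benjamini_yekutieli",
    "run_reggae_once",
]


@dataclass
class CombinedList:
    """The merged list L of (regulator, source gene, correlation) entries."""

    entries: list[tuple[str, str, float]]

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def regulator_ids(self) -> list[str]:
        return [r for r, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReggaeConfig:
    """Options for Steps 2-4.

    test : "wrs" (default) or "ks" (running-sum statistic).  Both use an
        exact null distribution when N*k <= exact_threshold (tie-free
        rank-sum distribution for WRS, lattice-path DP for KS) and an
        asymptotic form beyond it (continuity-corrected normal / KS tail).
    min_occurrences : regulators with fewer than this many entries in L are
        reported as untested.
    """

    test: str = "wrs"
    correlation: str = "pearson"
    sort_mode: str = "absolute"
    min_occurrences: int = 1
    exact_threshold: int = 1_000_000
    direction_tau: float = 0.0

    def __post_init__(self) -> None:
        if self.test not in ("wrs", "ks"):
            raise ValueError(f"unknown test {self.test!r} (expected 'wrs' or 'ks')")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.sort_mode not in ("absolute", "signed"):
            raise ValueError(f"unknown sort mode {self.sort_mode!r}")
        if self.min_occurrences < 1:
            raise ValueError("min_occurrences must be >= 1")


def build_combined_list(rankings: list[PerGeneRegulatorRanking]) -> CombinedList:
    """Merge per-gene rankings column by column into the list L.

    Genes with fewer regulators than the current column index are skipped, so
    ragged rankings interleave without gaps.
    """
    entries: list[tuple[str, str, float]] = []
    depth = max((len(r.entries) for r in rankings), default=0)
    for col in range(depth):
        for ranking in rankings:
            if col < len(ranking.entries):
                reg, corr = ranking.entries[col]
                entries.append((reg, ranking.gene_id, corr))
    if not entries:
        raise ValueError("empty combined list")
    return CombinedList(entries=entries)


def occurrence_positions(combined: CombinedList, regulator_id: str) -> tuple[int, ...]:
    """1-based positions of a regulator's entries in L (empty if absent)."""
    return tuple(
        i for i, (reg, _, _) in enumerate(combined.entries, start=1) if reg == regulator_id
    )


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------


def wrs_enrichment(N: int, positions, exact_threshold: int = 1_000_000) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test for enrichment toward the top of L.

    The statistic is the normal deviate of the rank sum W = sum(positions)
    with a 0.5 continuity correction toward the mean; small positions give a
    small p.  The p-value comes from the exact rank-sum null distribution
    (positions are distinct, so it is tie-free) when N*k <= exact_threshold,
    and from the normal approximation p = Phi(z) otherwise.  k == N (the
    regulator fills the whole list) is the degenerate no-contrast case with
    p = 1.
    """
    positions = np.asarray(sorted(positions), dtype=float)
    k = positions.size
    if k < 1:
        raise ValueError("need at least one occurrence position")
    if np.any(positions < 1) or np.any(positions > N) or len(set(positions)) != k:
        raise ValueError("positions must be distinct integers in 1..N")
    if k == N:
        return 0.0, 1.0
    w = positions.sum()
    mean = k * (N + 1) / 2.0
    sd = np.sqrt(k * (N - k) * (N + 1) / 12.0)
    z = (w - mean + 0.5) / sd
    if N * k <= exact_threshold:
        rest = np.setdiff1d(np.arange(1, N + 1), positions)
        p = stats.mannwhitneyu(positions, rest, alternative="less", method="exact").pvalue
    else:
        p = stats.norm.cdf(z)
    return float(z), float(max(p, 1e-300))


def ks_running_sum(N: int, positions) -> np.ndarray:
    """The running sum over L: +1/k at each occurrence, -1/(N-k) elsewhere."""
    pos = set(int(p) for p in positions)
    k = len(pos)
    if k == N:
        return np.ones(N)
    steps = np.full(N, -1.0 / (N - k))
    for p in pos:
        steps[p - 1] = 1.0 / k
    return np.cumsum(steps)


def _ks_exact_p(N: int, k: int, es_scaled: int) -> float:
    """P(max prefix of the scaled running sum >= es_scaled) under uniform
    placement of k hits among N slots, via a lattice-path DP.

    The walk is scaled by k(N-k): a hit steps +(N-k), a miss steps -k, so all
    prefix values are integers.  The DP tracks, over the hit count h, the
    probability that every prefix so far stayed strictly below the observed
    supremum; the complement is the exact one-sided p.
    """
    if es_scaled <= 0:
        return 1.0
    # f[h]: P(h hits after i steps and all prefixes < es_scaled)
    f = np.zeros(k + 1)
    f[0] = 1.0
    lo = 0
    for i in range(N):
        remaining = N - i
        h = np.arange(0, k + 1)
        p_hit = np.clip((k - h) / remaining, 0.0, 1.0)
        nxt = np.zeros(k + 1)
        nxt[1:] += f[:-1] * p_hit[:-1]
        nxt += f * (1.0 - p_hit)
        # prefix value after i+1 steps with h hits: h*(N-k) - (i+1-h)*k
        value = h * (N - k) - (i + 1 - h) * k
        nxt[value >= es_scaled] = 0.0
        f = nxt
    # floor keeps the p-value inside (0,1] even when float cancellation
    # would round it to 0
    return float(min(1.0, max(1e-300, 1.0 - f.sum())))


def ks_enrichment(N: int, positions, exact_threshold: int = 1_000_000) -> tuple[float, float]:
    """Unweighted KS enrichment: supremum of the running sum and its p-value.

    The enrichment score ES is the maximum prefix of the running sum
    (including the empty prefix, so ES >= 0).  The p-value is
    Pr(ES* >= ES) under uniform placement of the k hits: exact (lattice-path
    DP) when N*k <= exact_threshold, else the asymptotic one-sided tail
    exp(-2 ES^2 k(N-k)/N).
    """
    positions = sorted(int(p) for p in positions)
    k = len(positions)
    if k < 1:
        raise ValueError("need at least one occurrence position")
    if positions[0] < 1 or positions[-1] > N or len(set(positions)) != k:
        raise ValueError("positions must be distinct integers in 1..N")
    if k == N:
        return 1.0, 1.0
    # integer-scaled supremum: after the j-th hit at position p_j the prefix
    # value (scaled by k(N-k)) is j*(N-k) - (p_j - j)*k, and prefix maxima can
    # only occur immediately after a hit.
    es_scaled = 0
    for j, p in enumerate(positions, start=1):
        es_scaled = max(es_scaled, j * (N - k) - (p - j) * k)
    es = es_scaled / (k * (N - k))
    if es_scaled == 0:
        return 0.0, 1.0
    if N * k <= exact_threshold:
        p_val = _ks_exact_p(N, k, es_scaled)
    else:
        p_val = float(min(1.0, max(1e-300, np.exp(-2.0 * es**2 * k * (N - k) / N))))
    return float(es), p_val


def adjust_benjamini_yekutieli(p) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment (valid under arbitrary
    dependence); returns adjusted values in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_by")[1]


# ---------------------------------------------------------------------------
# One full pass of Steps 2-4
# ---------------------------------------------------------------------------


def _single_run(
    expr: ExpressionMatrix,
    gene_list: GeneScoreList,
    rti: RTICollection,
    config: ReggaeConfig,
    cols: np.ndarray | None = None,
) -> pd.DataFrame:
    """Steps 2-4 on (optionally resampled) columns; returns the per-regulator
    frame sorted by adjusted p.  Used directly and by the bootstrap."""
    rankings = rank_regulators(
        expr, gene_list, rti,
        corr_method=config.correlation, sort_mode=config.sort_mode, cols=cols,
    )
    combined = build_combined_list(rankings)
    N = combined.N

    positions: dict[str, list[int]] = {}
    corr_sum: dict[str, float] = {}
    for i, (reg, _, corr) in enumerate(combined.entries, start=1):
        positions.setdefault(reg, []).append(i)
        corr_sum[reg] = corr_sum.get(reg, 0.0) + corr

    tested = [r for r, pos in positions.items() if len(pos) >= config.min_occurrences]
    rows = []
    for reg in tested:
        pos = positions[reg]
        if config.test == "wrs":
            stat, p = wrs_enrichment(N, pos, exact_threshold=config.exact_threshold)
        else:
            stat, p = ks_enrichment(N, pos, exact_threshold=config.exact_threshold)
        rows.append((reg, len(pos), stat, p, corr_sum[reg] / len(pos)))
    frame = pd.DataFrame(
        rows, columns=["regulator", "n_occurrences", "statistic", "p_raw",
                       "mean_signed_correlation"],
    )
    frame["p_adjusted"] = adjust_benjamini_yekutieli(frame["p_raw"].to_numpy())
    frame = frame.sort_values(
        by=["p_adjusted", "p_raw", "statistic", "regulator"],
        ascending=[True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.attrs["N"] = N
    frame.attrs["n_untested"] = len(positions) - len(tested)
    return frame


def run_reggae_once(
    expr: ExpressionMatrix,
    gene_list: GeneScoreList,
    rti: RTICollection,
    config: ReggaeConfig | None = None,
) -> ResultTable:
    """One pass of Steps 2-4 (no bootstrap) on the original matrix."""
    config = config or ReggaeConfig()
    frame = _single_run(expr, gene_list, rti, config)
    return _frame_to_table(frame, config, gene_list)


def _frame_to_table(
    frame: pd.DataFrame, config: ReggaeConfig, gene_list: GeneScoreList,
    extra_meta: dict | None = None,
) -> ResultTable:
    out = frame.copy()
    out["p_median"] = out.get("p_median", out["p_adjusted"])
    out["p_sd"] = out.get("p_sd", np.nan)
    out["p_mad"] = out.get("p_mad", np.nan)
    out["ci_low"] = out.get("ci_low", np.nan)
    out["ci_high"] = out.get("ci_high", np.nan)
    out["direction"] = [
        _direction_from_mean(r, m, config.direction_tau).direction
        for r, m in zip(out["regulator"], out["mean_signed_correlation"])
    ]
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    meta = {
        "test": config.test,
        "correlation": config.correlation,
        "sort_mode": config.sort_mode,
        "min_occurrences": config.min_occurrences,
        "gene_list_size": len(gene_list),
        "gene_list_direction": gene_list.direction,
        "de_method": gene_list.method,
        "N": frame.attrs.get("N"),
        "n_untested": frame.attrs.get("n_untested"),
    }
    if extra_meta:
        meta.update(extra_meta)
    return ResultTable(table=out, metadata=meta)
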