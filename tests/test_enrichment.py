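"""Combined-list construction, enrichment tests and the BY adjustment."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from reggae import (
    ExpressionMatrix,
    RTICollection,
    ReggaeConfig,
    adjust_benjamini_yekutieli,
    build_combined_list,
    ks_enrichment,
    occurrence_positions,
    run_reggae_once,
    wrs_enrichment,
)
from reggae.association import PerGeneRegulatorRanking
from reggae.diffexp import GeneScoreList
from reggae.enrichment import ks_running_sum


def _rankings(spec: dict[str, list[str]]) -> list[PerGeneRegulatorRanking]:
    return [
        PerGeneRegulatorRanking(
            gene_id=g, entries=[(r, 0.5) for r in regs], sort_mode="absolute"
        )
        for g, regs in spec.items()
    ]


class TestCombinedList:
    @pytest.mark.parametrize(
        "spec,expected_regs,expected_sources",
        [
            ({"g1": ["a", "b"], "g2": ["b"]}, ["a", "b", "b"], ["g1", "g2", "g1"]),
            ({"g1": ["a"], "g2": ["b"], "g3": ["c"]}, ["a", "b", "c"], ["g1", "g2", "g3"]),
            ({"g1": ["a", "b", "c"], "g2": ["d"]}, ["a", "d", "b", "c"], ["g1", "g2", "g1", "g1"]),
        ],
    )
    def test_column_by_column_merge(self, spec, expected_regs, expected_sources):
        combined = build_combined_list(_rankings(spec))
        assert combined.regulator_ids == expected_regs
        assert [g for _, g, _ in combined.entries] == expected_sources

    def test_empty_rankings_raise(self):
        with pytest.raises(ValueError, match="empty combined list"):
            build_combined_list([])

    def test_mass_conservation_on_random_ragged_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_genes = rng.integers(1, 15)
            spec = {
                f"g{i}": [f"r{j}" for j in rng.choice(30, size=rng.integers(1, 8), replace=False)]
                for i in range(n_genes)
            }
            combined = build_combined_list(_rankings(spec))
            assert combined.N == sum(len(v) for v in spec.values())
            pairs = [(g, r) for r, g, _ in combined.entries]
            assert len(pairs) == len(set(pairs))

    @pytest.mark.parametrize(
        "regs,query,expected",
        [(["a", "b", "b"], "b", (2, 3)), (["a", "b", "b"], "c", ()), (["a", "a", "a"], "a", (1, 2, 3))],
    )
    def test_occurrence_positions(self, regs, query, expected):
        spec = {f"g{i}": [r] for i, r in enumerate(regs)}
        combined = build_combined_list(_rankings(spec))
        assert occurrence_positions(combined, query) == expected


def _enumerated_wrs_p(N: int, positions: tuple[int, ...]) -> float:
    """Exact one-sided rank-sum p by enumerating all C(N,k) placements."""
    k = len(positions)
    w_obs = sum(positions)
    sums = [sum(c) for c in combinations(range(1, N + 1), k)]
    return sum(1 for s in sums if s <= w_obs) / len(sums)


class TestWRS:
    def test_top_pair_of_five_matches_enumeration(self):
        z, p = wrs_enrichment(5, (1, 2))
        assert _enumerated_wrs_p(5, (1, 2)) == pytest.approx(0.1)
        assert p == pytest.approx(0.1, abs=1e-12)  # exact mode
        assert z < 0
        # the normal approximation stays within 0.05 of enumeration here
        _, p_approx = wrs_enrichment(5, (1, 2), exact_threshold=0)
        assert p_approx == pytest.approx(0.1, abs=0.05)

    def test_full_list_degenerates_to_p_one(self):
        assert wrs_enrichment(4, (1, 2, 3, 4))[1] == 1.0

    def test_approximation_matches_scipy_mann_whitney(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            N = int(rng.integers(10, 200))
            k = int(rng.integers(1, N // 2))
            pos = np.sort(rng.choice(N, size=k, replace=False) + 1)
            rest = np.setdiff1d(np.arange(1, N + 1), pos)
            want = stats.mannwhitneyu(
                pos, rest, alternative="less", method="asymptotic"
            ).pvalue
            assert wrs_enrichment(N, pos, exact_threshold=0)[1] == pytest.approx(
                want, rel=1e-9
            )

    def test_null_z_is_standard_normal_scale(self):
        rng = np.random.default_rng(2)
        zs = [
            wrs_enrichment(1000, rng.choice(1000, size=500, replace=False) + 1)[0]
            for _ in range(1000)
        ]
        assert np.mean(np.abs(zs) <= 3.0) >= 0.99

    def test_rejects_duplicate_or_out_of_range_positions(self):
        with pytest.raises(ValueError):
            wrs_enrichment(5, (2, 2))
        with pytest.raises(ValueError):
            wrs_enrichment(5, (0, 3))


class TestKS:
    def test_running_sum_and_exact_p_for_top_pair(self):
        np.testing.assert_allclose(ks_running_sum(4, (1, 2)), [0.5, 1.0, 0.5, 0.0])
        es, p = ks_enrichment(4, (1, 2))
        assert es == pytest.approx(1.0)
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_no_positive_prefix_gives_zero_score(self):
        es, p = ks_enrichment(4, (3, 4))
        assert es == 0.0 and p == 1.0

    @pytest.mark.parametrize("N,k", [(10, 3), (50, 7), (100, 1)])
    def test_all_hits_at_top_force_supremum_one(self, N, k):
        es, _ = ks_enrichment(N, tuple(range(1, k + 1)))
        assert es == pytest.approx(1.0)

    def test_running_sum_telescopes_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            N = int(rng.integers(2, 60))
            k = int(rng.integers(1, N))
            pos = rng.choice(N, size=k, replace=False) + 1
            assert ks_running_sum(N, pos)[-1] == pytest.approx(0.0, abs=1e-12)

    def test_asymptotic_tail_close_to_exact_at_moderate_size(self):
        # the exp(-2 ES^2 k(N-k)/N) form is a tail approximation: it is
        # decision-grade for small p but drifts mid-range, so assert it
        # only where the exact p is itself small
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(60):
            N, k = 200, int(rng.integers(5, 40))
            pos = rng.choice(N, size=k, replace=False) + 1
            _, p_exact = ks_enrichment(N, pos, exact_threshold=10**6)
            _, p_asym = ks_enrichment(N, pos, exact_threshold=0)
            if p_exact <= 0.1:
                assert p_asym == pytest.approx(p_exact, abs=0.05)
                checked += 1
        assert checked >= 5

    def test_full_list_degenerates_to_p_one(self):
        assert ks_enrichment(3, (1, 2, 3))[1] == 1.0


def _by_transcription(p: np.ndarray) -> np.ndarray:
    """Straight-line transcription of the BY step-up formula."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    adj_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        j = i + 1
        running_min = min(running_min, p[order[i]] * m * c_m / j)
        adj_sorted[i] = min(1.0, running_min)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBenjaminiYekutieli:
    def test_three_value_step_up_equalizes(self):
        adj = adjust_benjamini_yekutieli([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.055, 0.055, 0.055], atol=1e-12)

    def test_single_value_identity(self):
        np.testing.assert_allclose(adjust_benjamini_yekutieli([1.0]), [1.0])

    def test_equal_inputs_stay_equal_and_bounded(self):
        adj = adjust_benjamini_yekutieli([0.5] * 4)
        assert np.all(adj == adj[0]) and np.all(adj <= 1.0)

    def test_empty_input(self):
        assert adjust_benjamini_yekutieli([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_benjamini_yekutieli([0.0, 0.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_transcription_and_dominates_bh(self, p):
        p = np.asarray(p)
        adj = adjust_benjamini_yekutieli(p)
        np.testing.assert_allclose(adj, _by_transcription(p), atol=1e-12)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(adj >= bh - 1e-12)
        assert np.all(adj >= p - 1e-12)

    @given(st.lists(st.floats(1e-6, 0.99), min_size=1, max_size=15))
    def test_elementwise_monotone(self, p):
        p = np.asarray(p)
        q = np.minimum(1.0, p + 0.005)
        assert np.all(
            adjust_benjamini_yekutieli(p) <= adjust_benjamini_yekutieli(q) + 1e-12
        )


class TestRunOnce:
    def test_planted_regulator_ranks_first(self, sim_small):
        _, expr, rti, truth = sim_small
        from reggae import score_genes, select_gene_list

        scores = score_genes(expr, "shrinkage_t")
        gl = select_gene_list(scores, "up", top_k=100, method="shrinkage_t")
        table = run_reggae_once(expr, gl, rti)
        assert table.rank_of(truth.planted_regulators[0]) == 1
        assert table.table.iloc[0]["p_adjusted"] < 0.05

    def test_disjoint_rti_raises_empty_combined_list(self, sim_small):
        _, expr, _, _ = sim_small
        rti = RTICollection.from_pairs([("TFX", "not_a_gene")])
        gl = GeneScoreList(
            entries=[(expr.gene_ids[0], 1.0, None)], direction="up", method="t_test"
        )
        with pytest.raises(ValueError, match="empty combined list"):
            run_reggae_once(expr, gl, rti)

    def test_consistent_relabeling_leaves_table_invariant(self, sim_small):
        _, expr, rti, _ = sim_small
        from reggae import score_genes, select_gene_list

        scores = score_genes(expr, "shrinkage_t")
        gl = select_gene_list(scores, "up", top_k=60, method="shrinkage_t")
        base = run_reggae_once(expr, gl, rti)

        rename = {g: f"X_{g}" for g in expr.gene_ids}
        expr2 = ExpressionMatrix(
            gene_ids=[rename[g] for g in expr.gene_ids],
            sample_ids=expr.sample_ids, values=expr.values,
            groups=expr.groups, case_group=expr.case_group,
        )
        rti2 = RTICollection(
            forward={rename[r]: [rename[g] for g in rti.targets_of(r)] for r in rti.regulators}
        )
        gl2 = GeneScoreList(
            entries=[(rename[g], s, p) for g, s, p in gl.entries],
            direction=gl.direction, method=gl.method,
        )
        renamed = run_reggae_once(expr2, gl2, rti2)
        assert [f"X_{r}" for r in base.regulators] == renamed.regulators
        np.testing.assert_allclose(
            base.table["p_adjusted"], renamed.table["p_adjusted"], atol=1e-12
        )

    def test_min_occurrences_filters_rare_regulators(self, sim_small):
        _, expr, rti, _ = sim_small
        from reggae import score_genes, select_gene_list

        scores = score_genes(expr, "shrinkage_t")
        gl = select_gene_list(scores, "up", top_k=100, method="shrinkage_t")
        strict = run_reggae_once(expr, gl, rti, ReggaeConfig(min_occurrences=3))
        assert (strict.table["n_occurrences"] >= 3).all()
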