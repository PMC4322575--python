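import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from cofreq.counting import AggregationMode, CoFrequencyMatrix, SingletonCounts
from cofreq.stats import (
    association_stats,
    contingency_table,
    enrichment,
    feature_groups,
)


class TestContingencyTable:
    @pytest.mark.parametrize(
        "f_x, f_y, f_xy, n, cells",
        [
            (0, 0, 0, 10, (0, 0, 0, 10)),
            (5, 5, 5, 5, (5, 0, 0, 0)),
            (30, 40, 10, 100, (10, 20, 30, 40)),
        ],
    )
    def test_cell_identities(self, f_x, f_y, f_xy, n, cells):
        t = contingency_table(f_x, f_y, f_xy, n)
        assert (t.a, t.b, t.c, t.d) == cells
        assert t.a + t.b + t.c + t.d == t.n

    @pytest.mark.parametrize(
        "f_x, f_y, f_xy, n",
        [
            (3, 5, 4, 100),   # f_xy > min margin
            (30, 90, 10, 100),  # union exceeds N
            (200, 5, 5, 100),   # margin exceeds N
        ],
    )
    def test_inconsistent_counts_rejected(self, f_x, f_y, f_xy, n):
        with pytest.raises(ValueError, match="inconsistent"):
            contingency_table(f_x, f_y, f_xy, n)


class TestAssociationStats:
    def test_exact_independence(self):
        t = contingency_table(10, 10, 1, 100)  # A=1,B=9,C=9,D=81
        res = association_stats(t)
        assert res.lift == pytest.approx(1.0)
        assert res.chi_squared == pytest.approx(0.0, abs=1e-12)
        assert res.g_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_cross_product_odds_ratio_matches_scipy(self):
        t = contingency_table(30, 40, 10, 100)
        res = association_stats(t)
        assert res.odds_ratio == pytest.approx((10 * 40) / (20 * 30))
        oracle = sps.contingency.odds_ratio(
            [[t.a, t.b], [t.c, t.d]], kind="sample"
        ).statistic
        assert res.odds_ratio == pytest.approx(oracle)

    def test_chain_rule_identity(self):
        for f_x, f_y, f_xy, n in [(30, 40, 10, 100), (7, 9, 3, 50), (5, 5, 5, 5)]:
            res = association_stats(contingency_table(f_x, f_y, f_xy, n))
            assert res.p_y_given_x * res.p_marginal_x == pytest.approx(res.p_joint)

    def test_lift_symmetry(self):
        res_xy = association_stats(contingency_table(30, 40, 10, 100))
        res_yx = association_stats(contingency_table(40, 30, 10, 100))
        assert res_xy.lift == pytest.approx(res_yx.lift)
        assert res_xy.lift == pytest.approx(
            res_xy.p_joint / (res_xy.p_marginal_x * res_xy.p_marginal_y)
        )

    def test_zero_cells_reported_undefined_not_infinite(self):
        res = association_stats(contingency_table(10, 10, 10, 100))  # B=C=0
        assert res.odds_ratio is None
        assert "odds_ratio_zero_denominator" in res.undefined

    def test_haldane_correction_opt_in(self):
        res = association_stats(
            contingency_table(10, 10, 10, 100), continuity_correction=True
        )
        assert res.odds_ratio == pytest.approx((10.5 * 90.5) / (0.5 * 0.5))

    def test_chi2_and_g_agree_on_large_balanced_table(self):
        # near-independence: expected A is 1250, observed 1300
        res = association_stats(contingency_table(5000, 5000, 1300, 20000))
        assert res.chi_squared > 0
        assert abs(res.chi_squared - res.g_statistic) / res.chi_squared < 0.01

    def test_chi2_matches_scipy_without_yates(self):
        t = contingency_table(30, 40, 10, 100)
        res = association_stats(t)
        chi2, _, _, _ = sps.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False
        )
        assert res.chi_squared == pytest.approx(chi2)
        g, _, _, _ = sps.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=False, lambda_="log-likelihood"
        )
        assert res.g_statistic == pytest.approx(g)


def _fixture_counts(pairs, singles, n, mode=AggregationMode.PER_BIN, width=7.0):
    return (
        CoFrequencyMatrix(counts=pairs, mode=mode, width=width, n=n),
        SingletonCounts(counts=singles, mode=mode, width=width, n=n),
    )


class TestFeatureGroups:
    def test_no_edges_all_singletons(self):
        m, s = _fixture_counts({(1, 2): 1}, {1: 50, 2: 50, 3: 10}, 100)
        groups = feature_groups(m, s, lift_threshold=2.0, min_count=10)
        assert groups == [[1], [2], [3]]

    def test_planted_pair_grouped(self):
        # lift = (30/100)/((40/100)*(25/100)) = 3
        m, s = _fixture_counts({(1, 2): 30}, {1: 40, 2: 25}, 100)
        groups = feature_groups(m, s, lift_threshold=2.0, min_count=10)
        assert [1, 2] in groups

    def test_chain_forms_one_component(self):
        m, s = _fixture_counts(
            {(1, 2): 30, (2, 3): 30}, {1: 40, 2: 40, 3: 40}, 1000
        )
        groups = feature_groups(m, s, lift_threshold=2.0, min_count=10)
        assert [1, 2, 3] in groups

    def test_mismatched_universe_rejected(self):
        m, _ = _fixture_counts({(1, 2): 5}, {}, 100)
        _, s = _fixture_counts({}, {1: 10, 2: 10}, 200)
        with pytest.raises(ValueError, match="share"):
            feature_groups(m, s)


class TestEnrichment:
    def test_tail_probability_matches_exhaustive_enumeration(self):
        """N=20 items, 5 carry the annotation, cohort of 4, observed 3:
        compare against brute-force enumeration of all C(20,4) cohorts."""
        n, k, draw, obs = 20, 5, 4, 3
        hits = total = 0
        carriers = set(range(k))
        for cohort in itertools.combinations(range(n), draw):
            total += 1
            if len(carriers.intersection(cohort)) >= obs:
                hits += 1
        expected_p = hits / total

        background = SingletonCounts(counts={1: k}, n=n)
        [rec] = enrichment({1: obs}, draw, background)
        assert rec.p_value == pytest.approx(expected_p)
        assert rec.expected == pytest.approx(draw * k / n)

    def test_null_cohort_fold_near_one(self):
        rng = np.random.default_rng(11)
        n, draw = 1000, 200
        f_y = 400
        obs = int(rng.hypergeometric(f_y, n - f_y, draw))
        background = SingletonCounts(counts={1: f_y}, n=n)
        [rec] = enrichment({1: obs}, draw, background)
        assert rec.fold == pytest.approx(1.0, abs=0.25)
        assert rec.p_value > 1e-4

    def test_dependency_adjustment_raises_expectation(self):
        # cohort selected on x; y co-occurs with x at a rate above its
        # background rate, so the adjusted expectation is larger and the
        # adjusted p-value less significant
        background = SingletonCounts(counts={1: 100, 2: 100}, n=1000)
        matrix = CoFrequencyMatrix(counts={(1, 2): 60}, n=1000)
        draw, obs = 50, 20
        [unadj] = [r for r in enrichment({2: obs}, draw, background) if r.entity_id == 2]
        [adj] = [
            r
            for r in enrichment(
                {2: obs}, draw, background, adjust_with=matrix, conditioning_id=1
            )
            if r.entity_id == 2
        ]
        assert adj.expected > unadj.expected
        assert adj.expected == pytest.approx(draw * 60 / 100)
        assert adj.p_value > unadj.p_value

    def test_conditioning_id_must_be_in_matrix(self):
        background = SingletonCounts(counts={1: 10, 2: 10}, n=100)
        matrix = CoFrequencyMatrix(counts={(2, 3): 5}, n=100)
        with pytest.raises(ValueError, match="absent from the co-frequency"):
            enrichment({2: 1}, 5, background, adjust_with=matrix, conditioning_id=1)

    def test_selected_size_cannot_exceed_universe(self):
        background = SingletonCounts(counts={1: 10}, n=100)
        with pytest.raises(ValueError, match="exceeds"):
            enrichment({1: 1}, 101, background)

    def test_bh_adjustment_monotone(self):
        background = SingletonCounts(counts={1: 50, 2: 500, 3: 5}, n=1000)
        records = enrichment({1: 30, 2: 60, 3: 2}, 100, background)
        for r in records:
            assert r.adjusted_p >= r.p_value - 1e-12
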