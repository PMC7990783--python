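"""Effect computation, continuity correction, pooling and heterogeneity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metaor
from metaor.effects import (
    EffectEstimate,
    NonEstimableError,
    continuity_correct,
    effect_from_cells,
    heterogeneity_stats,
    pool_fixed,
    pool_random,
    select_model,
)


def _effects_from_tables(tables):
    return [effect_from_cells(f"s{i}", t) for i, t in enumerate(tables)]


def _swap_arms(tables):
    return [(c, d, a, b) for a, b, c, d in tables]


# independently coded brute-force oracles -------------------------------

def _oracle_iv(theta, se):
    w = [1 / s**2 for s in se]
    mu = sum(wi * t for wi, t in zip(w, theta)) / sum(w)
    return mu, math.sqrt(1 / sum(w))


def _oracle_dl(theta, se):
    w = [1 / s**2 for s in se]
    mu_f, _ = _oracle_iv(theta, se)
    Q = sum(wi * (t - mu_f) ** 2 for wi, t in zip(w, theta))
    df = len(theta) - 1
    denom = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (Q - df) / denom)
    wr = [1 / (s**2 + tau2) for s in se]
    mu = sum(wi * t for wi, t in zip(wr, theta)) / sum(wr)
    return mu, math.sqrt(1 / sum(wr)), tau2


class TestContinuityCorrection:
    def test_zero_cell_study_gets_half_added_to_all_cells(self):
        cells, corrected = continuity_correct((39, 6, 0, 40))
        assert cells == (39.5, 6.5, 0.5, 40.5)
        assert corrected

    def test_study_without_zero_cell_unchanged(self):
        cells, corrected = continuity_correct((64, 7, 11, 112))
        assert cells == (64.0, 7.0, 11.0, 112.0)
        assert not corrected

    def test_policy_all_corrects_every_study(self):
        cells, corrected = continuity_correct((64, 7, 11, 112), policy="all")
        assert cells == (64.5, 7.5, 11.5, 112.5)
        assert corrected

    def test_double_zero_table_is_estimable_with_null_or(self):
        e = effect_from_cells("s", (0, 10, 0, 10))
        assert e.corrected
        assert e.log_or == pytest.approx(0.0)

    def test_empty_arm_is_non_estimable(self):
        with pytest.raises(NonEstimableError, match="empty arm"):
            continuity_correct((0, 0, 5, 5))

    def test_policy_none_with_zero_cell_is_non_estimable(self):
        with pytest.raises(NonEstimableError, match="zero cell"):
            continuity_correct((5, 0, 3, 7), policy="none")


class TestLogOddsRatio:
    def test_cross_product_arithmetic(self):
        e = effect_from_cells("wang", (64, 7, 11, 112))
        assert e.odds_ratio == pytest.approx(64 * 112 / (7 * 11), rel=1e-12)

    def test_symmetric_table(self):
        e = effect_from_cells("s", (5, 5, 5, 5))
        assert e.log_or == pytest.approx(0.0)
        assert e.se == pytest.approx(math.sqrt(0.8))

    def test_corrected_cells_used_for_zero_cell_study(self):
        e = effect_from_cells("zhou_t", (39, 6, 0, 40))
        assert e.odds_ratio == pytest.approx((39.5 * 40.5) / (6.5 * 0.5), rel=1e-12)


class TestFixedPooling:
    def test_iv_matches_bruteforce_oracle_small_k(self):
        rng = np.random.default_rng(42)
        for k in (1, 2, 3):
            theta = rng.normal(0.5, 1.0, k)
            se = rng.uniform(0.2, 1.5, k)
            effects = [EffectEstimate(f"s{i}", float(t), float(s), False)
                       for i, (t, s) in enumerate(zip(theta, se))]
            pooled = pool_fixed(effects, method="iv")
            mu, pooled_se = _oracle_iv(theta, se)
            assert pooled.log_or == pytest.approx(mu, abs=1e-12)
            assert pooled.se == pytest.approx(pooled_se, abs=1e-12)

    def test_two_identical_effects_halve_the_variance(self):
        effects = [EffectEstimate("a", 0.7, 0.3, False),
                   EffectEstimate("b", 0.7, 0.3, False)]
        pooled = pool_fixed(effects, method="iv")
        assert pooled.log_or == pytest.approx(0.7)
        assert pooled.se == pytest.approx(0.3 / math.sqrt(2))

    def test_mh_agrees_with_statsmodels_stratified_table(self, builtin_effects):
        StratifiedTable = pytest.importorskip(
            "statsmodels.stats.contingency_tables").StratifiedTable
        pooled = pool_fixed(builtin_effects, method="mh")
        tables = [np.array(e.cells).reshape(2, 2) for e in builtin_effects]
        st_ = StratifiedTable(tables)
        assert pooled.odds_ratio == pytest.approx(st_.oddsratio_pooled, rel=1e-12)
        assert pooled.se == pytest.approx(st_.logodds_pooled_se, rel=1e-12)

    def test_normalized_weights_sum_to_one(self, builtin_effects):
        pool_fixed(builtin_effects)
        pool_random(builtin_effects)
        assert sum(e.weight_fixed for e in builtin_effects) == pytest.approx(1.0)
        assert sum(e.weight_random for e in builtin_effects) == pytest.approx(1.0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no effects"):
            pool_fixed([])


class TestHeterogeneity:
    def test_single_study_degenerates_cleanly(self):
        het = heterogeneity_stats([EffectEstimate("s", 1.0, 0.5, False)])
        assert (het.Q, het.df, het.i2, het.tau2) == (0.0, 0, 0.0, 0.0)
        assert het.p_het == 1.0

    def test_dl_matches_statsmodels_combine_effects(self, builtin_effects):
        combine_effects = pytest.importorskip(
            "statsmodels.stats.meta_analysis").combine_effects
        theta = np.array([e.log_or for e in builtin_effects])
        var = np.array([e.se**2 for e in builtin_effects])
        res = combine_effects(theta, var, method_re="dl")
        het = heterogeneity_stats(builtin_effects, center="iv")
        assert het.tau2 == pytest.approx(res.tau2, rel=1e-10)
        rand = pool_random(builtin_effects, center="iv")
        assert rand.log_or == pytest.approx(res.mean_effect_re, rel=1e-10)

    def test_i2_and_tau2_zero_when_q_below_df(self):
        effects = [EffectEstimate("a", 0.5, 0.4, False),
                   EffectEstimate("b", 0.5, 0.4, False),
                   EffectEstimate("c", 0.5, 0.4, False)]
        het = heterogeneity_stats(effects)
        assert het.i2 == 0.0 and het.tau2 == 0.0

    def test_mh_centered_q_at_least_iv_centered(self, builtin_effects):
        # the IV summary minimizes the weighted sum of squares
        q_mh = heterogeneity_stats(builtin_effects, center="mh").Q
        q_iv = heterogeneity_stats(builtin_effects, center="iv").Q
        assert q_mh >= q_iv


class TestRandomPooling:
    def test_matches_bruteforce_dl_oracle_small_k(self):
        rng = np.random.default_rng(1)
        for k in (2, 3):
            theta = rng.normal(1.0, 1.2, k)
            se = rng.uniform(0.2, 1.0, k)
            effects = [EffectEstimate(f"s{i}", float(t), float(s), False)
                       for i, (t, s) in enumerate(zip(theta, se))]
            pooled = pool_random(effects, center="iv")
            mu, pooled_se, tau2 = _oracle_dl(theta, se)
            assert pooled.log_or == pytest.approx(mu, abs=1e-12)
            assert pooled.se == pytest.approx(pooled_se, abs=1e-12)
            assert pooled.het.tau2 == pytest.approx(tau2, abs=1e-12)

    def test_collapses_to_fixed_when_tau2_zero(self):
        effects = [EffectEstimate("a", 0.5, 0.4, False),
                   EffectEstimate("b", 0.6, 0.5, False)]
        fixed = pool_fixed(effects, method="iv")
        rand = pool_random(effects, center="iv")
        if rand.het.tau2 == 0.0:
            assert rand.log_or == pytest.approx(fixed.log_or, abs=1e-14)
            assert rand.se == pytest.approx(fixed.se, abs=1e-14)

    def test_random_se_at_least_fixed_iv_se(self, builtin_effects):
        fixed = pool_fixed(builtin_effects, method="iv")
        rand = pool_random(builtin_effects)
        assert rand.se >= fixed.se

    def test_ci_brackets_point_estimate(self, builtin_effects):
        for pooled in (pool_fixed(builtin_effects), pool_random(builtin_effects)):
            assert pooled.ci_low < pooled.odds_ratio < pooled.ci_high


class TestSymmetries:
    @pytest.mark.parametrize("pool", [
        lambda eff: pool_fixed(eff, method="iv"),
        lambda eff: pool_fixed(eff, method="mh"),
        pool_random,
    ], ids=["fixed-iv", "fixed-mh", "random"])
    def test_label_swap_negates_pooled_log_or(self, builtin, pool):
        tables = [r.counts for r in builtin]
        direct = pool(_effects_from_tables(tables))
        swapped = pool(_effects_from_tables(_swap_arms(tables)))
        assert swapped.log_or == pytest.approx(-direct.log_or, abs=1e-12)
        assert swapped.se == pytest.approx(direct.se, abs=1e-12)

    def test_permutation_invariance(self, builtin):
        tables = [r.counts for r in builtin]
        rng = np.random.default_rng(0)
        base_f = pool_fixed(_effects_from_tables(tables))
        base_r = pool_random(_effects_from_tables(tables))
        for _ in range(5):
            perm = [tables[i] for i in rng.permutation(len(tables))]
            assert pool_fixed(_effects_from_tables(perm)).log_or == \
                pytest.approx(base_f.log_or, abs=1e-12)
            assert pool_random(_effects_from_tables(perm)).log_or == \
                pytest.approx(base_r.log_or, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(
        st.tuples(st.floats(-3, 3), st.floats(0.05, 2.0)),
        min_size=2, max_size=10))
    def test_iv_pooled_estimate_is_convex_combination(self, pairs):
        effects = [EffectEstimate(f"s{i}", t, s, False)
                   for i, (t, s) in enumerate(pairs)]
        pooled = pool_fixed(effects, method="iv")
        lo, hi = min(t for t, _ in pairs), max(t for t, _ in pairs)
        assert lo - 1e-9 <= pooled.log_or <= hi + 1e-9


class TestModelSelection:
    @pytest.mark.parametrize("p_het,expected", [
        (0.73, "fixed"), (0.009, "random"), (0.05, "random"), (0.051, "fixed"),
    ])
    def test_q_test_rule_with_boundary_significant(self, p_het, expected):
        het = metaor.HetStats(Q=1.0, df=1, p_het=p_het, i2=0.0, tau2=0.0)
        assert select_model(het) == expected
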