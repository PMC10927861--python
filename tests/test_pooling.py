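import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from smdmeta import (
    DomainError,
    EffectSize,
    SimulationConfig,
    dl_tau2,
    effect_from_record,
    fixed_effect_pool,
    heterogeneity,
    i2_from_q,
    random_effects_pool,
    reml_tau2,
    simulate_ensemble,
    subgroup_analysis,
)
from smdmeta.pooling import q_partition


def effects_from(g, v):
    return [EffectSize(gi, vi) for gi, vi in zip(g, v)]


effect_lists = st.lists(
    st.tuples(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=0.01, max_value=2),
    ),
    min_size=2,
    max_size=25,
)


class TestFixedEffectPool:
    def test_identical_effects(self):
        for k in (1, 3, 10):
            effects = effects_from([0.5] * k, [0.1] * k)
            res = fixed_effect_pool(effects)
            assert res.estimate == pytest.approx(0.5)
            width = res.ci_high - res.estimate
            assert width == pytest.approx(1.959963984540054 * math.sqrt(0.1 / k))

    def test_equal_weight_average(self):
        res = fixed_effect_pool(effects_from([0.0, 1.0], [1.0, 1.0]))
        assert res.estimate == pytest.approx(0.5)

    def test_brute_force_weighted_mean(self):
        g = [0.2, -0.4, 1.1]
        v = [0.05, 0.3, 0.12]
        res = fixed_effect_pool(effects_from(g, v))
        num = sum(gi / vi for gi, vi in zip(g, v))
        den = sum(1 / vi for vi in v)
        assert res.estimate == pytest.approx(num / den, rel=1e-12)
        assert res.ci_high - res.ci_low == pytest.approx(
            2 * 1.959963984540054 / math.sqrt(den), rel=1e-9
        )

    def test_empty_raises(self):
        with pytest.raises(DomainError):
            fixed_effect_pool([])

    @given(data=effect_lists)
    @settings(max_examples=200)
    def test_estimate_within_range(self, data):
        effects = effects_from(*zip(*data))
        res = fixed_effect_pool(effects)
        gs = [e.g for e in effects]
        assert min(gs) - 1e-9 <= res.estimate <= max(gs) + 1e-9

    @given(data=effect_lists, seed=st.integers(0, 2**16))
    @settings(max_examples=100)
    def test_permutation_invariance(self, data, seed):
        effects = effects_from(*zip(*data))
        shuffled = list(effects)
        np.random.default_rng(seed).shuffle(shuffled)
        a = fixed_effect_pool(effects)
        b = fixed_effect_pool(shuffled)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
        assert a.p == pytest.approx(b.p, rel=1e-9)


class TestDlTau2:
    def test_homogeneous_truncates_to_zero(self):
        assert dl_tau2(effects_from([0.4] * 6, [0.1, 0.2, 0.3, 0.1, 0.2, 0.3])) == 0.0

    def test_two_study_hand_case(self):
        # Q = 2, df = 1, sum(w) = 2, sum(w^2)/sum(w) = 1 -> tau2 = 1
        assert dl_tau2(effects_from([0.0, 2.0], [1.0, 1.0])) == pytest.approx(1.0)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(11)
        k = 500
        v = np.full(k, 1e-4)
        g = rng.normal(0.0, 0.5, k) + rng.normal(0, np.sqrt(v))
        assert dl_tau2(effects_from(g, v)) == pytest.approx(0.25, abs=0.03)

    def test_k1_raises(self):
        with pytest.raises(DomainError):
            dl_tau2(effects_from([1.0], [0.5]))

    @given(data=effect_lists)
    @settings(max_examples=100)
    def test_matches_statsmodels(self, data):
        g, v = (np.array(x) for x in zip(*data))
        res = combine_effects(g, v, method_re="chi2")
        # statsmodels reports the untruncated moment estimate
        assert dl_tau2(effects_from(g, v)) == pytest.approx(
            max(0.0, res.tau2), abs=1e-10
        )


class TestRemlTau2:
    def test_homogeneous_near_zero(self):
        assert reml_tau2(effects_from([0.4] * 8, [0.2] * 8)) < 1e-6

    def test_recovery(self):
        rng = np.random.default_rng(5)
        k = 500
        v = np.full(k, 0.02)
        g = rng.normal(0.3, 0.5, k) + rng.normal(0, np.sqrt(v))
        assert reml_tau2(effects_from(g, v)) == pytest.approx(0.25, abs=0.04)


class TestRandomEffectsPool:
    def test_reduces_to_fixed_when_homogeneous(self):
        effects = effects_from([0.4] * 5, [0.1] * 5)
        fixed = fixed_effect_pool(effects)
        pooled, het = random_effects_pool(effects)
        assert het.tau2 == 0.0
        assert pooled.estimate == pytest.approx(fixed.estimate)
        assert pooled.ci_low == pytest.approx(fixed.ci_low)
        assert pooled.ci_high == pytest.approx(fixed.ci_high)

    @given(data=effect_lists)
    @settings(max_examples=150)
    def test_ci_at_least_as_wide_as_fixed(self, data):
        effects = effects_from(*zip(*data))
        fixed = fixed_effect_pool(effects)
        pooled, _ = random_effects_pool(effects)
        fixed_width = fixed.ci_high - fixed.ci_low
        random_width = pooled.ci_high - pooled.ci_low
        assert random_width >= fixed_width - 1e-12

    @given(data=effect_lists)
    @settings(max_examples=100)
    def test_matches_statsmodels(self, data):
        from hypothesis import assume

        g, v = (np.array(x) for x in zip(*data))
        res = combine_effects(g, v, method_re="chi2")
        assume(res.tau2 >= 0)  # statsmodels keeps untruncated tau2
        pooled, het = random_effects_pool(effects_from(g, v))
        assert pooled.estimate == pytest.approx(res.mean_effect_re, rel=1e-10)
        ci = res.conf_int(use_t=False)[1]
        assert pooled.ci_low == pytest.approx(ci[0], abs=1e-10)
        assert pooled.ci_high == pytest.approx(ci[1], abs=1e-10)
        assert het.Q == pytest.approx(res.q, rel=1e-10)
        assert het.I2 == pytest.approx(max(0.0, res.i2 * 100), abs=1e-8)

    def test_parameter_recovery(self):
        records, _ = simulate_ensemble(
            SimulationConfig(k=300, mu=0.33, tau2=0.1, seed=123)
        )
        effects = [effect_from_record(r) for r in records]
        pooled, _ = random_effects_pool(effects)
        assert pooled.estimate == pytest.approx(0.33, abs=0.05)

    def test_k1_raises(self):
        with pytest.raises(DomainError):
            random_effects_pool(effects_from([0.3], [0.1]))

    def test_ci_symmetric_about_estimate(self):
        pooled, _ = random_effects_pool(effects_from([0.1, 0.9, 0.4], [0.2, 0.1, 0.3]))
        assert pooled.estimate - pooled.ci_low == pytest.approx(
            pooled.ci_high - pooled.estimate, rel=1e-9
        )


class TestHeterogeneity:
    def test_q_equals_df_gives_zero_i2(self):
        assert i2_from_q(7.0, 7) == 0.0
        assert i2_from_q(5.0, 7) == 0.0  # truncation below df
        assert i2_from_q(0.0, 0) == 0.0

    def test_i2_formula(self):
        assert i2_from_q(100.0, 10) == pytest.approx(90.0)

    def test_p_value_is_chi2_tail(self):
        from scipy import stats

        effects = effects_from([0.0, 0.5, 1.5], [0.1, 0.2, 0.1])
        het = heterogeneity(effects)
        assert het.df == 2
        assert het.p_Q == pytest.approx(stats.chi2.sf(het.Q, 2))

    @given(
        data=effect_lists,
        a_scale=st.floats(min_value=0.1, max_value=10),
    )
    @settings(max_examples=100)
    def test_i2_invariant_to_effect_rescaling(self, data, a_scale):
        # measuring every outcome on a rescaled axis (g -> a g, var -> a^2 var)
        # leaves Q, and hence I2, unchanged
        g, v = (np.array(x) for x in zip(*data))
        before = heterogeneity(effects_from(g, v))
        after = heterogeneity(effects_from(a_scale * g, a_scale**2 * v))
        assert after.Q == pytest.approx(before.Q, rel=1e-9, abs=1e-9)
        assert after.I2 == pytest.approx(before.I2, abs=1e-6)


class TestQPartition:
    @given(data=effect_lists, seed=st.integers(0, 2**16))
    @settings(max_examples=100)
    def test_identity(self, data, seed):
        effects = effects_from(*zip(*data))
        rng = np.random.default_rng(seed)
        labels = [str(x) for x in rng.integers(0, 3, len(effects))]
        q_total, q_within, q_between = q_partition(effects, labels)
        assert q_total == pytest.approx(q_within + q_between, abs=1e-8)


class TestSubgroupAnalysis:
    def test_single_level_equals_overall_pool(self, small_ensemble):
        records, _ = small_ensemble
        records = [r for r in records if r.strain == "Arbor Acres"]
        table = subgroup_analysis(records, "strain")
        assert len(table.levels) == 1
        (level,) = table.levels
        overall, _ = random_effects_pool([effect_from_record(r) for r in records])
        assert level.pooled.estimate == pytest.approx(overall.estimate)

    def test_counts_sum_to_analysis_set(self, small_ensemble):
        records, _ = small_ensemble
        for moderator in ("strain", "leaf_type", "dose_bin", "phase_bin", "microbes"):
            table = subgroup_analysis(records, moderator)
            assert table.total_k == len(records)

    def test_moderator_shift_recovered(self):
        config = SimulationConfig(
            k=300,
            mu=0.0,
            tau2=0.05,
            seed=77,
            moderator_effects={("dose_bin", "0-5"): 0.3},
            level_probabilities={
                "dose_bin": {"0-5": 0.5, "6-10": 0.5, "11-14": 0.0}
            },
        )
        records, _ = simulate_ensemble(config)
        table = subgroup_analysis(records, "dose_bin")
        by_level = {lvl.level: lvl for lvl in table.levels}
        low, mid = by_level["0-5"], by_level["6-10"]
        assert low.pooled.estimate > mid.pooled.estimate
        assert low.pooled.ci_low <= 0.3 <= low.pooled.ci_high
        assert mid.pooled.ci_low <= 0.0 <= mid.pooled.ci_high

    def test_k1_level_reports_no_heterogeneity(self):
        config = SimulationConfig(k=9, mu=0.3, tau2=0.1, seed=5)
        records, _ = simulate_ensemble(config)
        records[0].strain = "Lohmann"
        for r in records[1:]:
            r.strain = "Arbor Acres"
        table = subgroup_analysis(records, "strain")
        by_level = {lvl.level: lvl for lvl in table.levels}
        assert by_level["Lohmann"].k == 1
        assert by_level["Lohmann"].het is None
        assert by_level["Arbor Acres"].het is not None

    def test_unknown_moderator(self, small_ensemble):
        records, _ = small_ensemble
        with pytest.raises(DomainError):
            subgroup_analysis(records, "bird_colour")

    def test_shared_control_warns(self):
        config = SimulationConfig(k=12, seed=2, shared_control_block=3)
        records, _ = simulate_ensemble(config)
        with pytest.warns(UserWarning, match="sharing a control"):
            subgroup_analysis(records, "dose_bin")
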