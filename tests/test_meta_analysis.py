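"""Effect-size construction, three-level REML pooling, heterogeneity
statistics and the sensitivity power analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cautionmeta import (
    EffectSize,
    PowerSpec,
    SynthConfig,
    UndefinedCorrelationError,
    build_effects,
    cochran_q,
    fit_three_level,
    generate_study,
    multilevel_i2,
    power_table,
    run_meta_pipeline,
    score_questionnaire,
    sensitivity_power,
    spearman_rho,
    to_fisher_z,
    typical_sampling_variance,
)


class TestSpearman:
    def test_monotone_map_is_perfect(self):
        assert spearman_rho([1, 2, 3, 4], [1, 4, 9, 16]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (-1, 1, -1, 1)
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_reversal(self):
        x = np.arange(10.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, np.log(y - y.min() + 1.0)) == pytest.approx(base)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        z, v = to_fisher_z(0.0, 68)
        assert z == 0.0
        assert v == pytest.approx(1.0 / 65.0)

    def test_log_form_oracle(self):
        # atanh(rho) = 0.5 * log((1+rho)/(1-rho))
        z, _ = to_fisher_z(0.5, 20)
        assert z == pytest.approx(0.5 * math.log(3.0), rel=1e-12)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            to_fisher_z(1.0, 20)
        with pytest.raises(ValueError):
            EffectSize(rho=-1.0, n=30, dataset_id="d", measure_id="m", subscale="s")


def _effects(zs, var, datasets):
    return [EffectSize(rho=math.tanh(z), n=int(round(1.0 / var + 3)), dataset_id=d,
                       measure_id=f"m{i}", subscale="s")
            for i, (z, d) in enumerate(zip(zs, datasets))]


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        eff = _effects([0.2, 0.2, 0.2], 0.01, ["a", "b", "c"])
        q, df, p = cochran_q(eff)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_hand_arithmetic(self):
        eff = _effects([0.1, 0.3], 0.01, ["a", "b"])
        q, df, p = cochran_q(eff)
        assert q == pytest.approx(2.0, rel=1e-6)
        assert df == 1

    def test_order_invariance(self):
        eff = _effects([0.1, 0.25, -0.05, 0.4], 0.02, list("abcd"))
        q1, *_ = cochran_q(eff)
        q2, *_ = cochran_q(eff[::-1])
        assert q1 == pytest.approx(q2)


class TestMultilevelI2:
    def test_no_heterogeneity(self):
        eff = _effects([0.1, 0.2, 0.3], 0.02, list("abc"))
        assert multilevel_i2(0.0, 0.0, eff) == (0.0, 0.0, 0.0)

    def test_equal_components_give_thirds(self):
        eff = _effects([0.1, 0.2, 0.3], 0.02, list("abc"))
        vt = typical_sampling_variance(eff)
        i2w, i2b, i2t = multilevel_i2(vt, vt, eff)
        assert i2w == pytest.approx(100.0 / 3.0)
        assert i2b == pytest.approx(100.0 / 3.0)
        assert i2t == pytest.approx(200.0 / 3.0)

    def test_components_sum_and_bounds(self):
        eff = _effects([0.0, 0.4, -0.2, 0.1], 0.015, ["a", "a", "b", "b"])
        i2w, i2b, i2t = multilevel_i2(0.01, 0.004, eff)
        assert i2t == pytest.approx(i2w + i2b)
        assert 0 <= i2w <= 100 and 0 <= i2b <= 100 and 0 <= i2t <= 100


def two_level_reml_oracle(zs, vs):
    """Independent scalar REML for the standard random-effects model."""
    zs, vs = np.asarray(zs, float), np.asarray(vs, float)
    k = len(zs)

    def nll(tau2):
        if tau2 < 0:
            return np.inf
        w = 1.0 / (vs + tau2)
        beta = np.sum(w * zs) / np.sum(w)
        ll = -0.5 * (np.sum(np.log(vs + tau2)) + math.log(np.sum(w))
                     + np.sum(w * (zs - beta) ** 2))
        return -ll

    res = minimize_scalar(nll, bounds=(0.0, 2.0), method="bounded",
                          options={"xatol": 1e-12})
    tau2 = float(res.x)
    w = 1.0 / (vs + tau2)
    beta = float(np.sum(w * zs) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return tau2, beta, se


class TestThreeLevelREML:
    def test_identical_effects_collapse(self):
        eff = _effects([0.15] * 4, 0.02, ["a", "a", "b", "b"])
        res = fit_three_level(eff)
        assert res.tau2_within == pytest.approx(0.0, abs=1e-8)
        assert res.tau2_between == pytest.approx(0.0, abs=1e-8)
        assert res.pooled_z == pytest.approx(0.15, abs=1e-8)
        assert res.i2_total == pytest.approx(0.0, abs=1e-4)

    def test_one_effect_per_dataset_equals_two_level_reml(self):
        zs = [0.05, 0.30, -0.10, 0.22, 0.11, -0.02]
        vs = [0.020, 0.015, 0.030, 0.010, 0.025, 0.018]
        eff = [EffectSize(rho=math.tanh(z), n=int(round(1 / v + 3)), dataset_id=f"d{i}",
                          measure_id=f"m{i}", subscale="s")
               for i, (z, v) in enumerate(zip(zs, vs))]
        vs_exact = [e.var_z for e in eff]
        zs_exact = [e.z for e in eff]
        tau2, beta, se = two_level_reml_oracle(zs_exact, vs_exact)
        res = fit_three_level(eff)
        # with one effect per dataset only the sum of the components is
        # identified; it must match the two-level heterogeneity
        assert res.tau2_within + res.tau2_between == pytest.approx(tau2, abs=1e-3)
        assert res.pooled_z == pytest.approx(beta, abs=1e-4)
        assert res.se_z == pytest.approx(se, rel=1e-3)

    def test_ci_contains_pooled_and_rho_in_open_interval(self):
        eff = _effects([0.3, 0.1, 0.6, 0.2, 0.4, 0.0], 0.02,
                       ["a", "a", "a", "b", "b", "b"])
        res = fit_three_level(eff)
        lo, hi = res.ci95_rho
        assert lo < res.pooled_rho < hi
        assert -1 < lo < hi < 1
        assert res.q_df == res.k - 1

    def test_single_effect_degenerates_gracefully(self):
        res = fit_three_level(_effects([0.2], 0.02, ["a"]))
        assert res.tau2_within == 0.0 and res.tau2_between == 0.0
        assert res.k == 1
        lo, hi = res.ci95_z
        assert lo < 0.2 < hi

    def test_knapp_hartung_widens_interval_under_heterogeneity(self):
        eff = _effects([0.5, -0.3, 0.45, -0.25, 0.6, -0.4], 0.01,
                       ["a", "b", "c", "d", "e", "f"])
        wald = fit_three_level(eff, ci_method="wald")
        kh = fit_three_level(eff, ci_method="knapp_hartung")
        assert (kh.ci95_z[1] - kh.ci95_z[0]) >= (wald.ci95_z[1] - wald.ci95_z[0])


class TestSensitivityPower:
    def test_published_triple(self):
        table = power_table(k=19, n_bar=68, alpha=0.05, power=0.80)
        assert table["detectable_rho"].tolist() == [0.09, 0.11, 0.16]

    def test_no_heterogeneity_closed_form(self):
        spec = PowerSpec(heterogeneity=0.0)
        rho = sensitivity_power(spec, rounded=False)
        assert rho == pytest.approx(0.0795, abs=5e-4)
        assert sensitivity_power(spec) == 0.08

    def test_monotone_in_heterogeneity_k_and_n(self):
        base = sensitivity_power(PowerSpec(), rounded=False)
        assert sensitivity_power(PowerSpec(heterogeneity="moderate"), rounded=False) > base
        assert sensitivity_power(PowerSpec(k=38), rounded=False) < base
        assert sensitivity_power(PowerSpec(n_bar=136), rounded=False) < base

    def test_simulation_cross_check(self):
        spec = PowerSpec(heterogeneity="moderate")
        closed = sensitivity_power(spec, rounded=False)
        sim = sensitivity_power(spec, rounded=False, method="simulation", n_mc=3000,
                                seed=5)
        assert sim == pytest.approx(closed, abs=0.02)

    def test_full_heterogeneity_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_power(PowerSpec(heterogeneity=1.0))


class TestPipeline:
    def test_single_task_single_dataset_one_effect_per_subscale(self, small_config):
        from cautionmeta import StudyDesign

        design = StudyDesign((small_config.design.datasets[0],))
        config = SynthConfig(design=design, seed=3)
        study = generate_study(config, behaviour=False)
        scores = score_questionnaire(study.questionnaire["dsA"])
        effects, results = run_meta_pipeline(study.truth_boundaries, scores)
        assert (effects.groupby("subscale").size() == 1).all()
        assert len(results) == 5
        for res in results.values():
            assert res.k == 1

    def test_default_design_yields_19_effects_per_subscale(self):
        config = SynthConfig(seed=9)
        study = generate_study(config, behaviour=False)
        scores = pd.concat([score_questionnaire(q)
                            for q in study.questionnaire.values()], ignore_index=True)
        effects, results = run_meta_pipeline(study.truth_boundaries, scores)
        assert (effects.groupby("subscale").size() == 19).all()
        for res in results.values():
            assert res.k == 19
            assert res.n_datasets == 5
            assert -1 < res.pooled_rho < 1

    def test_empty_join_rejected(self, small_config):
        study = generate_study(small_config, behaviour=False)
        scores = score_questionnaire(study.questionnaire["dsA"])
        scores["subject_id"] = "nobody_" + scores["subject_id"].astype(str)
        with pytest.raises(ValueError, match="join"):
            build_effects(study.truth_boundaries, scores)
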