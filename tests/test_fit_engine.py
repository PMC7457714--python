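"""Binning rules, deviance, random-start screening and Nelder-Mead
refinement of the quantile-based fitting procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cautionmeta import (
    BinnedData,
    BinSpec,
    DDMParams,
    FitOptions,
    ParameterMap,
    bin_condition,
    bin_rts,
    choose_error_mode,
    deviance,
    fit_participant_task,
    predict_proportions,
    quantile_edges,
    random_starts,
    refine,
    simulate_ddm,
)
from cautionmeta.fit_engine import PredictedProportions

SMOKE_OPTS = FitOptions(n_starts=30, n_refine=3, n_restarts=1, n_sim=1500,
                        nm_maxfev=25, pool_size=1 << 20)


class TestErrorMode:
    @pytest.mark.parametrize("count,mode", [
        (11, "full"), (25, "full"),
        (10, "reduced"), (8, "reduced"), (5, "reduced"),
        (4, "median"), (0, "median"),
    ])
    def test_thresholds(self, count, mode):
        assert choose_error_mode(count) == mode

    def test_negative_count_rejected(self):
        with pytest.raises(Exception):
            choose_error_mode(-1)


class TestBinning:
    def test_quantile_counts_forced_by_definition(self):
        rts = np.linspace(0.3, 1.2, 100)
        assert bin_rts(rts).tolist() == [10, 20, 20, 20, 20, 10]

    def test_single_observation(self):
        counts = bin_rts(np.array([0.5]))
        assert counts.sum() == 1
        assert (counts >= 0).all()

    def test_ties_match_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        rts = np.round(rng.gamma(4, 0.1, size=20), 2)  # heavy ties
        qs = (0.1, 0.3, 0.5, 0.7, 0.9)
        counts = bin_rts(rts, qs)
        edges = np.quantile(rts, qs)
        # independent sort-and-threshold: bin j holds (e_{j-1}, e_j]
        oracle = []
        lo = -np.inf
        for e in list(edges) + [np.inf]:
            oracle.append(int(np.sum((rts > lo) & (rts <= e))))
            lo = e
        assert counts.tolist() == oracle
        assert counts.sum() == 20

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_rts(np.array([]))

    @given(st.lists(st.floats(0.2, 3.0), min_size=1, max_size=200))
    def test_counts_always_sum_to_n(self, rts):
        assert bin_rts(np.array(rts)).sum() == len(rts)

    def test_condition_binning_chooses_mode_from_errors(self):
        rng = np.random.default_rng(1)
        rts = rng.gamma(4, 0.1, size=200) + 0.2
        correct = np.ones(200, bool)
        correct[:8] = False
        b = bin_condition(rts, correct)
        assert b.error_mode == "reduced"
        assert b.correct_counts.sum() == 192
        assert b.error_counts.sum() == 8
        assert b.n_trials == 200


class TestDeviance:
    def _binned_halves(self):
        return BinnedData(correct_counts=np.array([50, 50]),
                          correct_edges=np.array([0.5]), error_mode="median",
                          n_trials=100, error_count=0)

    def test_zero_at_exactly_matching_proportions(self):
        obs = self._binned_halves()
        pred = PredictedProportions(p_correct_bins=np.array([0.5, 0.5]), p_error=0.0)
        assert deviance(obs, pred, n_model_trials=10**9) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_g2(self):
        # 2*(50 ln(50/60) + 50 ln(50/40)) = 100 ln(25/24)
        obs = self._binned_halves()
        pred = PredictedProportions(p_correct_bins=np.array([0.6, 0.4]), p_error=0.0)
        assert deviance(obs, pred, n_model_trials=10**9) == pytest.approx(
            4.082199452025478, rel=1e-9)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8),
           st.integers(0, 2**31 - 1))
    def test_nonnegative(self, counts, seed):
        counts = np.array(counts)
        if counts.sum() == 0:
            counts[0] = 1
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(len(counts)))
        obs = BinnedData(correct_counts=counts,
                         correct_edges=np.arange(len(counts) - 1, dtype=float),
                         error_mode="median", n_trials=int(counts.sum()), error_count=0)
        pred = PredictedProportions(p_correct_bins=p, p_error=0.0)
        assert deviance(obs, pred, n_model_trials=10**9) >= -1e-9

    def test_shape_mismatch_rejected(self):
        obs = self._binned_halves()
        pred = PredictedProportions(p_correct_bins=np.array([0.3, 0.3, 0.4]), p_error=0.0)
        with pytest.raises(ValueError):
            deviance(obs, pred, n_model_trials=1000)

    def test_median_mode_penalises_median_discrepancy(self):
        obs = BinnedData(correct_counts=np.array([96]), correct_edges=np.array([]),
                         error_mode="median", n_trials=100, error_count=4,
                         median_error_rt=0.5)
        near = PredictedProportions(p_correct_bins=np.array([0.96]), p_error=0.04,
                                    median_error_rt=0.5)
        far = PredictedProportions(p_correct_bins=np.array([0.96]), p_error=0.04,
                                   median_error_rt=0.8)
        assert deviance(obs, far, 10**6) > deviance(obs, near, 10**6)


class TestRandomStarts:
    def test_default_count_and_bounds(self):
        b = np.array([[0.05, 0.25], [0.1, 0.6]])
        x = random_starts(b, seed=3)
        assert x.shape == (5000, 2)
        assert (x >= b[:, 0]).all() and (x <= b[:, 1]).all()

    def test_degenerate_bounds(self):
        x = random_starts(np.array([[0.2, 0.2]]), n=10, seed=0)
        assert np.all(x == 0.2)

    def test_reproducible(self):
        b = np.array([[0.0, 1.0]])
        assert np.array_equal(random_starts(b, 100, seed=9), random_starts(b, 100, seed=9))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(Exception):
            random_starts(np.array([[1.0, 0.0]]), n=5, seed=0)


class TestRefine:
    def test_recovers_quadratic_minimum(self):
        obj = lambda x: (x[0] - 1.0) ** 2 + (x[1] + 2.0) ** 2
        starts = [np.array([0.0, 0.0]), np.array([3.0, 1.0])]
        x, f, converged, trace = refine(starts, obj, n_restarts=2, maxfev=400)
        assert np.allclose(x, [1.0, -2.0], atol=1e-3)
        assert f < 1e-5
        assert converged

    def test_final_never_worse_than_initial(self):
        obj = lambda x: np.sin(5 * x[0]) + x[0] ** 2
        starts = [np.array([v]) for v in (-1.0, 0.0, 1.0)]
        x, f, _, trace = refine(starts, obj, n_restarts=1, maxfev=100)
        assert f <= min(t[0] for t in trace)

    def test_identical_starts_match_single_start(self):
        obj = lambda x: (x[0] - 0.3) ** 2
        one = refine([np.array([0.0])], obj, n_restarts=1, maxfev=100)
        many = refine([np.array([0.0])] * 15, obj, n_restarts=1, maxfev=100)
        assert many[1] == pytest.approx(one[1])
        assert np.allclose(many[0], one[0])


class TestParticipantFit:
    def test_smoke_runs_and_is_deterministic(self, ddm_trials_480):
        res1 = fit_participant_task(ddm_trials_480, model="ddm", options=SMOKE_OPTS, seed=5)
        res2 = fit_participant_task(ddm_trials_480, model="ddm", options=SMOKE_OPTS, seed=5)
        assert np.isfinite(res1.deviance)
        assert res1.deviance == res2.deviance
        assert res1.best_params == res2.best_params
        # refinement can never lose to the screening optimum
        assert res1.deviance <= res1.trace[0][0]

    def test_session_pooling_is_concatenation(self, ddm_trials_480):
        pooled = ddm_trials_480.copy()
        split = ddm_trials_480.copy()
        split["session"] = np.where(np.arange(len(split)) < len(split) // 2, 1, 2)
        r1 = fit_participant_task(pooled, model="ddm", options=SMOKE_OPTS, seed=5)
        r2 = fit_participant_task(split, model="ddm", options=SMOKE_OPTS, seed=5)
        assert r1.deviance == r2.deviance
        assert r1.best_params == r2.best_params

    def test_boundary_groups_per_instruction(self):
        frames = []
        for (instr, a), s in zip((("speed", 0.08), ("accuracy", 0.16)), (31, 32)):
            p = DDMParams(boundary_a=a, drift_v=0.35, nondecision_ter=0.3)
            df = simulate_ddm(p, 300, seed=s, instruction_block=instr)
            frames.append(df)
        trials = pd.concat(frames, ignore_index=True)
        res = fit_participant_task(trials, model="ddm",
                                   pmap=ParameterMap("per_instruction"),
                                   options=FitOptions(n_starts=60, n_refine=3,
                                                      n_restarts=1, n_sim=3000,
                                                      nm_maxfev=40, pool_size=1 << 20),
                                   seed=2)
        est = res.best_params["boundary"]
        assert set(est) == {"speed", "accuracy"}
        assert est["speed"] < est["accuracy"]

    def test_all_error_cell_rejected(self, ddm_trials_480):
        bad = ddm_trials_480.copy()
        bad["correct"] = False
        with pytest.raises(ValueError):
            fit_participant_task(bad, model="ddm", options=SMOKE_OPTS, seed=1)

    def test_dmc_smoke(self):
        from cautionmeta import DMCParams, simulate_dmc

        p = DMCParams(boundary_a=0.11, controlled_drift_mu_c=0.4)
        trials = pd.concat([simulate_dmc(p, c, 120, seed=3)
                            for c in ("congruent", "incongruent")], ignore_index=True)
        res = fit_participant_task(trials, model="dmc", options=SMOKE_OPTS, seed=4)
        assert np.isfinite(res.deviance)
        assert 0.05 <= res.best_params["boundary"]["all"] <= 0.25
        assert set(res.error_modes) == {("congruent", "both"), ("incongruent", "both")}
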