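"""Candidate grid, exponential-family fitting, evaluation metrics, selection."""

import numpy as np
import pytest

import paleoniche as pn
from paleoniche.envspace import EnvMatrix
from paleoniche.errors import InvalidParameterError
from paleoniche.suitability import expand_features, split_indices


class TestCandidateGrid:
    def test_two_variable_grid_size(self):
        specs = pn.candidate_grid(("a", "b"), pn.default_multipliers(),
                                  pn.FEATURE_CLASSES)
        assert len(specs) == 1 * 17 * 5

    def test_order_deterministic(self):
        a = pn.candidate_grid(("a", "b", "c"), [1.0, 2.0], ("q", "lq"))
        b = pn.candidate_grid(("a", "b", "c"), [1.0, 2.0], ("q", "lq"))
        assert a == b
        assert a[0].variables == ("a", "b")

    def test_empty_lists_rejected(self):
        with pytest.raises(InvalidParameterError):
            pn.candidate_grid(("a", "b"), [], ("q",))


class TestSplit:
    def test_sizes_and_exhaustive_disjoint(self):
        train, test = split_indices(40, 0.25, seed=1)
        assert len(test) == 10 and len(train) == 30
        assert sorted(np.concatenate([train, test])) == list(range(40))

    def test_seeded(self):
        assert np.array_equal(split_indices(20, 0.25, 3)[0],
                              split_indices(20, 0.25, 3)[0])


class TestFeatureExpansion:
    def test_letter_codes(self):
        Z = np.array([[1.0, 2.0, 3.0]])
        F, names = expand_features(Z, ("x", "y", "z"), "lqp")
        assert names == ["x", "y", "z", "x^2", "y^2", "z^2",
                         "x*y", "x*z", "y*z"]
        assert np.allclose(F, [[1, 2, 3, 1, 4, 9, 2, 3, 6]])


class TestFitSuitability:
    def test_background_raw_scores_sum_to_one(self, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        m = pn.fit_suitability(occ_env, background, spec)
        assert np.isclose(np.exp(m.log_raw(background)).sum(), 1.0, atol=1e-9)

    def test_no_signal_fit_is_flat(self, background):
        """Training on a random background subsample leaves ~zero weights and
        near-uniform suitability, increasingly so as the penalty grows.

        At multiplier 1 the 1/sqrt(n) penalty is the same order as the
        sampling noise of the presence feature means, so a little residual
        structure survives; by multiplier 4 the fit is flat.
        """
        rng = np.random.default_rng(0)
        idx = rng.choice(background.n_points, 30, replace=False)
        train = EnvMatrix(background.values[idx], background.var_names, "raw")
        ratios = []
        for mult in (1.0, 4.0):
            spec = pn.CandidateSpec(("t_cold", "t_warm", "npp"), mult, "lq")
            m = pn.fit_suitability(train, background, spec)
            raw = np.exp(m.log_raw(background))
            ratios.append(raw.max() / raw.min())
        assert ratios[1] <= ratios[0]
        m4 = pn.fit_suitability(
            train, background, pn.CandidateSpec(("t_cold", "t_warm", "npp"), 4.0, "lq"))
        assert np.abs(m4.lambdas).max() < 0.05
        assert ratios[1] < 1.5

    def test_l1_path_monotone(self, occ_env, background):
        """Stronger regularization never grows the weight l1-norm."""
        norms = []
        for mult in (0.5, 2.0, 8.0):
            spec = pn.CandidateSpec(("t_cold", "t_warm", "npp"), mult, "lqp")
            m = pn.fit_suitability(occ_env, background, spec)
            norms.append(np.abs(m.lambdas).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_prediction_contract(self, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "q")
        m = pn.fit_suitability(occ_env, background, spec)
        s = m.suitability(background)
        assert s.min() >= 0 and s.max() == 1.0
        # identical rows -> identical scores
        twice = EnvMatrix(np.vstack([background.values[:1]] * 2),
                          background.var_names, "raw")
        assert m.suitability(twice)[0] == m.suitability(twice)[1]

    def test_model_json_round_trip(self, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        m = pn.fit_suitability(occ_env, background, spec)
        back = pn.FittedModel.from_dict(m.to_dict())
        assert np.allclose(back.log_raw(background), m.log_raw(background))


class TestOmission:
    def test_extremes(self):
        assert pn.omission_rate(np.array([0.9, 0.8]), 0.5) == 0.0
        assert pn.omission_rate(np.array([0.1, 0.2]), 0.5) == 1.0

    def test_self_consistency_at_five_percent(self, rng):
        scores = rng.random(200)
        thr = pn.train_threshold(scores, 0.05)
        assert pn.omission_rate(scores, thr) <= 0.05 + 1 / 200


class TestPartialROC:
    def test_null_scores_near_random(self):
        """Random grid, random test points: AUC ratio ~ 1 and mostly
        non-significant p.

        The bootstrap ratio p is anticonservative by construction (the kept
        curve region conditions on sensitivity >= 1-E), so a minority of
        null runs still report p <= 0.05; the ratio itself stays near 1.
        """
        non_significant = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            grid = g.random(4000)
            test = g.choice(grid, 200)
            res = pn.partial_roc(test, grid, E=0.05, n_iter=200, seed=seed)
            assert 0.8 <= res.mean_auc_ratio <= 1.2
            non_significant += res.proc_p > 0.05
        assert non_significant >= 14

    def test_separable_case_always_better_than_random(self, rng):
        grid = rng.random(2000)
        top = np.quantile(grid, 0.99)
        test = grid[grid >= top][:10]
        res = pn.partial_roc(test, grid, E=0.05, n_iter=100, seed=0)
        assert res.proc_p == 0.0
        assert np.nanmin(res.ratios) > 1.0

    def test_iteration_count_recorded(self, rng):
        res = pn.partial_roc(rng.random(20), rng.random(500), n_iter=500, seed=1)
        assert len(res.ratios) == 500

    def test_constant_grid_rejected(self):
        with pytest.raises(InvalidParameterError, match="constant"):
            pn.partial_roc(np.array([0.5]), np.full(100, 0.3))


class TestAICc:
    def test_closed_form(self, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        m = pn.fit_suitability(occ_env, background, spec)
        m.lambdas = np.array([0.5, -0.2, 0.0, 0.0])  # k = 2
        val = pn.aicc(m, np.full(10, -1.0), n_occ=10)
        assert np.isclose(val, 2 * 2 + 2 * 10 + 2 * 2 * 3 / 7)  # 24 + 12/7 + ...

    def test_overparameterized_undefined(self, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        m = pn.fit_suitability(occ_env, background, spec)
        m.lambdas = np.ones(4)
        with pytest.raises(InvalidParameterError, match="AICc undefined"):
            pn.aicc(m, np.full(5, -1.0), n_occ=5)


class TestSelection:
    def _ev(self, proc_p, om, aic):
        e = pn.EvaluationResult(pn.CandidateSpec(("a", "b"), 1.0, "q"))
        e.proc_p, e.omission_rate, e.aicc = proc_p, om, aic
        return e

    def test_single_passing_candidate(self):
        sel = pn.select_models([self._ev(0.0, 0.0, 100.0)])
        assert len(sel.selected) == 1
        assert sel.stage_counts["selected"] == 1

    def test_omission_filter(self):
        sel = pn.select_models([self._ev(0.0, 0.07, 100.0),
                                self._ev(0.0, 0.0, 105.0)])
        assert sel.stage_counts["low_omission"] == 1
        assert len(sel.selected) == 1

    def test_delta_aicc_band_keeps_both(self):
        sel = pn.select_models([self._ev(0.0, 0.0, 100.0),
                                self._ev(0.0, 0.0, 101.5)])
        assert len(sel.selected) == 2

    def test_delta_recomputed_among_survivors(self):
        """A non-significant model with the lowest AICc must not anchor ΔAICc."""
        sel = pn.select_models([self._ev(0.9, 0.0, 90.0),
                                self._ev(0.0, 0.0, 100.0),
                                self._ev(0.0, 0.0, 101.0)])
        assert len(sel.selected) == 2

    def test_empty_selection_reported_with_counts(self):
        sel = pn.select_models([self._ev(0.9, 0.5, 100.0)])
        assert sel.selected == []
        assert sel.stage_counts["significant"] == 0


class TestFinalModels:
    def test_replicate_count_and_median(self, scenario, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        models = pn.final_models(spec, occ_env, background, n_reps=10, seed=0)
        assert len(models) == 10
        median, reps = pn.median_suitability(models, scenario)
        assert len(reps) == 10
        stack = np.stack([g.scores for g in reps])
        r, c = np.nonzero(scenario.mask)
        assert np.allclose(median.scores[r, c], np.median(stack[:, r, c], axis=0))

    def test_single_replicate_median_is_itself(self, scenario, occ_env, background):
        spec = pn.CandidateSpec(("t_cold", "npp"), 1.0, "lq")
        models = pn.final_models(spec, occ_env, background, n_reps=1, seed=0)
        median, reps = pn.median_suitability(models, scenario)
        assert np.array_equal(median.scores[scenario.mask],
                              reps[0].scores[scenario.mask])

    def test_cellwise_median_example(self):
        assert np.median([0.2, 0.4, 0.9]) == 0.4
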