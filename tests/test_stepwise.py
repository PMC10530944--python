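import numpy as np
import pytest
from scipy import stats

from eigenstep import (
    CollinearityError,
    LabelVector,
    StepwiseConfig,
    ValidationError,
    fld_weights,
    partial_statistic,
    run_stepwise,
)
from conftest import make_class_instance


def ols_partial_t_oracle(x_full: np.ndarray, y: np.ndarray, col: int):
    """Squared partial t of one coefficient from an explicit OLS fit.

    ``x_full`` excludes the intercept; it is prepended here.  Returns
    (t^2, two-sided p), the classical single-response partial F.
    """
    design = np.column_stack([np.ones(len(y)), x_full])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(y) - design.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    j = col + 1  # skip intercept
    t = coef[j] / np.sqrt(cov[j, j])
    return t**2, 2 * stats.t.sf(abs(t), dof)


class TestLabelVector:
    def test_indicator_is_one_hot(self):
        lv = LabelVector(np.array([0, 2, 1, 2]), 3)
        ind = lv.indicator
        assert ind.sum(axis=1).tolist() == [1, 1, 1, 1]
        assert ind[1, 2] == 1.0

    def test_missing_class_rejected(self):
        with pytest.raises(ValidationError):
            LabelVector(np.array([0, 0, 2]), 3)


class TestFldWeights:
    def test_identity_design_returns_response(self):
        y = np.array([0, 1, 0, 1])
        weights = fld_weights(np.eye(4), LabelVector(y, 2))
        assert np.allclose(weights[:, 1], y)

    def test_single_column_hand_example(self):
        """M = (1,2,3)', y = (1,2,3): (M'M)^-1 M'y = 14/14 = 1."""
        m = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 3.0])
        weights, _, _, _ = np.linalg.lstsq(m, y[:, None], rcond=None)
        assert weights[0, 0] == pytest.approx(1.0)
        # package route on an equivalent 2-class indicator problem
        w = fld_weights(m, LabelVector(np.array([0, 1, 1]), 2))
        oracle = np.linalg.inv(m.T @ m) @ m.T @ np.array([[1, 0], [0, 1], [0, 1]])
        assert np.allclose(w, oracle, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        m = rng.standard_normal((20, 4))
        y = rng.integers(0, 3, size=20)
        y[:3] = [0, 1, 2]
        lv = LabelVector(y, 3)
        w = fld_weights(m, lv)
        oracle = np.linalg.inv(m.T @ m) @ m.T @ lv.indicator
        assert np.allclose(w, oracle, atol=1e-8)

    def test_rank_deficient_design_warns_and_returns_min_norm(self):
        m = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        lv = LabelVector(np.array([0, 0, 0, 1, 1, 1]), 2)
        with pytest.warns(UserWarning, match="rank deficient"):
            w = fld_weights(m, lv)
        assert np.all(np.isfinite(w))

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValidationError):
            fld_weights(np.empty((4, 0)), LabelVector(np.array([0, 1, 0, 1]), 2))


class TestPartialStatistic:
    def test_two_class_reduction_equals_squared_partial_t(self):
        """Wilks partial F == squared partial t on 20 random 2-class instances."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            x, y = make_class_instance(rng, n=30, p=4, n_classes=2,
                                       informative=(0,), effect=1.5)
            selected = [0, 2]
            candidate = 3
            f_stat, p_val = partial_statistic(x, selected, candidate, y, "enter")
            t2, p_oracle = ols_partial_t_oracle(
                x[:, [0, 2, 3]], (y == 0).astype(float), col=2
            )
            assert abs(f_stat - t2) < 1e-8
            assert abs(p_val - p_oracle) < 1e-8

    def test_orthogonal_candidate_has_null_statistic(self):
        """A candidate orthogonal to the indicator residuals contributes nothing."""
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 1])
        rng = np.random.default_rng(3)
        x0 = rng.standard_normal(12)
        resid = (y == 0).astype(float) - (y == 0).mean()
        # remove the candidate's projection onto the intercept-model residuals
        cand = rng.standard_normal(12)
        cand -= cand @ resid / (resid @ resid) * resid
        x = np.column_stack([x0, cand])
        f_stat, p_val = partial_statistic(x, [], 1, y, "enter")
        assert f_stat == pytest.approx(0.0, abs=1e-8)
        assert p_val == pytest.approx(1.0, abs=1e-8)

    def test_perfect_separator_is_overwhelmingly_significant(self):
        y = np.repeat([0, 1, 2], 10)
        x = np.column_stack([
            y.astype(float),  # noise-free separator
            np.random.default_rng(4).standard_normal(30),
        ])
        _, p_val = partial_statistic(x, [], 0, y, "enter")
        assert p_val < 1e-6

    def test_remove_mode_mirrors_enter_mode(self):
        rng = np.random.default_rng(5)
        x, y = make_class_instance(rng, n=40, p=5, n_classes=3,
                                   informative=(1,), effect=2.0)
        f_enter, p_enter = partial_statistic(x, [0, 2], 3, y, "enter")
        f_remove, p_remove = partial_statistic(x, [0, 2, 3], 3, y, "remove")
        assert f_enter == pytest.approx(f_remove, abs=1e-10)
        assert p_enter == pytest.approx(p_remove, abs=1e-10)

    def test_perfectly_fitted_reduced_model_raises_collinearity(self):
        """A selected set that already fits the labels exactly is degenerate."""
        y = np.arange(20) % 2
        x = np.column_stack([
            (y == 0).astype(float),  # exact indicator: zero residuals
            np.random.default_rng(6).standard_normal(20),
        ])
        with pytest.raises(CollinearityError, match="feature 1"):
            partial_statistic(x, [0], 1, y, "enter")

    def test_scale_invariance_of_partial_f(self):
        rng = np.random.default_rng(7)
        x, y = make_class_instance(rng, n=50, p=4, n_classes=3,
                                   informative=(0, 1), effect=2.0)
        f_a, p_a = partial_statistic(x, [0], 2, y, "enter")
        scaled = x.copy()
        scaled[:, 2] *= 1000.0
        f_b, p_b = partial_statistic(scaled, [0], 2, y, "enter")
        assert f_a == pytest.approx(f_b, rel=1e-9)
        assert p_a == pytest.approx(p_b, rel=1e-9)

    def test_mode_and_membership_validation(self):
        x = np.random.default_rng(8).standard_normal((12, 3))
        y = np.arange(12) % 2
        with pytest.raises(ValidationError):
            partial_statistic(x, [0], 0, y, "enter")
        with pytest.raises(ValidationError):
            partial_statistic(x, [0], 1, y, "remove")
        with pytest.raises(ValidationError):
            partial_statistic(x, [0], 1, y, "sideways")


class TestStepwiseConfig:
    def test_defaults_are_the_operating_thresholds(self):
        cfg = StepwiseConfig()
        assert cfg.alpha_enter == 0.35
        assert cfg.alpha_remove == 0.40
        assert cfg.max_features == 125

    def test_screening_preset(self):
        cfg = StepwiseConfig.screening_preset()
        assert (cfg.alpha_enter, cfg.alpha_remove) == (0.15, 0.20)

    def test_cycling_prone_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            StepwiseConfig(alpha_enter=0.5, alpha_remove=0.3)


class TestRunStepwise:
    def test_zero_cap_returns_empty_selection(self):
        x, y = make_class_instance(np.random.default_rng(9), informative=(0,))
        result = run_stepwise(x, y, StepwiseConfig(max_features=0))
        assert result.selected == []
        assert result.terminated_reason == "cap-reached"

    def test_planted_features_selected_first(self):
        """Two features carrying all signal are picked, and picked first."""
        rng = np.random.default_rng(10)
        x, y = make_class_instance(rng, n=200, p=10, n_classes=4,
                                   informative=(0, 1), effect=3.0)
        result = run_stepwise(x, y, StepwiseConfig())
        assert {0, 1} <= set(result.selected)
        first_two = [r.feature_id for r in result.trace[:2]]
        assert set(first_two) == {0, 1}
        # exhaustive best-subset oracle of size 2: smallest Wilks lambda
        # (residual scatter determinant) of the pairwise indicator regression
        indicator = np.zeros((len(y), 4))
        indicator[np.arange(len(y)), y] = 1.0
        response = indicator[:, :3]
        best_pair, best_det = None, np.inf
        for i in range(10):
            for j in range(i + 1, 10):
                design = np.column_stack([np.ones(len(y)), x[:, [i, j]]])
                coef, _, _, _ = np.linalg.lstsq(design, response, rcond=None)
                resid = response - design @ coef
                det = np.linalg.det(resid.T @ resid)
                if det < best_det:
                    best_det, best_pair = det, {i, j}
        assert best_pair == {0, 1}

    def test_first_selection_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x, y = make_class_instance(rng, n=60, p=6,
                                       n_classes=int(rng.integers(2, 5)),
                                       informative=(0,), effect=2.0)
            result = run_stepwise(x, y, StepwiseConfig(backward=False,
                                                       max_features=1))
            pvals = [partial_statistic(x, [], j, y, "enter")[1] for j in range(6)]
            assert result.trace[0].feature_id == int(np.argmin(pvals))

    def test_trace_replay_is_deterministic(self):
        rng = np.random.default_rng(13)
        x, y = make_class_instance(rng, n=80, p=8, n_classes=3,
                                   informative=(2, 5), effect=1.0)
        a = run_stepwise(x, y, StepwiseConfig())
        b = run_stepwise(x, y, StepwiseConfig())
        assert [r.to_dict() for r in a.trace] == [r.to_dict() for r in b.trace]
        assert a.selected == b.selected

    def test_selection_invariant_to_feature_scaling(self):
        rng = np.random.default_rng(14)
        x, y = make_class_instance(rng, n=100, p=6, n_classes=3,
                                   informative=(1, 3), effect=2.0)
        base = run_stepwise(x, y, StepwiseConfig())
        scaled = x.copy()
        scaled[:, 3] *= 1000.0
        assert run_stepwise(scaled, y, StepwiseConfig()).selected == base.selected

    def test_enter_records_respect_alpha_enter(self):
        rng = np.random.default_rng(15)
        x, y = make_class_instance(rng, n=80, p=8, n_classes=3,
                                   informative=(0,), effect=2.0)
        cfg = StepwiseConfig()
        result = run_stepwise(x, y, cfg)
        for record in result.trace:
            if record.action == "enter":
                assert record.p_value < cfg.alpha_enter
            elif record.action == "remove":
                assert record.p_value > cfg.alpha_remove
        assert len(result.selected) == len(set(result.selected))
        assert len(result.selected) <= cfg.max_features

    def test_more_classes_than_samples_rejected(self):
        with pytest.raises(ValidationError):
            run_stepwise(np.zeros((3, 2)), np.array([0, 1, 2]), StepwiseConfig())
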