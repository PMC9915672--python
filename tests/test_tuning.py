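import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcode.models import evaluate_model
from popcode.tuning import (
    INTERMEDIATE_LEVELS,
    ResponseLevelCurve,
    classify,
    curve_from_table,
    fit_curve,
    fit_table,
    interpolated_error,
    mcfadden_objective,
    monotonicity_index,
)

LEVELS = np.array([0.0, 30.0, 50.0, 60.0, 70.0, 80.0, 90.0])


def curve(mean, sem=0.1):
    mean = np.asarray(mean, dtype=float)
    sem = np.full_like(mean, sem) if np.isscalar(sem) else np.asarray(sem)
    return ResponseLevelCurve(LEVELS, mean, sem)


class TestMonotonicityIndex:
    def test_strictly_increasing_curve_is_one(self):
        assert monotonicity_index(curve(np.linspace(0, 1, 7))) == pytest.approx(1.0)

    def test_peaked_curve_returning_to_baseline_is_zero(self):
        assert monotonicity_index(curve([0, 0.3, 0.8, 1, 0.8, 0.3, 0])) == pytest.approx(0.0)

    def test_direct_formula_example(self):
        # (0.1 - 0) / (1 - 0) = 0.1
        assert monotonicity_index(curve([0, 0.2, 0.5, 1, 0.5, 0.2, 0.1])) == pytest.approx(0.1)

    def test_flat_curve_undefined(self):
        assert np.isnan(monotonicity_index(curve([0.5] * 7)))

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_positive_affine_invariance(self, a, b):
        m = np.array([0, 0.2, 0.5, 1, 0.5, 0.2, 0.1])
        assert monotonicity_index(curve(a * m + b)) == pytest.approx(
            monotonicity_index(curve(m))
        )


@pytest.mark.parametrize(
    "mi,want",
    [(0.1, "nonmonotonic"), (0.9, "monotonic"), (0.5, "ambiguous"), (0.3, "ambiguous"), (0.7, "ambiguous")],
)
def test_classification_thresholds(mi, want):
    assert classify(mi) == want


class TestMcFaddenObjective:
    def test_perfect_fit_is_zero(self):
        p = (0.1, 2.4, 60.0, 5.0)
        c = curve(evaluate_model("sigmoid", p, LEVELS), sem=[0.1, 0.2, 0.05, 0.3, 0.1, 0.15, 0.2])
        assert mcfadden_objective(p, "sigmoid", c) == pytest.approx(0.0, abs=1e-12)

    def test_intercept_model_is_exactly_one(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, 7)
        sem = rng.uniform(0.05, 0.4, 7)
        c = ResponseLevelCurve(LEVELS, m, sem)
        grand = m.mean()
        # a "model" that returns the grand mean at every level: flat sigmoid
        flat = (grand, 0.0, 50.0, 10.0)
        assert mcfadden_objective(flat, "sigmoid", c) == pytest.approx(1.0)

    def test_uniform_sem_rescaling_cancels(self):
        p = (0.0, 1.0, 55.0, 8.0)
        m = evaluate_model("sigmoid", (0.1, 0.9, 50.0, 10.0), LEVELS)
        a = mcfadden_objective(p, "sigmoid", curve(m, sem=0.1))
        b = mcfadden_objective(p, "sigmoid", curve(m, sem=0.05))
        assert a == pytest.approx(b)


class TestFitCurve:
    def test_noise_free_sigmoid_recovery(self):
        p = (0.1, 2.4, 60.0, 5.0)
        c = curve(evaluate_model("sigmoid", p, LEVELS), sem=0.1)
        fit = fit_curve(c, seed=0)
        assert fit.kind == "sigmoid" and fit.accepted
        assert fit.mcfadden_r2 > 0.999
        np.testing.assert_allclose(fit.params, p, rtol=0.01)

    def test_noise_free_gaussian_recovery(self):
        p = (0.15, 3.8, 49.0, 9.0)
        c = curve(evaluate_model("gaussian", p, LEVELS), sem=0.1)
        fit = fit_curve(c, seed=0)
        assert fit.kind == "gaussian" and fit.accepted
        np.testing.assert_allclose(fit.params, p, rtol=0.02)

    def test_out_of_range_gaussian_mean_refit_as_sigmoid(self):
        # peak below the sampled range: nonmonotonic class, gaussian mean ~5 dB
        p = (0.0, 1.0, 5.0, 13.0)
        c = curve(evaluate_model("gaussian", p, LEVELS), sem=0.05)
        fit = fit_curve(c, seed=1)
        assert fit.refit_from_gaussian
        assert fit.kind == "sigmoid"

    def test_determinism_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        c = curve(evaluate_model("sigmoid", (0, 1, 55, 10), LEVELS) + rng.normal(0, 0.1, 7))
        f1, f2 = fit_curve(c, seed=7), fit_curve(c, seed=7)
        assert f1 == f2

    def test_flat_curve_yields_unfit_result(self):
        fit = fit_curve(curve([0.3] * 7), seed=0)
        assert fit.kind is None and not fit.accepted


class TestInterpolatedError:
    def test_linear_regime_sigmoid_scores_one(self):
        # very wide sigmoid is nearly linear across the sampled levels
        assert interpolated_error("sigmoid", (0, 1, 45, 200.0), LEVELS) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_narrow_gaussian_scores_low(self):
        # narrow peak centred between sampled levels: the analytic curve
        # spikes where the interpolant cannot follow
        val = interpolated_error("gaussian", (0, 1, 55.0, 4.0), LEVELS)
        assert val < 0.25
        val = interpolated_error("gaussian", (0, 1, 55.0, 3.0), LEVELS)
        assert val < 0.0

    def test_matches_brute_force_oracle(self):
        p = (0.1, 2.4, 60.0, 5.0)
        dense = np.sort(np.concatenate([LEVELS, INTERMEDIATE_LEVELS]))
        anchors = evaluate_model("sigmoid", p, LEVELS)
        interp = np.interp(dense, LEVELS, anchors)
        model = evaluate_model("sigmoid", p, dense)
        want = 1 - np.sum((model - interp) ** 2) / np.sum((interp - interp.mean()) ** 2)
        assert interpolated_error("sigmoid", p, LEVELS) == pytest.approx(want)


def test_fit_table_round_trip(small_population):
    """Table-level fitting recovers each neuron's generative kind at no laser."""
    _, truth, table = small_population
    fits = fit_table(table[table.laser == "none"], seed=3)
    fits = fits.sort_values("neuron_id")
    assert (fits["kind"] == list(truth.kinds)).mean() >= 5 / 6
    assert fits["accepted"].mean() >= 5 / 6


def test_curve_from_table(small_population):
    _, _, table = small_population
    c = curve_from_table(table, 0, "none")
    assert len(c.levels) == 7 and (c.sem >= 0).all()
    with pytest.raises(ValueError):
        curve_from_table(table, 99, "none")
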