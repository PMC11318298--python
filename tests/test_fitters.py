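"""NLLS fitting strategies: round-trips, closed-form steps, boundary flags."""

import numpy as np
import pytest

from ivimfit import (
    DecayCurve,
    FitBounds,
    IVIMParams,
    fit_1step,
    fit_2step,
    fit_3step,
    fit_all_methods,
    ivim_signal,
)

from .conftest import interior_truths, noiseless_curve


def grid_search_objective(curve, bounds, n=50):
    """Exhaustive objective minimum over an n^3 grid of the bounded box."""
    b, y = curve.b_values, curve.signal
    f_ax = np.linspace(*bounds.f_range, n)
    ds_ax = np.linspace(*bounds.Dstar_range, n)
    d_ax = np.linspace(*bounds.D_range, n)
    e_s = np.exp(-np.outer(ds_ax, b))
    e_d = np.exp(-np.outer(d_ax, b))
    G = (
        f_ax[:, None, None, None] * e_s[None, :, None, :]
        + (1 - f_ax[:, None, None, None]) * e_d[None, None, :, :]
    ).reshape(-1, b.size)
    sse = ((G - y) ** 2).sum(axis=1)
    best = int(np.argmin(sse))
    f_i, rest = divmod(best, n * n)
    ds_i, d_i = divmod(rest, n)
    return float(sse[best]), np.array([f_ax[f_i], ds_ax[ds_i], d_ax[d_i]])


class TestOneStep:
    def test_noiseless_roundtrip(self, bounds):
        truth = IVIMParams(0.15, 40.7e-3, 1.33e-3)
        r = fit_1step(noiseless_curve(truth), bounds)
        np.testing.assert_allclose(r.params.as_array(), truth.as_array(), rtol=1e-6)
        assert r.converged and not r.any_at_boundary

    def test_degenerate_mono_exponential(self, bounds):
        truth = IVIMParams(0.0, 0.02, 1.2e-3)
        r = fit_1step(noiseless_curve(truth), bounds)
        assert r.params.f < 1e-6
        assert r.params.D == pytest.approx(1.2e-3, abs=1e-8)

    def test_saturating_f_is_flagged_and_grid_confirms_boundary(self, bounds, b_protocol):
        # generated beyond the admissible range: the optimum inside the box
        # must sit on the f = 0.5 face
        truth = IVIMParams(0.6, 30e-3, 1.3e-3)
        curve = noiseless_curve(truth)
        r = fit_1step(curve, bounds)
        assert r.at_boundary["f"]
        assert r.params.f == pytest.approx(bounds.f_range[1], abs=1e-12)
        _, grid_best = grid_search_objective(curve, bounds)
        assert grid_best[0] == bounds.f_range[1]

    def test_objective_not_worse_than_grid_search(self, bounds, b_protocol):
        rng = np.random.default_rng(12)
        for _ in range(5):
            truth = IVIMParams(rng.uniform(0.05, 0.45), rng.uniform(5e-3, 0.4), rng.uniform(2e-4, 2.4e-3))
            y = ivim_signal(truth, b_protocol) + rng.normal(0, 1 / 45, b_protocol.size)
            curve = DecayCurve(b_protocol, y)
            r = fit_1step(curve, bounds)
            grid_obj, _ = grid_search_objective(curve, bounds)
            assert r.resid_sq_norm <= grid_obj + 1e-12

    def test_too_few_points(self, bounds):
        with pytest.raises(ValueError):
            fit_1step(DecayCurve([0.0, 10.0, 700.0], [1.0, 0.99, 0.4]), bounds)


class TestTwoStep:
    def test_noiseless_roundtrip(self, bounds):
        truth = IVIMParams(0.11, 32.4e-3, 1.37e-3)
        r = fit_2step(noiseless_curve(truth), bounds)
        # truncation of the pseudo-diffusion tail above the cutoff leaves a
        # systematic residual of order 1e-3 relative on D*
        np.testing.assert_allclose(r.params.as_array(), truth.as_array(), rtol=2e-3)
        assert r.intercept_A is not None

    def test_mono_exponential_gives_zero_f(self, bounds):
        truth = IVIMParams(0.0, 0.02, 1.4e-3)
        r = fit_2step(noiseless_curve(truth), bounds)
        assert r.params.D == pytest.approx(1.4e-3, rel=1e-6)
        assert r.params.f < 1e-4

    def test_step_a_matches_two_point_log_slope(self, bounds):
        # mono-exponential sampled at exactly two high-b shells: NLLS step A
        # must land on the closed-form log-ratio slope
        b = np.array([0.0, 300.0, 700.0])
        D_true = 1.9e-3
        s = np.exp(-b * D_true)
        r = fit_2step(DecayCurve(b, s), bounds)
        closed_form = np.log(s[1] / s[2]) / (b[2] - b[1])
        assert r.params.D == pytest.approx(closed_form, rel=1e-6)

    def test_needs_two_high_b_points(self, bounds):
        with pytest.raises(ValueError):
            fit_2step(DecayCurve([0.0, 10.0, 300.0], [1.0, 0.99, 0.6]), bounds)


class TestThreeStep:
    def test_noiseless_roundtrip(self, bounds, muscle_params):
        r = fit_3step(noiseless_curve(muscle_params), bounds)
        np.testing.assert_allclose(r.params.as_array(), muscle_params.as_array(), rtol=5e-3)

    def test_mono_exponential_flags_f_at_zero(self, bounds):
        truth = IVIMParams(0.0, 0.02, 1.2e-3)
        r = fit_3step(noiseless_curve(truth), bounds)
        assert r.params.f <= 1e-12
        assert r.at_boundary["f"]
        assert r.params.D == pytest.approx(1.2e-3, rel=1e-9)

    def test_two_point_log_linear_closed_form(self, bounds):
        b = np.array([0.0, 100.0, 300.0, 700.0])
        f_true, D_true = 0.2, 1.1e-3
        s = ivim_signal(IVIMParams(f_true, 0.2, D_true), b)
        r = fit_3step(DecayCurve(b, s), bounds)
        slope = np.log(s[3] / s[2]) / (b[3] - b[2])
        intercept = np.log(s[2]) - slope * b[2]
        assert r.params.D == pytest.approx(-slope, rel=1e-9)
        assert r.params.f == pytest.approx(1 - np.exp(intercept), rel=1e-9)

    def test_rejects_nonpositive_high_b_signal(self, bounds, b_protocol):
        sig = ivim_signal(IVIMParams(0.1, 0.03, 2.4e-3), b_protocol)
        sig[-1] = -0.01
        with pytest.raises(ValueError):
            fit_3step(DecayCurve(b_protocol, sig), bounds)


class TestCrossMethod:
    def test_all_methods_agree_on_noiseless_d(self, bounds, muscle_curve):
        results = fit_all_methods(muscle_curve, bounds, methods=("nlls1", "nlls2", "nlls3"))
        ds = [r.params.D for r in results.values()]
        np.testing.assert_allclose(ds, ds[0], rtol=1e-3)

    def test_batch_never_aborts_on_partial_failure(self, bounds, b_protocol):
        sig = ivim_signal(IVIMParams(0.1, 0.03, 2.4e-3), b_protocol)
        sig[-1] = -0.01  # breaks the log step only
        results = fit_all_methods(DecayCurve(b_protocol, sig), bounds)
        assert set(results) == {"nlls1", "nlls2", "nlls3", "bayes"}
        assert results["nlls3"].params is None and results["nlls3"].error
        assert results["nlls1"].params is not None
        assert results["nlls2"].params is not None

    def test_four_entries_for_valid_curve(self, bounds, muscle_curve):
        assert len(fit_all_methods(muscle_curve, bounds)) == 4

    def test_noiseless_interior_roundtrip_within_one_percent(self, bounds, b_protocol):
        rng = np.random.default_rng(77)
        for truth in interior_truths(20, bounds, rng):
            curve = noiseless_curve(truth)
            for fn in (fit_1step, fit_2step, fit_3step):
                r = fn(curve, bounds)
                rel = np.abs(r.params.as_array() - truth.as_array()) / truth.as_array()
                assert rel.max() < 0.01, (fn.__name__, truth)
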