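"""Monte Carlo machinery: truth sampling, noise model, ICC, full runs."""

import numpy as np
import pandas as pd
import pytest

from ivimfit import SimDesign, add_noise, icc_2_1, run_simulation, sample_truth
from ivimfit.model import PROTOCOL_B_VALUES, DecayCurve, IVIMParams, ivim_signal
from ivimfit.fitters import fit_1step, fit_3step

from ._oracles import anova_icc_2_1_oracle


class TestSampleTruth:
    def test_empty_design(self):
        assert sample_truth(SimDesign(seed=1, n_combinations=0)) == []

    def test_determinism(self):
        d = SimDesign(seed=7, n_combinations=50)
        a = [p.as_array() for p in sample_truth(d)]
        b = [p.as_array() for p in sample_truth(d)]
        np.testing.assert_array_equal(a, b)

    def test_uniform_over_bounds(self, bounds):
        d = SimDesign(seed=2, n_combinations=20000)
        draws = np.array([p.as_array() for p in sample_truth(d)])
        lo, hi = bounds.lower, bounds.upper
        assert np.all(draws >= lo) and np.all(draws <= hi)
        se = (hi - lo) / np.sqrt(12 * len(draws))
        np.testing.assert_array_less(np.abs(draws.mean(0) - (lo + hi) / 2), 3 * se)


class TestAddNoise:
    def test_infinite_snr_limit(self):
        clean = np.linspace(1, 0.3, 13)
        out = add_noise(clean, 1e12, np.random.default_rng(0))
        np.testing.assert_allclose(out, clean, atol=1e-10)

    def test_noise_moments(self):
        rng = np.random.default_rng(1)
        out = add_noise(np.zeros(100000), 50.0, rng)
        assert np.std(out) == pytest.approx(0.02, rel=0.01)
        assert np.mean(out) == pytest.approx(0.0, abs=3 * 0.02 / np.sqrt(1e5))

    def test_determinism_and_validation(self):
        clean = np.ones(13)
        a = add_noise(clean, 30, np.random.default_rng(5))
        b = add_noise(clean, 30, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        with pytest.raises(ValueError):
            add_noise(clean, 0.0, np.random.default_rng(0))


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert icc_2_1(x, x) == pytest.approx(1.0)

    def test_constant_shift_penalized_matches_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0
        val = icc_2_1(x, y)
        assert val == pytest.approx(anova_icc_2_1_oracle(x, y), abs=1e-12)
        assert val < 1.0  # absolute agreement punishes the offset

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 1000)
        y = rng.permutation(x)
        assert abs(icc_2_1(x, y)) < 0.1

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(icc_2_1(np.ones(5), np.ones(5)))

    def test_matches_pingouin_two_way_model(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(5, 30))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.2, 0.5, n)
            df = pd.DataFrame(
                {
                    "targets": np.r_[np.arange(n), np.arange(n)],
                    "raters": ["truth"] * n + ["fit"] * n,
                    "score": np.r_[x, y],
                }
            )
            ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
            ref = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_2_1(x, y) == pytest.approx(ref, abs=1e-10)


class TestRunSimulation:
    def test_shapes_counts_and_determinism(self):
        d = SimDesign(seed=9, n_combinations=8, snr_levels=(40, 80))
        r1 = run_simulation(d, methods=("nlls3",))
        r2 = run_simulation(d, methods=("nlls3",))
        assert len(r1.raw) == d.n_experiments  # one method
        assert set(r1.icc["parameter"]) == {"f", "Dstar", "D"}
        assert len(r1.icc) == 2 * 3
        pd.testing.assert_frame_equal(r1.raw, r2.raw)

    def test_noiseless_limit_recovers_truth(self):
        d = SimDesign(seed=6, n_combinations=60, snr_levels=(1e9,))
        res = run_simulation(d, methods=("nlls1", "nlls2", "nlls3"))
        for _, row in res.icc.iterrows():
            if row["parameter"] in ("f", "D"):
                assert row["icc"] > 0.999, row

    def test_dstar_best_for_one_step(self):
        d = SimDesign(seed=14, n_combinations=250, snr_levels=(40,))
        res = run_simulation(d, methods=("nlls1", "nlls3"))
        icc = res.icc.set_index(["method", "parameter"])["icc"]
        assert icc[("nlls1", "Dstar")] >= icc[("nlls3", "Dstar")]

    def test_icc_improves_with_snr(self):
        d = SimDesign(seed=4, n_combinations=80, snr_levels=(15, 40, 80))
        res = run_simulation(d, methods=("nlls3",))
        icc = res.icc.set_index(["snr", "parameter"])["icc"]
        for p in ("f", "D"):
            assert icc[(80, p)] > icc[(15, p)]

    def test_segmented_d_unbiased_in_near_monoexponential_regime(self, bounds, b_protocol):
        # truths with f < 0.05: D is essentially the mono-exponential rate and
        # the segmented estimator, which reads D off the high-b shells alone,
        # should be free of systematic error (the joint fit is not: its f >= 0
        # constraint lets noise leak decay into the perfusion term)
        rng = np.random.default_rng(10)
        errs = []
        for _ in range(150):
            truth = IVIMParams(rng.uniform(0, 0.05), rng.uniform(5e-3, 0.4), rng.uniform(3e-4, 2.2e-3))
            y = ivim_signal(truth, b_protocol) + rng.normal(0, 1 / 40, b_protocol.size)
            try:
                errs.append(fit_3step(DecayCurve(b_protocol, y), bounds).params.D - truth.D)
            except ValueError:
                pass
        e = np.asarray(errs)
        se = e.std(ddof=1) / np.sqrt(e.size)
        assert abs(e.mean()) < 3 * se
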