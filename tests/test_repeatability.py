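"""Within-subject CV and the three variability analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivimfit import DecayCurve, IVIMParams, ivim_signal, spatial_consistency, temporal_stability, ws_cv
from ivimfit.model import PROTOCOL_B_VALUES

from ._oracles import wscv_hand_oracle


class TestWsCv:
    def test_identical_replicates_zero(self):
        assert ws_cv([[5.0, 5.0, 5.0], [2.0, 2.0]]) == 0.0

    def test_single_subject_pair(self):
        # SD of (90, 110) is 14.142..., mean 100
        assert ws_cv([[90.0, 110.0]]) == pytest.approx(14.142135623730951, rel=1e-12)

    def test_two_subject_rms_of_cvs(self):
        # per-subject CVs of 10% and 20% -> sqrt((0.01+0.04)/2) = 15.81%
        a = [100.0 - 10.0 / np.sqrt(2), 100.0 + 10.0 / np.sqrt(2)]  # CV 10%
        b = [100.0 - 20.0 / np.sqrt(2), 100.0 + 20.0 / np.sqrt(2)]  # CV 20%
        assert ws_cv([a, b]) == pytest.approx(np.sqrt(0.025) * 100, rel=1e-12)

    def test_intersession_style_pair(self):
        # replicates (x, 1.1x): SD = 0.1x/sqrt(2), mean 1.05x -> 6.7343%
        x = 3.7
        assert ws_cv([[x, 1.1 * x]]) == pytest.approx(100 * (0.1 / np.sqrt(2)) / 1.05, rel=1e-12)

    def test_matches_hand_oracle_on_random_table(self):
        rng = np.random.default_rng(2)
        vecs = [rng.uniform(50, 150, 4) for _ in range(6)]
        assert ws_cv(vecs) == pytest.approx(wscv_hand_oracle(vecs), rel=1e-12)

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        vecs = [np.array([90.0, 100.0, 115.0]), np.array([40.0, 44.0])]
        assert ws_cv([c * v for v in vecs]) == pytest.approx(ws_cv(vecs), rel=1e-9)

    def test_pooled_variant_differs_but_agrees_for_common_mean(self):
        vecs = [[95.0, 105.0], [98.0, 102.0]]
        assert ws_cv(vecs, variant="pooled") == pytest.approx(
            100 * np.sqrt((50 + 8) / 2) / 100.0, rel=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError, match="subject 'k'"):
            ws_cv({"k": [0.0, 0.0]})
        with pytest.raises(ValueError):
            ws_cv([[1.0]])
        with pytest.raises(ValueError):
            ws_cv([])


def synth_repeat_curves(f, ds, d, n_reps=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    b = PROTOCOL_B_VALUES
    clean = ivim_signal(IVIMParams(f, ds, d), b)
    out = {}
    for rep in range(1, n_reps + 1):
        sig = clean + (rng.normal(0, noise, b.size) if noise else 0.0)
        out[rep] = DecayCurve(b, sig)
    return out


class TestTemporalStability:
    def test_identical_repeats_zero_wscv(self):
        curves = {0: synth_repeat_curves(0.11, 0.028, 1.36e-3), 1: synth_repeat_curves(0.13, 0.03, 1.3e-3)}
        rep = temporal_stability(curves, methods=("nlls3",))
        t = rep.table[rep.table["parameter"] != "resid_sq_norm"]
        assert (t["ws_cv_pct"].abs() < 1e-6).all()

    def test_single_subject_report(self):
        curves = {0: synth_repeat_curves(0.11, 0.028, 1.36e-3, noise=2e-3, seed=3)}
        rep = temporal_stability(curves, methods=("nlls3",))
        row = rep.table[(rep.table["parameter"] == "f")].iloc[0]
        assert row["n_subjects"] == 1
        assert np.isnan(row["sd"])  # no cross-subject spread with one subject

    def test_subject_order_invariance(self):
        curves = {
            "a": synth_repeat_curves(0.11, 0.028, 1.36e-3, noise=2e-3, seed=1),
            "b": synth_repeat_curves(0.09, 0.04, 1.2e-3, noise=2e-3, seed=2),
        }
        r1 = temporal_stability(curves, methods=("nlls3",))
        r2 = temporal_stability(dict(reversed(curves.items())), methods=("nlls3",))
        a = r1.table.sort_values(["method", "parameter"]).reset_index(drop=True)
        b = r2.table.sort_values(["method", "parameter"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestSpatialConsistency:
    def test_toy_table_matches_hand_computation(self):
        seg_map = {0: "L1", 1: "L1", 2: "L1", 3: "L1", 4: "L2", 5: "L2", 6: "L2", 7: "L2"}
        rng = np.random.default_rng(9)
        rows = []
        for subj in range(3):
            for sl in range(8):
                rows.append(
                    {
                        "subject": subj,
                        "method": "nlls3",
                        "slice": sl,
                        "f": rng.uniform(0.08, 0.14),
                        "Dstar": rng.uniform(0.02, 0.04),
                        "D": rng.uniform(1.2e-3, 1.5e-3),
                        "fDstar": rng.uniform(2e-3, 5e-3),
                    }
                )
        df = pd.DataFrame(rows)
        rep = spatial_consistency(df, seg_map)
        # hand-compute L1 / f: per-subject vectors over slices 0..3
        vecs = [df[(df.subject == s) & (df.slice < 4)]["f"].to_numpy() for s in range(3)]
        hand = wscv_hand_oracle(vecs)
        got = rep.per_segment
        val = got[(got.segment == "L1") & (got.parameter == "f")]["ws_cv_pct"].iloc[0]
        assert val == pytest.approx(hand, rel=1e-12)
        # summary = mean over segments
        f_rows = got[got.parameter == "f"]["ws_cv_pct"]
        summary = rep.table[rep.table.parameter == "f"]["ws_cv_pct"].iloc[0]
        assert summary == pytest.approx(f_rows.mean(), rel=1e-12)

    def test_identical_slices_zero(self):
        seg_map = {0: "L1", 1: "L1", 2: "L1", 3: "L1"}
        rows = [
            {"subject": 0, "method": "nlls3", "slice": sl, "f": 0.1, "Dstar": 0.03, "D": 1.3e-3, "fDstar": 3e-3}
            for sl in range(4)
        ]
        rep = spatial_consistency(pd.DataFrame(rows), seg_map)
        assert (rep.table["ws_cv_pct"] == 0).all()

    def test_segment_map_requires_four_slices(self):
        from ivimfit import ROIMask

        with pytest.raises(ValueError):
            ROIMask(np.zeros((2, 2, 3), int), {"background": 0}, segment_map={0: "L1", 1: "L1"})
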