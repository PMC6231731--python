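import math

import numpy as np
import pandas as pd
import pytest

from ppgkit.core import bandpass
from ppgkit.beats import BeatConfig, build_beat_series
from ppgkit.synthetic import (
    HRVParams,
    PulseShapeParams,
    RespModulationParams,
    render_ppg,
    sample_subject_params,
    synthesize_session,
)
from ppgkit.core import segment_windows
from ppgkit.validation import (
    align_beats,
    bilateral_agreement,
    bland_altman,
    error_metrics,
    pearson,
    window_sensitivity,
)
from ppgkit.vitals import compute_window_metrics


def _pairs(test, ref, subject=None):
    df = pd.DataFrame({"test": test, "ref": ref})
    if subject is not None:
        df["subject"] = subject
    return df


class TestAlignBeats:
    @staticmethod
    def _beat_train(seed=5, n=80):
        rng = np.random.default_rng(seed)
        t = np.cumsum(rng.normal(0.9, 0.05, n))
        return t - t[0]

    def test_recovers_known_shift(self):
        ref = self._beat_train()
        # test series lags the reference by 3 s -> offset +3 re-aligns it
        offset = align_beats(ref - 3.0, ref, max_lag=6.0)
        assert offset == pytest.approx(3.0, abs=0.25)
        offset = align_beats(ref + 3.0, ref, max_lag=6.0)
        assert offset == pytest.approx(-3.0, abs=0.25)

    def test_zero_shift(self):
        ref = self._beat_train()
        assert align_beats(ref, ref, max_lag=5.0) == pytest.approx(0.0, abs=0.25)

    def test_unrelated_series_fail(self):
        a = self._beat_train(seed=1)
        b = np.arange(80) * 0.9  # metronome: no shared IBI structure
        with pytest.raises(ValueError, match="alignment failed"):
            align_beats(a, b, max_lag=5.0)

    def test_requires_ten_beats(self):
        with pytest.raises(ValueError):
            align_beats(np.arange(5.0), np.arange(20.0), max_lag=2.0)


class TestErrorMetrics:
    def test_hand_computed_three_pairs(self):
        em = error_metrics(_pairs([60.0, 70.0, 80.0], [61.0, 69.0, 80.0]))
        assert em.mae == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert em.me == pytest.approx(0.0, abs=1e-12)

    def test_identical_pairs_zero(self):
        em = error_metrics(_pairs([5.0, 6.0], [5.0, 6.0]))
        assert em.mae == 0.0 and em.mape == 0.0 and em.me == 0.0

    def test_single_pair(self):
        em = error_metrics(_pairs([100.0], [90.0]))
        assert em.mae == 10.0
        assert em.mape == pytest.approx(100.0 / 9.0, abs=1e-6)
        assert em.me == 10.0
        assert em.mae_sd == 0.0

    def test_zero_reference_excluded_from_mape(self):
        em = error_metrics(_pairs([1.0, 2.0], [0.0, 2.0]))
        assert em.mape == 0.0  # only the nonzero-ref pair contributes

    def test_mae_symmetric_me_antisymmetric(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(70, 5, 30), rng.normal(70, 5, 30)
        e1 = error_metrics(_pairs(a, b))
        e2 = error_metrics(_pairs(b, a))
        assert e1.mae == pytest.approx(e2.mae)
        assert e1.me == pytest.approx(-e2.me)


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson(_pairs(x, x)) == pytest.approx(1.0)
        assert pearson(_pairs(-x + 10.0, x)) == pytest.approx(-1.0)

    def test_hand_computed_five_pairs(self):
        # x=(1..5), y=(2,2,3,4,4): r = 6 / sqrt(10*4) = 0.948683
        r = pearson(_pairs([2.0, 2.0, 3.0, 4.0, 4.0], [1.0, 2.0, 3.0, 4.0, 5.0]))
        assert r == pytest.approx(0.9487, abs=1e-4)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson(_pairs(x, y))
        assert pearson(_pairs(3.0 * x + 7.0, y)) == pytest.approx(r0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson(_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestBlandAltman:
    def test_three_point_toy(self):
        res = bland_altman(_pairs([9.0, 10.0, 11.0], [10.0, 10.0, 10.0]))
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)
        assert res.ba_ratio == pytest.approx(1.96 / np.mean([9.5, 10.0, 10.5]))

    def test_all_zero_differences(self):
        res = bland_altman(_pairs([10.0, 12.0], [10.0, 12.0]))
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.ba_ratio == 0.0

    def test_variance_components_closed_form(self):
        """Two subjects x three repeats with within-variance 1 and
        between-variance 4 must give sd_diff = sqrt(5)."""
        m = math.sqrt(13.0 / 6.0)
        diffs = [-m - 1, -m, -m + 1, m - 1, m, m + 1]
        ref = np.full(6, 50.0)
        res = bland_altman(
            _pairs(ref + diffs, ref, subject=["a"] * 3 + ["b"] * 3),
            repeated_measures=True,
        )
        assert res.repeated_measures
        assert res.sd_diff == pytest.approx(math.sqrt(5.0), abs=1e-6)

    def test_single_observation_per_subject_matches_classic(self):
        rng = np.random.default_rng(2)
        t = rng.normal(70, 5, 12)
        r = t + rng.normal(0, 2, 12)
        classic = bland_altman(_pairs(t, r), repeated_measures=False)
        assert classic.sd_diff == pytest.approx(np.std(t - r, ddof=1))
        assert classic.loa_high - classic.loa_low == pytest.approx(2 * 1.96 * classic.sd_diff)

    def test_one_subject_falls_back(self):
        res = bland_altman(
            _pairs([1.0, 2.0, 3.0], [1.5, 2.5, 2.0], subject=["a"] * 3),
            repeated_measures=True,
        )
        assert not res.repeated_measures


@pytest.fixture(scope="module")
def sensitivity_table():
    sessions = []
    for s in range(2):
        hrv, resp = sample_subject_params(500 + s)
        sessions.append(
            synthesize_session(hrv=hrv, resp=resp, duration_s=150.0, seed=s)
        )
    return window_sensitivity(sessions, durations=(60.0, 45.0, 30.0))


class TestWindowSensitivity:
    def test_n_grows_as_duration_shrinks(self, sensitivity_table):
        for metric in ("hr_bpm", "sdnn_ms", "rmssd_ms"):
            sub = sensitivity_table[sensitivity_table.metric == metric]
            ns = sub.sort_values("duration_s", ascending=False)["n"].to_numpy()
            assert ns[0] < ns[1] < ns[2]

    def test_hr_error_stable_across_durations(self, sensitivity_table):
        sub = sensitivity_table[sensitivity_table.metric == "hr_bpm"]
        mae60 = float(sub[sub.duration_s == 60.0]["mae"].iloc[0])
        mae30 = float(sub[sub.duration_s == 30.0]["mae"].iloc[0])
        assert mae30 - mae60 < 0.5

    def test_single_duration_single_row_per_metric(self):
        hrv, resp = sample_subject_params(501)
        sess = synthesize_session(hrv=hrv, resp=resp, duration_s=130.0, seed=0)
        table = window_sensitivity([sess], durations=(60.0,), metrics=("hr_bpm",))
        assert len(table) == 1
        assert table.iloc[0]["duration_s"] == 60.0


class TestBilateralAgreement:
    @staticmethod
    def _metrics(sess):
        wins = segment_windows(sess.ppg, 60.0)
        return compute_window_metrics(sess.ppg, wins, motion=sess.motion)

    def test_identical_streams_zero(self, clean_session):
        mets = self._metrics(clean_session)
        table = bilateral_agreement(mets, mets)
        for _, row in table.iterrows():
            if row["n"]:
                assert row["mean_abs_diff"] == 0.0
                assert row["sd"] == 0.0

    def test_constant_offset(self, clean_session):
        import copy

        left = self._metrics(clean_session)
        right = copy.deepcopy(left)
        for m in right:
            if m.hr_bpm is not None:
                m.hr_bpm += 1.0
        row = bilateral_agreement(left, right).set_index("metric").loc["hr_bpm"]
        assert row["mean_abs_diff"] == pytest.approx(1.0)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_wrists_same_heart(self):
        """Two noisy renderings of the same truth IBIs agree within 1 bpm."""
        base = synthesize_session(duration_s=120.0, seed=21)
        pulse, resp0 = PulseShapeParams(), RespModulationParams()
        left_w = render_ppg(base.truth.beat_times, pulse, resp0, 0.05, 86.0,
                            seed=100, duration_s=120.0)
        right_w = render_ppg(base.truth.beat_times, pulse, resp0, 0.05, 86.0,
                             seed=200, duration_s=120.0)
        lm = compute_window_metrics(left_w, segment_windows(left_w, 60.0))
        rm = compute_window_metrics(right_w, segment_windows(right_w, 60.0))
        row = bilateral_agreement(lm, rm).set_index("metric").loc["hr_bpm"]
        assert row["n"] >= 1
        assert row["mean_abs_diff"] < 1.0

    def test_no_common_valid_windows(self, clean_session):
        table = bilateral_agreement(self._metrics(clean_session), [])
        assert (table["n"] == 0).all()
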