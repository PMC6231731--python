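import itertools

import numpy as np
import pytest

from ppgkit.beats import (
    BeatConfig,
    BeatSeries,
    _local_prominence,
    beats_to_ibis,
    build_beat_series,
    cwt_response,
    detect_peaks_cwt,
    qualify_beats,
    refine_onset,
    select_onsets,
)
from ppgkit.core import Waveform, bandpass
from ppgkit.synthetic import (
    PulseShapeParams,
    RespModulationParams,
    render_ppg,
)

FS = 86.0


def _series(times, quality=None):
    times = np.asarray(times, dtype=float)
    q = np.ones(times.size, dtype=bool) if quality is None else np.asarray(quality)
    return BeatSeries(
        onset_times=times,
        quality=q,
        amplitude=np.zeros(times.size),
        rise_time_s=np.zeros(times.size),
        refined=np.ones(times.size, dtype=bool),
    )


def _interior_truth(sess, margin=1.5):
    bt = sess.truth.beat_times
    return bt[(bt > sess.ppg.t0 + margin) & (bt < sess.ppg.end - margin)]


class TestDetectPeaksCwt:
    def test_clean_60bpm_candidates_cover_truth(self, hr60_session):
        wb = bandpass(hr60_session.ppg, 0.3, 10.0)
        cands = detect_peaks_cwt(wb)
        assert cands.size >= 59
        for tau in _interior_truth(hr60_session):
            assert np.min(np.abs(cands / FS - tau)) <= 1.0 / FS

    def test_flat_signal_gives_no_candidates(self):
        w = Waveform(np.zeros(int(10 * FS)), fs=FS)
        assert detect_peaks_cwt(w).size == 0

    def test_noisy_recall(self, noisy_session):
        wb = bandpass(noisy_session.ppg, 0.3, 10.0)
        cands = detect_peaks_cwt(wb)
        truth = _interior_truth(noisy_session)
        hits = sum(np.min(np.abs(cands / FS - tau)) <= 2.0 / FS for tau in truth)
        assert hits / truth.size >= 0.95


def _five_beat_setup():
    """Five clean pulses 1 s apart, plus a spurious candidate 0.1 s after
    each apex."""
    beats = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
    resp0 = RespModulationParams(bw_depth=0, am_depth=0, fm_depth=0)
    w = render_ppg(beats, PulseShapeParams(), resp0, 0.0, FS, seed=0, duration_s=9.0)
    resp = cwt_response(bandpass(w, 0.3, 10.0))
    true_idx = np.array([int(round(b * FS)) for b in beats])
    spur_idx = true_idx + int(round(0.1 * FS))
    return resp, true_idx, spur_idx


class TestSelectOnsets:
    def test_spurious_candidates_rejected_vs_brute_force(self):
        resp, true_idx, spur_idx = _five_beat_setup()
        cands = np.concatenate([true_idx, spur_idx])
        cfg = BeatConfig()
        sel, _ = select_onsets(cands, resp, cfg)

        # independent brute force: among all min-gap-feasible subsets take
        # the largest, breaking ties by total prominence
        half = int(round(cfg.min_ibi_s * FS))
        proms = {i: _local_prominence(resp.values, int(i), half) for i in cands}
        min_gap = cfg.min_ibi_s * FS
        best = ()
        for r in range(len(cands), 0, -1):
            feasible = [
                s for s in itertools.combinations(sorted(cands), r)
                if all(b - a >= min_gap for a, b in zip(s, s[1:]))
            ]
            if feasible:
                best = max(feasible, key=lambda s: sum(proms[i] for i in s))
                break
        assert set(sel.tolist()) == set(best)
        assert set(sel.tolist()) == set(true_idx.tolist())

    def test_exact_truth_all_retained(self):
        resp, true_idx, _ = _five_beat_setup()
        sel, _ = select_onsets(true_idx, resp, BeatConfig())
        assert np.array_equal(sel, np.sort(true_idx))

    def test_single_candidate_passthrough(self):
        resp, true_idx, _ = _five_beat_setup()
        sel, reliable = select_onsets(true_idx[:1], resp, BeatConfig())
        assert np.array_equal(sel, true_idx[:1])
        assert reliable is False  # too few beats to vouch for the train

    def test_permutation_stability(self):
        resp, true_idx, spur_idx = _five_beat_setup()
        cands = np.concatenate([true_idx, spur_idx])
        sel_ref, _ = select_onsets(cands, resp, BeatConfig())
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = rng.permutation(cands)
            sel, _ = select_onsets(shuffled, resp, BeatConfig())
            assert np.array_equal(sel, sel_ref)

    def test_never_emits_sub_minimum_ibi(self, clean_session, noisy_session):
        cfg = BeatConfig()
        for sess in (clean_session, noisy_session):
            wb = bandpass(sess.ppg, 0.3, 10.0)
            series = build_beat_series(wb, cfg, sess.motion)
            assert np.all(np.diff(series.onset_times) >= cfg.min_ibi_s - 1e-9)
            kept = beats_to_ibis(series, cfg)
            assert np.all(kept >= cfg.min_ibi_s * 1000.0)
            assert np.all(kept <= cfg.max_ibi_s * 1000.0)


class TestRefineOnset:
    def test_symmetric_parabola_refines_to_center(self):
        w = Waveform(np.array([0.0, 1.0, 2.0, 1.0, 0.0]), fs=FS)
        t, refined = refine_onset(w, 2)
        assert refined
        assert t == pytest.approx(2 / FS)

    def test_known_parabola_vertex(self):
        # y = -(x - (idx + 0.3))^2 sampled on integers: vertex at idx + 0.3
        idx = 5
        x = np.arange(11, dtype=float)
        w = Waveform(-((x - (idx + 0.3)) ** 2), fs=FS)
        t, refined = refine_onset(w, idx)
        assert refined
        assert t == pytest.approx((idx + 0.3) / FS, abs=1e-9 / FS)

    def test_sinusoid_apex_within_1ms(self):
        x = np.sin(2 * np.pi * 1.2 * np.arange(200) / FS)
        idx = int(np.argmax(x[:100]))
        t, refined = refine_onset(Waveform(x, fs=FS), idx)
        assert refined
        assert abs(t - 1.0 / (4 * 1.2)) < 1e-3

    def test_boundary_returns_unrefined(self):
        w = Waveform(np.array([2.0, 1.0, 0.0]), fs=FS)
        t, refined = refine_onset(w, 0)
        assert not refined
        assert t == 0.0


class TestQualifyBeats:
    def test_clean_signal_all_interior_qualified(self, clean_session):
        wb = bandpass(clean_session.ppg, 0.3, 10.0)
        series = build_beat_series(wb, BeatConfig(), clean_session.motion)
        assert series.quality[1:-1].all()

    def test_motion_overlap_disqualifies_only_those(self, motion_session):
        """Beats whose support overlaps the 60–64 s artifact are rejected;
        everything clear of the artifact (allowing for the band-pass filter's
        impulse-response spread, bounded here by 2 s) stays qualified."""
        wb = bandpass(motion_session.ppg, 0.3, 10.0)
        series = build_beat_series(wb, BeatConfig(), motion_session.motion)
        t = series.onset_times
        half = 0.5 * float(np.median(np.diff(t)))
        overlap = (t + half > 60.0) & (t - half < 64.0)
        assert np.all(~series.quality[overlap])  # every overlapping beat out
        clear = ((t + half < 58.0) | (t - half > 66.0))
        clear[[0, -1]] = False  # edge beats have truncated support
        assert np.all(series.quality[clear])

    def test_identical_beats_fully_self_similar(self):
        beats = np.arange(2.0, 12.0, 1.0)
        resp0 = RespModulationParams(bw_depth=0, am_depth=0, fm_depth=0)
        w = render_ppg(beats, PulseShapeParams(), resp0, 0.0, FS, seed=0)
        series = build_beat_series(bandpass(w, 0.3, 10.0), BeatConfig())
        assert series.quality[1:-1].all()

    def test_fewer_than_three_beats_all_unqualified(self):
        w = Waveform(np.sin(2 * np.pi * np.arange(int(5 * FS)) / FS), fs=FS)
        series = _series([1.0, 2.0])
        out = qualify_beats(series, w, None, BeatConfig())
        assert not out.quality.any()


class TestBeatsToIbis:
    def test_all_qualified(self):
        s = _series([0.0, 1.0, 2.0])
        assert np.allclose(beats_to_ibis(s), [1000.0, 1000.0])

    def test_middle_unqualified_drops_both(self):
        s = _series([0.0, 1.0, 2.0], quality=[True, False, True])
        assert beats_to_ibis(s).size == 0

    @pytest.mark.parametrize("bad", range(5))
    def test_matches_exhaustive_pair_enumeration(self, bad):
        times = np.array([0.0, 0.9, 1.9, 3.0, 3.8])
        quality = np.ones(5, dtype=bool)
        quality[bad] = False
        s = _series(times, quality)
        expected = [
            (times[k + 1] - times[k]) * 1000.0
            for k in range(4)
            if quality[k] and quality[k + 1]
        ]
        assert np.allclose(beats_to_ibis(s), expected)


class TestEndToEnd:
    def test_clean_ibi_recovery_under_1_5_samples(self, clean_session):
        wb = bandpass(clean_session.ppg, 0.3, 10.0)
        series = build_beat_series(wb, BeatConfig(), clean_session.motion)
        det = series.onset_times
        truth = _interior_truth(clean_session)
        matched = []
        for tau in truth:
            j = int(np.argmin(np.abs(det - tau)))
            assert abs(det[j] - tau) < 2.0 / FS
            matched.append(j)
        # consecutive truth beats map to consecutive detections
        for (t0, t1), (j0, j1) in zip(
            zip(truth, truth[1:]), zip(matched, matched[1:])
        ):
            if j1 == j0 + 1:
                err = abs((det[j1] - det[j0]) - (t1 - t0))
                assert err < 1.5 / FS
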