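"""Per-window vital signs: HR, SDNN, RMSSD and respiration rate.

Ectopic / non-normal interbeat intervals are removed first: an IBI is an
outlier when its logarithm lies more than 6.25 median absolute deviations
from the median log-IBI, with median and MAD computed over the *full
recording* and the rule then applied within each window; outliers are
removed without replacement.

Respiration rate combines two estimators and a threshold-based
qualification:

* baseline wander (BW): the raw window is band-limited to the respiratory
  band (0.1–0.5 Hz) and breath cycles are detected with the same
  wavelet-transform peak detector used for beats; the rate is the mean cycle
  length, and the quality score is the regularity (1 - CV) of the cycle
  lengths;
* frequency modulation (FM, respiratory sinus arrhythmia): the
  instantaneous-HR series is resampled to a uniform 4 Hz grid, a Morlet CWT
  is taken over respiratory pseudo-frequencies, and the per-time ridge
  (argmax of power, parabolically interpolated across scales) is traced; the
  rate is 60 x the median ridge frequency and the quality score is the
  fraction of respiratory-band power concentrated near the ridge.

Estimates below the quality threshold are discarded; surviving estimates
that agree within a tolerance are fused by a quality-weighted mean,
disagreement yields no output for the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pywt
from scipy import signal as _sig

from .beats import BeatConfig, BeatSeries, beats_to_ibis, build_beat_series, cwt_response, detect_peaks_cwt
from .core import MotionTrace, Waveform, Window, bandpass, slice_window
from .quality import QualityConfig, hnr_recording, motion_flag, qualify

__all__ = [
    "OutlierConfig",
    "VitalsConfig",
    "WindowMetrics",
    "OutlierResult",
    "log_mad_stats",
    "remove_outliers",
    "hr",
    "sdnn",
    "rmssd",
    "rr_baseline_wander",
    "rr_frequency_modulation",
    "rr_fuse",
    "compute_window_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierConfig:
    """MAD-based ectopic rejection on log-IBIs (unscaled MAD, full-recording
    scope)."""

    mad_threshold: float = 6.25

    def __post_init__(self) -> None:
        if not self.mad_threshold > 0:
            raise ValueError("mad_threshold must be positive")


@dataclass(frozen=True)
class VitalsConfig:
    """Window-metric parameters.

    ``min_beats_per_min`` scales linearly with window duration (30 beats per
    60-s window by default). The respiratory band 0.1–0.5 Hz corresponds to
    6–30 breaths/min.
    """

    min_beats_per_min: float = 30.0
    rr_band_hz: tuple[float, float] = (0.1, 0.5)
    rr_quality_min: float = 0.5
    rr_agree_brpm: float = 4.0
    hr_resample_hz: float = 4.0
    rr_n_freqs: int = 32
    sd_ddof: int = 1  # sample SD for SDNN; set 0 for population SD


class OutlierResult(NamedTuple):
    kept: np.ndarray
    removed_indices: np.ndarray
    mad_fallback: bool


def log_mad_stats(ibis_ms: np.ndarray) -> tuple[float, float]:
    """Median and (unscaled) MAD of log-IBIs, for full-recording scope."""
    logs = np.log(np.asarray(ibis_ms, dtype=float))
    med = float(np.median(logs))
    mad = float(np.median(np.abs(logs - med)))
    return med, mad


def remove_outliers(
    ibis_ms: np.ndarray,
    cfg: OutlierConfig = OutlierConfig(),
    stats: tuple[float, float] | None = None,
) -> OutlierResult:
    """Drop ectopic IBIs by the log-MAD rule, without replacement.

    ``stats`` supplies the (median log, MAD log) of the full recording; when
    omitted they are computed from ``ibis_ms`` itself. A zero MAD (e.g. all
    intervals identical) falls back to an absolute log-deviation threshold
    of log(1.5), flagged via ``mad_fallback``.
    """
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.size < 3 and stats is None:
        raise ValueError("need at least 3 IBIs to estimate outlier statistics")
    if np.any(ibis <= 0):
        raise ValueError("IBIs must be positive")
    med, mad = stats if stats is not None else log_mad_stats(ibis)
    dev = np.abs(np.log(ibis) - med)
    if mad == 0:
        removed = np.flatnonzero(dev > math.log(1.5))
        fallback = True
    else:
        removed = np.flatnonzero(dev > cfg.mad_threshold * mad)
        fallback = False
    keep_mask = np.ones(ibis.size, dtype=bool)
    keep_mask[removed] = False
    return OutlierResult(ibis[keep_mask], removed, fallback)


def hr(ibis_ms: np.ndarray) -> float:
    """Window heart rate in bpm: 60000 / mean IBI."""
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.size < 1:
        raise ValueError("no IBIs")
    return 60000.0 / float(np.mean(ibis))


def sdnn(ibis_ms: np.ndarray, ddof: int = 1) -> float:
    """SD of normal-to-normal intervals (sample SD by default), ms."""
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.size < 2:
        raise ValueError("need at least 2 IBIs")
    return float(np.std(ibis, ddof=ddof))


def rmssd(ibis_ms: np.ndarray) -> float:
    """Root mean square of successive IBI differences, ms."""
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.size < 2:
        raise ValueError("need at least 2 IBIs")
    return float(np.sqrt(np.mean(np.diff(ibis) ** 2)))


def rr_baseline_wander(
    w_raw: Waveform,
    cfg: VitalsConfig = VitalsConfig(),
    beat_cfg: BeatConfig | None = None,
) -> tuple[float, float] | None:
    """Respiration rate from baseline wander of the raw window.

    Returns ``(brpm, quality)`` or None when fewer than 2 full breath cycles
    are detected or the respiratory band carries no appreciable power.
    """
    lo, hi = cfg.rr_band_hz
    x = w_raw.values - np.mean(w_raw.values)
    ac_rms = float(np.std(x))
    if ac_rms == 0:
        return None
    sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=w_raw.fs, output="sos")
    resp = _sig.sosfiltfilt(sos, x)
    if float(np.std(resp)) < 1e-6 * ac_rms:
        return None
    # breath cycles via the CWT peak detector, scales matched to breath widths
    bcfg = BeatConfig(
        cwt_width_range_s=(0.5 / hi, 0.5 / lo),
        min_ibi_s=1.0 / hi,
        max_ibi_s=1.0 / lo,
        prom_floor_frac=0.3,
    )
    wf = Waveform(resp, fs=w_raw.fs, t0=w_raw.t0, label="resp")
    response = cwt_response(wf, bcfg)
    cands = detect_peaks_cwt(wf, bcfg, _response=response)
    from .beats import select_onsets  # local import avoids name clutter above

    sel, _ = select_onsets(cands, response, bcfg)
    if sel.size < 3:
        return None
    t_peaks = w_raw.t0 + sel / w_raw.fs
    cycles = np.diff(t_peaks)
    rate = 60.0 * cycles.size / float(t_peaks[-1] - t_peaks[0])
    cv = float(np.std(cycles) / np.mean(cycles))
    # spectral concentration guard: band-filtered noise is quasi-periodic
    # (low CV) but spreads its power across the band, a true respiratory
    # oscillation concentrates it near the detected rate
    f, p = _sig.periodogram(x, fs=w_raw.fs)
    band = (f >= lo) & (f <= hi)
    f_est = rate / 60.0
    near = band & (np.abs(f - f_est) <= 0.2 * f_est)
    p_band = float(np.sum(p[band]))
    conc = float(np.sum(p[near])) / p_band if p_band > 0 else 0.0
    quality = max(0.0, 1.0 - cv) * conc
    return rate, quality


def rr_frequency_modulation(
    interval_times_s: np.ndarray,
    ibis_ms: np.ndarray,
    cfg: VitalsConfig = VitalsConfig(),
) -> tuple[float, float] | None:
    """Respiration rate from respiratory sinus arrhythmia (FM of the heart
    period).

    ``interval_times_s`` are the midpoint times of the qualified,
    outlier-filtered intervals of one window, ``ibis_ms`` their durations.
    Returns ``(brpm, quality)`` or None when the series is too short or
    flat.
    """
    mid = np.asarray(interval_times_s, dtype=float)
    ibis = np.asarray(ibis_ms, dtype=float)
    if ibis.size < 8 or mid.size != ibis.size:
        return None
    hr_inst = 60000.0 / ibis
    if float(np.std(hr_inst)) == 0:
        return None
    fs_r = cfg.hr_resample_hz
    t_grid = np.arange(mid[0], mid[-1], 1.0 / fs_r)
    if t_grid.size < 8 * fs_r:  # need a few breath periods of support
        return None
    x = np.interp(t_grid, mid, hr_inst)
    x = _sig.detrend(x, type="linear")
    lo, hi = cfg.rr_band_hz
    freqs = np.geomspace(lo, hi, cfg.rr_n_freqs)
    fc = pywt.central_frequency("morl")
    scales = fc * fs_r / freqs
    coef, _ = pywt.cwt(x, scales, "morl")
    power = coef**2
    # trim edge-effect columns (10% each side)
    k = max(1, int(0.1 * power.shape[1]))
    power = power[:, k:-k]
    if not np.any(power):
        return None
    amax = np.argmax(power, axis=0)
    # parabolic interpolation across (log-spaced) scales for a continuous ridge
    logf = np.log(freqs)
    ridge_logf = np.empty(amax.size)
    for j, i in enumerate(amax):
        if 0 < i < freqs.size - 1:
            ym, y0, yp = power[i - 1, j], power[i, j], power[i + 1, j]
            denom = ym - 2 * y0 + yp
            d = 0.0 if denom == 0 else float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))
        else:
            d = 0.0
        ridge_logf[j] = np.interp(i + d, np.arange(freqs.size), logf)
    f_med = float(np.exp(np.median(ridge_logf)))
    rate = 60.0 * f_med
    # quality: fraction of respiratory-band power within +-20% of the ridge
    near = np.abs(logf[:, None] - np.log(f_med)) <= math.log(1.2)
    quality = float(np.sum(power[near[:, 0], :]) / np.sum(power))
    return rate, quality


def rr_fuse(
    bw: tuple[float, float] | None,
    fm: tuple[float, float] | None,
    cfg: VitalsConfig = VitalsConfig(),
) -> float | None:
    """Combine BW and FM estimates with threshold-based qualification.

    Estimates below ``rr_quality_min`` are discarded; if both survive they
    must agree within ``rr_agree_brpm`` (quality-weighted mean), otherwise
    no respiration rate is reported for the window.
    """
    cands = []
    for est in (bw, fm):
        if est is not None and est[1] >= cfg.rr_quality_min:
            cands.append(est)
    if not cands:
        return None
    if len(cands) == 1:
        return float(cands[0][0])
    (r1, q1), (r2, q2) = cands
    if abs(r1 - r2) > cfg.rr_agree_brpm:
        return None
    return float((r1 * q1 + r2 * q2) / (q1 + q2))


@dataclass
class WindowMetrics:
    """Vital signs of one analysis window; absent metrics are None with the
    matching validity flag False."""

    window: Window
    hr_bpm: float | None
    sdnn_ms: float | None
    rmssd_ms: float | None
    rr_brpm: float | None
    hnr_db: float
    n_beats: int
    n_outliers_removed: int
    recording_qualified: bool
    valid: dict = field(default_factory=dict)


def compute_window_metrics(
    ppg_raw: Waveform,
    windows: list[Window],
    *,
    motion: MotionTrace | None = None,
    quality_cfg: QualityConfig = QualityConfig(),
    beat_cfg: BeatConfig = BeatConfig(),
    vitals_cfg: VitalsConfig = VitalsConfig(),
    outlier_cfg: OutlierConfig = OutlierConfig(),
    bandpass_hz: tuple[float, float] = (0.3, 10.0),
    beat_series: BeatSeries | None = None,
) -> list[WindowMetrics]:
    """Run the full per-window pipeline on a recording.

    Beat segmentation and the outlier statistics are computed once over the
    whole recording; each window is then gated on its mean HNR and motion
    flag, and HR/SDNN/RMSSD/RR are emitted with per-metric validity.
    """
    wb = bandpass(ppg_raw, *bandpass_hz)
    series = beat_series if beat_series is not None else build_beat_series(
        wb, beat_cfg, motion
    )
    rec_ibis = beats_to_ibis(series, beat_cfg)
    stats = log_mad_stats(rec_ibis) if rec_ibis.size >= 3 else None

    out: list[WindowMetrics] = []
    t = series.onset_times
    q = series.quality
    for win in windows:
        wslice = slice_window(wb, win)
        hnr_res = hnr_recording(wslice, quality_cfg)
        mflag = motion_flag(motion, win, quality_cfg.motion_threshold)
        rec_ok = qualify(hnr_res, mflag, quality_cfg)

        in_win = (t >= win.start) & (t < win.end)
        n_beats_q = int(np.sum(in_win & q))
        n_beats_all = int(np.sum(in_win))
        min_beats = math.ceil(vitals_cfg.min_beats_per_min * win.duration / 60.0)
        enough = (
            n_beats_q >= min_beats
            and n_beats_all > 0
            and n_beats_q >= beat_cfg.min_qualified_frac * n_beats_all
        )

        # intervals bounded by two qualified beats inside the window
        pair_ok = (
            in_win[:-1] & in_win[1:] & q[:-1] & q[1:]
            & (series.ibis_ms >= beat_cfg.min_ibi_s * 1000.0)
            & (series.ibis_ms <= beat_cfg.max_ibi_s * 1000.0)
        ) if series.n_beats >= 2 else np.array([], dtype=bool)
        win_ibis = series.ibis_ms[pair_ok] if series.n_beats >= 2 else np.array([])
        win_bt = t[:-1][pair_ok] if series.n_beats >= 2 else np.array([])

        n_removed = 0
        if win_ibis.size and stats is not None:
            res = remove_outliers(win_ibis, outlier_cfg, stats=stats)
            n_removed = int(res.removed_indices.size)
            keep = np.ones(win_ibis.size, dtype=bool)
            keep[res.removed_indices] = False
            win_ibis = res.kept
            win_bt = win_bt[keep]

        hr_v = sdnn_v = rmssd_v = rr_v = None
        if rec_ok and enough and win_ibis.size >= 2:
            hr_v = hr(win_ibis)
            sdnn_v = sdnn(win_ibis, ddof=vitals_cfg.sd_ddof)
            rmssd_v = rmssd(win_ibis)
        if rec_ok and enough:
            bw_est = rr_baseline_wander(slice_window(ppg_raw, win), vitals_cfg)
            fm_est = None
            if win_ibis.size >= 8:
                mids = win_bt + win_ibis / 2000.0
                fm_est = rr_frequency_modulation(mids, win_ibis, vitals_cfg)
            rr_v = rr_fuse(bw_est, fm_est, vitals_cfg)

        out.append(
            WindowMetrics(
                window=win,
                hr_bpm=hr_v,
                sdnn_ms=sdnn_v,
                rmssd_ms=rmssd_v,
                rr_brpm=rr_v,
                hnr_db=hnr_res.mean_db,
                n_beats=n_beats_q,
                n_outliers_removed=n_removed,
                recording_qualified=rec_ok,
                valid={
                    "hr": hr_v is not None,
                    "sdnn": sdnn_v is not None,
                    "rmssd": rmssd_v is not None,
                    "rr": rr_v is not None,
                },
            )
        )
    return out
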