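"""Signal qualification by harmonic-to-noise ratio (HNR) and motion gating.

The HNR of a window is computed with the Boersma autocorrelation method: the
normalized autocorrelation of the mean-removed signal is corrected for the
rectangular analysis window (division by ``1 - tau/n``), its maximum ``r*``
over a lag range covering plausible heart periods is taken as the harmonic
power fraction, and

    HNR = 10 * log10(r* / (1 - r*))   [dB]

For a perfectly periodic signal ``r* -> 1`` and the HNR diverges; values are
clipped to [-20, +40] dB. A sinusoid in white noise with power ratio SNR has
``r* ~= SNR / (1 + SNR)``, so the estimator reads ``10*log10(SNR)`` dB.

A 60-second recording is scored by averaging HNR over 6-second windows
centered 1 second apart; recordings whose mean HNR falls below a threshold,
or that overlap wrist-motion artifacts, do not qualify for vital-sign
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MotionTrace, Waveform, Window, slice_motion

__all__ = [
    "QualityConfig",
    "HNRResult",
    "hnr_window",
    "hnr_recording",
    "motion_flag",
    "qualify",
]

logger = logging.getLogger(__name__)

HNR_FLOOR_DB = -20.0
HNR_CAP_DB = 40.0


@dataclass(frozen=True)
class QualityConfig:
    """Qualification parameters.

    The lag search range (0.33–2.0 s) corresponds to heart rates between
    30 and 180 bpm. The HNR threshold defaults to 3 dB (twice as much
    harmonic as noise power); it is configurable because the appropriate
    cut-off depends on the device.
    """

    hnr_window_s: float = 6.0
    hnr_step_s: float = 1.0
    hnr_threshold_db: float = 3.0
    motion_threshold: float = 0.25
    lag_search_s: tuple[float, float] = (0.33, 2.0)

    def __post_init__(self) -> None:
        if not self.hnr_window_s > self.hnr_step_s > 0:
            raise ValueError("require hnr_window_s > hnr_step_s > 0")
        if not 0 < self.lag_search_s[0] < self.lag_search_s[1]:
            raise ValueError("invalid lag search range")


@dataclass
class HNRResult:
    per_window_db: np.ndarray
    mean_db: float
    n_windows: int


def hnr_window(w: Waveform, lag_search_s: tuple[float, float] = (0.33, 2.0)) -> float:
    """HNR (dB) of one short window of band-passed PPG.

    Expects the input already band-passed to the cardiovascular component
    (0.3–10 Hz) and at least twice the maximum search lag long.
    """
    x = w.values - np.mean(w.values)
    n = x.size
    if not np.any(x):
        raise ValueError("flat signal")
    lag_lo = max(1, int(round(lag_search_s[0] * w.fs)))
    lag_hi = int(round(lag_search_s[1] * w.fs))
    if lag_hi >= n:
        raise ValueError("window shorter than twice the maximum search lag")
    # Boersma estimator: window the segment, take the biased (divide-by-n)
    # normalized autocorrelation via FFT, and divide out the autocorrelation
    # of the window function itself so a perfectly periodic signal reads
    # r(tau) ~= 1 at its period
    win = np.hanning(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))

    def _nacf(y: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(y, nfft)
        acf = np.fft.irfft(spec * np.conj(spec), nfft)[: lag_hi + 2]
        return acf / acf[0]

    r_full = _nacf(x * win) / _nacf(win)
    lags = np.arange(lag_lo, lag_hi + 1)
    r = r_full[lags]
    imax = int(np.argmax(r))
    r_star = float(r[imax])
    # parabolic interpolation of the peak across the lag grid
    j = lags[imax]
    if 1 <= j < lag_hi + 1:
        ym, y0, yp = r_full[j - 1], r_full[j], r_full[j + 1]
        denom = ym - 2 * y0 + yp
        if denom < 0:
            d = 0.5 * (ym - yp) / denom
            r_star = float(y0 - 0.25 * (ym - yp) * d)
    if r_star <= 0:
        return HNR_FLOOR_DB
    r_star = min(r_star, 1.0 - 1e-12)
    hnr = 10.0 * np.log10(r_star / (1.0 - r_star))
    if hnr > HNR_CAP_DB or hnr < HNR_FLOOR_DB:
        logger.debug("HNR %.1f dB clipped to [%g, %g]", hnr, HNR_FLOOR_DB, HNR_CAP_DB)
    return float(np.clip(hnr, HNR_FLOOR_DB, HNR_CAP_DB))


def hnr_recording(w: Waveform, cfg: QualityConfig = QualityConfig()) -> HNRResult:
    """Mean HNR of a recording from overlapping short windows.

    Windows of ``hnr_window_s`` are centered ``hnr_step_s`` apart, the first
    centered at ``hnr_window_s / 2`` so every window fits entirely; a 60-s
    recording at the 6-s / 1-s defaults yields 55 windows (centers 3..57 s).
    """
    if w.duration < cfg.hnr_window_s - 1e-9:
        raise ValueError("recording shorter than one HNR window")
    half = cfg.hnr_window_s / 2.0
    n_win = int(np.floor((w.duration - cfg.hnr_window_s) / cfg.hnr_step_s + 1e-9)) + 1
    nwin_samp = int(round(cfg.hnr_window_s * w.fs))
    vals = np.empty(n_win)
    for i in range(n_win):
        center = half + i * cfg.hnr_step_s
        i0 = int(round((center - half) * w.fs))
        sub = Waveform(w.values[i0 : i0 + nwin_samp], fs=w.fs, t0=w.t0, label=w.label)
        vals[i] = hnr_window(sub, cfg.lag_search_s)
    return HNRResult(per_window_db=vals, mean_db=float(np.mean(vals)), n_windows=n_win)


def motion_flag(m: MotionTrace | None, win: Window, threshold: float) -> bool:
    """True iff the robust motion envelope in the window exceeds ``threshold``.

    The envelope is the 95th percentile of ``|magnitude - median|`` over the
    window, which ignores the resting-gravity offset and brief single-sample
    glitches. A missing/empty trace returns False (motion gating optional).
    """
    if m is None:
        return False
    mag = slice_motion(m, win)
    if mag.size == 0:
        logger.warning("no motion samples in window %s; motion gate skipped", win)
        return False
    env = float(np.percentile(np.abs(mag - np.median(mag)), 95))
    return env > threshold


def qualify(hnr: HNRResult, motion_flagged: bool, cfg: QualityConfig = QualityConfig()) -> bool:
    """Recording-level qualification: mean HNR above threshold and no motion."""
    return (hnr.mean_db >= cfg.hnr_threshold_db) and not motion_flagged
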