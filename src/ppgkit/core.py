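"""Waveform primitives shared by every processing stage.

A :class:`Waveform` is a uniformly sampled single channel (PPG infrared or
red, or any derived series) with an explicit sampling rate and start time.
Per-window vital-sign reporting uses nonoverlapping, contiguous
:class:`Window` tiles; the boundary convention is half-open
``[start, start + duration)`` with sample index ``round(t * fs)``, so window
assignment of beats and interbeat intervals is reproducible.

The only preconditioning applied before beat detection and signal-quality
scoring is a zero-phase band-pass (0.3–10 Hz by default), which isolates the
cardiovascular component of the PPG from respiratory baseline wander and
high-frequency noise without shifting beat timing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "Waveform",
    "MotionTrace",
    "Window",
    "segment_windows",
    "bandpass",
    "slice_window",
    "slice_motion",
]


@dataclass
class Waveform:
    """Uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample values (arbitrary units). Must be 1-D, non-empty, finite.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    label : str
        Channel name, e.g. ``"ir"`` or ``"red"``.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "ir"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("empty signal")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite samples in waveform")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (round-to-nearest convention)."""
        return int(round((t - self.t0) * self.fs))


@dataclass
class MotionTrace:
    """3-axis accelerometer magnitude series (nominally 10 Hz)."""

    magnitude: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.ndim != 1 or self.magnitude.size < 1:
            raise ValueError("empty motion trace")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.magnitude)):
            raise ValueError("non-finite samples in motion trace")
        if np.any(self.magnitude < 0):
            raise ValueError("motion magnitude must be nonnegative")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.magnitude.size) / self.fs


@dataclass(frozen=True)
class Window:
    """Half-open analysis window ``[start, start + duration)``."""

    start: float
    duration: float
    index: int = 0

    @property
    def end(self) -> float:
        return self.start + self.duration


def segment_windows(w: Waveform, duration: float) -> list[Window]:
    """Tile a waveform into nonoverlapping windows of ``duration`` seconds.

    The trailing remainder shorter than ``duration`` is discarded, matching
    the nonoverlapping 60-second measurement convention.
    """
    if w.n < 1:  # unreachable via constructor, kept for defensive clarity
        raise ValueError("empty signal")
    if duration <= 0:
        raise ValueError("window duration must be positive")
    # small epsilon guards float representation of exact multiples
    k = int(math.floor(w.duration / duration + 1e-9))
    return [Window(start=w.t0 + i * duration, duration=duration, index=i) for i in range(k)]


def bandpass(w: Waveform, lo: float, hi: float, order: int = 4) -> Waveform:
    """Zero-phase Butterworth band-pass copy of ``w``.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective order
    and cancels phase delay, preserving beat timing. The mean (DC) is removed
    by construction of the band-pass.
    """
    if not (0 < lo < hi):
        raise ValueError("band edges must satisfy 0 < lo < hi")
    if hi >= w.fs / 2:
        raise ValueError("band above Nyquist")
    sos = _sig.butter(order, [lo, hi], btype="bandpass", fs=w.fs, output="sos")
    y = _sig.sosfiltfilt(sos, w.values)
    return replace(w, values=y)


def slice_window(w: Waveform, win: Window) -> Waveform:
    """Sample-aligned sub-waveform for a window (half-open)."""
    i0 = w.index_at(win.start)
    i1 = i0 + int(round(win.duration * w.fs))
    if i0 < 0 or i1 > w.n or i1 <= i0:
        raise ValueError(
            f"window [{win.start}, {win.end}) s outside waveform extent "
            f"[{w.t0}, {w.end}) s"
        )
    return Waveform(w.values[i0:i1], fs=w.fs, t0=win.start, label=w.label)


def slice_motion(m: MotionTrace, win: Window) -> np.ndarray:
    """Motion magnitude samples falling in a window (may be empty)."""
    t = m.times()
    return m.magnitude[(t >= win.start) & (t < win.end)]
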