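"""Ground-truth PPG generator.

Renders pulsatile waveforms with controllable heart rate, heart-rate
variability, respiratory modulations and noise, retaining the true beat
times, interbeat intervals (IBIs) and respiration rate so that the full
processing chain can be tested by parameter recovery.

Model
-----
Beat-to-beat periods are generated first::

    ibi_k = mean_ibi * (1 + fm_depth * sin(2*pi*f_resp*t_k))
            + lf_amp * sin(2*pi*lf_freq*t_k) + eps_k,   eps_k ~ N(0, jitter_sd^2)

i.e. respiratory sinus arrhythmia (RSA) as a sinusoidal frequency modulation
of the heart period at the breathing frequency, plus a slow low-frequency
oscillation and white jitter. Beat times are the cumulative sums.

The waveform renderer then places one systolic + dicrotic complex (two
Gaussian bumps) at each beat time, applies respiratory amplitude modulation
and baseline wander at the same breathing frequency, and adds white noise.
The systolic bump apex is the ground-truth beat time. Motion artifacts are
injected as high-variance random-walk transients with a matching elevated
segment in a concurrent 10 Hz accelerometer-magnitude trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import MotionTrace, Waveform

__all__ = [
    "PulseShapeParams",
    "RespModulationParams",
    "HRVParams",
    "GroundTruth",
    "SyntheticSession",
    "generate_ibis",
    "render_ppg",
    "inject_motion",
    "synthesize_session",
    "sample_subject_params",
]


@dataclass(frozen=True)
class PulseShapeParams:
    """Two-Gaussian pulse morphology (systolic bump + delayed dicrotic bump).

    ``systolic_width`` is the Gaussian standard deviation in seconds; the
    dicrotic bump reuses 1.2x that width.
    """

    systolic_amp: float = 1.0
    systolic_width: float = 0.10
    dicrotic_amp_frac: float = 0.30
    dicrotic_delay: float = 0.30

    def __post_init__(self) -> None:
        if self.systolic_amp < 0 or self.dicrotic_amp_frac < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not 0 <= self.dicrotic_amp_frac <= 1:
            raise ValueError("dicrotic_amp_frac must be in [0, 1]")
        if self.systolic_width <= 0 or self.dicrotic_delay <= 0:
            raise ValueError("widths and delays must be positive")


@dataclass(frozen=True)
class RespModulationParams:
    """Respiratory influence on the PPG.

    rr_brpm : breathing rate, breaths/min (4–60).
    bw_depth : baseline-wander amplitude, same units as the pulse.
    am_depth : amplitude-modulation depth, fraction of pulse amplitude.
    fm_depth : RSA depth, fraction of the mean IBI.
    """

    rr_brpm: float = 15.0
    bw_depth: float = 0.3
    am_depth: float = 0.1
    fm_depth: float = 0.05

    def __post_init__(self) -> None:
        if not 4.0 <= self.rr_brpm <= 60.0:
            raise ValueError("rr_brpm must be in [4, 60]")
        if min(self.bw_depth, self.am_depth, self.fm_depth) < 0:
            raise ValueError("modulation depths must be nonnegative")

    @property
    def f_resp_hz(self) -> float:
        return self.rr_brpm / 60.0


@dataclass(frozen=True)
class HRVParams:
    """Heart-period statistics driving the IBI generator."""

    hr_mean_bpm: float = 70.0
    jitter_sd_ms: float = 25.0
    lf_amp_ms: float = 15.0
    lf_freq_hz: float = 0.095

    def __post_init__(self) -> None:
        if not 30.0 <= self.hr_mean_bpm <= 180.0:
            raise ValueError("hr_mean_bpm must be in [30, 180]")
        if self.jitter_sd_ms < 0 or self.lf_amp_ms < 0:
            raise ValueError("variability amplitudes must be nonnegative")

    @property
    def mean_ibi_ms(self) -> float:
        return 60000.0 / self.hr_mean_bpm


@dataclass
class GroundTruth:
    """Retained truth for parameter-recovery tests.

    ``window_metrics`` applies the estimator definitions (mean-IBI heart
    rate, sample-SD SDNN, RMSSD of successive differences) directly to the
    noiseless generated IBI series, window by window, so recovery tests
    compare against the same definitions without running the pipeline.
    """

    beat_times: np.ndarray  # s
    ibis_ms: np.ndarray
    rr_brpm: float

    def window_metrics(self, duration_s: float, n_windows: int, t0: float = 0.0):
        """Per-window truth table (list of dicts).

        An IBI belongs to a window iff both of its bounding beat times fall
        inside the half-open window — the same convention the pipeline uses.
        """
        out = []
        bt = self.beat_times
        for i in range(n_windows):
            lo = t0 + i * duration_s
            hi = lo + duration_s
            inside = (bt >= lo) & (bt < hi)
            # IBI k bounded by beats k and k+1
            pair_in = inside[:-1] & inside[1:]
            ibis = self.ibis_ms[pair_in]
            row: dict = {
                "window_index": i,
                "window_start_s": lo,
                "n_ibis": int(ibis.size),
                "hr_bpm": None,
                "sdnn_ms": None,
                "rmssd_ms": None,
                "rr_brpm": self.rr_brpm,
            }
            if ibis.size >= 2:
                row["hr_bpm"] = 60000.0 / float(np.mean(ibis))
                row["sdnn_ms"] = float(np.std(ibis, ddof=1))
                row["rmssd_ms"] = float(np.sqrt(np.mean(np.diff(ibis) ** 2)))
            out.append(row)
        return out


@dataclass
class SyntheticSession:
    """A rendered recording plus its retained ground truth."""

    ppg: Waveform
    motion: MotionTrace | None
    truth: GroundTruth


def generate_ibis(
    hrv: HRVParams,
    resp: RespModulationParams,
    n_beats: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate beat times (s) and IBIs (ms).

    Returns ``(beat_times, ibis_ms)`` with ``len(beat_times) == n_beats`` and
    ``len(ibis_ms) == n_beats - 1``; beat times are cumulative sums of the
    IBIs starting at t = 0. Deterministic for a fixed seed.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    rng = np.random.default_rng(seed)
    f_resp = resp.f_resp_hz
    mean_ibi = hrv.mean_ibi_ms
    eps = rng.normal(0.0, hrv.jitter_sd_ms, size=n_beats - 1)
    times = np.empty(n_beats)
    ibis = np.empty(n_beats - 1)
    t = 0.0
    times[0] = 0.0
    for k in range(n_beats - 1):
        ibi = (
            mean_ibi * (1.0 + resp.fm_depth * math.sin(2 * math.pi * f_resp * t))
            + hrv.lf_amp_ms * math.sin(2 * math.pi * hrv.lf_freq_hz * t)
            + eps[k]
        )
        if ibi <= 0:
            raise ValueError("nonphysiological IBI")
        ibis[k] = ibi
        t += ibi / 1000.0
        times[k + 1] = t
    return times, ibis


def render_ppg(
    beat_times: np.ndarray,
    pulse: PulseShapeParams,
    resp: RespModulationParams,
    noise_sd: float,
    fs: float,
    seed: int,
    duration_s: float | None = None,
) -> Waveform:
    """Render a PPG waveform from beat times.

    One systolic Gaussian bump plus a delayed dicrotic bump per beat; the
    pulsatile sum is amplitude-modulated at the breathing frequency, baseline
    wander and white noise are added. The truth beat time is the systolic
    bump apex.
    """
    if fs < 20:
        raise ValueError("fs must be >= 20 Hz")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    if duration_s is None:
        duration_s = (beat_times[-1] + 2.0) if beat_times.size else 1.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    sw = pulse.systolic_width
    dw = 1.2 * sw
    for tau in beat_times:
        for amp, center, width in (
            (pulse.systolic_amp, tau, sw),
            (pulse.systolic_amp * pulse.dicrotic_amp_frac, tau + pulse.dicrotic_delay, dw),
        ):
            if amp == 0:
                continue
            i0 = max(0, int((center - 6 * width) * fs))
            i1 = min(n, int((center + 6 * width) * fs) + 1)
            if i1 <= i0:
                continue
            tt = t[i0:i1] - center
            x[i0:i1] += amp * np.exp(-0.5 * (tt / width) ** 2)
    f = resp.f_resp_hz
    x *= 1.0 + resp.am_depth * np.sin(2 * np.pi * f * t)
    x += resp.bw_depth * np.sin(2 * np.pi * f * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x += rng.normal(0.0, noise_sd, size=n)
    return Waveform(x, fs=fs, t0=0.0, label="ir")


def inject_motion(
    w: Waveform,
    start: float,
    dur: float,
    scale: float,
    seed: int,
    motion: MotionTrace | None = None,
    motion_fs: float = 10.0,
    baseline_g: float = 1.0,
) -> tuple[Waveform, MotionTrace]:
    """Corrupt ``[start, start + dur)`` with a random-walk transient.

    Returns the corrupted waveform and a 10 Hz motion-magnitude trace that
    sits at a flat ``baseline_g`` (resting gravity magnitude) everywhere and
    is elevated only inside the corrupted segment. With ``scale == 0`` both
    outputs are unchanged / flat.
    """
    i0 = w.index_at(start)
    i1 = w.index_at(start + dur)
    if i0 < 0 or i1 > w.n or i1 <= i0:
        raise ValueError("motion segment outside waveform")
    rng = np.random.default_rng(seed)
    values = w.values.copy()
    n_seg = i1 - i0
    if scale > 0:
        # a random walk's spread about its own path mean is ~ (step_sd^2 * n)/6;
        # scale the steps so the transient RMS is approximately `scale`
        step_sd = scale * math.sqrt(6.0) / math.sqrt(n_seg)
        walk = np.cumsum(rng.normal(0.0, step_sd, size=n_seg))
        # taper the ends so the transient enters and leaves smoothly
        ramp = min(n_seg // 10 + 1, n_seg // 2)
        env = np.ones(n_seg)
        if ramp > 0:
            env[:ramp] = np.linspace(0, 1, ramp)
            env[-ramp:] = np.linspace(1, 0, ramp)
        values[i0:i1] += walk * env
    out_w = Waveform(values, fs=w.fs, t0=w.t0, label=w.label)

    if motion is None:
        n_m = int(round(w.duration * motion_fs))
        motion = MotionTrace(np.full(n_m, baseline_g), fs=motion_fs, t0=w.t0)
    mag = motion.magnitude.copy()
    tm = motion.times()
    seg = (tm >= start) & (tm < start + dur)
    if scale > 0:
        mag[seg] = motion.magnitude[seg] + np.abs(
            rng.normal(0.0, 0.2 * scale, size=int(seg.sum()))
        )
    return out_w, MotionTrace(mag, fs=motion.fs, t0=motion.t0)


def synthesize_session(
    hrv: HRVParams = HRVParams(),
    resp: RespModulationParams = RespModulationParams(),
    pulse: PulseShapeParams = PulseShapeParams(),
    duration_s: float = 120.0,
    fs: float = 86.0,
    snr: float | None = None,
    motion_events: tuple[tuple[float, float, float], ...] = (),
    seed: int = 0,
    with_motion_trace: bool = True,
) -> SyntheticSession:
    """Render a full recording with retained ground truth.

    ``snr`` is the pulsatile-power to white-noise-power ratio (None = no
    noise). ``motion_events`` is a sequence of ``(start_s, dur_s, scale)``
    transients. Beats start 1 s into the recording so the first pulse is
    rendered completely. All randomness derives from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_ibi, s_noise, s_motion = (int(s) for s in ss.generate_state(3) % (2**31))
    n_beats = int(math.ceil(duration_s * hrv.hr_mean_bpm / 60.0)) + 4
    beat_times, ibis = generate_ibis(hrv, resp, n_beats, seed=s_ibi)
    beat_times = beat_times + 1.0  # lead-in so the first complex fits

    noise_sd = 0.0
    if snr is not None:
        # measure the pulsatile AC power from a noise-free, wander-free render
        resp_nobw = RespModulationParams(
            rr_brpm=resp.rr_brpm, bw_depth=0.0,
            am_depth=resp.am_depth, fm_depth=resp.fm_depth,
        )
        clean = render_ppg(beat_times, pulse, resp_nobw, 0.0, fs, seed=0,
                           duration_s=duration_s)
        noise_sd = float(np.std(clean.values)) / math.sqrt(snr)

    ppg = render_ppg(beat_times, pulse, resp, noise_sd, fs, seed=s_noise,
                     duration_s=duration_s)

    motion: MotionTrace | None = None
    if with_motion_trace or motion_events:
        # flat baseline trace first, then apply each event
        n_m = int(round(duration_s * 10.0))
        motion = MotionTrace(np.full(n_m, 1.0), fs=10.0, t0=0.0)
        for j, (ms, md, msc) in enumerate(motion_events):
            ppg, motion = inject_motion(
                ppg, ms, md, msc, seed=s_motion + j, motion=motion
            )

    truth = GroundTruth(beat_times=beat_times, ibis_ms=ibis, rr_brpm=resp.rr_brpm)
    return SyntheticSession(ppg=ppg, motion=motion, truth=truth)


def sample_subject_params(subject_seed: int) -> tuple[HRVParams, RespModulationParams]:
    """Draw one virtual subject's physiological parameters.

    Ranges span resting adults: heart rate 55–95 bpm, white IBI jitter
    15–40 ms, a low-frequency (Mayer-wave) heart-period oscillation of
    10–30 ms at 0.04–0.09 Hz, and respiration at 8–20 breaths/min with
    moderate baseline wander, amplitude modulation, and RSA depth
    0.02–0.08 of the mean IBI (together giving window SDNN truths of
    roughly 20–80 ms). The Mayer-wave band is kept below the respiratory
    analysis band (0.1–0.5 Hz); when the two overlap — as they can in very
    slow breathers — the frequency-modulation respiration tracer locks onto
    whichever heart-period oscillation dominates, and fusion discards the
    window.
    """
    rng = np.random.default_rng(subject_seed)
    hrv = HRVParams(
        hr_mean_bpm=float(rng.uniform(55, 95)),
        jitter_sd_ms=float(rng.uniform(15, 40)),
        lf_amp_ms=float(rng.uniform(10, 30)),
        lf_freq_hz=float(rng.uniform(0.04, 0.09)),
    )
    resp = RespModulationParams(
        rr_brpm=float(rng.uniform(8, 20)),
        bw_depth=float(rng.uniform(0.15, 0.4)),
        am_depth=float(rng.uniform(0.05, 0.15)),
        fm_depth=float(rng.uniform(0.02, 0.08)),
    )
    return hrv, resp
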