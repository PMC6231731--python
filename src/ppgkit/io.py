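"""CSV/JSON readers and writers, pipeline configuration, and the offline
pipeline runner.

Interchange formats are plain CSV: waveforms as ``time_s,<channel>...`` with
a strictly constant sampling step (1 ppm tolerance), motion as
``time_s,ax,ay,az``, per-window metrics as one row per window with
per-metric validity flags. Configuration is a nested, strictly validated
(unknown keys rejected) structure that round-trips through YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .beats import BeatConfig, BeatSeries
from .core import MotionTrace, Waveform, segment_windows
from .quality import QualityConfig
from .synthetic import GroundTruth
from .vitals import OutlierConfig, VitalsConfig, WindowMetrics, compute_window_metrics

__all__ = [
    "PipelineConfig",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_motion_csv",
    "write_motion_csv",
    "metrics_to_frame",
    "write_metrics_csv",
    "write_beats_csv",
    "write_ground_truth_json",
    "read_reference_csv",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STEP_TOLERANCE = 1e-6  # 1 ppm relative deviation of the sampling step


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BandpassSection(_Section):
    lo_hz: float = 0.3
    hi_hz: float = 10.0


class WindowSection(_Section):
    duration_s: float = 60.0


class QualitySection(_Section):
    hnr_window_s: float = 6.0
    hnr_step_s: float = 1.0
    hnr_threshold_db: float = 3.0
    motion_threshold: float = 0.25
    lag_search_s: tuple[float, float] = (0.33, 2.0)


class BeatSection(_Section):
    cwt_width_range_s: tuple[float, float] = (0.15, 0.6)
    n_cwt_scales: int = 8
    cwt_prominence_frac: float = 0.05
    prom_floor_frac: float = 0.4
    min_ibi_s: float = 0.33
    max_ibi_s: float = 2.0
    template_corr_min: float = 0.8
    stft_band_hz: tuple[float, float] = (0.5, 3.0)
    stft_energy_min: float = 0.5
    min_qualified_frac: float = 0.5
    motion_threshold: float = 0.25
    template_points: int = 50


class VitalsSection(_Section):
    mad_threshold: float = 6.25
    min_beats_per_min: float = 30.0
    rr_band_hz: tuple[float, float] = (0.1, 0.5)
    rr_quality_min: float = 0.5
    rr_agree_brpm: float = 4.0
    hr_resample_hz: float = 4.0
    rr_n_freqs: int = 32
    sd_ddof: int = 1


class PipelineConfig(_Section):
    """Full pipeline configuration; serializes losslessly to/from YAML."""

    bandpass: BandpassSection = BandpassSection()
    window: WindowSection = WindowSection()
    quality: QualitySection = QualitySection()
    beats: BeatSection = BeatSection()
    vitals: VitalsSection = VitalsSection()
    seed: int = 0
    verbosity: str = "INFO"

    # converters into the domain-module parameter objects
    def quality_config(self) -> QualityConfig:
        return QualityConfig(**self.quality.model_dump())

    def beat_config(self) -> BeatConfig:
        return BeatConfig(**self.beats.model_dump())

    def vitals_config(self) -> VitalsConfig:
        d = self.vitals.model_dump()
        d.pop("mad_threshold")
        return VitalsConfig(**d)

    def outlier_config(self) -> OutlierConfig:
        return OutlierConfig(mad_threshold=self.vitals.mad_threshold)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(json.loads(self.model_dump_json())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _validate_time_axis(time_s: np.ndarray, path: str) -> float:
    """Return fs after checking a strictly constant sampling step."""
    if time_s.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    steps = np.diff(time_s)
    med = float(np.median(steps))
    if med <= 0:
        bad = int(np.flatnonzero(steps <= 0)[0]) + 1
        raise ValueError(f"{path}: non-increasing timestamp at row {bad}")
    rel = np.abs(steps - med) / med
    bad_rows = np.flatnonzero(rel > STEP_TOLERANCE)
    if bad_rows.size:
        raise ValueError(
            f"{path}: irregular sampling step at row {int(bad_rows[0]) + 1} "
            f"(step {steps[bad_rows[0]]:.9g} s vs {med:.9g} s)"
        )
    return 1.0 / med


def read_waveform_csv(path: str | Path) -> list[Waveform]:
    """Read one waveform per value column from ``time_s,<ch>[,<ch>...]``."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_s" or df.shape[1] < 2:
        raise ValueError(f"{path}: expected header 'time_s,<channel>[,...]'")
    t = df["time_s"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError(f"{path}: non-finite timestamps")
    fs = _validate_time_axis(t, str(path))
    out = []
    for col in df.columns[1:]:
        v = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"{path}: non-finite value in column '{col}' at row {bad}")
        out.append(Waveform(v, fs=fs, t0=float(t[0]), label=str(col)))
    return out


def write_waveform_csv(path: str | Path, waveforms: Sequence[Waveform]) -> None:
    if not waveforms:
        raise ValueError("no waveforms to write")
    n, fs, t0 = waveforms[0].n, waveforms[0].fs, waveforms[0].t0
    if any(w.n != n or w.fs != fs or w.t0 != t0 for w in waveforms):
        raise ValueError("waveforms must share length, fs and t0")
    data = {"time_s": waveforms[0].times()}
    for w in waveforms:
        data[w.label] = w.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_motion_csv(path: str | Path) -> MotionTrace:
    """Read a 3-axis motion CSV (``time_s,ax,ay,az``) as a magnitude trace."""
    df = pd.read_csv(path)
    need = ["time_s", "ax", "ay", "az"]
    if list(df.columns[:4]) != need:
        raise ValueError(f"{path}: expected header 'time_s,ax,ay,az'")
    t = df["time_s"].to_numpy(dtype=float)
    fs = _validate_time_axis(t, str(path))
    axyz = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(axyz)):
        raise ValueError(f"{path}: non-finite motion values")
    mag = np.sqrt(np.sum(axyz**2, axis=1))
    return MotionTrace(mag, fs=fs, t0=float(t[0]))


def write_motion_csv(path: str | Path, m: MotionTrace) -> None:
    # magnitude stored on the z axis; x/y zero
    pd.DataFrame(
        {"time_s": m.times(), "ax": 0.0, "ay": 0.0, "az": m.magnitude}
    ).to_csv(path, index=False)


def metrics_to_frame(metrics: Sequence[WindowMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "window_start_s": m.window.start,
                "window_duration_s": m.window.duration,
                "hr_bpm": m.hr_bpm,
                "sdnn_ms": m.sdnn_ms,
                "rmssd_ms": m.rmssd_ms,
                "rr_brpm": m.rr_brpm,
                "hnr_db": m.hnr_db,
                "n_beats": m.n_beats,
                "n_outliers": m.n_outliers_removed,
                "qualified": m.recording_qualified,
                "valid_hr": m.valid.get("hr", False),
                "valid_sdnn": m.valid.get("sdnn", False),
                "valid_rmssd": m.valid.get("rmssd", False),
                "valid_rr": m.valid.get("rr", False),
            }
        )
    return pd.DataFrame(rows)


def write_metrics_csv(path: str | Path, metrics: Sequence[WindowMetrics]) -> None:
    metrics_to_frame(metrics).to_csv(path, index=False)


def write_beats_csv(path: str | Path, series: BeatSeries) -> None:
    ibis = np.append(series.ibis_ms, np.nan) if series.n_beats else np.array([])
    pd.DataFrame(
        {
            "onset_time_s": series.onset_times,
            "ibi_ms": ibis,
            "qualified": series.quality,
            "amplitude": series.amplitude,
            "rise_time_s": series.rise_time_s,
        }
    ).to_csv(path, index=False)


def write_ground_truth_json(
    path: str | Path, truth: GroundTruth, duration_s: float, n_windows: int
) -> None:
    payload = {
        "beat_times_s": truth.beat_times.tolist(),
        "ibis_ms": truth.ibis_ms.tolist(),
        "rr_brpm": truth.rr_brpm,
        "window_truth": truth.window_metrics(duration_s, n_windows),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    """Reference measurements: ``subject,session,window_start_s,metric,value``."""
    df = pd.read_csv(path)
    need = {"subject", "session", "window_start_s", "metric", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return df


def run_pipeline(
    config: PipelineConfig,
    ppg_path: str | Path,
    motion_path: str | Path | None = None,
    out_dir: str | Path = ".",
) -> tuple[list[WindowMetrics], Path]:
    """Offline end-to-end run: read → window → qualify → vitals → CSV.

    Deterministic for a given config; the per-window qualification decisions
    and counts are logged so the validity accounting can be reconstructed.
    Returns the metrics and the path of the written CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    waves = read_waveform_csv(ppg_path)
    ppg = waves[0]
    if len(waves) > 1:
        logger.info("multiple channels found; analyzing '%s'", ppg.label)
    motion = None
    if motion_path is not None:
        if Path(motion_path).exists():
            motion = read_motion_csv(motion_path)
        else:
            logger.warning("motion file %s missing; motion gating disabled", motion_path)

    windows = segment_windows(ppg, config.window.duration_s)
    metrics = compute_window_metrics(
        ppg,
        windows,
        motion=motion,
        quality_cfg=config.quality_config(),
        beat_cfg=config.beat_config(),
        vitals_cfg=config.vitals_config(),
        outlier_cfg=config.outlier_config(),
        bandpass_hz=(config.bandpass.lo_hz, config.bandpass.hi_hz),
    )
    for m in metrics:
        logger.info(
            "window %d @ %.0f s: HNR %.1f dB qualified=%s beats=%d outliers=%d "
            "valid=%s",
            m.window.index, m.window.start, m.hnr_db, m.recording_qualified,
            m.n_beats, m.n_outliers_removed,
            "".join(k[0] for k, v in m.valid.items() if v) or "-",
        )
    out_csv = out_dir / "metrics.csv"
    write_metrics_csv(out_csv, metrics)
    return metrics, out_csv
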