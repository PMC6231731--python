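"""Method-comparison statistics for device validation.

Paired test/reference measurements (per subject, session and window) are
summarized with mean (absolute / percentage) errors, Pearson correlation,
and Bland–Altman limits of agreement. Because validation studies collect
multiple windows per subject, the repeated-measures variant of the
Bland–Altman SD is used: a one-way variance-components decomposition of the
differences (subject as the grouping factor) combines within-subject and
between-subject variance, so the limits of agreement are not narrowed by
treating repeated windows from one person as independent. The Bland–Altman
ratio normalizes the half-width of the limits (1.96 x SD) by the mean of
the pairwise measurement means.

Paired data are held in a pandas DataFrame with columns ``test`` and
``ref`` (plus ``subject`` for repeated-measures analyses); pairs exist only
where both devices produced a valid value for the same window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core import segment_windows
from .vitals import WindowMetrics, compute_window_metrics

__all__ = [
    "BlandAltmanResult",
    "ErrorMetrics",
    "align_beats",
    "error_metrics",
    "pearson",
    "bland_altman",
    "bland_altman_plot",
    "window_sensitivity",
    "bilateral_agreement",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("hr_bpm", "sdnn_ms", "rmssd_ms", "rr_brpm")


class ErrorMetrics(NamedTuple):
    n: int
    mae: float
    mae_sd: float
    mape: float | None
    mape_sd: float | None
    me: float
    me_sd: float


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ba_ratio: float
    n_pairs: int
    n_subjects: int
    ci_bias: tuple[float, float]
    repeated_measures: bool


def _ibi_step(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """IBI-vs-time step function: value over [t_k, t_k+1) is that interval."""
    ibis = np.diff(times)
    return times, ibis


def align_beats(
    test_times: np.ndarray,
    ref_times: np.ndarray,
    max_lag: float = 10.0,
    step: float = 0.25,
    grid_hz: float = 4.0,
) -> float:
    """Time offset (s) aligning a test beat series to a reference series.

    The offset maximizing the cross-correlation of the two IBI-vs-time step
    functions (sampled on a uniform grid) is searched over ``±max_lag`` at
    ``step`` granularity; the offset is to be *added* to the test times.
    Raises when the best correlation is below 0.5 (series unrelated).
    """
    test_times = np.asarray(test_times, dtype=float)
    ref_times = np.asarray(ref_times, dtype=float)
    if test_times.size < 10 or ref_times.size < 10:
        raise ValueError("need at least 10 beats in each series")

    def step_fn(times: np.ndarray, t: np.ndarray) -> np.ndarray:
        ibis = np.diff(times)
        idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, ibis.size - 1)
        return ibis[idx]

    best_r, best_off = -np.inf, 0.0
    for off in np.arange(-max_lag, max_lag + step / 2, step):
        lo = max(ref_times[0], test_times[0] + off)
        hi = min(ref_times[-1], test_times[-1] + off)
        if hi - lo < 5.0:
            continue
        t = np.arange(lo, hi, 1.0 / grid_hz)
        x = step_fn(ref_times, t)
        y = step_fn(test_times + off, t)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r:
            best_r, best_off = r, float(off)
    if best_r < 0.5:
        raise ValueError("alignment failed")
    return best_off


def error_metrics(pairs: pd.DataFrame) -> ErrorMetrics:
    """MAE, MAPE and mean error (each with sample SD) of test vs reference.

    Pairs whose reference is zero are excluded from MAPE (with a warning);
    SDs are sample SDs of the per-pair quantities (0 for a single pair).
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    t = pairs["test"].to_numpy(dtype=float)
    r = pairs["ref"].to_numpy(dtype=float)
    diff = t - r
    ad = np.abs(diff)
    nz = r != 0
    if not np.all(nz):
        logger.warning("%d pairs with zero reference excluded from MAPE", int((~nz).sum()))
    ape = 100.0 * ad[nz] / np.abs(r[nz])

    def sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return ErrorMetrics(
        n=len(pairs),
        mae=float(np.mean(ad)),
        mae_sd=sd(ad),
        mape=float(np.mean(ape)) if ape.size else None,
        mape_sd=sd(ape) if ape.size else None,
        me=float(np.mean(diff)),
        me_sd=sd(diff),
    )


def pearson(pairs: pd.DataFrame) -> float:
    """Product-moment correlation of test vs reference."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    t = pairs["test"].to_numpy(dtype=float)
    r = pairs["ref"].to_numpy(dtype=float)
    if np.std(t) == 0 or np.std(r) == 0:
        raise ValueError("zero variance")
    return float(_st.pearsonr(t, r).statistic)


def bland_altman(pairs: pd.DataFrame, repeated_measures: bool = False) -> BlandAltmanResult:
    """Bland–Altman agreement of test vs reference.

    With ``repeated_measures`` the SD of differences combines the
    between-subject variance of the subject-mean differences with the
    within-subject variance, estimated by one-way variance components
    (subject as factor)::

        sd_diff^2 = sigma_between^2 + sigma_within^2
        sigma_within^2 = MSW,   sigma_between^2 = (MSB - MSW) / n0

    where n0 is the variance-components average group size. Without it the
    classic formula (sample SD of all differences) is used. The 95% CI on
    the bias uses a t distribution with (subjects - 1) df under repeated
    measures, (pairs - 1) otherwise.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = (pairs["test"] - pairs["ref"]).to_numpy(dtype=float)
    mean_of_means = float(np.mean((pairs["test"] + pairs["ref"]) / 2.0))
    bias = float(np.mean(d))
    n = d.size

    use_rm = repeated_measures
    n_subjects = n
    if repeated_measures:
        if "subject" not in pairs.columns:
            raise ValueError("repeated_measures requires a 'subject' column")
        groups = pairs.assign(_d=d).groupby("subject")["_d"]
        n_subjects = groups.ngroups
        sizes = groups.size().to_numpy(dtype=float)
        if n_subjects < 2 or np.all(sizes == 1):
            logger.warning(
                "repeated-measures Bland–Altman needs >=2 subjects with repeats; "
                "falling back to the simple SD"
            )
            use_rm = False

    if use_rm:
        means = groups.mean().to_numpy(dtype=float)
        grand = bias
        I, N = n_subjects, n
        ssb = float(np.sum(sizes * (means - grand) ** 2))
        ssw = float(groups.apply(lambda g: float(np.sum((g - g.mean()) ** 2))).sum())
        msb = ssb / (I - 1)
        msw = ssw / (N - I) if N > I else 0.0
        n0 = (N - float(np.sum(sizes**2)) / N) / (I - 1)
        sigma_b2 = max(0.0, (msb - msw) / n0)
        sd_diff = float(np.sqrt(sigma_b2 + msw))
        se = float(np.std(means, ddof=1) / np.sqrt(I))
        df = I - 1
    else:
        sd_diff = float(np.std(d, ddof=1))
        se = sd_diff / np.sqrt(n)
        df = n - 1

    tcrit = float(_st.t.ppf(0.975, df)) if df >= 1 else float("nan")
    loa_low = bias - 1.96 * sd_diff
    loa_high = bias + 1.96 * sd_diff
    ba_ratio = (1.96 * sd_diff) / abs(mean_of_means) if mean_of_means != 0 else float("inf")
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        ba_ratio=ba_ratio,
        n_pairs=n,
        n_subjects=n_subjects,
        ci_bias=(bias - tcrit * se, bias + tcrit * se),
        repeated_measures=use_rm,
    )


def bland_altman_plot(pairs: pd.DataFrame, result: BlandAltmanResult, path: str) -> None:
    """Write a Bland–Altman scatter (difference vs pairwise mean) to a file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (pairs["test"] + pairs["ref"]) / 2.0
    diffs = pairs["test"] - pairs["ref"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.6)
    ax.axhline(result.bias, color="k")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference (test - reference)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _metrics_to_pairs(
    metrics: Sequence[WindowMetrics],
    truth_rows: Sequence[dict],
    metric: str,
    subject: object = 0,
    session: object = 0,
) -> pd.DataFrame:
    rows = []
    for m, tr in zip(metrics, truth_rows):
        mv = getattr(m, metric)
        tv = tr.get(metric)
        if mv is not None and tv is not None:
            rows.append(
                {"subject": subject, "session": session,
                 "window": m.window.index, "test": mv, "ref": tv}
            )
    return pd.DataFrame(rows, columns=["subject", "session", "window", "test", "ref"])


def window_sensitivity(
    sessions: Sequence,
    durations: Sequence[float] = (60.0, 45.0, 30.0),
    metrics: Sequence[str] = METRIC_COLUMNS,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Re-segment and re-analyze recordings at several window durations.

    ``sessions`` are synthetic sessions (waveform + motion + retained
    truth); for each duration the full pipeline is re-run and per-metric
    error statistics against the per-window truth are tabulated. Returns a
    long-format DataFrame with columns duration_s, metric, n, mae, mae_sd,
    me, me_sd.
    """
    rows = []
    for dur in durations:
        frames: dict[str, list[pd.DataFrame]] = {m: [] for m in metrics}
        for si, sess in enumerate(sessions):
            wins = segment_windows(sess.ppg, dur)
            mets = compute_window_metrics(
                sess.ppg, wins, motion=sess.motion, **pipeline_kwargs
            )
            truth = sess.truth.window_metrics(dur, len(wins), t0=sess.ppg.t0)
            for m in metrics:
                frames[m].append(_metrics_to_pairs(mets, truth, m, subject=si))
        for m in metrics:
            nonempty = [f for f in frames[m] if len(f)]
            pairs = (
                pd.concat(nonempty, ignore_index=True)
                if nonempty
                else frames[m][0]
            )
            if len(pairs) == 0:
                rows.append({"duration_s": dur, "metric": m, "n": 0,
                             "mae": None, "mae_sd": None, "me": None, "me_sd": None})
                continue
            em = error_metrics(pairs)
            rows.append({"duration_s": dur, "metric": m, "n": em.n,
                         "mae": em.mae, "mae_sd": em.mae_sd,
                         "me": em.me, "me_sd": em.me_sd})
    return pd.DataFrame(rows)


def bilateral_agreement(
    left: Sequence[WindowMetrics],
    right: Sequence[WindowMetrics],
    metrics: Sequence[str] = METRIC_COLUMNS,
) -> pd.DataFrame:
    """Pairwise mean absolute left/right difference per metric.

    Windows are paired by index where both sides are valid; returns a
    DataFrame with columns metric, n, mean_abs_diff, sd (empty rows where no
    common valid windows exist).
    """
    right_by_idx = {m.window.index: m for m in right}
    rows = []
    for metric in metrics:
        diffs = []
        for lm in left:
            rm = right_by_idx.get(lm.window.index)
            if rm is None:
                continue
            lv, rv = getattr(lm, metric), getattr(rm, metric)
            if lv is not None and rv is not None:
                diffs.append(abs(lv - rv))
        if diffs:
            arr = np.asarray(diffs)
            rows.append({"metric": metric, "n": arr.size,
                         "mean_abs_diff": float(np.mean(arr)),
                         "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0})
        else:
            rows.append({"metric": metric, "n": 0, "mean_abs_diff": None, "sd": None})
    return pd.DataFrame(rows)
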