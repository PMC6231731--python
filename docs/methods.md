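# Methods

This note documents the models and estimators in ppgkit, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions that affect results.

## Signal model and preconditioning

A PPG recording is a uniformly sampled scalar series (IR channel by
default, nominally 86 Hz). All cardiac-band analysis runs on a zero-phase
band-passed copy: a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`, so an 8th-order magnitude response with no phase delay),
with band edges 0.3–10 Hz. The band isolates the cardiovascular component —
respiratory baseline wander sits below 0.3 Hz, wide-band noise above 10 Hz —
and zero-phase filtering is essential because beat *timing* is the
measurand. Analysis windows are nonoverlapping half-open tiles
(`[start, start + duration)`, sample index `round(t·fs)`, default 60 s);
the trailing remainder of a recording is discarded.

## Harmonic-to-noise ratio (signal qualification)

HNR measures periodicity from the normalized autocorrelation of the
mean-removed signal, after Boersma: the segment is Hann-windowed, the
biased (divide-by-n) autocorrelation is computed by FFT and divided by the
autocorrelation of the window function itself, which removes the taper of
the biased estimator so that a perfectly periodic signal reads r(τ) ≈ 1 at
its period. The maximum r* over lags 0.33–2.0 s (heart periods for 30–180
bpm) gives

    HNR = 10·log10( r* / (1 − r*) )  [dB],

clipped to [−20, +40] dB to keep the r* → 1 singularity finite. The lag
maximum is refined by parabolic interpolation across the lag grid. For a
sinusoid of power P in white noise of variance σ², r* ≈ P/(P+σ²), so the
estimator reads ≈ 10·log10(P/σ²); this is the oracle the tests check
(within 1.5 dB across SNR 1–31.6). Without the window-function correction
the biased estimator under-reads by several dB at 6-s windows, which is why
the correction is part of the estimator and not optional.

Recording-level HNR averages 6-s windows centered 1 s apart, the first
centered at 3 s so every window fits entirely (a 60-s recording gives
exactly 55 windows). A recording qualifies for vitals when its mean HNR is
at least `hnr_threshold_db` (default 3 dB — roughly twice as much harmonic
as noise power; the appropriate cut-off is device-specific and therefore
configurable) and its motion envelope stays below threshold.

Caveat: at high HNR the estimator's sensitivity grows like 1/(1−r*), so
small residuals (e.g. imperfectly removed baseline wander) move the dB
value noticeably; near the qualification threshold (~3–10 dB), where the
decision matters, a sub-band wander component at half the cardiac
amplitude shifts HNR by well under 1 dB after the 0.3 Hz high-pass.

## Beat segmentation

*Detection.* The band-passed signal is transformed with a Mexican-hat CWT
at 8 logarithmic scales spanning plausible pulse widths (0.15–0.6 s full
width, i.e. Gaussian σ ≈ 0.04–0.15 s), and the scale-averaged response is
searched for local maxima with a permissive prominence floor (5% of the
response span). This stage is deliberately a superset of the true apices.

*Selection.* Candidates with prominence below 40% of the 75th-percentile
candidate prominence are discarded (sub-pulse ripples), then candidates are
accepted greedily in order of decreasing prominence (ties: earlier time),
each only if it lies at least `min_ibi_s` (0.33 s) from every accepted
beat — so of two crowding candidates the more prominent survives, and the
result is independent of input order. If the dominant frequency of the
selected train falls outside the heart-rate band the series is flagged
unreliable.

*Refinement.* Apex times are refined by 3-point parabolic interpolation —
applied to the scale-averaged CWT response rather than the raw samples.
The response acts as a matched filter for the pulse, which keeps
beat-timing noise at moderate SNR several times below one sample; for
symmetric pulses its maximum coincides with the waveform apex, and any
small shape-induced offset is common to all beats and cancels in the
intervals.

*Fiducial choice.* Interbeat intervals are measured apex-to-apex. The
preceding waveform valley (systolic onset / foot) is also located and
reported through the amplitude and rise-time features, but it is not used
as the timing fiducial: between well-separated pulses the valley sits in a
broad, nearly flat region whose minimum moves with the neighbouring
intervals, so valley-to-valley IBIs cannot reach sub-sample accuracy. For
pulses of stable shape the two conventions differ only by a constant
offset, which cancels in all interval statistics.

*Per-beat qualification.* With at least 3 beats, each beat's segment
(half a median IBI on either side of the apex, linearly detrended) must
(a) correlate at least 0.8 with the point-wise median beat template on a
50-point resampled grid, (b) hold at least half of its short-time spectral
energy in 0.5–3.0 Hz, and (c) not overlap motion samples whose magnitude
deviates from the trace median by more than the motion threshold. An
interval enters downstream statistics only when both bounding beats
qualify and the interval itself lies in [0.33, 2.0] s.

## Vitals

*Ectopic filtering.* An IBI is removed (without replacement) when its
logarithm is more than 6.25 (unscaled) median absolute deviations from the
median log-IBI; median and MAD are computed over the full recording and
applied within each window. The MAD is deliberately not scaled by the
normal-consistency factor 1.4826; the 6.25 threshold is calibrated to the
unscaled statistic. If the MAD is zero the rule degenerates and an absolute
log-deviation threshold of log(1.5) is used instead (flagged in the
result).

*Time-domain metrics.* HR = 60000/mean(IBI) bpm; SDNN = sample SD (n−1;
configurable to population SD); RMSSD = √mean(ΔIBI²). A window reports
these only when it qualifies, holds at least `min_beats_per_min·duration/60`
qualified beats (default 30 per 60 s, scaling to 23/15 at 45/30 s), and at
least half of its detected beats qualified.

*Respiration rate.* Two estimators, both restricted to 0.1–0.5 Hz
(6–30 brpm, resting adults):

- **Baseline wander**: the raw (pre-high-pass) window is band-limited to
  the respiratory band (2nd-order Butterworth, zero-phase) and breath
  cycles are detected with the same CWT peak detector, scales matched to
  breath half-periods. The rate is the mean cycle length expressed in
  brpm — using peak-to-peak spans rather than a cycle count divided by the
  window length avoids ±1 brpm quantization. Quality is cycle regularity
  (1 − CV of cycle lengths) multiplied by the fraction of respiratory-band
  spectral power within ±20% of the detected rate; the spectral factor is
  essential because narrow band-filtered *noise* is always quasi-periodic
  and would otherwise pass on regularity alone.
- **Frequency modulation (RSA)**: instantaneous HR (60000/IBI at interval
  midpoints, qualified and outlier-filtered intervals only) is linearly
  resampled to a uniform 4 Hz grid, detrended, and transformed with a
  Morlet CWT at 32 log-spaced pseudo-frequencies across the band. The
  ridge (per-time argmax of power, parabolically interpolated across
  scales to remove grid quantization, 10% of columns trimmed at each edge)
  is traced and the median ridge frequency × 60 is the rate. Quality is
  the fraction of band power within ±20% of the ridge frequency.

Estimates with quality below 0.5 are discarded. If both survive they must
agree within 4 brpm and are fused by a quality-weighted mean; disagreement
reports no RR for that window (a wrong value is worse than a missing one).
Because both estimators are band-limited, any reported RR lies in 6–30
brpm. Known confound: a strong Mayer-wave (LF, ~0.04–0.15 Hz) heart-period
oscillation overlapping the respiratory band can capture the FM ridge; the
fusion rule then discards the window because BW and FM disagree.

## Validation statistics

Pairs exist only where both methods produced a valid value for the same
window. MAE, MAPE (zero-reference pairs excluded, with a warning) and mean
error are reported with sample SDs. Bland–Altman limits of agreement are
bias ± 1.96·SD of differences; with repeated measures per subject the SD
combines one-way variance components of the differences,

    sd² = σ²_between + σ²_within,  σ²_within = MSW,
    σ²_between = (MSB − MSW)/n₀,

with n₀ the variance-components average group size and σ²_between clipped
at zero; a single subject (or no repeats) falls back to the classic sample
SD with a warning. The 95% CI of the bias uses a t distribution with
(subjects − 1) df under repeated measures. The Bland–Altman ratio is
(1.96·SD)/|mean of pairwise means|. Beat-series alignment maximizes the
correlation of the two IBI-vs-time step functions on a 4 Hz grid over
±max_lag at 0.25 s steps and fails below correlation 0.5; the recovered
offset absorbs pulse-transit-time delay, which is physiologic and cannot
be separated from clock offset.

## Synthetic generator

IBIs: `ibi_k = mean_ibi·(1 + fm_depth·sin(2π f_resp t_k)) +
lf_amp·sin(2π f_lf t_k) + ε_k`, ε white Gaussian; beat times are the
cumulative sums (an IBI ≤ 0 raises). Waveform: per beat a systolic
Gaussian bump (amplitude 1, σ = 0.10 s) plus a dicrotic bump (30%
amplitude, +0.30 s delay, 1.2× width); the pulsatile sum is multiplied by
`1 + am_depth·sin(2π f_resp t)`, baseline wander `bw_depth·sin(2π f_resp t)`
and white noise are added. The `snr` argument sets the noise variance from
the measured pulsatile AC power. Motion artifacts are tapered random-walk
transients (RMS ≈ `scale`) with a matching elevated segment in a 10 Hz
motion-magnitude trace that is otherwise flat at 1 g.

The virtual study conditions (`sample_subject_params`) draw resting adults:
HR 55–95 bpm, IBI jitter 15–40 ms, LF oscillation 10–30 ms at 0.04–0.09 Hz,
RR 8–20 brpm, baseline wander 0.15–0.4 of pulse amplitude, AM 0.05–0.15,
RSA depth 0.02–0.08 of the mean IBI — together yielding window SDNN truths
of roughly 20–80 ms. The Mayer band is kept below the 0.1 Hz edge of the
respiratory analysis band so RR truth stays identifiable.

Fidelity limits, hence what passing recovery tests do **not** show: RSA is
sinusoidal IBI modulation, not phase-coupled integral-pulse-frequency
modulation; pulse morphology is fixed per session (no beat-to-beat shape
variation, no site- or perfusion-dependent morphology); breathing is
perfectly periodic; noise is white and Gaussian rather than colored or
pulsatile-correlated; motion corrupts additively rather than decoupling
the sensor. Recovery error bounds on this generator demonstrate the
pipeline's correctness and numerical accuracy, not its performance on
human recordings.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global state. Pipeline analysis itself
  is deterministic.
- Window boundary convention is half-open with `round(t·fs)` indexing, so
  interval-to-window assignment is reproducible; an interval belongs to a
  window iff both bounding beats fall inside it.
- Flat signals: empty candidate list (detection), error (HNR).
- Parabolic refinement at a boundary sample or over a degenerate (flat)
  triple returns the unrefined time with a flag.
- HNR values are clipped to [−20, 40] dB; r* is clipped just below 1.
- Fewer than 3 beats: no template, all beats unqualified. Fewer than 2
  usable IBIs in a window: HR/SDNN/RMSSD absent, never an exception.
- CSV ingestion rejects non-finite samples and irregular time steps
  (>1 ppm relative deviation), naming the first offending row; repair or
  interpolation is out of scope.

## Benchmark sizes

The test suite and the acceptance script use 70 sessions of 120 s for the
recovery study, 8–10 sessions of 150 s for the 60/45/30-s window
re-analysis, 200 random IBI batteries for the ectopic-filter cross-check,
and 60-s signals for the HNR oracle — sizes chosen so the complete
benchmark reruns from scratch in tens of seconds while every window-level
statistic still rests on ≥ 100 paired measurements.
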