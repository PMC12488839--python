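# Methods

This note documents the models, numerical choices and limitations behind
each pipeline stage, in the order the data flow through them.

## Synthetic HD-sEMG generator

**What it emulates.** One recording session per participant × condition:
a 13 × 5 monopolar electrode grid (8 mm inter-electrode distance, 2048 Hz,
μV) over the knee extensors during 9 maximal isometric contractions of 5 s
separated by 15 s of rest, with breath-by-breath heart rate, ventilation
and oxygen uptake over the 3-minute task and an endpoint SpO₂ per
condition. The contraction envelope is rectangular (on/off): the task has
no force ramp, so no recruitment dynamics are modelled.

**Discharge trains.** Inter-spike intervals are Gaussian with mean
`1/mean_dr` and SD `isi_cv/mean_dr`, truncated below at a 10 ms refractory
floor (scipy's truncated normal). Defaults: `isi_cv = 0.15`, discharge
rates drawn per motor unit around a condition/sex/subject-dependent centre
(see *Condition effects*). Discharge times are kept at sub-sample (float)
resolution; signal synthesis rounds them to the nearest sample.

**Action potentials.** The motor-unit action potential (MUAP) is the first
derivative of a Gaussian (biphasic), duration parameter `dur_ms = 6` with
sigma = `dur_ms`/12 (0.5 ms), giving a 1 ms peak-to-peak transient. The
sharp rise keeps spectral energy beyond the 500 Hz analysis corner, which
real MUAPs retain through the gentle 2nd-order acquisition roll-off; this
matters because the pulse-to-noise ratio of a perfectly recovered source
is bounded by the source's bandwidth — a brick-wall 20–500 Hz impulse
train at 2048 Hz caps near 26.9 dB under the PNR definition used here, so
a spectrally duller wavelet would make the 28 dB acceptance gate
unattainable for *any* decomposition algorithm, which contradicts the
empirical regime the gate comes from (clean units at ≈ 28–35 dB).

Within each column the waveform at row *r* is the base wavelet delayed by
`|r − iz_row| · IED / cv_true` (bidirectional propagation away from the
innervation zone; sub-sample delays via frequency-domain phase shift,
valid because the wavelet vanishes at the window edges), with amplitude
decaying as `exp(−|r − iz_row| / 3 rows)`. An optional non-propagating
end-of-fiber bump at the two extreme rows is off by default (needed only
to exercise channel-exclusion logic). Innervation zones are drawn without
replacement from the middle third of the grid: motor-unit territories are
spread along the muscle, and two units sharing both innervation zone and
conduction velocity are physically indistinguishable at the grid.

**Superposition and noise.** The signal is the sum over motor units of
the spike train convolved with the per-channel template, plus white
Gaussian noise per channel (default RMS 2 μV for sessions, 1 μV for the
decomposition fixture — both below the 20 μV resting-noise QC bound).
No volume conductor, no fatigue dynamics, no motion artifacts: passing
tests show algorithmic correctness on data obeying the propagation model,
not robustness to tissue filtering or electrode artifacts.

**Condition effects (defaults).** Motor-unit discharge rate (pps) and
conduction velocity (m/s) are drawn as
`base + sex offset + condition shift + subject intercept + unit noise`:

| quantity | base | sex (F/M) | CON/H1/H2 shift | subject SD | unit SD |
|---|---|---|---|---|---|
| discharge rate | 15.5 | +0.75 / −0.75 | 0 / +0.3 / +1.0 | 1.5 | 2.0 |
| conduction velocity | 4.1 | −0.35 / +0.35 | 0 / +0.10 / +0.25 | 0.4 | 0.35 |

SpO₂ endpoints are Normal(97.1, 0.90), (91.3, 1.60), (86.9, 1.83) % for
CON/H1/H2. Exercise-phase HR 95/103/110 bpm, V̇e 30/35/41 L/min, V̇O₂
900/940/990 mL/min, with breath-level noise (3 bpm / 3 L·min⁻¹ /
60 mL·min⁻¹), subject-level offsets, ~2.5 s breath intervals and 2%
outlier contamination. These cardiorespiratory levels are plausible for
maximal intermittent knee extension; they are generator choices, not
measured values. Directions (CV and IDR rise from CON to H2, males higher
CV, SpO₂ falls) mirror the physiology the analysis is designed to detect.

## Preprocessing

Band-pass: 20–500 Hz Butterworth of order 2, applied forward–backward
(`sosfiltfilt`) so spike timing is not biased by group delay. The
acquisition hardware's own 10–500 Hz filter is not emulated (configurable
upstream of this stage if desired). Resting-noise QC flags channels with
RMS ≥ 20 μV and warns rather than fails — on synthetic data it is a
sanity check, as in acquisition it is a pre-recording criterion.
Segmentation defaults to protocol mode (fixed 5 s windows at declared
onsets); detection mode thresholds the grid-mean RMS envelope (250 ms
window) at 5 × resting RMS, keeps runs ≥ 2 s and merges gaps < 1 s —
those constants are this module's own, chosen to track the 5 s/15 s
protocol. Contraction selection restricts to the first five bouts
(fatigue guard), ranks by grid-mean RMS and keeps the top two, ties to
the earlier bout. The double differential is the centre-negative second
difference along columns; it annihilates common-mode and row-linear
fields exactly and yields 11 × 5 channels from the 13 × 5 grid.

## Decomposition

Gradient convolution-kernel-compensation / fixed-point ICA with deflation
on the band-passed **monopolar** observations (the DD montage is reserved
for the MUAP/CV stage):

* channel extension with factor 16 (the ~1000-extended-channels heuristic
  for a 64-channel grid; at 10 the whitened sources of even perfectly
  recovered units fall 1–2 dB short of the 28 dB gate);
* whitening by eigenvalue decomposition with a relative eigenvalue floor
  of 1e-8 (rank deficiency is floored, never fatal);
* 50 extraction runs, each initialized at a high-activity sample,
  fixed-point iterations with the skewness contrast g(u) = u·|u| to
  cosine convergence (tol 1e-4, ≤ 100 iterations; non-convergent runs are
  dropped and logged);
* spike-triggered refinement: peaks of the squared source (10 ms
  refractory distance), 2-means clustering of peak heights
  (parameter-free spike/noise split), separation vector re-estimated as
  the mean whitened observation at spike times, iterated while the ISI
  coefficient of variation improves;
* quality gate: pulse-to-noise ratio ≥ 28 dB on the unit-normalized
  source with a ±1-sample guard band around spikes excluded from the
  off-spike set, and ≥ 5 discharges;
* deduplication: greedy by descending PNR; two trains are duplicates when,
  after alignment by the best constant lag within ±30 ms, more than 30%
  of the smaller train's discharges coincide within ±0.5 ms. The ±30 ms
  window covers the constant offsets that extension (16 samples) plus the
  waveform's internal propagation delays (up to ~25 ms at low CV) can
  introduce; spike-train agreement scores use the same alignment.

The PNR gate plus deduplication replace the operator's visual editing,
which cannot be specified reproducibly. Decomposition of real maximal
contractions is much harder than this synthetic setting (MUAP
superposition, waveform nonstationarity); the ground-truth agreement
demonstrated here (≥ 0.9, typically 1.0) validates the implementation,
not field performance.

## Motor-unit properties

Instantaneous discharge rate is the reciprocal inter-spike interval. The
smoothed profile convolves the IDR sequence with a unit-sum 4-point
Hanning kernel with nonzero endpoints — the interior samples of a 6-point
Hann window, weights sin²(πk/5)/Σ, k = 1…4 ≈ (0.138, 0.362, 0.362,
0.138) — with partial windows at the edges renormalized to unit sum
(a 'valid' convolution would discard edge discharges of these short
maximal-contraction trains). Trains with fewer IDR values than the kernel
fall back to the raw mean and are flagged. The mean smoothed discharge
rate averages the full train (no sub-window is defined for this task).

MUAP templates are spike-triggered averages over a 50 ms window
(`round(0.05·fs)` = 102 samples) on the DD montage; triggers whose window
leaves the segment are dropped and counted, never zero-padded (unbiased
averaging).

Channel selection for conduction velocity works per column on the
mean-removed 50 ms templates: adjacent-pair normalized cross-correlation
maximized over lags (sub-sample peak by parabolic interpolation), pairs
admissible when the coefficient ≥ 0.8, the delay sign is consistent and
the delay magnitude maps into the physiological CV range 2–8 m/s (a
zero-lag pair — identical waveforms — implies infinite CV and is
rejected, as are non-propagating end-of-fiber channels). Where
consecutive pair lags flip sign, the shared channel sits on the
innervation zone and mixes both propagation directions: both pairs
touching it are rejected, which keeps the selected run on one side of the
zone. Among columns with runs of ≥ 2 contiguous channels the highest mean
pair correlation wins (ties: longer run, then lower column index); runs
of exactly 2 channels are visible in the output (`n_channels`) for
sensitivity checks. If no column qualifies, CV is undefined for that unit
and it is excluded from CV summaries only.

CV itself is the maximum-likelihood delay under additive Gaussian noise:
minimize the summed squared error between each channel and the mean of
all channels aligned under the pure-propagation model (channel *k*
delayed by *k*·θ), channels normalized to unit energy (the model
constrains timing, not amplitude — MUAP amplitude decays along the
array). Delays are applied by frequency-domain phase shift; θ is located
by a 41-point grid over the admissible range in both propagation
directions and polished by bounded scalar minimization (xatol 1e-12).
Estimates at the admissible-range boundary are flagged unreliable.
`CV = IED·fs/|θ|`. On noiseless synthetic templates recovery is exact to
optimizer precision; at 20 dB SNR the median error is well under 1%.

Participant × condition summaries use the **median** across motor units
(robust to outlying units); empty cells propagate missing values, never
imputed.

## Cardiorespiratory responses

Breath series are cleaned per variable by a centred rolling median
(window 9 breaths): a breath is an outlier when its absolute deviation
from the rolling median exceeds 3 × 1.4826 × rolling MAD (any deviation,
when the MAD is zero); outliers are replaced by linear interpolation over
time, endpoints clamped to the nearest valid breath. Non-flagged breaths
are never altered. Series shorter than the window pass through with a
warning. These parameters are this module's own contract; they are
deliberately conservative.

Exercise medians are taken over the full 3-minute physical-task window by
default. HVR and HCR divide the hypoxia-minus-normoxia rise in V̇e / HR by
ΔSpO₂ **defined as normoxia minus hypoxia** — stated prominently because
a sign error here inverts every response metric; both are positive when
ventilation or heart rate rise while saturation falls. ΔSpO₂ = 0 yields a
missing value with a warning; a saturation *rise* in hypoxia is legal and
flips the sign (logged). ΔIDR, ΔCV and ΔV̇O₂ are simple
hypoxia-minus-normoxia differences of participant-level values, not
normalized to desaturation.

## Statistics

IDR observations are filtered once (non-iteratively) at |z| > 2.5 over
all motor-unit observations, then natural-log transformed; CV is analysed
untransformed. The mixed model is
`response ~ condition * sex + (1 | participant)`, REML, fit by
statsmodels' `MixedLM`; sum-to-zero factor coding makes each term's Wald
F a Type-III marginal test. Satterthwaite denominator degrees of freedom
are not available from statsmodels, so they are computed on top of the
fit: the REML profile log-likelihood of the random-intercept model is
written in closed form (per-group Woodbury identities), its numerical
Hessian at the fitted variance components gives their covariance, the
delta method gives per-contrast dfs, and multi-df terms combine
eigen-direction dfs as in lmerTest. The whole layer is validated to 3–4
significant figures against an independent lmerTest/emmeans run on an
identical table (variance components, Type-III F and dfs, pairwise
contrasts, ML AIC/BIC) — see `tests/test_stats.py`.

Effect sizes: η²p = F·df1/(F·df1 + df2) and f = √(η²p/(1 − η²p)).
Marginal/conditional R² follow the standard mixed-model definitions
(fixed-effect variance over total; fixed plus random over total). The
random effect is tested by a boundary-corrected (½·χ²₁) likelihood ratio
against the fixed-effects-only model, both fit by ML. Pairwise condition
contrasts are estimated-marginal-mean differences averaged over sex, with
Satterthwaite t tests and Holm step-down correction.

Model calibration is verified by simulation: under the null generator the
condition term rejects at the nominal 5% (500 scaled-down cohorts of 12
participants × 4 units; the reduced size keeps the check fast without
changing the calibration question), and an injected +0.3 m/s condition
effect is detected with the correct direction in ~100% of cohorts.

Correlations are Pearson's r with two-sided t-based p values, pairwise
deletion of missing values; a Shapiro–Wilk screen is logged, not
enforced; constant inputs yield flagged missing coefficients. The mixed
models use motor-unit-level observations (random intercept absorbing the
repeated structure), while correlations use participant-level medians —
the two levels at which the corresponding questions are posed.

## Known limitations

* The generator has no volume conductor: amplitude decay and innervation
  zone mixing are phenomenological. CV recovery on real tissue will be
  noisier than the synthetic figures.
* Decomposition performance is reported against synthetic ground truth;
  the real study's unit yield cannot be reproduced and is not claimed.
* The random structure is intercept-only; condition-by-participant random
  slopes are not modelled (and not identifiable at 2 contractions ×
  condition).
* Breath-by-breath cleaning parameters are conventions, not estimates;
  all are keyword-configurable.
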