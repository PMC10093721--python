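# Methods

## Problem and pipeline

`ppg2bp` estimates systolic and diastolic arterial pressure (SBP/DBP,
mmHg) from the shape of the photoplethysmogram. The premise is
physiological: pulse amplitude, pulse width and heart period co-vary with
arterial pressure, so a regression model trained on waveform-shape
features against arterial-line references can predict pressure from the
optical signal alone. The pipeline is strictly staged — preprocess →
segment → extract 24 features → regress → evaluate — and every stage is a
pure function of its inputs plus an explicit configuration object, so runs
are reproducible from (data, config, seed).

## Preprocessing

**Baseline wander removal.** Wander is the sub-0.5 Hz drift under the
pulse train (respiration, motion, perfusion changes). The estimate is a
two-pass running median (0.6 s then 1.2 s windows): the short pass
flattens individual pulses, the long pass smooths the residual steps. A
raw median of a continuously oscillating signal still carries intra-beat
ripple (the median inside a window shorter than one beat tracks intra-beat
structure), so the estimate is band-limited with a zero-phase 4th-order
Butterworth low-pass at 0.5 Hz — the defining band of wander — before
subtraction. With this design the correction is idempotent on clean
signals to within ~2% of pulse amplitude, removes a 0.2 Hz unit-amplitude
drift to a residual under 3%, and perturbs pulse shape under drift by
less than 0.1 amplitude units (all measured in the test suite). All three
constants are configurable (`baseline.window1_s`, `baseline.window2_s`,
and the smoothing cutoff).

**Low-pass filtering.** 4th-order Butterworth at 5 Hz, applied
forward-backward (`sosfiltfilt`). Zero phase preserves pulse timing, which
the slope/derivative features depend on; the effective response is the
squared magnitude, giving ≥ 40 dB at twice the cutoff.

**Segmentation.** Fixed-length left-aligned windows, default 8 s with no
overlap, trailing partial window dropped; 0-based half-open sample
coordinates. 8 s holds at least six beats at 50 bpm, enough support for
the entropy estimators. Whether to window per-beat instead is a genuinely
open design point; fixed windows were chosen for their deterministic
segment count and because window-mean references are robust to single odd
beats.

**Reference extraction.** Systolic peaks in the ABP window are local
maxima above the 60th amplitude percentile with a 0.33 s refractory
period; each beat's diastolic value is the minimum over the inter-peak
interval preceding its peak (the pre-upstroke trough). The window's
references are the means over detected beats. Windows with fewer than two
peaks are excluded and counted. On noise-free synthetic records the
extracted references equal the generator's truth exactly, because the
synthetic ABP places its extrema on sample points.

## The 24 features

Seventeen time-domain features are the established EMG amplitude/
complexity family applied to PPG: MAV, waveform length, zero crossings,
slope-sign changes, RMS, average amplitude change, DASDV, log detector,
the enhanced variants EMAV/EWL (position-dependent exponent P = 0.75 in
the central half of the window, 0.5 at the edges), the modified MAVs
(central-half weighting; constant 0.5 vs linear 4i/L ramps at the edges),
myopulse percentage rate, simple square integral, variance, Willison
amplitude, and maximum fractal length log₁₀√Σ(Δx)². Conventions worth
noting:

* VAR is computed **without mean subtraction** ((1/(L−1))Σx²), matching
  its printed definition in this feature family; after baseline removal
  segments are near-zero-mean, so it approximates the usual variance.
* ZC/SSC thresholds default to 0; WAMP and MYOP thresholds default to
  0.5·SD(x). SD-relative thresholds make the counts invariant to PPG gain,
  which differs across sensors.
* The log detector floors |x| at 1e−12 so exact zeros do not produce −∞;
  the perturbation to the geometric mean is negligible.

Seven chaotic features quantify regularity and complexity:

* **Sample entropy** (m = 2, r = 0.2·SD, Chebyshev distance, inclusive
  matching, self-matches excluded, both template counts over the same
  N−m starting positions). When no (m+1)-template pair matches, the
  conventional finite bound log(B+1) is returned so feature tables stay
  finite; a constant signal scores 0.
* **Approximate entropy** by the standard Φᵐ − Φᵐ⁺¹ construction with
  self-matches included.
* **Fuzzy entropy** here is the fuzzy-set (De Luca–Termini) membership
  entropy of min–max-normalized |x|: (1/L)Σ −[μ log μ + (1−μ)log(1−μ)].
  This is a per-sample membership-uncertainty measure, *not* the
  template-matching FuzzyEn common elsewhere in the PPG literature; the
  choice follows the feature table this package implements, and the
  tolerance/gradient parameters are retained in `FeatureParams` for
  forward compatibility although this form does not use them.
* **Shannon entropy** of a 16-bin equal-width amplitude histogram,
  natural log, empty bins skipped.
* **Permutation entropy**, order 3, delay 1, natural log, unnormalized;
  ties broken by index order (stable sort), so a constant signal has a
  single pattern and entropy 0.
* **Higuchi fractal dimension**, kmax = 10: slope of log L(k) vs
  log(1/k) over the standard offset-averaged curve lengths.
* **Katz fractal dimension** log₁₀n / (log₁₀(d/L) + log₁₀n) with L the
  total absolute first-difference length, d the maximum amplitude
  excursion from the first sample, n = N−1 steps; constants return 1 (a
  line) by convention.

All entropies use the natural logarithm; the fractal formulas use log₁₀ as
printed. Every optimized estimator is paired with an independent
brute-force loop implementation (`ppg2bp.naive`) and the two are held to
1e-10 agreement on random segments in the test suite.

## Regression models

Features are z-scored inside `fit()` (constants stored on the results
object), making all seven models invariant to affine rescaling of any
feature column. Targets are modelled per-pressure (separate SBP and DBP
fits).

* `linear` — OLS via least squares; rank-deficient designs (e.g. a
  constant feature column) fall back to the pseudo-inverse solution with
  a logged warning.
* `robust_linear` — IRLS with Huber loss, tuning constant 1.345 (the
  standard 95%-efficiency choice), via statsmodels RLM.
* `gpr_rq` / `gpr_se` / `gpr_matern52` — exact GP regression
  (scikit-learn) with kernel σ_f²·c(·) + white noise. Hyperparameters are
  optimized by L-BFGS on the log marginal likelihood from three fixed
  length-scale starts (0.5, 2, 8 in z-scored units), best likelihood
  wins; the iteration budget is capped at 40 per start. Fits are
  therefore deterministic without any seed. The white-noise level is
  bounded below (1e-6 in normalized-target units) and a 1e-10 jitter
  guarantees Cholesky stability. `gpr_matern52` implements the true
  Matérn 5/2 form (1 + √5r/σ + 5r²/3σ²)e^(−√5r/σ); a config switch
  `as_printed=True` selects the Matérn 3/2 (√3) form for comparison,
  since the two are easy to conflate in print. `gpr_rq` exposes the shape
  parameter α (freeze with `alpha_fixed`); as α → ∞ the RQ kernel
  collapses onto the squared exponential, a limit verified to 1e-4
  prediction RMSE in the tests.
* `svm_linear` / `svm_gaussian` — ε-insensitive SVR. Defaults are
  scale-adaptive: C = IQR(y)/1.349 (a robust SD estimate of the target),
  ε = C/10. The Gaussian kernel scale defaults to σ = √p with p = 24
  features (the common "medium" preset), used as exp(−r²/2σ²).

Every default is a documented hyperparameter, not a constant.

## Evaluation

Cross-validation is a shuffled k-fold split (default k = 10; 5 is a
supported alternative since both appear in practice) from an explicit
seed. Every row is predicted exactly once out of fold; the headline
metrics are computed on the pooled out-of-fold vector (per-fold metrics
are retained for dispersion). R² is the standard coefficient of
determination 1 − SSE/SST about the target mean. MAPE is reported as
undefined (NaN with reason) when a reference value is zero. Bland–Altman
uses predicted − actual differences and ±1.96·SD (n−1) limits of
agreement. The BHS grading maps (SBP, DBP) to eight categories with
inclusive printed bounds; the higher-severity grade wins when the two
pressures disagree, and SBP ≥ 140 with DBP < 90 is labelled isolated
systolic hypertension (Grade 2 when SBP ≥ 160).

## Synthetic data: what it emulates and what it does not

The generator is a statistical stand-in for bedside recordings, not a
hemodynamic model. Per beat it draws heart period (via rate ~ N(70, 3²)
bpm), pulse amplitude ~ N(1, 0.15²) and Gaussian pulse width ~ N(0.14,
0.012²) s; the PPG is systolic + dicrotic Gaussians (dicrotic ratio 0.35)
plus a 0.25 Hz, 0.3-unit baseline sinusoid and white noise (SD 0.02); the
sampling rate defaults to 125 Hz, the common bedside-monitor waveform
rate. SBP/DBP are **linear** in (amplitude, width, period) — defaults
SBP = 115 − 25a + 60w + 10T, DBP = 65 − 10a + 30w + 5T — plus 1 mmHg
Gaussian map noise, and the ABP channel is a piecewise pulse whose
per-beat extrema land exactly on those values at sample points. The PPG
systolic peak sits at 0.65 of the beat while the ABP peak sits early
(≈0.3); this pulse-arrival lag makes the waveform-level correlation
between the normalized channels negative (≈ −0.23 under defaults), the
qualitative relationship seen in bedside data. Seeding is per-record
((seed, record_index) pairs), so records are independent and individually
reproducible.

What passing tests on this generator do **not** show: robustness to real
artifacts (motion, clipping, probe detachment), to nonlinear or
subject-specific feature→pressure physiology, to non-stationary pressure
trends within a record, or to the distribution shift between subjects.
The linear map with small noise makes recovery *easy* by construction;
results on synthetic data are a correctness check of the pipeline, not a
clinical performance claim. Published per-beat errors of a few mmHg on
intensive-care waveform databases are not reproducible from this
generator and are not targeted by the test suite.

## Numerical choices and degenerate inputs

* All amplitudes are double precision end to end; text round-trips use
  17-significant-digit formatting and exact float parsing.
* WFDB export digitizes to 16-bit with per-channel gain spanning the
  signal range; round trips are exact to half an ADC step. CSV is the
  lossless interchange format.
* Constant signals: baseline correction returns zeros; SampEn, fuzzy,
  Shannon and permutation entropy return 0; Katz and Higuchi return 1;
  log detector returns the constant.
* Windows with no detectable ABP beats are excluded with a logged count
  rather than raising.
* Robust (Huber IRLS) fits need residual degrees of freedom to estimate
  scale; when n ≤ p + 1 the fit falls back to the least-squares solution
  with a logged warning.
* Segment counts follow floor((N − L)/step) + 1; a signal shorter than
  one window yields an empty segment list, not an error.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data
sized for quick, deterministic verification: feature-table studies use
n = 500 segments; oracle-equivalence checks use 50 segments of length
≤ 400; the end-to-end study uses 8 records of 90 s (≈ 88 windows). These
sizes were chosen so each statistical check has comfortable power while a
full run stays in the minutes range on a single core.

## Known limitations

* The `evaluation` CLI and library report GPR predictive variance but do
  not calibrate it; only point predictions are scored.
* No signal-quality indexing beyond the no-beat exclusion rule; grossly
  corrupted windows will produce features, not rejections.
* The WFDB reader supports single-.dat, format-16 records — enough for
  interchange with the common waveform-database layout, not a full
  implementation of the format family.
* MAPE is undefined for zero references; physiological pressures never
  hit zero, so this matters only for malformed input.
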