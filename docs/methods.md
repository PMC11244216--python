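# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions (tie-breaks, tolerances, degenerate inputs) that
matter when reproducing results.

## Synthetic ECG model

A beat is a sum of five Gaussian bumps, one per wave, in conventional
lead-II polarity. Defaults at a 1 s beat period (amplitude a.u. / center
offset from R in s / Gaussian sd in s):

| wave | amplitude | offset | width |
|------|-----------|--------|-------|
| P    | +0.15     | −0.18  | 0.025 |
| Q    | −0.12     | −0.035 | 0.008 |
| R    | +1.00     |  0.00  | 0.010 |
| S    | −0.25     | +0.04  | 0.009 |
| T    | +0.35     | +0.22  | 0.050 |

These values make R the global per-beat extremum and T larger than P,
matching ordinary lead-II morphology; they are conventional choices, not
fits to any particular recording. At heart rates other than 60 bpm both
offsets and widths are multiplied by sqrt(RR) — a Bazett-style rate
adaptation, reflecting that the QT interval (and, less strongly, PR)
shortens as the rate rises. Without this scaling a fixed 0.12–0.20 s pre-Q
search window at 180 bpm would land on the previous beat's T wave; with it,
beats from 40 to 180 bpm keep every wave inside the correspondingly scaled
search windows.

R-to-R intervals carry uniform ±2% jitter by default (switch off with
`rr_jitter=0`) so the beat grid is not perfectly periodic. Ground-truth
fiducials are the actual extrema of the clean rendered signal within
±2.5 sd of each wave center (capped at the midpoint to the neighboring
wave), so overlap between adjacent bumps is reflected in the truth rather
than idealized away.

Noise terms, all seeded and drawn in a fixed order so that toggling one
source does not shift another's draws:

* baseline wander — a sinusoid, default amplitude 0.15 a.u. at 0.25 Hz,
  random phase (respiration/electrode-motion drift);
* mains interference — a sinusoid at 50 Hz (or 60), default 0.10 a.u.;
* impulse noise — isolated single-sample spikes, Poisson-thinned at 0.2
  spikes/s, amplitude ±1.0 a.u. (the artifact class the median stage
  targets);
* white Gaussian noise — sd 0.02 a.u.

Inversion is applied as a final global sign flip, which guarantees the
exact sample-wise negation symmetry used by the polarity tests.

What the generator does **not** emulate: physiologic heart-rate
variability beyond white RR jitter, arrhythmia-specific morphologies
(ectopy, fibrillation), electrode-motion transients longer than one
sample, amplitude modulation by respiration, or recording-device
quantization. Passing tests therefore demonstrate correctness of the
algorithmic chain under controlled morphology and noise, not clinical
performance on pathological rhythms.

## Filtering

* `response_magnitude` implements the analytic band-edge model
  1/(1+(f/f_c)^(2n)): gain 1 at DC, exactly 0.5 at the cut-off for every
  order, monotone decreasing. It is the testable specification of the
  band edge, not a realizable digital filter.
* The realizable band-pass is a Butterworth (default order 2, 0.5–100 Hz,
  fs 360 Hz) applied forward-backward (`sosfiltfilt`), because zero phase
  is what keeps fiducial indices from being systematically delayed. The
  forward-backward pass squares the magnitude response, which only deepens
  stop-band attenuation.
* Median filter: default window 3 samples (the minimal window that removes
  isolated spikes while leaving wave flanks intact); boundaries handled by
  edge replication. Window 1 is the identity; even windows are rejected.
* Notch: IIR notch at the mains frequency, quality factor 30 (≈1.7 Hz
  bandwidth at 50 Hz), zero-phase. The default chain order is median →
  band-pass → notch so spikes cannot ring through the IIR stages.

## Polarity

Clustering is 1-D K-means over sample amplitudes (k = 5, k-means++, ten
restarts, fixed seed, ≤300 iterations). Amplitudes are min-max scaled to
[−1, 1] before clustering — making the fit gain-invariant — and centroids
are mapped back to original units. The polarity rule compares the extreme
centroids: inverted iff |most negative| > |most positive|, with the
quotient reported as the evidence ratio. The rule is the package's own
construction (a cluster-level formalization of "the dominant deflection
should be positive"); correction is a single global negation, an exact
involution. Degenerate inputs (constant signals, fewer distinct amplitudes
than clusters) raise rather than guess.

## Delineation

R detection: local maxima (plateaus resolved to their first sample)
exceeding `threshold_factor` (default 0.5) × a rolling amplitude envelope,
then a 0.2 s refractory period resolved greedily by amplitude, earlier
index winning ties. The envelope is a centered 2 s rolling maximum by
default. A rolling high quantile is available via the `quantile`
parameter, but on clean synthetic morphology the 95th percentile sits near
the T-wave amplitude, which makes any fixed factor either admit T peaks or
reject everything across the 40–180 bpm range; the rolling maximum is
scale-free and rate-robust, and the detector is provably equivariant to
positive amplitude scaling.

Q/S are window minima and T/P window maxima, with the windows given in the
README; all argmin/argmax tie-breaks take the earliest sample. Fractional
window lengths (14.4 and 28.8 samples at 360 Hz) are floored, consistent
with fiducial tables whose printed rows show constant R−Q = 14 and
S−R = 28. Beats whose windows cross a signal boundary, or whose located
points violate P < Q < R < S < T (possible under tachycardic overlap), are
dropped and counted in a warning. Indices are 0-based throughout,
including CSV export.

The default windows describe beats near 60 bpm.
`FiducialWindows.for_heart_rate(bpm)` rescales all five durations by
sqrt(60/bpm), mirroring the generator's rate adaptation; the 40–180 bpm
recovery results are computed with these rate-scaled windows.

## Anomaly labelling

Isolation Forest with 100 estimators, contamination "auto",
random_state 42 — deterministic for a fixed table. Default features are
the five raw index columns exactly as tabulated; because raw indices grow
with recording time, a whole-beat displacement is visible to the forest
only when it leaves the column's marginal range, which is why the injected
outliers in the acceptance suite are offset by 10× the R-column standard
deviation. An `intervals` feature mode (RR, PR, QRS, QT, ST durations) is
provided for stationary, position-free screening; raw-index features can
conflate a beat's position in the recording with its physiology, so
interval mode is the better choice on long recordings.

`inject_fiducial_outliers` shifts whole rows (all five columns together),
preserving within-beat ordering while breaking the across-row trend; the
perturbed table intentionally violates the "R strictly increasing"
file-validation invariant, which is enforced at the IO boundary, not here.
The observed false-positive rate of the auto-thresholded forest on
50-row tables is noticeably nonzero (the threshold is conservative on
small samples); the suite's guaranteed quantity is the true-positive rate.

## Cohort generator and risk models

Binary risk factors are independent Bernoulli draws at the configured
rates (defaults: 74.2% male, 45% chest pain, 43.18% alcohol, 31.06%
diabetes, 55.30% smoking, 37.12% ECG change). Age is uniform on 28–68
years. Blood pressure is truncated-normal, mean 129.93 mmHg, sd 12,
support [94, 200]; cholesterol truncated-normal mean 225 mg/dL, sd 40,
support [126, 341]. The sd values are chosen so the truncation shifts the
means by well under one standard error at n = 10,000 and the supports are
respected exactly.

The condition outcome uses a logistic link on standardized continuous
features and rate-centered binaries with coefficients (age 0.8, sex 0.2,
chest pain 0.9, blood pressure 0.7, cholesterol 0.6, alcohol 0.3,
diabetes 0.8, ECG change 1.0, smoking 0.6; intercept 0.2), giving
prevalence near 54% and learnable but noisy signal. `separable(margin)`
switches to a deterministic threshold on the same risk score and resamples
rows whose |score| falls inside the margin band. The default margin of
2.5 logit units (~1.3 sd of the score) is what "wide margin" means here:
it was set so that even the least margin-tolerant family in the
comparison — a single axis-parallel decision tree generalizing across an
oblique 9-D boundary — clears high accuracy, which is the regime the
separability checks are meant to probe.

Model comparison: 50 repeats (default) of stratified 80/20 splits; a
z-score scaler and fresh model instances are fit per training fold only
(no test-fold statistics reach the models). The six families are logistic
regression (lbfgs, ≤1000 iterations), an unpruned decision tree, a
100-tree random forest, an RBF SVM (C = 1), XGBoost (100 rounds, depth 3,
η = 0.3), and an in-package numpy 1-D CNN: valid convolution with kernel 3
and 16 filters over the 9-feature vector, ReLU, dense layer to one logit,
sigmoid; full-batch Adam (lr 0.01, 300 epochs), He/Glorot initialization
from a fixed seed, single-threaded. F1 with no predicted and no true
positives is reported as 0 with a warning. With fixed seeds the full
report is bit-reproducible.

`standardize_features` uses the population sd (ddof = 0) so that a
balanced binary column maps exactly to ±1 and the standalone scaler agrees
with the in-fold scaler. Correlation is plain Pearson on all ten columns;
entries involving a constant column are NaN, never zero. Boxplot summaries
use linear-interpolation quartiles and 1.5·IQR outlier fences.

## Problem sizes and tolerances

The shipped checks run at desk scale: 10–50 s traces at 360 Hz, 100-trace
polarity populations, 50-beat anomaly tables with 20 seeded injections,
and 132–400-row cohorts with 5–10 split repeats — sizes at which every
stochastic quantity reported has comfortably converged while the whole
suite plus the acceptance script completes in a couple of minutes on one
core. Fiducial recovery is asserted to ±3 samples (≈8 ms at 360 Hz) on
clean signals; spectral checks allow 5% ripple in the passband and demand
≥90% attenuation at 0.1 Hz and at the mains frequency; cohort marginal
checks use 3-sd binomial bounds.

## Known limitations

* The polarity rule assumes an R-dominant morphology; leads where the
  physiologic dominant deflection is negative would be "corrected"
  wrongly.
* The R detector is designed for filtered, polarity-corrected signals;
  it is not a Pan–Tompkins-class detector and is not validated against
  arrhythmic rhythms.
* Raw-index anomaly features inherit the position/physiology confound
  described above.
* The CNN is a deliberately small architecture for 9-feature vectors, not
  a general tabular deep-learning baseline.
* WFDB record ingestion is not included; signals enter via the CSV
  dialects (or directly as in-memory arrays).
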