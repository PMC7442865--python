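# Methods

## Measurement model

The device couples the eye, the enclosed air volume and the loudspeaker
membrane into one oscillatory system.  Each loudspeaker excitation produces
a decaying membrane oscillation recorded by the displacement sensor, which
the pipeline models as a damped sinusoid

    x(t) = A · exp(−λ t) · sin(2π f t) + baseline(t) + ε(t),

with decay rate λ (1/s), frequency f (Hz, device band 350–570 Hz), slow
baseline drift from subject movement and additive Gaussian sensor noise ε.
The chamber-pressure channel shows a touchdown overpressure when the device
seals against the orbit; a measurement without that pattern never started.

## Synthetic cohort and recordings

The generator's defaults are the study conditions: 96 subjects, two eyes,
four measurements per eye, 20 pulses per measurement, 10 kHz sampling,
evaluation from 5 s, pulses every 0.5 s from 5.5 s.  Biometric covariates
are Gaussian per eye (age 61.7 ± 17.1 y; IOP 16.4 ± 4.4 / 17 ± 5.7 mm Hg
OD/OS; visual acuity 0.7 ± 0.3; cornea radius 7.8 ± 0.3 mm; corneal
thickness 546.9 ± 36.4 / 544 ± 37.6 µm; axial length 24 ± 3.1 / 24.2 ± 1.7
mm; anterior chamber depth 3.1 ± 0.7 mm), clipped to physiological ranges,
with inter-eye correlation 0.8 (applied to IOP as well — eyes of one
subject are physiologically correlated, and only per-eye marginals are
otherwise constrained).

The latent acoustic state of an eye comes from an invented, deliberately
smooth and invertible forward model

    f = f0 + a_f (IOP − 16) + b_f (AL − 24),
    λ = d0 · exp(−a_d (IOP − 16)) · (1 + b_d (CCT − 545)/545),

defaults f0 = 450 Hz, a_f = 4 Hz/mm Hg, b_f = 6 Hz/mm, d0 = 150 1/s,
a_d = 0.03 /mm Hg, b_d = 0.3.  Only the *existence* of IOP sensitivity is
established by the measurement principle; the functional form and
coefficients are package choices that keep f inside the device band for
IOP 8–35 mm Hg and make the map recoverable, so calibration quality can be
scored against ground truth.  No attempt is made to predict clinical
coefficient values.

Disturbances, all config-exposed:

* sensor noise, default SD 2% of pulse amplitude — chosen once so the
  within-measurement damping CV lands in the low-single-digit-percent
  regime clinical recordings showed (≈ 2%);
* smooth baseline drift (sum of < 0.5 Hz sinusoids, default amplitude 30%
  of pulse amplitude);
* **chamber-coupling jitter**: each placement realises λ and f with a
  multiplicative perturbation (default 5% SD on λ, 1% on f).  Seal and
  placement quality differ between measurements; without this term the
  extracted features recover IOP to ~0.1 mm Hg equivalent and calibration
  is trivially perfect, which no physical device achieves;
* failure modes drawn per measurement: `no_start` (no touchdown, no
  pulses; default 6.8%), `movement` (extra slow excursions, nearly all
  pulses overdriven into the ±1.2·A sensor rail; 30%), `leakage` (λ × 1.6,
  f × 0.92, otherwise undetectable; default 0), `pressure_deviation`
  (out-of-band chamber swing; 0.5%).  The rates mirror the published
  success-rate table so the taxonomy shares are reproduced in expectation.
  Movement corrupts essentially all pulses of its measurement on purpose:
  it keeps the mode → category mapping deterministic, which the share
  checks rely on.

Touchdown is a 100 Pa step at 2.8 s relaxing (τ = 1 s) toward a 30 Pa seal
plateau; magnitudes are package choices (only the timing and the existence
of the pattern are constrained).

## Signal processing

Baseline balancing happens twice: a coarse bin-median spline makes onset
detection drift-free, then the final baseline is a cubic spline through the
medians of 20 ms quiet windows between responses ("interpolation using
third-order polynomials"), held constant outside the anchored span.  With
fewer than four anchors a single cubic fit is used (logged).  The procedure
is idempotent for polynomial offsets; sub-0.5 Hz sinusoidal drift is
removed to about 1%.

Onsets are where the 2 ms magnitude envelope exceeds 5× the noise floor
(1.4826·MAD); windows are 40 ms or until the next onset.  Clipping is
judged on the *raw* trace (rail contact precedes baseline removal).

Per pulse, estimators run on the above-noise analysis region (trimmed at
both ends at max(5× noise floor, 1% of peak) on a short envelope):

* **frequency** — interpolated zero crossings, f̂ = (n−1)/(2(t_last −
  t_first)), crossings debounced at 0.5 ms (the band's shortest
  half-period is 0.88 ms, so no genuine crossing can be dropped).  The
  crossing count used by the validity rule is the same debounced count;
  a raw sign-change count would be inflated by tail noise.  An FFT peak
  with parabolic interpolation is kept as an internal cross-check only:
  the zero-crossing form is the same primitive the validity rules use.
* **damping** — least-squares slope of ln A_i against t_i, where A_i is a
  per-half-cycle RMS envelope magnitude, A_i² = 2(mean x² − floor²).
  Subtracting the noise variance makes A_i unbiased; raw extremum heights
  are inflated preferentially at the decayed tail and biased λ̂ low by
  3–6% at the 2% noise level, versus +0.3% for this form.  The
  per-half-cycle decay factor is constant, so it moves the intercept, not
  the slope.  Noiseless worst-case errors over the band grid: < 0.01% (f),
  < 0.5% (λ).

Measurement summaries average valid pulses only (averaging per-pulse
features, not waveforms: both readings of the protocol are defensible and
feature averaging keeps single corrupted pulses from contaminating the
mean); the damping spread is reported both as SD and as CV (%), since the
clinical "2.1%" figure does not disambiguate the two.

## Validity rules and taxonomy

Valid pulse: ≥ 7 zero crossings, 350 ≤ f ≤ 570 Hz (closed interval — "from
350 to 570" read inclusively), not clipped.  Undefined frequency rejects as
out-of-band.  Measurement categories, in precedence order (invented; the
clinical table reports disjoint counts without tie-breaking): `no_start`
(no touchdown or zero pulses; the pressure channel is primary, pulse
presence secondary), `pressure_deviation` (any evaluation-window sample
> 3× the touchdown overpressure from the window median), `quality_fail`
(< 3 valid pulses), else `expectancy_compliant`.

## Calibration network and trial protocol

Inputs are z-scored with training-set statistics stored in the model; the
label (reference IOP, mm Hg) likewise.  Architecture 9–7–10–1, tanh hidden
layers, identity output; full-batch L-BFGS (up to 400 iterations) on the
squared error with a small L2 penalty (1e-5), keeping the weights with the
best validation error seen along the path.  The original evaluation was
MATLAB-era; neither optimiser nor activation is constrained, and L-BFGS
makes desk-scale repetition cheap and deterministic.

The nine-input set is a documented guess: the six biometric covariates plus
mean damping and mean frequency make eight, and mean pulse amplitude is the
ninth; the list is config-overridable.

Split 70/15/15, stratified by reference-IOP tertile with rotated
largest-remainder allocation; all rows of one subject stay in one
partition (no subject leakage into the test split — the protocol only
states that a share is separated).  The test split touches no gradient
step and no selection decision; `TrialEnsemble.assert_test_isolation()`
verifies it from the stored indices.

Trials differ only in weight initialisation (that is what traps trainings
in different local minima).  Each is scored on validation data by slope
and R of prediction vs. reference; selection ranks trials by the rank-sum
of |slope − 1| and (1 − R) — the protocol says "combination" without a
formula, and a rank-sum is scale-free in both ingredients.  Degenerate
constant predictors rank last.  Desk default: 200 trials, keep 10%
(semantics of 100,000/best-1000 preserved via `keep_fraction`; the full
scale is configuration, not code).  The ensemble prediction is the mean of
the selected models' outputs.

## Agreement

Differences are prediction − reference.  U = k_p · SD(d) with the n−1
sample SD and the coverage factor applied exactly as k_p = 2 (not the
Gaussian 1.96).  Regression is prediction-on-reference (the direction is
not fixed by the protocol; this one makes the slope a sensitivity).  The
report flags whether U < 5 mm Hg, the approval threshold for tonometers.

## Problem sizes and numerical choices

Desk-scale runs use 96 subjects × 2 eyes × 4 measurements (768 recordings)
for the study simulation, 150 eyes / 200 trials for noiseless recovery, 60
trials per condition for the noise-degradation ladder, and 10 trials per
cell for the 81-architecture scan; these sizes make the whole suite run in
minutes while keeping every statistical check inside its sampling band.
Master seeds fan out through `numpy.random.SeedSequence([master, tag, ...])`
so each measurement and trial has an independent, order-insensitive
substream and full runs are byte-identical under a fixed seed.

## What passing tests do and do not show

The generator reproduces the *structure* of clinical recordings — pulse
physics, touchdown semantics, failure taxonomy, covariate priors,
within-measurement reproducibility — and the pipeline demonstrably
recovers known ground truth through the full chain.  It does not model
orbital acoustics from first principles, eye pulsation, undetected chamber
leakage at clinical rates, reference-tonometer error, or the real
covariate–IOP dependence; the clinical headline numbers (U = 6.53 mm Hg,
slope 0.73, R 0.83) depend on the unreleased 828-record cohort and are
*regimes*, not targets, for the synthetic study.  Accordingly the synthetic
expanded uncertainty (~2 mm Hg at defaults) is smaller than the clinical
value: the simulation contains fewer unexplained cross-sensitivities than
reality did.

## Known limitations

* The forward model is monotone and smooth by construction; real
  eye-to-eye acoustic variation is certainly richer.
* Quiet-anchor detrending assumes inter-pulse gaps exist; continuous
  oscillation would starve it of anchors (it falls back to one cubic).
* The damping estimator needs ≥ 3 usable half-cycles; heavily damped
  pulses (λ well above 400 1/s) at high noise become undefined and are
  rejected by the gate rather than estimated badly.
* `pressure_deviation` and `no_start` thresholds (300 Pa, 50 Pa/0.2 s) are
  package choices; only the qualitative behaviour is constrained.
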