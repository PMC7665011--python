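# Methods

This note documents the generative model behind the synthetic recordings,
the estimators, the numerical choices, and what the parameter-recovery
tests do and do not demonstrate.

## The experiment being modelled

A longitudinal DSM strip is mounted in an organ bath under a 5 mN preload.
Early in the recording a 60 mM KCl challenge elicits the reference
contraction used to normalize every later amplitude (removing strip-size
dependence). After washout the strip shows quasi-periodic spontaneous
contractions; EFS trains (0.5 ms pulses, 100 V, 10 Hz, train duration
0.4–10 s, one train every 3 min) evoke neurogenic contractions; drugs are
applied as timed windows. Recordings are uniformly sampled tension traces
(mN) with an annotation sidecar marking the KCl window, EFS trains and drug
windows.

## Generative model

Tension is a sum of independent components on a shared time grid:

```
x(t) = baseline + drift·t + KCl(t) + Σ spontaneous bumps + Σ EFS responses
       + Σ drug transients + N(0, σ²)
```

* **KCl pulse** — exponential rise (τ = 2 s) to `kcl_amp_mN` over the
  annotated window, exponential washout (τ = 20 s) after it. Rhythmic
  activity is suppressed until 180 s after the window ends, by which time
  the washout residual is < 10⁻³ of the pulse; this keeps the reference
  amplitude and the analysis segment clean.
* **Spontaneous contractions** — a renewal process: inter-event intervals
  are gamma-distributed with mean 1/`fsc_true` and coefficient of variation
  `period_cv` (default 0.1). Each event is a flat-topped tapered-cosine
  bump of height `asc_true·kcl_amp/100`, width `event_duty/fsc_true`
  (duty default 0.5) and peak-dwell fraction `event_plateau` (default
  0.35). The dwell at the peak is what gives the amplitude histogram its
  second mode; a pure raised cosine (plateau 0) has an arcsine value
  density with no mass *at* the peak and the histogram estimator then
  under-reads the amplitude by more than a percent even without noise.
* **EFS responses** — total amplitude follows the duration-saturation law
  `A(D) = efs_Amax·(1 − exp(−D/efs_tauD))` (τ_D default 1.3 s, so the
  curve saturates by ~4 s). The response splits into a fast
  non-cholinergic kernel (rise τ 0.5 s) and a slow cholinergic kernel
  (rise τ 2 s) in constant proportions `chol_fraction_plateau`/(1 − c);
  both rise until 2 s past the train end and decay with τ 5 s. While an
  atropine window is active the cholinergic part is zeroed. Because the
  slow kernel has not fully risen at short trains, the measured
  atropine-blockable share grows with duration and levels just above 0.51
  at D ≥ 4 s for the configured 0.52 — mirroring the levelling behaviour
  of the real dissection.
* **Drug transients** — alpha-function baseline shift
  `tension_amp·(t/τ)·exp(1 − t/τ)` (τ default 60 s) from window onset;
  while a window is active, its `asc_fold`/`fsc_fold`/`efs_fold`
  multiply event height, event rate and EFS amplitude respectively
  (`efs_fold = 0` models a full neurogenic block).
* **Noise** — white Gaussian, σ default 0.02 mN (0.2 % of the default KCl
  amplitude), a realistic digitized-transducer noise floor. Slow drift
  defaults to 0 and is exercised explicitly in segment-selection tests.

Group defaults anchor the published control/cancer contrast: control
`asc_true` 4.6 % of KCl, `fsc_true` 0.047 Hz, cholinergic plateau fraction
0.52; cancer 2.8 %, 0.027 Hz, with the cholinergic plateau component
divided by 3.54 and the non-cholinergic by 1.38 (hence `efs_Amax` 29.7 %
against the control 60 % — the 60 % plateau itself is a morphology-level
choice, not a published number; only component *ratios* and the plateau
fraction are anchored). Drug defaults: GSK1016790A tension 7 %/4.5 % of
KCl and A_SC fold 2.2/1.3 for intact/denuded control, fold 1.3 and
unchanged f_SC in cancer; TEA doubles amplitude and frequency in control
but leaves frequency unchanged in cancer; capsaicin and cannabidiol carry
plausible mid-range values for quantities the source prints only as bar
graphs.

Cohorts draw per-strip unit-mean lognormal factors (CV `strip_cv`,
default 0.10) on amplitude and frequency parameters from seeds spawned off
the master seed, so cohort means are unbiased for the configured values
and runs are exactly reproducible. The default CV is deliberately smaller
than the published between-strip SD/mean ratios (≈ 0.6 for A_SC): those
printed SDs mix biological spread with measurement scatter, and a
9-strip recovery design needs the ensemble mean to estimate the group
value to well under 10 %. The full printed spread can be requested via
`strip_cv`.

## Estimators

* **Stationary segment** — sliding 60 s windows every 10 s; each window's
  baseline is its 10th-percentile level (a lower envelope, so contraction
  bumps do not read as drift); the longest run of windows whose
  step-to-step baseline slope stays below 1 % of the KCl amplitude per
  minute (default) and lasts ≥ 300 s is selected. KCl/EFS/drug windows
  plus washout margins are excluded from the search.
* **Amplitude histogram** — equal-width bins; count by Freedman–Diaconis
  clamped to [30, 200]. Bin *centers* span [min, max] (edges extended half
  a bin) so extreme values sit at centers rather than on edges — otherwise
  a noise-free plateau value falls on a bin edge and the fit inherits a
  half-bin bias per side.
* **Two-Gaussian fit** — least squares of
  `a₁·exp(−(x−μ₁)²/2σ₁²) + a₂·exp(−(x−μ₂)²/2σ₂²)` against bin counts
  (the histogram itself, not a density MLE), means initialized at the
  10th/90th amplitude percentiles with perturbed restarts, means bounded
  to the observed amplitude range, σ bounded below by a quarter bin.
  Components are returned with μ₁ < μ₂. The fit is flagged *unimodal* —
  and A_SC reported as 0 with a warning, since a quiescent strip is a
  valid observation — when the means are closer than the mean width or
  when one component carries under 5 % of the fitted area.
* **Spectrum** — Welch periodogram, Hann taper, linear detrend, 50 %
  overlap; per-segment length chosen so the resolution is at least a fifth
  of the search-band low edge (so a 0.005 Hz band edge needs ≥ 1000 s of
  data). f_SC is the argmax in the band (default 0.005–0.5 Hz, bracketing
  the published 0.027–0.047 Hz with margin), refined by parabolic
  interpolation over the three bins around the peak, and must exceed 4×
  the band median power — otherwise a "no dominant rhythm" error.
* **EFS amplitude** — peak minus the median of the 10 s pre-stimulus
  window, over [onset, onset + duration + 30 s] (the 30 s tail captures
  the slow cholinergic peak); negative differences clamp to zero.
  Peak-minus-baseline (not area) is used, consistent with "amplitude".
* **Dissection** — per-duration fractions clamped to [0, 1] (noise can
  push A_ATR marginally above A_pre); plateau = mean over durations ≥ 4 s,
  computed per strip then averaged across strips.
* **Drug effects** — lower-envelope baseline (rolling 10th percentile over
  30 s, EFS windows masked) for the tension shift, reported at its signed
  extremum (drug transients are peaks, not steady states). Spontaneous
  parameters are re-estimated on stationary segments before the window and
  from 90 s after onset (skipping the transient); the pre/post band is
  0.015–0.4 Hz since the within-window segments are shorter than a full
  recording.
* **Statistics** — pooled-variance Student t-test by default (Welch behind
  a flag), df = n₁ + n₂ − 2, two-sided; strips are the unit of analysis,
  pooled across animals — a pseudo-replication caveat that is documented,
  not "corrected", to match the analysis being reproduced. No
  multiple-testing correction (footnoted in the report).

## What the synthetic tests show — and what they do not

Parameter recovery on this generator demonstrates that the estimator chain
is unbiased and correctly normalized *for signals of this structure*:
renewal-timed smooth bumps on a stable baseline, saturating EFS responses,
alpha-shaped drug transients, white noise. Real organ-bath data add
slow non-linear drift, amplitude run-down, temperature and perfusion
artefacts, occasional movement spikes, and spontaneous activity whose
shape and rhythm wander within a recording. Passing recovery tests here
does not certify behaviour under those conditions; the stationarity gate
and the robust (median/percentile) baselines are the defences, and the
recovery suite verifies them only against the failure modes the generator
can express (linear drift, timing jitter, noise).

Numerical edge cases: constant segments raise a degenerate-histogram
error; a fit that cannot converge after three restarts raises with
diagnostics; zero pooled variance yields t = 0, p = 1 for equal means and
a degenerate flag otherwise; fold-to-percent rejects folds below 1
(percent-increase is a different report path).

## Problem sizes

Default recovery runs use 9-strip cohorts of 1800 s at 10 Hz for
spontaneous activity, 10 strips of ~3510 s for the pre/post-atropine
duration series, and 10 strips of 1800 s for drug windows — enough for
≤ 5 % ensemble-mean error on every anchored quantity while a full
recovery run completes in seconds.
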