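# Methods

## Audiometric metrics

Air-conduction thresholds live on a 5-dB grid in [−10, 120] dB HL; a
stimulus not heard at the equipment limit is recorded as *no response*.
PTA averages 0.5/1/2 kHz; HFA averages 4 and 8 kHz.  A no-response
contributes 95 dB HL to either average (the clinical convention for an
unmeasurable 8 kHz threshold, extended to the other average
frequencies and always logged).  Hearing is classified abnormal when
PTA > 20 dB HL or when more than two *measured* frequencies (octaves
plus any recorded inter-octaves) exceed 20 dB HL; profound means
PTA ≥ 80 dB HL.  Counting over measured frequencies is the only
self-consistent reading when inter-octaves are tested conditionally.

### Unaided SII

The unaided Speech Intelligibility Index is computed octave-band-wise:

    SII = Σᵢ Iᵢ · clip((Lᵢ + p − Tᵢ) / d, 0, 1)

with importance weights `Iᵢ` (non-negative, Σ = 1), band speech levels
`Lᵢ` (dB HL, average vocal effort), dynamic range `d = 30` dB and peak
offset `p = 15` dB: a band is fully audible when the threshold sits
15 dB below its speech level + 15 dB of headroom, and inaudible 15 dB
above it.  Clinical devices implement proprietary variants of this
computation (transfer functions, speech spectra); the shipped constants
(`data/sii_constants.yaml`) use ANSI-style octave importance weights
and speech-banana band levels and are fully overridable, so agreement
with any specific device is a matter of configuration, not code.  A
no-response gives zero audibility in its band.  SII is reported as an
integer percent; < 75 % flags compromised speech audibility
(amplification-candidacy screen).

### Ear ranking

The worse ear has the lower SII; ties fall back to the higher HFA,
then the higher PTA; a complete metric tie deterministically designates
the left ear (any fixed rule works; this one is stable and logged).
The worse/better assignment is made once per patient — at the first
analyzed session with two clean ears — and held fixed, because
re-ranking per session would splice different physical ears into one
modelled trajectory.

**Selection caveat.** Ranking ears on the same noisy measurement that
enters the model induces regression to the mean: the ear that looks
worse at baseline is, in expectation, slightly inflated by measurement
error there, so its fitted slope is biased downward (the better ear
mirrors upward).  On synthetic cohorts at default noise the effect is
about −0.08 dB/yr on a 1.77 dB/yr worse-ear HFA slope (≈5 %).  The
recovery harness therefore supports two ranking modes: `observed`
(the analysis pipeline as run on real data) and `oracle` (ranking from
the generative truth), whose comparison isolates the selection effect
from the model machinery.  Any natural-history analysis that selects
the worse ear from baseline data shares this property.

## Cohort descriptives

Onset summaries use only diagnosed patients (mean, SD with the n−1
denominator; SD undefined at n = 1).  `Normal` (hearing confirmed
normal), `Not Diagnosed` and `No dx` all exclude a patient from onset
means; `Normal` additionally marks the confirmed-normal denominator.
Cochlear-implant users count as diagnosed with SNHL (their onsets are
known) but contribute no audiograms.  A symptom is *first* for a
patient when its onset is strictly below every other diagnosed onset;
exact ties are co-counted and flagged.  The sex-by-SNHL association
uses the Pearson chi-square without continuity correction — the
uncorrected statistic is what the field reports for 2×2 tables of this
size and is the one our packaged table reproduces.

### Exclusions

Before modelling: ears flagged conductive are dropped per ear (the
other ear's record survives), sessions with an ear judged invalid are
dropped entirely, cochlear-implant patients are dropped, and visits
beyond the fifth analyzed session are dropped (sixth-year data are too
sparse to support inference).  Every drop is logged with its reason so
each input patient is accounted for.

## Random-slope model

For outcome `y` (HFA or PTA in dB, SII in percentage points):

    y_ij = β₀ + β₁ t_ij + β₂ age0cᵢ + β₃ t_ij·age0cᵢ (+ sex terms)
           + u₀ᵢ + u₁ᵢ t_ij + e_ij

with `t` the years since the patient's first analyzed session, `age0c`
the age at that session centered at the sample mean, independent
random intercept `u₀ᵢ ~ N(0, τ²)` and slope `u₁ᵢ ~ N(0, δ²)`, and
residual `e_ij ~ N(0, ε²)`.  Because age is centered, β₁ is the average
annual change at the cohort's mean entry age — the quantity reported
as "estimated average change over 1 year" — and it is read from the
interaction model (a no-interaction variant is available by flag).
The random intercept is on by default (trajectories differ far more in
level than the residual allows); a pure random-slope covariance is
available and is the model used inside the power simulations.

### Estimation

REML, with the residual variance profiled out and the restricted
likelihood maximized over the log variance ratios log(τ²/ε²),
log(δ²/ε²) by a Nelder-Mead simplex from several starts
(`_reml.py`).  The derivative-free profiled search is deliberate:
near the boundary δ² → 0 or τ² → 0 the unprofiled problem has a
gradient that never vanishes along constrained directions and makes
gradient-based optimizers report spurious failures.  Ratios below
1e−5 are reported as exactly zero (boundary).  The fit is deterministic
(no seed involved) and is verified in the test suite against lme4's
REML on identical data (coefficients, SEs and variance components to
3+ decimals).

Fixed effects are tested by Wald F = (β̂/se)² with a residual-style
denominator df (n_obs − n_patients − rank X); a Satterthwaite or
Kenward-Roger correction would change the df by a few counts at these
sample sizes and is not implemented — exact F values are not a
deliverable of this package.  95 % CIs for β₁ use the same df.

## Power and sample size

Two-arm trial, equal allocation, visits at 0, 0.5, …, 3 years.
Subject slopes are `β_g + N(0, δ²)` with
`β_treatment = (1 − r)·β_placebo` (r = proportional slowing), equal
baseline means, residual `N(0, ε²)`.  Each simulated trial is analyzed
with the pure random-slope model `y ~ time + group + group:time`; the
trial is a success when the group-by-time effect is significant at
two-sided α.

For balanced complete data the per-subject OLS slope
`bᵢ ~ N(β_g, δ² + ε²/Sxx)` is the sufficient statistic and the REML
interaction test reduces exactly to the pooled two-sample t-test on
the `bᵢ` (df 2n−2); `analyze_trial` uses this reduction by default and
the numerical REML fit for unbalanced tables (the two agree on
balanced tables in the test suite, up to the t-vs-Wald df convention).
The closed-form normal-approximation power of the same slope test is
exposed as `analytic_slope_power` and doubles as the independent
oracle for the simulation at δ = 0.

Monte-Carlo: one master seed spawns an independent substream per
replicate (`numpy` `SeedSequence`), so results are reproducible and
independent of execution order; non-converged replicates would be
excluded from the rejection denominator and counted (with the
closed-form path this does not occur).  `sample_size_search` walks a
step-5 grid starting from the analytic approximation, with optional
step-1 refinement at the boundary, and reports the full power-vs-n
trace.

The published sample sizes for slowing WFS hearing progression
(150/100 per arm whole-group, 75/55 with known SNHL) depended on
variance components estimated from raw data that were never published;
this package reproduces the *procedure* and demonstrates it at its
own documented parameters (β = 1.77 dB/yr, δ = 1.35, ε = 3.0,
baseline 39 dB — the worse-ear HFA values implied by the synthetic
generator's defaults), for which ~45 (r = 0.6) and ~60 (r = 0.5)
patients per arm reach 80 % power.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes.
Defaults, all configurable:

* **Demographics/onsets** — enrollment age N(13.5, 5.6²) truncated to
  [5, 26]; onset distributions per symptom matching the packaged
  cohort's summary row (e.g. HL: N(8.3, 5.1²), 25 % never diagnosed →
  75 % prevalence); 45 % male.
* **Thresholds** — near-normal baselines (5–10 dB HL); at HL onset an
  immediate sensorineural shift (5–30 dB, high-frequency-dominant,
  patient-scaled, +50 dB extra for onset ≤ 3 years) followed by linear
  progression in study time at 0.4–1.97 dB/yr per frequency; the 4/8 kHz
  slopes (1.57, 1.97) make the mean affected HFA slope exactly
  1.77 dB/yr.  One standard-normal draw per patient scales the
  per-frequency slope SDs (0.3–1.5 dB/yr), so the patient's HFA slope
  SD is δ ≈ 1.35; slopes are shared between ears and ears differ by a
  stable offset (SD 6 dB), which keeps worse-ear selection from
  distorting slopes when ranking is truth-based.
* **Measurement** — residual SD 4 dB per frequency-session, 5-dB
  quantization, ceiling 100 dB HL recorded as no-response, visit
  attendance 0.85 (first visit always kept), small age jitter, 2 %
  conductive sessions, 0.5 % invalid, cochlear implantation with
  probability 0.67 for onset ≤ 3 years (implant users ship no
  audiograms).

These defaults put session-1 worse-ear descriptives in the vicinity of
a real WFS cohort (HFA ≈ 35–40 dB with SD ≈ 20–26) — a soft
calibration, not an equality the package asserts.  What the generator
does **not** emulate: bone conduction and tympanometry traces,
speech-in-noise scores, correlated onset ages across symptoms,
nonlinear (e.g. accelerating or saturating) trajectories, and
informative missingness — so passing recovery tests demonstrate the
machinery under the stated model, not robustness to those violations.

The recovery study uses 35 patients × up to 5 annual visits × 200
replicates (the smallest design that leaves Monte-Carlo error well
below the effects of interest while keeping the whole study in about a
minute); with truth-based ear ranking the full pipeline recovers the
1.77 dB/yr slope without detectable bias and with ~95 % CI coverage,
and the 5-dB quantization moves the recovered slope by far less than
one step per decade.

## Numerical conventions and degenerate inputs

* Rounding is centralized: dB to one decimal, SII to integer percent;
  JSON carries unrounded values.
* Full ties in ear ranking go to the left ear (logged).
* Variance ratios under 1e−5 report as zero; at that boundary the
  Wald CI can be slightly anti-conservative (the usual boundary
  caveat).
* A cohort with a zero margin in the sex-by-SNHL table reports the
  chi-square as undefined rather than raising.
* Fits require ≥ 2 patients with ≥ 2 time points; trial analysis
  requires ≥ 2 visits per subject; single-replicate recovery reports
  are flagged underpowered.

## Limitations

Linear-in-time trajectories only; no joint modelling of the three
outcomes; no sibship clustering in descriptives or models; the SII is
a configurable octave-band approximation rather than any specific
device's implementation; and the worse-ear selection bias described
above is a property of the analysis design itself that users should
keep in mind when interpreting worse-vs-better ear contrasts.
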