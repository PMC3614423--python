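# Methods

## Scope and model

`suitflux` analyses high-resolution respirometry (HRR) runs of tissue
homogenates subjected to a substrate–uncoupler–inhibitor titration (SUIT)
protocol, and verifies the whole analysis chain by parameter recovery on
synthetic cohorts.

The chamber O2 balance gives the volume-specific oxygen flux

    J_V(t) = −1000 · dC/dt      [pmol·s⁻¹·ml⁻¹],   C in µM (= nmol/ml),

positive for consumption.  The SUIT sequence — malate/pyruvate/glutamate →
ADP → cytochrome *c* → succinate → stepwise FCCP → rotenone → antimycin A →
TMPD/ascorbate — steps the preparation through eight respiratory states
(LEAK, CI_OXPHOS, CI_OXPHOS_CYTC, CI_CII_OXPHOS, CI_CII_ETS, CII_ETS, ROX,
CIV_MAX).  Steady-state flux is extracted per state, residual oxygen
consumption (ROX) is subtracted from every state, and CIV_MAX additionally
loses the TMPD/ascorbate autoxidation background, modelled linearly in O2:
autox(C) = a0 + a1·C (clamped at ≥ 0), with (a0, a1) fitted on a tissue-free
chemical blank.  Flux control ratios (FCR) normalise each corrected state
flux to the maximal uncoupled respiration CI_CII_ETS; the respiratory
control ratio (RCR) is CI_CII_OXPHOS / LEAK.  Group comparison uses the
D'Agostino–Pearson omnibus normality check, the pooled-variance Student
t-test (two-tailed), significance at p < 0.05 and trends at p < 0.1, with
differences reported as mean difference ± SEM of the difference.

Assumptions: the chamber is well mixed with a single response time constant;
measurement noise on C is white; the autoxidation background is linear in C
over the working range; duplicates are exchangeable technical replicates.

## Flux estimation and the noise floor

The derivative is estimated by centred local linear regression (first-order
Savitzky–Golay) with halfwidth *h* (default **40 s**).  For white O2 noise
σ_C on a uniform grid Δt, the pointwise flux noise is

    σ_J = 1000 · σ_C · sqrt(12 / (n(n²−1)Δt²)),  n = 2h/Δt + 1,

≈ 1.3 pmol·s⁻¹·ml⁻¹ at σ_C = 0.2 µM, Δt = 2 s, h = 40 s, and the standard
error of a window-mean flux over support L falls as ≈ 1000·σ_C·sqrt(24/L³).
These two numbers drive every windowing default:

* **Plateau window** — the full span from `settle_s` (default 140 s ≈ 5–7
  chamber time constants) after the state's titration to `lag_s` (5 s) plus
  one halfwidth before the next titration.  A short fixed window (e.g. the
  last 60 s) would have a ≈ 0.26 pmol·s⁻¹·ml⁻¹ standard error — larger than
  the ~0.1 pmol·s⁻¹·ml⁻¹ scale of 1% duplicate variation at LEAK-like
  fluxes — so the extractor uses all post-stabilisation data.
* **Stability flags** — a plateau is stable when |slope| ≤ 0.15
  pmol·s⁻¹·ml⁻¹/s and SD/|mean| ≤ 0.25, or when |mean| < 10 pmol·s⁻¹·ml⁻¹.
  The relative-scatter test is meaningless once the mean approaches the
  pointwise noise σ_J (ROX ≈ 4, LEAK ≈ 6–10 after correction), which is what
  the absolute floor encodes; the floor sits just above σ_J / cv_tol ≈ 5.3.
* Windows containing a chamber reoxygenation are truncated at the reset,
  keeping the longer fragment clear of the concentration jump.

An optional instrumental background subtraction J_bg = b0 + b1·C is
available but off by default: the pipeline operates on the homogenate
signal.

## Autoxidation blank

The blank regression (flux on smoothed O2 over the post-TMPD window) uses a
wide halfwidth (default 120 s) and benefits from a long blank: at the
default noise the slope precision is ≈ 2% relative for a ~2.5 h blank
spanning 190 → ~50 µM.  The prediction a0 + a1·C̄ inside the blank's O2
range is far more precise than either coefficient alone, which is what the
CIV correction actually consumes.  a1 is clamped at ≥ 0; a degenerate
(constant-O2) blank falls back to an intercept-only fit.

## Citrate synthase assay

Activity = (ΔA412/min from OLS over the early linear window, default first
1.5 min) / (ε · pathlength) · dilution · assay-to-sample volume ratio, with
ε(TNB, 412 nm) = 13.6 mM⁻¹cm⁻¹ (standard DTNB chemistry; configurable).
A negative fitted rate is clamped to zero activity with a warning.

## Statistics conventions

* Percent difference is signed, 100·(affected − control)/control, computed
  from group means; its SEM is propagated by the delta method.  Reports can
  phrase decreases as positive magnitudes alongside.
* The per-sample duplicate-variation scalar averages 100·|d1−d2|/mean over
  the seven non-reference states on ROX-corrected fluxes (the reference
  ratio is identically 1; corrected ROX contributes 0 by construction).
* Normality failures are logged but never switch the test to a
  non-parametric alternative; no multiple-testing correction is applied and
  the comparison table records the number of tests.
* Degenerate t-tests (zero pooled variance) return p = 1 for equal means
  and p = 0 otherwise, with a warning.  The omnibus normality test is
  skipped (not failed) below n = 8 or for constant samples.

## Synthetic cohort generator

The generator is phenomenological at the state-flux level; it does not model
substrate kinetics or membrane potential.  Per sample:

* absolute scale (true CI_CII_ETS flux): 80 pmol·s⁻¹·ml⁻¹ × lognormal
  (CV 25%);
* true FCR per state: baseline × (1 − effect/100 in the affected group) ×
  lognormal (CV 10.5%), applied to the seven non-reference states only.
  Putting independent noise on the reference as well would inflate the
  *measured* FCR dispersion by √2 above the 10.5% the generator is required
  to reproduce — the reference instead carries the scale noise that FCR
  normalisation must cancel.  Baselines: LEAK 0.08, CI_OXPHOS 0.55
  (declared assumptions anchoring the unchanged states), CI_CII_OXPHOS
  0.673, CII_ETS 0.350, CIV_MAX 1.342 (each the ratio of the configured
  absolute to fractional group difference).  Effects: −5.2%, −11.7%,
  −11.1% on those three states; nothing elsewhere.  The cytochrome-c state
  tracks the sample's CI_OXPHOS flux (the check probes membrane integrity,
  not an independent capacity), so the simulated cytochrome-c response is
  ~0 ± technical noise.
* ROX: 5% of the sample's ETS flux, same lognormal dispersion.
* duplicates: per-state lognormal perturbation, CV 0.9% (control) / 2.3%
  (affected); CS duplicates CV 3.6% around a per-sample activity of
  0.12 µmol/ml/min × lognormal (CV 38.5%).  All noise is multiplicative
  lognormal with mean exactly 1 — a 38.5% Gaussian CV would produce
  negative activities.
* traces: flux relaxes exponentially (τ = 20 s) to each titration's target,
  O2 is integrated at Δt = 2 s from 190 µM with white noise σ = 0.2 µM
  added to the concentration; if the noise-free O2 would fall below 20 µM a
  reoxygenation resets it to 190 µM and is recorded as an event.  The CIV
  segment's target includes the autoxidation background a0 + a1·C(t)
  (defaults a0 = 10, a1 = 0.05), resolved by fixed-point iteration; FCCP
  step multipliers (0.85, 1.0, 0.97) place the maximum at step 2 so the
  max-over-steps rule is actually exercised.
* schedule durations (LEAK 1200 s, ROX 1500 s, CI states 420 s, FCCP steps
  300 s, CII_ETS 600 s, CIV 480 s, ~103 min total) are budgeted from the
  noise floor above so that extraction noise stays below roughly half the
  control duplicate CV at every state; low-flux states get the longest
  segments.  The blank runs 2.5 h for the same reason.

Randomness: every sample draws from an independent child stream of the
cohort seed keyed by (group, sample index), so cohorts are bit-reproducible
and changing `n_per_group` never reshuffles earlier samples.

What the generator does **not** emulate: sensor drift, O2 back-diffusion,
temperature excursions, inter-state correlations beyond the shared scale,
chamber-to-chamber calibration offsets, or pathology-dependent CS activity.
Passing recovery tests therefore demonstrate that the analysis chain is
correct and calibrated under the declared noise model — not that it is
robust to instrument artefacts absent from that model.

## Problem sizes

The recovery study runs 200 cohorts of 12 samples per group (seeds
base…base+199); the headline significance summary uses the first 100; the
null-calibration suite uses 40 cohorts with all effects at zero; Monte-Carlo
calibration of the t and normality tests uses 2000 and 500 replicates.  The
full study completes in about half a minute on one core.

## Known limitations

* The extraction windows assume the titration schedule leaves several
  minutes per state; protocols with very short segments will trip the
  minimum-window logic and degrade low-flux precision.
* The autoxidation model is linear in O2; strongly curved blanks would bias
  the CIV correction.
* Percent-difference SEMs via the delta method differ slightly from
  per-sample-percentage SEMs when dispersion is large.
* QC exclusion is binary per sample; partial runs are not salvaged.
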