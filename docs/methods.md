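# Methods

## The experiment being modelled

A random-dot kinematogram fills an annulus (24 deg outer, 4.8 deg inner
diameter) with 0.12 deg dots at 7.35 dots/deg² (3192 dots).  Global motion
coherence alternates between 100% (all dots follow one flow pattern —
radial, rotational or translational, at 2, 4 or 8 deg/s) and 0% (each dot
takes a fresh uniform-random direction per update) every 417 ms, i.e. a
square-wave coherence modulation at f1 = 1.2 Hz.  Dot positions update at
f2 = 24 Hz (a 72 Hz refresh divided by 3), and the coherent direction
reverses every other cycle (0.6 Hz) to limit adaptation.  Dots are
repositioned after a maximum lifetime of 100 updates (4.17 s), and 1% of
dots per update are repositioned on a fixed schedule.  EEG is recorded from
128 channels referenced to the vertex at 432.43 Hz; each trial spans 10
coherence cycles (8.33 s).  A phase-locked (steady-state) response is
expected at harmonics of f1 — with odd harmonics indexing onset/offset
asymmetries and even harmonics any coherence change — and at the update
rate f2, which indexes local motion/luminance transients.

## Stimulus simulator

Kinematics are continuous (pixel geometry is metadata).  Coordinates are
screen-centered degrees of visual angle, x rightward, y upward, angles CCW
positive.  Every dot moves exactly `speed/f2` deg per update in both
phases, so coherent and incoherent motion energy per update is identical.
Conventions the display description leaves open, fixed here and
configurable where noted:

- **Phase order:** the coherent half leads each cycle (configurable via
  `coherent_first`).
- **Dots leaving the annulus** are repositioned uniformly at random inside
  it with age reset; uniform repositioning preserves the density invariant.
- **The fixed 1% repositioning schedule** is a deterministic round-robin
  over dot indices (cohort k = indices [k·m, (k+1)·m) mod n with
  m = floor(0.01 n)), which also guarantees no dot outlives the maximum
  lifetime by construction.
- **RNG:** one top-level seed; per-subject/per-trial streams are split off
  with `numpy.random.SeedSequence.spawn`, so any trial is independently
  reproducible and a fixed seed yields a bit-identical trajectory export.

## Forward EEG model

Each channel is a sum of sinusoids at the analysis harmonics
({1.2, 2.4, 3.6, 24} Hz) whose complex coefficients are the condition means
plus a per-subject complex intercept, plus stationary noise.  This is
deliberately the simplest model consistent with steady-state phase-locked
analysis: no onset transients, no trial-to-trial amplitude drift, no
inter-channel noise correlation, no volume conduction.  Passing tests on
this generator therefore demonstrate correctness of the analysis under its
own assumptions, not robustness to every property of real EEG (non-
stationarity, correlated noise across channels, non-sinusoidal responses).

Defaults (changeable on `ResponseTopography`):

| parameter | default | rationale |
| --- | --- | --- |
| subject_intercept_sd | 0.25 uV/component | isotropic complex Gaussian; circular symmetry matches the T2Circ null |
| pink exponent / sd | 1.0 / 6 uV | generic 1/f EEG background; the source study does not characterize its noise spectrum, so this is a modelling choice |
| white sd | 3 uV | sensor noise floor |
| artifact rate / amplitude | 0.05 per cycle / 120 uV | square ~50 ms transient on one channel; 2x the rejection threshold so the flagging rule must fire |

Study-design defaults are the study conditions: 29 subjects, 3 patterns x
3 speeds (2/4/8 deg/s), 5 trials per condition (the protocol collected 4-10
contingent on compliance; 5 is a realistic mid-range value fixed once),
128 channels at 432.43 Hz.

The demo effect preset plants a pattern-selective response at 1F1 in a
right-lateral channel group, a speed-selective response (larger for faster
speeds) at 3F1 and 1F2 in a posterior-midline group, and an unselective
broad posterior response at 2F1 — the qualitative topology reported for
this paradigm.  Effect amplitudes (~0.5-1 uV differences against 0.35 uV
subject-level component scatter) were chosen a priori so that the
noncentrality of the planted effects at n = 29 puts per-channel power well
above 0.9 at α = .0005.

`simulate_subject_components` draws subject-level coefficients directly
(mean + intercept + isotropic complex noise, default component sd 0.35 uV —
the residual scatter left after cycle- and trial-averaging).  Statistics
calibration and power studies run at this stage because that is the input
stratum of the statistics; the time-domain path is exercised separately by
the round-trip and end-to-end checks.

## Preprocessing

- **Low-pass:** 145-tap Kaiser(β=8) FIR at 50 Hz, applied forward-backward
  (zero phase).  Passband gain at the analysis harmonics deviates from
  unity by <0.01%; stopband attenuation exceeds 80 dB by 60 Hz.  The design
  is recorded in the output metadata.
- **Cycle segmentation** is by continuous time (sample n belongs to the
  cycle containing n/fs), since 432.43/1.2 ≈ 360.36 samples per cycle is
  not an integer; cycle sample counts are 360 or 361 and the slices tile
  the trial exactly.
- **Artifact rule:** "amplitude modulations exceeding 60 uV" is read as: a
  cycle is flagged when any channel's within-cycle peak-to-peak range
  exceeds 120 uV (±60 uV about the cycle mean) — robust to DC offsets.  An
  absolute-deviation variant (any |sample − cycle mean| > 60 uV) is
  available via `rule="abs_deviation"`.  Comparisons are strict.  The rule
  is applied per channel on filtered data (the original study does not say
  whether its criterion was per channel or applied to raw data).
- **Exclusions:** a trial is excluded when ≥15% of its cycles are flagged
  (2 of 10); a subject is excluded when any condition retains fewer than 3
  trials.  Flagged cycles inside retained trials are dropped from the
  coherent average.  The decision is a pure function of the counts.
- No re-referencing (synthetic data are generated vertex-referenced), no
  bad-channel interpolation, no ICA — none appear in the modelled pipeline.

## Harmonic extraction

Coefficients are least-squares projections onto cos/sin regressors at the
exact harmonic frequencies, with an intercept, evaluated at absolute sample
times so all cycles share the trial-onset phase reference.  Two entry
points exist on purpose:

- `fourier_coefficient` fits one frequency.  Its amplitude recovery for a
  pure sinusoid is exact, but with a non-integer number of samples per
  period the discrete cos/sin bases of *different* harmonics are not
  exactly orthogonal, leaving O(1/N) ≈ 3·10⁻⁴ cross-talk between
  harmonics.
- `fit_harmonics` fits all analysis harmonics jointly and is what the
  pipeline uses: any signal in the span of the basis is recovered to
  machine precision, which is why the noiseless round trip meets a 1e−9
  tolerance and why a pure 2F1 sinusoid contributes exactly zero at 1F1.

Averaging is the arithmetic mean of (re, im) — coherent averaging — in the
fixed hierarchy cycle → trial → subject (the stage at which the original
software averaged is unstated; this convention is fixed and documented).
RMS amplitude is √((re²+im²)/2); the vector magnitude √(re²+im²) is a
separate named quantity to avoid conflation.

## Statistics

- **T2Circ** = n(n−1)|z̄|²/SS referenced to F(2, 2n−2), implemented from
  first principles (the frequency-domain adaptation of Hotelling's T² for
  a zero-mean test under circular noise).  Degenerate inputs: SS = 0 with
  z̄ = 0 reports p = 1; SS = 0 with z̄ ≠ 0 reports p = 0 with a warning.
  The statistic is invariant to global phase rotation and scaling.
- **Channel-wise MANOVA:** subject is a categorical blocking factor, which
  for a balanced within-subject design is numerically equivalent to a
  random intercept; a true random-effects fit is out of scope.  Effects are
  computed from sequential cross-products of a QR-decomposed sum-coded
  design; with balanced data the effect subspaces are orthogonal, so
  sequential and Type III sums coincide (verified against an independent
  paired-Hotelling oracle to 1e−10).  The Pillai F approximation uses
  m = (|p−q|−1)/2, n′ = (df_e−p−1)/2, df1 = s(2m+s+1), df2 = s(2n′+s+1),
  F = (df2/df1)·V/(s−V).  Unbalanced data are handled by listwise deletion
  at the subject level per channel, with counts reported; channels left
  with <3 complete subjects are reported as NA, never dropped.
- **Mass univariate:** no multiplicity correction beyond the fixed
  conservative α = .0005 (equivalent to Bonferroni .05/100), thresholds
  applied with strict '<'; significant sets nest monotonically across the
  default threshold ladder {.05, .01, .005, .001, .0005}.
- **Omnibus model:** a single pooled observation-level model over channels
  with age (centered, in weeks), channel, pattern, speed and the
  channel×pattern / channel×speed interactions, tested against the pooled
  residual.  Its df bookkeeping is this model's own convention.  Known
  limitation: with nonzero subject intercepts the pooled residual
  understates the between-subject error stratum, making the age term
  anti-conservative; the calibration test therefore runs with intercepts
  disabled, and the age term should be read as descriptive.  Degenerate
  inputs (constant age, single channel) drop the affected terms with a
  warning.

## Problem sizes

Calibration suites use 10⁴ null replicates for T2Circ at n = 29, 200 null
replicates and 100 planted replicates of the full 128-channel
mass-univariate study at the component stage, 100 random datasets for the
Hotelling-equivalence check, and a 6-subject, 5-trial time-domain study
for the end-to-end run — sizes chosen so the whole acceptance pass
completes in minutes on one CPU while keeping Monte-Carlo error well below
the decision margins.

## Known limitations

- The generator's stationary additive model omits onset dynamics, alpha
  rhythms, eye/EMG artifact morphology (a square transient suffices to
  exercise the threshold rule) and inter-channel noise correlation.
- The channel layout is a schematic approximation of a 128-channel geodesic
  net for plotting and group definitions, not a scalp-accurate
  digitization.
- The omnibus model's pooled error stratum (above).
- Rendering of stimuli to video, luminance/gamma modelling, eye-movement
  simulation and source localization are out of scope.
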