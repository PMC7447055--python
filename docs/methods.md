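# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Design and data model

The emulated experiment is fully within-subject: every participant hears
every excerpt twice, once under each task (assessing the expressed emotion vs
rating the intensity of the induced feeling, 1–5). Trials of ~30 s are
grouped in four blocks, each opening with a 30 s rest; a 4 s task prompt
precedes each excerpt and a rating screen follows it. Five channels are
recorded at 500 Hz: zygomaticus EMG, corrugator EMG, blood-volume pulse,
respiration belt and skin conductance. The unit of statistical analysis is
one (participant, stimulus, task, interval, measure) cell, where *interval*
is the first or second half of the trial — 25,600 rows per measure-set at the
full design (40 × 32 × 2 × 2 × 5).

Stimulus ratings (valence, energy, tension on 1–9, collected in an external
rating study) are fixed covariates. For modelling they are collapsed to three
levels. The printed rule is stated on integers (1–3, 4–6, 7–9); ratings are
continuous means, so the package bins by nearest integer: below 3.5 →
low/negative, [3.5, 6.5) → medium/neutral, at or above 6.5 → high/positive.
This reproduces the rule exactly on integers and is symmetric; the edges are
configurable. Grouping labels (e.g. `ENERGY POS MOD`) are read from the
table, never re-derived from the ratings, because the original selection
involved representativeness judgments that are not reconstructible.

## Signal processing

**Facial EMG.** Band-pass 20–249 Hz (4th-order Butterworth magnitude,
zero-phase), magnitude of the analytic signal (Hilbert transform), then a
centered moving average. The smoothing kernel is unspecified in the source
procedure; a 100 ms moving average is used because it preserves the mean
level that downstream interval averaging consumes. For a pure in-band tone
the envelope equals the amplitude to well under 2% away from edges.

**Cardiac and respiratory rate.** BVP and respiration are conditioned
zero-phase with a 0.05 Hz high-pass (drift, slow movement) and a 40 Hz
low-pass (noise); zero-phase filtering is essential because peak *timing* is
the measurement. The high-pass settles over ~1/0.05 Hz = 20 s, so the filter
is applied with padding of that order. Peaks are local maxima under a
refractory interval (0.33 s for BVP ⇒ ≤ 180 beats/min; 2 s for respiration ⇒
≤ 30 breaths/min) and a prominence floor of 0.5 signal SD — an automated
stand-in for the manual inspection used on the original recordings, encoding
the same physiological bounds. Rates are reciprocal inter-peak intervals
placed at interval midpoints (symmetric, standard for tachogram resampling)
and linearly interpolated onto a 10 Hz grid with edge-hold extrapolation.

**Skin conductance.** The trace is decimated to 10 Hz (anti-aliased), a
tonic baseline is estimated as a sliding 10 s / 10th-percentile curve
(smoothed by a same-width moving average), and the remainder is deconvolved
against the Bateman kernel `exp(−t/τ₁) − exp(−t/τ₂)` by non-negative least
squares with a small ridge penalty (10⁻³), which selects the smallest-norm
admissible driver. Phasic activity is the driver reconvolved with the
kernel; the residual is whatever the tonic + phasic split cannot explain, so
`tonic + phasic + residual` reconstructs the decimated input exactly.
Defaults τ₁ = 2 s, τ₂ = 0.75 s are within the range conventional in
electrodermal deconvolution; both are configurable. The per-trial feature is
the time-averaged phasic series over the trial window — deliberately with no
amplitude threshold, so small responses contribute. On synthetic
single-response inputs the driver mass is recovered within a few percent and
two responses 2 s apart are resolved as separate driver modes.

**Feature assembly.** Each measure's continuous feature is standardized to
mean 0 / SD 1 within participant × measure, pooling samples across all trials
of both tasks (the sentence order of the source procedure puts normalization
before interval averaging; whether the original pooled samples or trial means
is not stated — pooling samples is the literal reading and is what the
package does). Then the first- and second-half means are taken; for
odd-length windows the middle sample joins the first half (deterministic, and
at ~15,000 samples per window the effect is negligible). Looped excerpts are
treated like any other trial: halves of the realized duration.

## Statistical layer

Per measure, a linear mixed model with one affective dimension
(treatment-coded, references: valence *neutral*, energy/tension *high*) plus
Task (reference *felt*) as fixed effects and crossed random intercepts of
item (excerpt) and interval (first/second half). The three dimensions are
fitted separately because their ratings correlate. No participant random
intercept is included: the within-participant normalization removes the
participant mean by construction, and ratings are external, so there is no
participant-level variance for the fixed effects to absorb.

Fitting is REML via statsmodels `MixedLM`, with the two crossed intercepts
expressed as variance components over a single trivial group. Boundary fits
(a variance component at zero) are reported with a warning, not an error; if
the default optimizer fails, a ladder of optimizers is tried and the
best-likelihood converged fit is kept.

**F-tests.** Wald tests of each factor's coefficients, converted to F with
containment (between-within) denominator degrees of freedom: the dimension
factor is constant within item and is tested against the item stratum
(`n_items − 3`, i.e. 29 at the full design); Task varies within item and is
tested against the observation stratum (`N − n_items − n_intervals`, i.e.
5086 at the full design). This choice reproduces the df pattern of the
original analyses exactly and costs nothing; Satterthwaite approximations
were considered and rejected because no installed solver provides them for
this model class and the containment df are exact for this balanced design.
With crossed random intercepts and a large observation stratum the Task
F-test is calibrated: its empirical type-I error over 200 null cohorts sits
inside [2%, 8%] at nominal 5% (the acceptance script recomputes this).

**Confidence intervals** are Wald (normal) intervals on the fixed effects.
Profile-likelihood intervals are not available for this model class in the
installed stack; at the design sizes used (≥ 640 observations) the two
coincide to well within reporting precision.

**R² for mixed models.** `var_fixed` is the variance of the fixed-effects
linear predictor over the data; marginal R² = var_fixed / (var_fixed +
Σ variance components + residual variance) and conditional R² adds the
variance components to the numerator. Scale-invariance and the worked
example (1, 1, 2) → (0.25, 0.50) are tested.

**Felt-intensity analyses.** Ratings are z-scored within participant across
felt trials. Per-stimulus means are correlated (Pearson, two-sided p at n−2
df) with each dimension rating; and per measure, a mixed model with the same
random structure regresses the felt-task observations on the z-scored rating,
reporting the slope with a t-test at the observation-stratum df.

No multiple-testing correction is applied anywhere, matching the
hypothesis-driven reporting of the source analyses.

## Synthetic-data generator

The generator's task is to emulate the *design* and the *assumed effect
structure*, not the biophysics of any participant. Per-trial latent means are
additive on a dimensionless scale:

```
z = Σ level_effects(dimension level of the stimulus)
  + task_effect · 1[task = perceived]
  + item offset + interval offset + participant offset + residual
```

with defaults `sd_item = 0.07`, `sd_interval = 0.1`, `sd_participant = 0.15`,
`sd_residual = 0.8`, `task_effect = +0.2` (perceived above felt) and level
effects whose signs and magnitudes are anchored to the effect sizes reported
for this design (e.g. zygomaticus up for positive valence, corrugator up for
low energy, arousal measures up with energy). The residual dominates by
design: the real effects are small against trial-to-trial variability, and
the conditional R² of fitted models stays in the few-percent range, as
observed. Felt-intensity ratings are generated as a linear function of the
stimulus energy rating plus item-, participant- and trial-level noise, mapped
to the 1–5 scale; the noise SDs are set so that the per-stimulus intensity /
energy correlation lands in the moderate range reported for this paradigm
(r ≈ 0.4) rather than saturating once ratings are averaged over 40
participants.

Latents are rendered into channels by per-measure affine maps (heart rate
70 + 3·z beats/min; respiration 14 + 1.5·z breaths/min; EMG envelope
amplitude 20·(1 + 0.3·z) µV-scale units; SC event-amplitude scale
0.4 + 0.12·z µS), piecewise constant over the two trial halves, baseline
between trials. Channel nuisances exist so each conditioning stage has
something nontrivial to remove: EMG is band-limited Gaussian noise modulated
by the envelope (the extracted envelope reads √(π/2) times the amplitude —
the Rayleigh mean of a unit-RMS analytic magnitude); BVP is a train of
smooth unimodal pulses with fractional inter-beat jitter, sub-0.05 Hz drift
and white noise; respiration is a frequency-modulated sinusoid with drift and
noise; SC is a sparse Poisson driver (8 events/min) with Gamma-distributed
amplitudes convolved with the Bateman kernel on a drifting tonic level.

Because the latent scale is constructed to be the standardized scale, the
observation-level simulator (`simulate_observations`) only centers values
within participant; injected effects keep their configured magnitude exactly,
which is what the parameter-recovery and type-I suites need. The rendered
path (`simulate_cohort(render=True)`) goes through the genuine
standardization, whose realized scale deflates coefficients by the inverse of
each participant's latent SD — the end-to-end test computes that effective
truth from the stored ground truth.

**What the generator does not emulate:** realistic pulse/ECG morphology,
motion and electrode artifacts, non-stationary baselines within trials,
inter-measure coupling beyond the shared latent, and any nonlinearity in how
attention modulates physiology. Passing tests therefore demonstrate that the
pipeline recovers the effects *its own assumptions* encode — calibration and
correctness of the machinery — not that the machinery would extract identical
numbers from the human recordings.

## Problem sizes used in tests and the acceptance script

Simulation suites run at reduced size chosen so the whole suite runs on one
CPU in minutes: type-I error uses 200 null cohorts of 10 participants × 16
stimuli at the observation level; CI coverage uses 20 such cohorts with a
+0.3 task shift on heart rate; the rendered end-to-end check uses 6
participants × 8 stimuli at the full 500 Hz / 30 s trial resolution. The
full 40 × 32 design is used where rendering is not needed (the intensity
correlation). All randomness derives from explicit seeds; identical
(config, seed) reproduces identical output bytes.

## Known limitations

* The SC deconvolution solves a dense NNLS per trial window at 10 Hz; very
  long windows (many minutes) would need a sparse or windowed solver.
* The interval random intercept has only two levels; its variance component
  is weakly identified and often sits at the boundary (reported as a
  singular-fit warning, as intended).
* Containment df are exact for the balanced design the package targets;
  under heavy missingness a Satterthwaite/Kenward–Roger approximation would
  be preferable.
* Automated peak detection may diverge from manually curated peaks on real
  recordings with artifacts; the prominence floor and refractory intervals
  are the knobs to adjust.
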