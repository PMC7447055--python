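# musicphys

**Psychophysiological responses to perceived vs felt musical emotion:
a raw-signal-to-statistics analysis pipeline with a synthetic-cohort
generator.**

When people listen to music they can either judge the emotion the music
*expresses* (external locus, "perceived") or introspect on the emotion the
music *induces* in them (internal locus, "felt"). The two listening modes
leave different traces in the autonomic and facial-muscle signals. This
package implements the complete analysis chain for a within-subject design
that contrasts the two tasks: 40 participants × 32 movie-soundtrack excerpts
× 2 tasks, with facial EMG (zygomaticus major `EMGZ`, corrugator supercilii
`EMGC`), blood-volume pulse (→ heart rate `HR`), a respiration belt
(→ respiration rate `RR`) and skin conductance (`SC`), all sampled at 500 Hz.

Because the laboratory recordings themselves cannot be shipped, the package
includes a first-class synthetic-data generator that emulates the design and
the additive effect structure with known ground truth, so every stage —
and the statistical calibration of the whole chain — is testable end to end.

## What it computes

1. **Stimuli** (`musicphys.stimuli`) — the packaged table of 32 excerpts with
   1–9 ratings on three affective dimensions (valence, energy, tension) and
   emotion-grouping labels; three-level categorization of the ratings
   (1–3 = low/negative, 4–6 = medium/neutral, 7–9 = high/positive, continuous
   ratings binned at 3.5/6.5).
2. **Signal conditioning** (`musicphys.sigproc`) —
   * EMG: 20–249 Hz band-pass → |Hilbert analytic signal| → moving-average
     smoothing (100 ms) ⇒ amplitude envelope;
   * BVP/respiration: zero-phase 0.05–40 Hz conditioning, local-maximum peak
     detection with physiological refractory intervals, rate
     `r_k = 1/(t_{k+1} − t_k)` at interval midpoints, linear resampling to a
     10 Hz grid;
   * SC: tonic baseline (sliding 10th percentile) + non-negative ridge
     deconvolution of the remainder against a Bateman kernel
     `e^{−t/τ₁} − e^{−t/τ₂}` (τ₁ = 2 s, τ₂ = 0.75 s) ⇒ driver and phasic
     component; the per-trial feature is the time-averaged phasic activity,
     with no amplitude threshold.
3. **Features** (`musicphys.features`) — per-trial windows (music onset to
   offset), within-participant normalization of each measure (pooled over all
   trials of both tasks), and first/second-half (15 s) interval means ⇒ a long
   observation table keyed on (participant, stimulus, task, interval, measure).
4. **Statistics** (`musicphys.stats`) — per measure, REML linear mixed models

   `value ~ Dimension + Task + (1 | item) + (1 | interval)`

   with treatment coding (references: valence *neutral*, energy/tension
   *high*, task *felt*), one affective dimension per model (their ratings
   correlate, so the three dimensions are fitted separately). Reported per
   model: fixed effects with SE and Wald 95% CIs, variance components, Wald
   F-tests with containment denominator df, and marginal/conditional
   R²: `R²_m = σ²_f / (σ²_f + Σσ²_r + σ²_ε)`,
   `R²_c = (σ²_f + Σσ²_r) / (σ²_f + Σσ²_r + σ²_ε)`.
   Felt-intensity analyses: Pearson correlation of per-stimulus mean
   intensity with the dimension ratings, and mixed models with the z-scored
   intensity rating as a continuous fixed effect. No multiple-comparison
   correction is applied.
5. **Pipeline & CLI** (`musicphys.pipeline`, `musicphys` command) — YAML
   config, HDF5/TSV/JSON containers with provenance (config hash + seed),
   structured validation, and the four-stage chain
   `simulate → preprocess → features → fit`.

## Worked example

```bash
musicphys reproduce-demo --seed 7 --out demo_run
```

simulates a reduced cohort (4 participants × 8 stimuli, full 30 s trials at
500 Hz), extracts features and fits all 15 dimension models plus the 5
intensity models. It prints one line per model, e.g.

```
20 model reports in demo_run
EMGZ ~ Valence + Task: Task(perceived) b=0.149 [-0.165, 0.462]
EMGC ~ Valence + Task: Task(perceived) b=0.412 [0.116, 0.708]
HR   ~ Energy + Task:  Task(perceived) b=0.194 [-0.101, 0.488]
...
```

`b` is the shift (in within-participant standardized units) of the perceived
task relative to the felt task, with its Wald 95% CI; the generator injected
a +0.2 shift on every measure, and at this small demo size the CIs are wide
enough that some models cover zero. `demo_run/model_reports.json` carries the
full per-model detail, e.g. for `HR ~ Energy + Task`:

```json
{"term": "Task (perceived)", "b": 0.194, "se": 0.150,
 "ci_low": -0.101, "ci_high": 0.488}
"f_tests": {"Energy": {"F": 1.32, "df_num": 2, "df_den": 5, "p": 0.347},
            "Task":   {"F": 1.66, "df_num": 1, "df_den": 118, "p": 0.200}}
"r2_marginal": 0.033, "r2_conditional": 0.033
```

The same stages are scriptable individually (`musicphys simulate / preprocess
/ features / fit / validate`) and available as plain functions:

```python
from musicphys import (GeneratorConfig, simulate_cohort,
                       cohort_observation_table, fit_measure_model, ModelSpec)

cohort = simulate_cohort(GeneratorConfig(n_participants=6, n_stimuli=8, seed=1))
obs = cohort_observation_table(cohort)
fit = fit_measure_model(obs, ModelSpec("HR", "energy"))
print(fit.f_tests["Task"], fit.r2_marginal, fit.r2_conditional)
```

## Layout

```
src/musicphys/
  stimuli.py    stimulus table, rating categorization, grouping counts
  synth.py      synthetic cohort generator (channels, schedule, ground truth)
  sigproc.py    EMG envelope, rate estimation, SC decomposition
  features.py   segmentation, normalization, interval means, observation table
  stats.py      mixed models, F-tests, R2, intensity analyses, reports
  pipeline.py   config, containers, validation, end-to-end runner
  cli.py        command-line interface
docs/methods.md   modelling assumptions, parameter choices, limitations
```
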