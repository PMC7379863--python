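# effortframe

Simulation and analysis toolkit for cognitive-effort experiments under
gain/loss framing. It covers the full analysis chain of a three-part
study design — adaptive staircase titration of effort-indifference
points, effort-discounting model fitting and BIC comparison, AUC
summaries, motivated-vigilance and N-Back performance scoring, and
pupillometry preprocessing — with a synthetic-agent generator standing
in for human data, so every stage is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `effortframe.synthetic_data` | softmax discounting agents; vigilance RT sessions (blocked / intermixed cues, max 3-in-a-row constraint); pupil traces with blinks; N-Back runs with exactly 16/64 targets |
| `effortframe.staircase` | midpoint-bisection titration (5 trials/run, 2 runs, averaged), loss-pegging so net outcomes match across frames, interleaved scheduling, replay of recorded choice sequences |
| `effortframe.discounting` | five subjective-value families (hyperbolic, exponential, linear, quadratic, sigmoid), softmax choice likelihoods, multi-start MLE, BIC model comparison, normalized AUC, paired gain/loss contrasts (with the √k transform) |
| `effortframe.performance` | response speed (1/RT), baseline-median RT criterion, % faster than criterion, time-on-task OLS slopes, signal detection (d′, β with 1/(2N) correction), 2¢/6¢ payoff bookkeeping |
| `effortframe.pupillometry` | blink padding + short-gap interpolation (idempotent), 1-s pre-stimulus tonic means, ≥50% validity and ≥23-trials/condition gates, tonic time-on-task slopes |
| `effortframe.pipeline` | experiment orchestration (`exp1`, `exp2`, `exp3a`, `exp3b`), one-way repeated-measures ANOVA, 2×2 mixed Incentive × Order interaction, versioned JSON reports with CSV intermediates |
| `effortframe.benchmarks` | seeded recovery/calibration studies against independent oracles (used by the acceptance suite and report) |

## CLI

```bash
effortframe simulate --what nback --seed 1 --out out/
effortframe score --what nback --input out/nback_trials.csv --out out/
effortframe simulate --what choices --config agents.yaml --seed 0 --out out/
effortframe auc --indifference out/indifference.csv --out out/
effortframe fit --choices out/choices.csv --out out/
effortframe pupil --trace trace.csv --events events.csv --out out/
effortframe run --config experiment.yaml --seed 7 --out out/
```

`run` consumes a YAML file mirroring `effortframe.pipeline.ExperimentConfig`
(experiment id, population parameters, task sim configs) and writes
per-stage CSVs plus `report.json`; re-running with the same seed
reproduces every file byte-identically. Exit codes distinguish config
(2), data (3) and numerical (4) failures.

CSV schemas are fixed: vigilance `subject, trial, onset_s, condition,
rt_ms, valid`; N-Back `subject, load, frame, trial, letter, is_target,
response, correct`; pupil `time_s, diameter_mm, valid`; choices
`subject, frame, effort_low, effort_high, amount_low, amount_high,
choice`; indifference `subject, frame, effort_level, indifference`.

## Statistical conventions

All p values are two-sided; no multiple-testing correction is applied;
repeated-measures ANOVAs report uncorrected degrees of freedom (no
sphericity adjustment) — with the balanced designs generated here Type
II and Type III sums of squares coincide. BIC uses per subject × frame
trial counts. Subjective values are clipped at zero; staircase ties at
infinite choice precision resolve to the low-effort option; responses
exactly at the RT criterion count as not-faster.
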