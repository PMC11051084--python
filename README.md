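# lapsepipe

Interruption detection for online-learning interaction logs.

Given an event log with one row per timed learner–item interaction (question
attempts and feedback reviews), `lapsepipe` classifies interactions as
interrupted or normal with three detectors of increasing robustness,
reconstructs digital sessions from inactivity gaps, and compares interruption
rates across calendar periods:

- **`io_eventlog`** — CSV event-log data model, validation with an explicit
  rejects channel, derivation of the four interaction strata
  (initial/subsequent × attempt/feedback) from encounter order, and grouping
  into per-learner module attempts.
- **`synthetic_cohort`** — a seeded generator producing logs with right-skewed
  log-normal durations, multiplicative learner speed heterogeneity, injected
  interruption pauses and long between-session breaks, with ground-truth
  labels for every record and true session counts per module attempt.
- **`stat_threshold`** — per (item, stratum) mean + k·SD thresholds (k = 2 by
  default), interruption rates and interrupted-time shares.
- **`speed_factor`** — per-learner, per-stratum relative speed factors
  (learner total duration ÷ cohort-mean total duration over the same
  interactions) and speed-adjusted threshold classification; cohort
  restriction for sensitivity analyses.
- **`robust_outlier`** — modified Z-scores (0.6745·(x − median)/MAD, cutoff
  3.5, high tail only) of natural-log, speed-adjusted durations.
- **`session_reconstruct`** — session partitioning at ≥ 30 min inactivity
  gaps; a module completed in *s* sessions had *s − 1* long interruptions.
- **`period_inference`** — monthly and per-period rates (pre-COVID /
  peak-COVID / post-peak windows with March 2020 excluded, plus seasonal
  windows), Pearson test of equal proportions, pairwise Cohen's h with
  SESOI verdicts, and combination of within-session and long-interruption
  rates.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked-example
fidelity, reproduction of the reference chi-square / Cohen's h / rate values
from the per-period count tables, rate additivity, brute-force oracle
equivalence for all classifiers, injection-rate recovery on synthetic logs,
and invariance/degenerate-input suites.

## CLI

```sh
lapsepipe simulate --seed 1 --out sim/                 # synthetic labeled log
lapsepipe study1 --log sim/log.csv --k 2 --out s1/     # mean + 2 SD
lapsepipe study2 --log sim/log.csv --out s2/           # speed-adjusted
lapsepipe study4 --log sim/log.csv --cutoff 3.5 --out s4/   # modified Z
lapsepipe study5 --log sim/log.csv --timeout-min 30 \
    --window 2019-10:2022-12 --out s5.json             # long interruptions
lapsepipe compare --flags s1/flags.csv --out report.json    # period inference
```

Event logs are UTF-8 CSV with header columns
`learner_id,item_id,module_id,kind,start_time,duration_s` (optional
`encounter_index`, `completed`); timestamps are ISO-8601 and interpreted as
UTC. Invalid rows are reported with reasons, never silently dropped.

## Library example

```python
import lapsepipe as lp

log = lp.generate(lp.GeneratorConfig(n_learners=100, interruption_prob=0.05, seed=1))
stats = lp.compute_stats(log.records)
thresholds = lp.make_thresholds(stats, k=2)
factors, _ = lp.compute_speed_factors(log.records, stats)
cls = lp.classify_adjusted(log.records, thresholds, factors)
report = lp.period_report(cls.flags, log.records)
print(cls.rate, report.period_table)
```
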