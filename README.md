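# sleepfrag

Multi-resolution sleep-fragmentation analysis for hypnogram cohorts.

Nocturnal sleep in narcolepsy type 1 (NT1) is fragmented by brief stage
shifts that conventional 30-s epoch scoring can conceal. `sleepfrag`
quantifies that fragmentation from scored sleep-stage sequences
("hypnograms") at both 30-s epoch and 5-s mini-epoch resolution, and
compares groups (e.g. patients vs. their non-narcoleptic siblings) with
mixed-effects models that respect family clustering and repeated measures.
It is aimed at sleep researchers who already have staged polysomnography
and want reproducible fragmentation analytics, and it ships a synthetic
cohort generator so the entire pipeline is testable without patient data.

## What it computes

For each night, restricted to the lights-off → lights-on window over the
five stages (WAKE, N1, N2, N3, REM):

* **Transition indices** — stage-change counts per hour of total sleep
  time (TST), overall and by category:
  all-stages, NREM↔REM, sleep↔wake, within-NREM; the three categories
  partition every stage change.
* **Markov transition matrices** — the per-subject discrete-time
  5×5 matrix `P[i,j] = n(i→j) / n(i→·)`, row-normalized by the number of
  transitions originating in each stage (diagonals = stage stability;
  e.g. an N2 row with 390 self-transitions out of 432 originating steps
  gives P(N2→N2) = 0.90).
* **Wake-period taxonomy** (5-s sequences) — maximal wake runs between
  sleep onset and the last sleep unit, classified short (1 mini-epoch,
  ≤5 s), intermediate (2–3), long (≥4, >15 s), counted per hour of TST.
* **Sleep architecture** — TIB, TST, sleep efficiency, stage percentages,
  sleep/REM latencies and early-appearing REM (a REM unit starting
  strictly <15 min after sleep onset), identically at both resolutions.
* **Split-night stratification** — the total sleep period halved at
  `floor(n/2)`; every fragmentation metric recomputed per half for
  repeated-measures modelling.
* **Cohort statistics** — linear mixed-effects models (family-ID random
  intercept for group contrasts, participant-ID for night-half models),
  β with 95 % CI, Cohen's *d* = β / residual SD, automatic log-transform
  of skewed outcomes, and Benjamini–Hochberg FDR correction across the
  50-model transition-probability grid (25 cells × 2 resolutions).

## Worked example

Simulate the default NT1-like vs sibling-like cohort and analyze it:

```bash
sleepfrag simulate --out data --n-patients 60 --n-siblings 60 \
    --night-length 2880 --seed 2
sleepfrag analyze --hypnograms data/hypnograms --cohort data/cohort.csv \
    --out results_run --seed 2
sleepfrag report --run-dir results_run
```

Or in Python:

```python
from sleepfrag import GeneratorConfig, generate_cohort, transition_indices

cohort = generate_cohort(GeneratorConfig(
    n_patients=100, n_siblings=100, night_length_miniepochs=2880, seed=2))
groups = dict(zip(cohort.cohort_table.subject_id, cohort.cohort_table.group))
for h in cohort.hypnograms_5s[:1]:
    print(transition_indices(h).indices_per_hour)
```

On this cohort (seed 2) the mini-epoch sleep–wake transition indices come
out as patient mean 45.5 ± 15.0 /h versus sibling 16.2 ± 7.3 /h — the
patients' elevated wake-entry dynamics, injected on the transition-matrix
scale, emerge in the index exactly as the analysis is meant to detect.
`report` prints each fitted contrast (β, p, Cohen's *d*) plus how many of
the 50 grid models survive BH correction.

## Layout

* `sleepfrag.hypnogram`, `sleepfrag.io` — stage vocabulary, the
  `Hypnogram` container, canonical CSV dialect, validation, lights-window
  cropping, majority-vote downsampling.
* `sleepfrag.architecture`, `sleepfrag.fragmentation`, `sleepfrag.markov`,
  `sleepfrag.splitnight` — the per-night metrics.
* `sleepfrag.stats` — mixed models, Cohen's *d*, transforms, BH, the
  transition-probability grid and split-night contrasts.
* `sleepfrag.simulate` — the synthetic cohort generator with ground truth.
* `sleepfrag.pipeline`, `sleepfrag.cli` — end-to-end orchestration
  (`simulate`, `analyze`, `split`, `compare`, `report`).

See `docs/methods.md` for the model assumptions, generator design and
known limitations.
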