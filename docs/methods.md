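# Methods

## Scope and data model

The unit of analysis is the hypnogram: an ordered sequence of sleep-stage
labels (WAKE, N1, N2, N3, REM, plus an UNSCORED artifact sentinel), one
per scoring unit of fixed duration — 30-s epochs for conventional human
scoring, 5-s mini-epochs for high-resolution automatic scoring. Indices
are 0-based and the lights window is half-open, `[lights_off, lights_on)`;
every metric is computed inside that window. UNSCORED units are retained
in the sequence but never enter a metric: adjacency-based counts skip any
pair containing UNSCORED, and occupancy denominators exclude it. This
skip rule is a declared convention — scoring artifacts are rare enough in
practice that any reasonable handling changes results negligibly, and
skipping is the conservative, testable choice.

## Fragmentation metrics

A transition is an ordered adjacent pair `(s_t, s_{t+1})` with
`s_t ≠ s_{t+1}`, both scored. Three categories partition all changes
among the five stages: sleep↔wake (WAKE against any sleep stage),
NREM↔REM, and within-NREM; their sum is the all-stages count. Indices
divide each count by TST and are expressed per hour of TST — the hour
scale is the field's convention for stage-transition indices.

The discrete-time Markov model assumes the next stage depends only on the
current one. The 5×5 count matrix accumulates every ordered adjacent pair
(self-pairs included); probabilities are row-normalized by the number of
transitions originating in each stage. The final unit of a window
originates no transition, so origin totals exclude it; consequently
normalizing by originating transitions and normalizing by time-in-stage
agree to within 1/origin-total, and both interpretations are covered by a
test. Rows whose stage never originates a transition are explicitly
undefined (NaN, flagged) and propagate as per-cell exclusions in the
statistics layer, never as silent zeros.

Wake-periods are maximal runs of consecutive WAKE mini-epochs classified
by run length: short (exactly 1; ≤5 s), intermediate (2–3), long (≥4;
>15 s). The nominal "5–15 s" label sometimes attached to the middle bin
is treated as labelling looseness; classification is by run length, which
is the operational definition. Counting is restricted to the region from
sleep onset through the last sleep unit: pre-onset wake is sleep latency
and terminal wake is the final awakening, and neither is fragmentation.
This region choice is declared (a lights-window alternative would count
both) and the region is always bounded by sleep units, so every counted
run is interior.

Sleep onset is the first unit scored as any sleep stage after lights off
(AASM-style), the same rule at both resolutions; REM latency is measured
from sleep onset, consistent with the early-REM definition below. Stage
percentages use the scored (non-UNSCORED) window as denominator so that
WAKE% plus the four sleep-stage percentages always partition 100%.
Early-appearing REM is flagged when at least one REM unit begins strictly
less than 15 minutes after sleep onset — a strict inequality, applied
identically at 30-s and 5-s resolution (one mini-epoch of REM suffices).

## Split-night analysis

The total sleep period (SPT) runs from sleep onset through the last sleep
unit, inclusive, and is divided at `floor(len/2)`; an odd SPT gives the
extra unit to the second half (any fixed rule suffices; this one is
declared for reproducibility). Anchoring the halves on the SPT rather
than the lights window keeps sleep latency and terminal wake out of
half-specific metrics; the lights-window alternative is available via
`boundary="lights"`. All fragmentation metrics are recomputed per half
exactly as on full nights, yielding one value per subject per half per
metric. The only count not attributable to either half is the single pair
straddling the boundary, which the additivity test accounts for exactly.

## Statistical models

Group contrasts on full-night outcomes use a linear mixed-effects model
with fixed effects for group, age and sex and a family-ID random
intercept absorbing patient–sibling relatedness. Split-night models use a
participant-ID random intercept for the two repeated half-values; the
interaction model (group × night-half) is accompanied by four post-hoc
contrasts — within-group half effects and within-half group differences
(the latter fitted with the family random intercept, since each subject
contributes one value per half). Patients-only predictor models use
ordinary multiple regression, as patients are mutually unrelated.

Numerical fitting is delegated to statsmodels (`MixedLM`, `OLS`); the
contribution of this layer is the model specification, the effect-size
derivation and the correction scheme. Coefficients are reported with 95 %
Wald confidence intervals (the CI method is recorded in each result's
model descriptor). Cohen's *d* is the fixed-effect coefficient divided by
the model's residual standard deviation. When the random-effect variance
is estimated at zero, or the optimizer fails, the fit degrades to the
fixed-effects model with a logged notice — a documented fallback, not a
failure.

Outcomes are natural-log transformed under an automatic policy that
mechanizes the usual visual Q–Q inspection: after an initial fit, if the
residual skewness exceeds 1 in absolute value and the outcome is strictly
positive, the outcome is logged and the model refitted. The threshold is
configurable; `always`/`never` overrides exist. Visual steps cannot live
in a tested pipeline, hence the proxy.

The transition-probability grid fits one model per matrix cell per
resolution — 50 models for the two canonical resolutions — excluding,
per cell only, subjects whose originating-stage row is undefined. Cells
with fewer than 10 subjects after exclusions (configurable) are marked
unfit and drop out of the correction family with a logged count.
Benjamini–Hochberg at FDR 0.05 is applied jointly across all fitted cells
of the grid. Exploratory predictor analyses are deliberately left
uncorrected and labelled as such.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with effects
injected on the transition-matrix scale so that every downstream
statistic is an emergent consequence rather than a painted-on difference.

* **Presets.** Per group × night-half 5×5 row-stochastic matrices at 5-s
  steps. No cohort-level matrices are published for this design, so the
  presets are plausibility-tuned: the sibling base matrix is tuned so its
  stationary occupancies sit near normative mini-epoch stage percentages
  (~10 % wake, ~7 % N1, ~52 % N2, ~16 % N3, ~15 % REM) and its per-hour
  indices in the normative range; the patient presets elevate wake-entry
  probabilities (×2.0), wake→REM (×3), N1→REM (×2.5), N2→N1 and REM→N1
  (×2), with wake-entry rising a further ×1.4 in the second night-half.
  Sibling dynamics are identical in both halves (half-stationary).
  Scaled cells absorb their change into the diagonal so rows stay
  stochastic.
* **Heterogeneity and clustering.** Each subject's matrices are Dirichlet
  row perturbations of the group presets (concentration 150, chosen so
  between-subject index dispersion matches the spread reported for real
  cohorts, e.g. sleep–wake index SDs near half the patient mean); each
  family carries a shared log-normal multiplier (σ = 0.2) on wake-entry
  probabilities, creating the within-family correlation the family random
  intercept is meant to absorb. Default cohort: 125 patients and 100
  siblings, every sibling paired with one patient's family.
* **Nights.** Default 5,760 mini-epochs (~8 h), sampled stepwise; the
  first-half matrix governs steps before the chain midpoint, the
  second-half matrix after. REM entry is disabled for the first 30 min of
  the chain (folded into the diagonal), emulating normal REM latency;
  early-REM nights are then created by explicit injection of a short REM
  bout within 15 min of onset, with per-group probabilities 0.60
  (patients) and 0.14 (siblings), matching observed early-REM prevalence.
  Wake padding (5 min before, 2 min after) frames the lights window. The
  30-s twin is derived by majority-vote downsampling (ties to the stage
  occurring last in the window — deterministic and continuity-biased; the
  choice is immaterial since only synthetic data uses it).

**What the generator does not emulate.** Real 30-s scorings are
independent human scorings, not downsamples, so epoch-scale index
magnitudes here exceed those of human-scored epochs (brief bouts survive
majority voting more often than a human scorer would report them); only
cross-resolution directions, not epoch-scale magnitudes, should be read
from synthetic output. Wake-bout durations are geometric within the
chain, so the three wake-period bins are not equally populated as they
tend to be in real mini-epoch scorings; there is no circadian or
ultradian cycling, no scorer error structure, and no arousal semantics —
wake runs are not claimed to capture cortical arousals. Passing tests
therefore demonstrate correctness of the computations and calibration of
the inference machinery under the assumed Markov structure, not fidelity
of any particular real cohort's numbers.

## Numerical and degenerate-input choices

Zero TST makes every index undefined: transition indices raise a
subject-named error, and a night-half with zero TST is flagged undefined
rather than failing the night. Matrix estimation requires at least two
adjacent scored units. Row-stochasticity is asserted to 1e-12. The
stationary distribution used in validation is computed by power iteration
to 1e-12. Degenerate mixed models fall back as described above.
Hypnogram validation reports all violated invariants instead of raising,
so cohort runs can exclude-and-continue (strict mode aborts instead);
every exclusion is tallied in the run summary, which reconciles against
input counts.

## Problem sizes in the test suite

Deterministic identities are exercised on hundreds of random sequences up
to ~150 units. Stochastic checks use seeded, scaled cohorts chosen as the
smallest sizes at which the checked property is statistically stable:
parameter recovery on 50,000-step chains (max-abs error < 0.02);
null calibration of the full generate→features→model path on 200
replicate cohorts of 30+30 subjects with 720-mini-epoch nights (type-I
error within [0.02, 0.08] at α = 0.05) plus 20 null cohorts of
2,880-mini-epoch nights for the BH grid; the qualitative signature
(patient > sibling sleep–wake indices at both resolutions; patient-only
second-half increases in sleep–wake transitions and intermediate/long
wake-periods; sibling half-stability) on one 100+100 preset cohort with
full-length nights.
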