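# arcgait

How many days must a resident of an aged-care facility wear an accelerometer
before their daily walking outcomes are measured reliably? `arcgait` answers
that question for trunk-worn step-event data: it segments steps into
ambulatory bouts, computes daily volume/pattern/variability walking outcomes,
estimates each outcome's **single-day reliability** (intraclass correlation,
ICC) by variance partitioning in a random-intercept model, and inverts the
**Spearman–Brown prophecy formula** to project the number of monitoring days
needed to reach a target reliability — overall and stratified by care level
(intermediate, high, dementia). A fully specified synthetic-cohort generator
stands in for raw wearable data, so every stage is testable end to end.

## The model

An *ambulatory bout* is a run of consecutive steps in which no inter-step rest
exceeds 2.5 s; bouts with fewer than 3 steps are discarded. Each
participant-day yields six outcomes: total walking time, total steps, total
bouts (volume); mean bout length and the power-law exponent α of the
bout-length distribution, `α = 1 + n / Σ ln(dᵢ/d_min)` (pattern); and the
within-day SD of bout lengths (variability).

For each outcome y (square-root transformed where right-skewed), a linear
mixed model with a participant random intercept and fixed covariates
(care level, weekday/weekend, facility) is fit by REML:

```
y_ij = x_ij'β + b_i + e_ij ,   b_i ~ N(0, σ²_b),  e_ij ~ N(0, σ²_e)

ICC_single = σ²_b / (σ²_b + σ²_e)
```

The days N whose average reaches a target reliability ICC_t follow from the
Spearman–Brown prophecy formula, rounded up (minimum 1 day):

```
N = ICC_t/(1 − ICC_t) × (1 − ICC_s)/ICC_s
```

Because the model always carries a single random intercept, REML is profiled
to a one-dimensional optimisation over σ²_b/σ²_e — precise (it matches the
closed-form balanced ANOVA solution to ~1e-8) and fast enough for
cluster-bootstrap confidence intervals and simulation studies.

## Worked example

```python
from arcgait import days_needed, segment_bouts, day_outcomes

bouts = segment_bouts([0, 0.5, 1.0, 4.0, 4.5, 5.0, 5.5])
# [Bout(start_s=0.0, duration_s=1.0, n_steps=3),
#  Bout(start_s=4.0, duration_s=1.5, n_steps=4)]
# the 3.0 s rest exceeds 2.5 s and splits the sequence into two bouts

days_needed(0.71, 0.8)   # -> 2   (N = 4 x 0.29/0.71 = 1.63, rounded up)
days_needed(0.37, 0.8)   # -> 7   a noisy outcome needs most of a week
days_needed(0.80, 0.8)   # -> 1   one day already meets the target
```

An outcome whose single day explains 71% of between-person variance needs
only 2 averaged days to reach composite reliability 0.8; at ICC 0.37 it takes
7 days.

The full study pipeline runs from a config + seed, either as numbered
analysis drivers (`analysis/01_simulate_cohort.py` … `06_project_days_needed.py`)
or via the CLI:

```
arcgait run --seed 1 --out-dir my_run
```

which simulates the cohort (196 enrolled across 17 facilities, with realistic
wear dropout), applies the ≥3-full-days inclusion rule, and writes the
day-outcome table, the 6 outcome × 4 strata reliability table, day-of-week
contrasts, a weekend-effect table, a wear-compliance summary and a manifest.
On the default synthetic cohort (seed 1) the volume outcomes reach single-day
ICCs of 0.59–0.76 (2–3 days needed), day-of-week contrasts are null at
p < 0.01, and 46% of participants return the full week, with skin irritation
the dominant recorded loss reason — mirroring the qualitative structure of
real aged-care deployments.

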