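# Methods

## Outcome definitions and segmentation

Step events (seconds from midnight, strictly increasing within a
participant-day) are segmented into ambulatory bouts with two parameters:
`max_rest_s` (default 2.5 s), the longest rest allowed inside a bout, and
`min_steps` (default 3), the smallest bout retained. A rest of exactly 2.5 s
does **not** split a bout (the rule is strictly-greater); "minimum bout
length" is read inclusively, so 3-step bouts are retained. Bout duration is
last-step time minus first-step time — no cadence-based tail is appended,
keeping segmentation exactly invertible and deterministic.

Per day: total walking time = Σ durations; total steps; total bouts; mean
bout length = total time / total bouts; variability = sample SD (n−1) of
bout durations in raw seconds (a log-scale option is not provided; the raw
scale is what the day-level SD of short bouts naturally lives on); and the
bout-length power-law exponent α estimated by continuous maximum likelihood,
α = 1 + n / Σ ln(dᵢ/x_min). α needs at least `min_bouts_for_alpha` (default
5) bouts — the MLE is unstable below that — and x_min defaults to the day's
minimum observed duration (globally overridable). Degenerate inputs never
raise: zero bouts give zero volume and missing pattern/variability; all
durations equal to x_min (Σ ln = 0, α → ∞) gives a missing α.

Participants with fewer than `min_full_days` (default 3) recorded days are
excluded and logged, never raised. Days are relabelled into a Monday-first
week structure so day-of-week contrasts align across participants.

## Reliability model

For outcome y with transform t (square root for total walking time, steps,
bouts and mean bout length, which are right-skewed; identity for α and
variability):

t(y)_ij = x_ij'β + b_i + e_ij, with b_i ~ N(0, σ²_b) per participant and
e_ij ~ N(0, σ²_e). Fixed covariates: care level + weekday/weekend + facility
for whole-group fits; weekday/weekend + facility within a care level.
Facility enters as a fixed factor by default (a random-facility option is a
possible extension but is not the default). The single-day ICC is
σ²_b/(σ²_b+σ²_e) — fixed-effect variance is deliberately excluded from the
denominator (covariate-adjusted ICC).

Estimation is REML, profiled to one dimension: with a single random
intercept, given λ = σ²_b/σ²_e the GLS solution and residual variance are
closed-form, so the REML criterion is minimised over log λ by bounded scalar
search (xatol 1e-12, λ ∈ [e⁻²⁵, e²⁵], with λ = 0 evaluated explicitly).
Negative between-variance is impossible by construction; a boundary solution
(λ → 0) is returned as σ²_b = 0 with a `boundary` flag. On balanced designs
without covariates this reproduces the closed-form ANOVA expected-mean-squares
solution to ~1e-8 and agrees with statsmodels `MixedLM` to that package's
convergence tolerance (both are kept as independent cross-checks in the test
suite). Collinear design columns are dropped by SVD rank detection before
fitting. Rows with a missing outcome are dropped listwise per outcome, never
imputed.

Confidence intervals for the ICC are percentile cluster bootstrap:
participants resampled with replacement (re-keyed to keep clusters distinct),
each resample refit, 2.5/97.5 percentiles reported; 1000 resamples by
default in the library, 200 in the pipeline/analysis defaults (the profiled
fit makes either cheap; the narrower default keeps a full 24-cell run around
a minute). The bootstrap CI method is a package choice — day-count
projections depend only on the point ICC.

Days needed: N = ICC_t/(1−ICC_t) × (1−ICC_s)/ICC_s, returned as
max(1, ceil(N − 1e-9)). Ceiling is the only rounding policy consistent with
the full published reference table (plain rounding fails, e.g. ICC 0.75 gives
N = 1.33 but 2 reported days); the 1e-9 guard prevents IEEE-double artifacts
(0.8/0.2 × 0.25/... evaluating to 1.0000000000000002) from inflating exact
integer solutions.

Week-structure tests fit day-of-week as a 7-level fixed factor in the same
random-intercept model and report all 21 pairwise Wald contrasts (normal
reference); the p < 0.01 threshold is itself the multiplicity control — no
further correction is layered on. The weekday/weekend effect is a separate
fit with a weekend dummy at the day level (not pre-averaged; pre-averaging
weekday/weekend blocks is intentionally not implemented, as the day-level
dummy uses strictly more information). Absent day levels make the contrasts
involving them unavailable, not an error.

## Synthetic cohort

The generator emulates a week-long ARC deployment: by default 104
intermediate / 68 high / 24 dementia participants enrolled across 17
facilities. Per participant: subject intercept b_i ~ N(0, σ²_between)
(default SD 0.7), facility intercept ~ N(0, 0.15²); per day, latent log
walking volume mu_level + b_i + facility + weekend·1[weekend] + e_ij with
e_ij ~ N(0, 0.45²) and a small weekend deficit (−0.02 log units). Defaults
give a latent single-day volume ICC of 0.7²/(0.7²+0.45²) ≈ 0.71, in the range
reported for volume outcomes in this population; exp(mu) is ~22/17/20 min of
daily walking for intermediate/high/dementia — plausible for mobility-limited
residents. The latent volume is censored at a physiological ceiling (6 h/day
default); configs whose *median* volume exceeds the ceiling are rejected.

Bout durations are truncated Pareto (x_min 1.5 s, cap 1800 s) with care-level
exponents 2.3/2.5/2.1 (dementia heaviest-tailed, a crude wandering proxy).
Exponents above 2 keep the mean bout length finite; x_min × cadence ≥ 2
guarantees every bout has ≥ 3 steps at the default 1.8 steps/s isochronous
cadence, so segmentation recovers the generated bouts exactly (a tested
invariant). Inter-bout rests are drawn ≥ 2.6 s (strictly above the 2.5 s
threshold) by splitting the day's slack with a Dirichlet draw. Bout
composition is keyed to the day's latent volume, so degenerate-variance
configs produce exactly identical days — a deliberate property used by the
tests.

Wear compliance: each participant is full wear (7 days), partial
(uniform 1–6 days) or zero, with default probabilities 0.44/0.44/0.12 and
loss reasons distributed 51.6/15.8/14.7/17.9% over skin irritation / device
loss / equipment failure / other. Under these defaults the ≥3-day inclusion
rule retains ~73% of enrolment and wearers average ~5.3 recorded days. The
configured per-level counts are the *enrolled* cohort; the analyzable subset
is whatever survives dropout plus inclusion (reliability-focused simulations
disable dropout when exact cohort sizes are needed).

A single seed drives everything; participants use deterministic substreams
(seed, care-level index, participant index), so cohorts are reproducible and
order-independent.

### What the generator does and does not emulate

It reproduces: nested facility/subject variance structure with a known
between/within split, right-skewed raw outcomes (motivating the square-root
transform), heavy-tailed bout lengths with level-specific exponents, realistic
wear dropout, and varied recording start weekdays. It does **not** give
subjects their own bout-length exponents — every subject in a care level
shares one — so the synthetic *pattern* and *variability* outcomes carry
almost no between-subject variance and their fitted ICCs sit near zero. Tests
of ICC estimation therefore use latent cohorts with exactly known ICC
(`simulate_latent_cohort`) rather than the full event generator; passing
tests validate the estimation machinery, not the claim that the generator
reproduces any real cohort's reliability profile. No raw accelerometry,
sensor noise, misplacement or cadence variation is simulated.

## Simulation scales

Validation studies are sized to run on one CPU in a few minutes: parameter
recovery uses 200 subjects × 7 days × 20 replicates per true ICC in
{0.3, 0.5, 0.7, 0.9}; the type-I-error study uses 1000 cohorts of 50 subjects
× 7 days (nominal per-contrast rate at p < 0.01 observed ≈ 0.0095);
segmentation is cross-checked against a brute-force gap scan on 1000 random
days. The analysis drivers run the full 196-participant cohort (~3M step
events, ~90 s for the bootstrap reliability table at 200 resamples).

## Known limitations

- The prophecy projection assumes days are exchangeable (parallel
  measurements); day-of-week tests probe, but cannot prove, that assumption.
- Percentile bootstrap CIs are approximate in small strata (the 24-participant
  dementia stratum often hits the σ²_b = 0 boundary in resamples, widening
  the lower limit toward 0).
- When the estimated ICC is near a day-count boundary of the prophecy formula
  (e.g. exactly 0.5 → N = 4.0), sampling noise flips the projected integer on
  either side; projected day counts should be read with their ICC CIs, not as
  sharp integers.
- Minimal-detectable-change estimation would need a repeated measurement week
  and is out of scope; so is any individual-level reliability.
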