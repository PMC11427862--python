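# Methods

This note documents the models, generative assumptions, numerical
choices and known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The system being modelled

A workplace JITAI system observes an information worker through
everyday work devices and decides, every 5 minutes, whether to prompt
("nudge") the worker to perform a sub-5-minute stress-reduction
microintervention. The package models three layers: the **decision
engine** (deterministic), the **worker's behaviour** (stochastic,
drawn from logistic truth models), and the **analysis** that a
researcher runs afterwards on the event log.

## Decision engine

**Stress score.** The momentary score is the arithmetic mean of five
components, each clipped to [0, 1] by a monotone min–max normalizer:

| component | raw signal | default floor–cap |
|---|---|---|
| emails_received | emails received so far today | 0–20 /day |
| meetings_today | meetings so far today | 0–12 /day |
| fraction_of_day | share of workday elapsed | 0–1 (identity) |
| facial | corrugator + lip depressor − zygomatic | ±3, symmetric |
| heart_rate | beats/min | 55–110 bpm |

The normalizer floors/caps are package defaults chosen to be monotone,
bounded and physiologically plausible; the original sensing stack's
exact normalization is not public. The meetings cap (12/day) was set
during the calibration pass described below.

**Baselines.** Each participant's score threshold and EMA threshold
are the means of their week-1 computed scores and week-1 EMA answers;
before any data exist the defaults are the midpoints of the ranges
(0.5 and 3). Baselines are frozen after week 1 — no rolling update —
because they act as fixed thresholds for the remaining weeks.

**Trigger combination.** The two thresholds are combined with OR
(score above its baseline, or a fresh EMA above its baseline). The
combination is configurable (`trigger_mode`: or/and/score/ema)
because the underlying system description does not pin it down; OR is
the default as the more reactive reading. An EMA answer is treated as
"fresh" for 15 minutes (`ema_freshness_min`) — a momentary rating is
taken to describe the present only briefly.

**Gate order.** The block reason reported is the first failing rule
in the fixed order: working hours (half-open [start, end)), pending
user-scheduled intervention, 60-min post-completion cooldown, 120-min
nudge cooldown, 4-per-day cap, stress trigger. Rescheduled nudges
fire at their user-chosen time without re-checking the trigger, but
still honour cooldowns and the daily cap (they are nudges in the log
and count toward the published totals); if blocked they retry each
tick and lapse at the end of the day. A nudge may be postponed once
(`allow_repostpone` to change).

## Behavioural truth models

Each behavioural outcome is drawn from a logistic model on the
log-odds scale. The default coefficient maps are the natural logs of
published odds-ratio tables for: engagement (22 terms incl.
intercept), the three category-choice outcomes, engagement after
choice, liking, and stress improvement. Three deliberate
approximations:

1. **Category choice** is a single multinomial over the three
   choice-model linear predictors (softmax of utilities). The three
   published binary models are not jointly coherent as a generative
   law; the softmax is the closest single mechanism.
2. **Rating** is drawn from a fixed 5-point categorical
   (mean ≈ 3.6); *liked* is then derived by the ≥ "good" rule
   (rating ≥ 4) rather than drawn from its own table — drawing both
   would be circular, since the improvement model uses the rating as
   a covariate.
3. **Improvement intercept.** The published improvement table prints
   its intercept OR as 0.00 (below display precision), so its log is
   not recoverable from the table. The default intercept (−8.84 on
   the log-odds scale) was calibrated once so that the marginal
   improved rate under the default covariate generator matches the
   deployment's 150/521 ≈ 0.29; any intercept ≤ ln 0.005 is
   consistent with the printed value.

Post-intervention stress is set consistently with the improvement
draw: a reduction of 1–3 points (probabilities 0.80/0.15/0.05) when
improved, else unchanged or one point worse (10%), clipped to the 1–5
scale. An improved draw at pre-stress 1 cannot be realised and
collapses to "no change"; the analysis labels are always recomputed
from the stress values, so the log stays internally consistent. The
dedicated recovery samplers fit the *drawn* label, which is the
quantity the recovery experiment is about.

Auxiliary behaviour probabilities default to the deployment's
empirical shares: postponement 248/1585, completing the rating and
post-stress prompts after "done" 521/563, choosing a category without
finishing 87/1022.

## Synthetic deployment generator

**What it emulates.** 43 participants, 4 weeks of weekdays, 9:00–17:00
workdays, 5 EMA prompts/day at random times spaced ≥ 45 min, half-hour
telemetry windows, continuous sensed streams at the 5-minute tick, and
the full nudge/engagement flow.

**Covariate distributions.** Traits are clipped normals with the
cohort's published means/SDs (e.g. cognitive reappraisal 4.69 ± 1.09
on 1–7); gender and age follow 29 men/14 women and 14/18/11.
Count telemetry uses Poisson (meetings 0.30, self events 0.12, ad hoc
calls 0.04 per half hour) and negative binomial for the overdispersed
channels (emails sent/read 0.39/3.22, chats 3.88, attention 1442.64
capped at 5705 — published SDs exceed the means, ruling out Poisson).
Heart rate and the facial score are AR(1) streams; emails received
(the score input, distinct from sent/read) accumulate through the day.

**Day-to-day load.** All count rates for a day are multiplied by a
mean-one lognormal day effect (σ = 0.35) on top of a mean-one
per-participant effect (σ = 0.35). This produces busy-vs-light-day
clustering of high stress — the mechanism by which the trigger rate,
and hence the nudge volume, is controlled. These dispersions, together
with the meetings normalizer cap, were calibrated **once** so that the
default 43 × 4-week run lands near the deployment's printed totals
(≈ 1,585 nudges) with per-nudge context means within ±30% of the
published descriptives; the calibration was then frozen.

**EMA answers** are `1 + Poisson(0.8 · score)` capped at 5, keeping
the cohort in the observed low-stress regime and making the
self-report trigger informative about the latent score.

**Determinism.** One global seed fans out into per-participant
substreams (`SeedSequence((seed, index))`), so enlarging the cohort
never reshuffles existing participants; the event log is byte-stable
for a fixed (config, seed).

**What it does not emulate** (hence what passing tests do and do not
show about real data): actual webcam action-unit coding or
camera-based heart rate (only their aggregate statistical shape); any
feedback of interventions onto later telemetry; within-participant
trait drift; weekends, meetings spilling over window boundaries, or
time zones; and nonresponse patterns beyond the modelled
postpone/ignore/abandon paths. Recovery results therefore demonstrate
the correctness of the estimation pipeline, not the validity of the
original study's substantive findings.

**Known divergence.** The per-slot nudge-probability covariate
averages ≈ 9% in the simulated per-nudge table versus the
deployment's 6%: the gate's cooldown structure concentrates simulated
nudges in afternoon slots more strongly than the real system did.

**Latent vs. empirical features.** The behavioural draws need
engagement skewness and nudge probability *before* the log exists, so
profiles carry a latent skewness tendency (normal, −0.09 ± 0.58,
clipped at ±1.41) and a latent typical slot share; the feature builder
later recomputes both empirically from the log. The two agree only in
distribution, which is why the large-sample recovery experiments use
the direct record samplers (`sample_nudge_records`,
`sample_completed_records`) in which the covariate entering the draw
is the covariate being fitted.

## Feature construction

Context is joined to a nudge by the half-hour window holding its
timestamp (floor to :00/:30, half-open intervals). Attention counts
are divided by 2000 in the model tables; nudge probability is the
participant's share of nudges in the slot-of-day, ×100. Engagement
skewness is the Fisher–Pearson g1 = m3/m2^{3/2} of the participant's
engagement hours (fractional hour of the "done" event); fewer than
3 values or zero variance yield 0 with a logged warning, keeping
every participant usable as a covariate row. The hour-value reading
of "hourly engagements" (rather than counts-per-hour) matches the
sign convention that positive skewness means early-day engagement.
Chat counts are built but excluded from the default model formulas
(the nudges travelled over the same chat channel). `no_meeting_minutes`
is capped at the 30-minute window length, with a warning for larger
inputs. All timestamps are timezone-naive study-local times.

## Statistical layer

Fits are maximum-likelihood binomial GLMs (statsmodels IRLS) over a
patsy formula with explicit treatment references (age 18–35, man,
system trigger, distract, conversation, at-desk). Numerical policy:

* **Separation** fails loudly (diverging coefficients or standard
  errors raise `SeparationError`); no penalization by default.
* **Rank deficiency** raises with the names of aliased columns
  (detected by sequential least-squares projection).
* **CIs are Wald** (symmetric on the log-odds scale), matching the
  style of published OR tables; profile CIs are not computed.
* **BH correction** is applied within one model's non-intercept
  p-value family, not across models.
* **Type-II analysis of deviance** refits the model without each term
  (all columns of a factor at once) and LR-tests against the full fit;
  per-term refit failures are reported per term, not fatally.
* **Tukey-style contrasts** for ≥ 3-level factors use the single-step
  max-|z| adjustment under the estimated multivariate normal of the
  contrasts, evaluated by seeded Monte Carlo (2 × 10⁵ draws) — the
  GLM analogue of Tukey's HSD; exact studentized-range tables apply
  only to linear models and are not used. Adjusted p-values are
  floored at the unadjusted ones.
* Models are fixed-effects only, mirroring the published analysis
  despite repeated measures per participant; this understates
  standard errors on clustered deployment data and is a faithfulness
  choice, not a recommendation.

## Problem sizes

The recovery experiments use 50,000 records (log-scale standard
errors ≈ 0.02–0.03, so 3-SE checks resolve the published ORs
comfortably). Null-calibration checks use 500 replicates of n = 250;
CI-coverage checks 500 replicates of n = 5,000; the calibration run is
the full default deployment (43 × 4 weeks, ≈ 2,100 nudges).

## Known limitations

* The trigger combination, EMA freshness window and component
  normalizers are plausible defaults, not recovered ground truth; all
  are configurable.
* Recovery of the choice, liked and engaged-after-chosen models is
  exercised structurally (fits, dfs, diagnostics) but not pinned to
  3-SE checks the way the engagement and improvement models are.
* The simulated per-nudge covariate distribution is conditioned on
  the trigger, so it is not identical to the unconditional generator
  distribution; calibration targets the per-nudge means.
* On deployment-sized tables (~1.6k nudges, ~500 completed) the
  30-term models are estimable but noisy; small simulated cohorts can
  lack a reference level entirely, in which case the pipeline records
  the model as unfitted rather than failing.
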