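# Methods

`sleepmood` analyses two coupled daily self-report series — sleep quality
(one rating each morning, describing the night just ended) and mood (up to
three ratings per day, averaged) — to ask a directional question: does
sleeping better than usual improve the next day's mood more than a better
mood improves the following night's sleep?  This note records the models,
the choices behind them, and what the synthetic validation does and does
not establish.

## Data model and lag pairing

The unit of analysis is the subject-day.  A panel holds, per day: sleep
quality (0–8 Likert), daily means of mood/stress/energy/focus (each the
average of up to three 0–8 ratings), physical-activity minutes, mean
temperature, clear-sky minutes, day of week and day type
(normal/partial/off work).  Day indices are calendar days; missing days
stay visible as gaps.

Sleep reported on the morning of day *t* refers to the night between days
*t−1* and *t* (surveys launch in the morning).  Two directional datasets
follow:

* **sleep → mood**: treatment = sleep quality reported on day *t*,
  outcome = mean mood of day *t*;
* **mood → sleep**: treatment = mean mood of day *t*, outcome = sleep
  quality reported on day *t+1*.

Confounders attached to a row are the six daily covariates
(stress/energy/focus/activity/temperature/clear sky) of the day preceding
the outcome day, the calendar context (day of week, day type) of the
treatment day, and — at history depth T ∈ {1,2,3} — the mood and sleep
values of the T days preceding the *treatment* day.  Anchoring history to
the treatment day is deliberate: anchoring to the outcome day would, in
the mood → sleep direction, make the treatment its own lag-1 confounder.
Any required day missing ⇒ the row is dropped; nothing is imputed.  The
alternative covariate timing (day before the treatment) is available
behind `confounder_timing=`.

## Within-person normalization

Respondents use Likert scales with different baselines and ranges.  Each
subject's series is therefore z-scored with that subject's own mean and
SD (n−1 denominator), computed over their full daily series; zero-SD
subjects are flagged and excluded from analyses of that variable rather
than silently dropped.  Because the scaling parameters come from the full
panel, normalizing before or after building the lagged datasets yields
identical rows.  On the latent (pre-rounding) scale the z-score removes an
affine response style exactly; on the observed ordinal scale it removes it
up to rounding.

## Mixed-effects cross-effects

* **Raw arm** — `outcome ~ 1 + treatment` with correlated per-subject
  random intercepts and slopes, REML via statsmodels `MixedLM`.  If the
  full structure does not converge the model falls back to a random
  intercept only; a fit that still fails to converge is returned with
  `converged=False` and the optimizer diagnostics instead of raising.  An
  exactly linear outcome leaves the variance components unidentified, so
  that degenerate input short-circuits to the OLS solution (residual
  variance ~0).  A random-intercept-only variant is available via
  `random_slope=False`.
* **Normalized arm** — after within-person z-scoring every subject has
  mean zero on both axes, so the model is `outcome ~ 0 + treatment` with a
  per-subject random slope and no intercept of any kind.  This
  one-variance-component model profiles to a one-dimensional REML problem
  in λ = var(slope)/var(residual): with V_i = σ²(I + λ x_i x_iᵀ),
  Sherman–Morrison reduces the criterion to the per-subject sums Σx²,
  Σxy, Σy², and a bounded scalar minimization gives the estimate in
  microseconds.  This is what makes subject-level bootstrap refits cheap
  (a `MixedLM` refit costs ~0.2 s; the acceptance properties need
  thousands of refits).  `engine="statsmodels"` fits the identical
  specification through `MixedLM` and is the cross-check used in the test
  suite (agreement to ~1e-5 on the slope).

p-values use the large-sample normal approximation on b₁/se.  The
direction comparison resamples subjects with replacement, refits both
directions per replicate, and reports the two-sided percentile p-value of
the b₁ difference (with the (k+1)/(n+1) finite-sample correction).

## Per-subject propensity-score matching

Each subject is their own observational study:

1. **Variance filter.** Subjects whose raw daily treatment variance
   (sample, n−1) is below 0.5 cannot be discretized reliably and are
   excluded, with the exclusion recorded.  The threshold comparison is
   strict (`< 0.5`); the variance formula is configurable since either
   convention is defensible.
2. **Binarization** at the subject's own mean: strictly above ⇒ treated
   ("better than usual").  Ties go to control; the rule is configurable.
3. **Propensity model**: ridge-penalized logistic regression (default
   C = 1) of the binary treatment on the confounders, all z-scored within
   the subject.  The penalty keeps the model defined under perfect
   separation, which is routine at n ≤ 42.  Day of week (1–7) and day type
   (normal=0 < partial=1 < off=2) enter as single standardized numeric
   codes, not one-hot blocks: with ~30–40 rows, six extra dummy columns
   overfit the model enough to near-separate the classes, collapsing the
   median matched-pair count from ~13 to ~4 and doubling the per-subject
   effect noise.  A constant design degenerates to the treated fraction.
4. **Matching**: greedy 1:1 nearest neighbour on the logit propensity,
   without replacement, treated units processed in seed-shuffled order,
   optional caliper of 0.2 × SD(logit propensity).  Without a caliper the
   greedy pass always attains the maximum pair count min(n₁, n₀); the
   caliper trades pairs for comparability and is what produces the
   bias-correction behaviour, at a real cost in retained data on short
   panels (subjects ending with zero pairs are excluded as `no_match`).
5. **Personal causal effect**: (mean outcome, matched treated − matched
   controls) / pooled SD of the two matched groups, the usual df-weighted
   (Cohen's-d) pooled SD.  A single pair or a zero pooled SD is excluded
   as `degenerate_outcome`.  The unmatched comparator applies the same
   statistic to all the subject's rows.

Balance diagnostics report, per confounder: the point-biserial correlation
with the binary treatment (with p-value) before matching, and the
standardized mean difference before vs after matching, per subject and
averaged, plus the count of subjects with p < .05.

## Cohort inference

All cohort-level uncertainty comes from resampling *subjects* with
replacement (default 100 replicates): the mean personal effect with its
bootstrap SD and 2.5/97.5 percentile interval; the paired direction
comparison on subjects valid in both directions (unpaired fallback when
the sets are disjoint, flagged); contrasts of each symptom group against
control by independent within-group resampling (groups share no
subjects); and the T-sweep, which reports the unmatched effect plus
matched effects at T = 0..3 with a per-T exclusion ledger — row counts are
non-increasing in T, and a depth at which fewer than two subjects survive
yields a NaN summary plus the ledger, not an error.  No multiple-testing
correction is applied across contrasts.

## Synthetic cohorts

The generator emulates a four-group, six-week mobile diary study.  Latent
dynamics (per subject, daily):

    m(t)   = ar_mood·m(t−1) + β_sm·s(t) + g·c(t) + ε_m(t)
    s(t+1) = ar_sleep·s(t)  + β_ms·m(t) + g·c(t) + ε_s(t+1)

with c(t) iid N(0,1) shared between the two equations and emitted — with
independent noise (SD 0.3) — as the latent stress/energy/focus of day t,
so the measured covariates of the day before the outcome carry exactly the
confounding signal matching needs.  Activity, weather and calendar
covariates are exogenous.  Observation passes through a subject-specific
affine style (shift ~ N(0, 0.8), scale ~ U(0.7, 1.3)) and ordinalization:
`clip(round_half_up(4 + scale·latent + shift), 0, 8)`; the three
within-day ratings add N(0, 0.5) report noise each.  Screening scores are
drawn from per-group truncated normals (control 4.5/3.8, depressed
13.4/5.9, anxious 7.1/13.4, both 14.2/14.3 for PHQ-9/GAD-7) and
rejection-sampled to respect the cutoff-10 group definitions.  Days are
dropped MCAR with probability `missing_prob`.

Defaults are the study conditions: 51 subjects per group × 42 days,
β_sm = 0.4, β_ms = 0.1, ar_mood = 0.3, ar_sleep = 0.1, g = 0.3,
noise SD = 1, 10% missing days.  `group_betas` can override the couplings
per group (e.g. a more strongly coupled anxious group), since
group-varying coupling is itself part of the design the cohort emulates.
Seeds fan out through `SeedSequence`; identical config ⇒ bit-identical
cohort.

What the generator does *not* emulate: informative (non-MCAR) missingness,
dropout, serially correlated weather, floor/ceiling-heavy response styles,
or item-level (within-day) missingness.  Passing tests therefore establish
estimator correctness under MCAR ordinal reporting with affine styles, not
robustness to informative missingness.

## Validation design and problem sizes

The acceptance suite checks, at sizes chosen to keep the full run within a
desk-scale budget: exact agreement of the per-subject matched effect with
an independent straight-line reference on 8-day fixtures (all T, with and
without caliper); closed-form values; recovery of latent cross-lags
0.4/0.1 through heterogeneous ordinal reporting to ±0.07 (mean over 20
seeds, 100 subjects × 42 days, unconfounded — the paired mixed model
adjusts for nothing, so its recovery property is defined on an
unconfounded cohort; under the default shared confounder the mood→sleep
estimate correctly inflates to ~0.17–0.19, which is the bias the matching
stage exists to remove); direction-test rejection in ≥90% of seeds; null
calibration of both direction tests at ≤10% over 20 seeds (52 subjects);
confounding correction and balance improvement under a strong shared
confounder (g = 0.8, 52 subjects, true effects zero); mutual
bootstrap-interval overlap of unmatched and T = 0..3 matched effects on
unconfounded cohorts; and group contrasts — an anxious group whose
mood→sleep coupling is doubled (0.3 → 0.6) is flagged against control at
T=0 in ≥80% of 20 seeds at 50 subjects/group, with no spurious contrasts
on homogeneous cohorts in ≥85%.  A power analysis during design showed the
per-subject SMD at ~34 rows carries an SD of ~0.6–0.8, so contrasts below
roughly 0.3 in d-units are not reliably detectable at this cohort size;
the doubled-coupling scenario is sized accordingly.

## Known limitations

* The lag-pair mixed models omit autoregressive terms, so with strong
  carryover or shared confounding the cross-effect estimates absorb bias
  by design (the matching arm, not the mixed model, addresses
  confounding).
* Ordinalization attenuates slopes by a few percent (errors-in-variables
  on the treatment); the recovery tolerance absorbs this.
* Per-subject propensity models at n ≤ 42 are necessarily coarse; the
  ridge penalty and compact day-context coding mitigate but do not remove
  small-sample overfitting, and the caliper can exclude short or
  well-separated subjects entirely (always reported, never silent).
* Matching on noisy proxies of a latent confounder removes most but not
  all of its bias (a few percent residual at the default proxy noise).
* The percentile bootstrap with 100 replicates resolves p-values only to
  ~0.02; smallest reportable two-sided p is 2/101.
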