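# Methods

`bandittrial` simulates and analyzes a two-arm randomized trial of
reinforcement-learning–personalized daily text messages for medication
adherence in type 2 diabetes, monitored by electronic pill bottles.  This
note documents the generative model, the learning algorithm, the analysis
pipeline, the numerical choices behind each, and what the simulations do and
do not establish.

## The simulated trial

Sixty patients (HbA1c ≥ 7.5%, 1–3 daily oral diabetes medications) are
randomized 1:1 within four strata — self-reported missed doses (≤1 vs >1 in
the prior 30 days) crossed with baseline HbA1c (<9 vs ≥9%) — using permuted
blocks (block size 4, configurable).  Message-arm patients receive one
composed text per day for 180 days; control patients receive none.  Daily
adherence is the fraction of scheduled doses taken (one dose per medication,
averaged across a patient's medications), so it lies in [0, 1] and is the
bandit's reward, observed with a one-day delay.

## Message action space

Each message is composed from five behavioral factors: framing (neutral /
positive / negative), observed feedback on the prior week's pill-bottle
record ("history"), social reinforcement, reminder-vs-informational content,
and a reflective question.  Framing contributes two indicators against the
neutral reference, giving six binary decision indicators.  The synthetic
catalog enumerates all 48 factor combinations with ≥2 placeholder templates
each; the concrete message is drawn uniformly from the templates matching
the chosen factor set.  Wording is out of scope: templates are format
strings with named slots (first name; prior-week adherent-day count when
history is on).

## Generative adherence model

A patient-day is Bernoulli per dose on the logistic scale:

    p = expit( b_i + Σ_f d_f β_{i,f} + Σ_f d_f d'_f γ_f )

where `b_i` is the patient's baseline propensity (Normal, mean logit 0.68,
SD 1.2), `d_f` / `d'_f` indicate factor `f` in today's / yesterday's
message, `β_{i,f}` are the patient's factor effects and `γ_f` carryover
effects active only when a factor repeats on consecutive days (planted at
+0.4 log-odds for negative framing and history, for all patients).  The
propensity SD was set so the between-patient spread of six-month mean
adherence is roughly 25–30 percentage points, matching what small adherence
trials in this population report.  A per-patient disconnection rate (default
0.02/day) makes measurements missing at random; a sustained-gap mode (≥30
consecutive missing days) can be injected to exercise the censoring
sensitivity analysis.

Three latent responsiveness phenotypes drive the factor effects
(`effect_scale` defaults to 0.8 log-odds):

* **feedback responders** (9/29 expected): history = +`effect_scale`,
  every other factor at the baseline level −0.25 × `effect_scale`;
* **social-feedback responders** (4/29): history and social elevated,
  others at the baseline level;
* **uniform responders** (16/29): all factors at +0.375 × `effect_scale`.

Two structural choices matter and were made deliberately.  First, the
baseline level for non-resonant factors is mildly **negative** (message
fatigue): if every effect were non-negative, the optimal policy would be
"send every factor to everyone", factor indicators would degenerate over
time, and no personalization signal could exist.  Second, phenotype
membership is **tilted by partner status** (married/partnered patients have
6× the odds of being feedback responders, with the cohort-level 9:4:16 mix
preserved by renormalization): responsiveness that correlates with
observable characteristics is precisely what a contextual policy can
personalize on, and it makes the cluster-membership analysis non-trivial.
Setting `membership_tilt = 1` removes the association; `effect_scale = 0`
and `carryover_scale = 0` give a behaviorally null cohort in which the arms
are exchangeable.

Baseline covariates are drawn independently from marginal frequencies
(no copula — only marginals are available to match); unreported fields
(insulin use, employment, therapeutic-class flags) use values realistic for
this population.

## The personalization engine

One shared linear model scores (context, decision) pairs:

    r̂ = clip( 0.5 + w·x + Σ_f d_f v_f·x + Σ_{f<g} d_f d_g c_{fg}, 0, 1 )

The context `x` encodes the baseline block (age, sex, race/ethnicity,
education, partner status, number of medications, insulin use, activation,
employment, HbA1c, therapeutic classes), days since each factor was last
sent (capped at 30, scaled), and whether medication was already taken
before the daily decision.  All bounded components are centered (binary at
±0.5); centering decorrelates the intercept from covariate directions so
the factor-by-covariate interaction blocks `v_f` learn differential
response directly rather than through a shared offset — without it,
personalization is an order of magnitude slower.  The intercept carries the
0.5 prior mean, so an untrained model predicts 0.5 everywhere.

**Decisions.** Each of the six inclusion flags is epsilon-greedy
(ε = 0.2, optional linear decay) on its predicted-reward advantage given
the flags already decided, in a fixed coordinate order; if both framing
learners vote to include, the higher advantage wins and an exact tie
resolves to neutral.

**Updates.** The day-t decision is credited with day-t adherence, delivered
at day t+1; missing rewards (disconnected bottles) trigger no update.  Each
event applies a normalized, inverse-propensity-weighted LMS step: with
error `e = (0.5 + score) − reward`, per-factor importance weights
`i_f = min(1/p_f, 10)` (p_f the policy probability of the realized flag),
and gain `G = |x|² (1 + Σ_f d_f i_f) + #included pairs`, the step
`s = η e / G` updates `w ← w − s x`, `v_f ← v_f − s i_f x`, and
`c_{fg} ← c_{fg} − s`.  Each event therefore moves the prediction exactly
`η e` toward the observed reward — stable for any learning rate η < 1
regardless of context scale, unlike a raw IPS-weighted gradient step, whose
effective step size (IPS weight × |x|²) violates the LMS stability bound
and diverges.  The default η = 0.02 puts the policy's personalization
transition on the months scale, the regime the daily learning diagnostics
are designed to detect.

Feature importance is the ranked absolute weights over base features,
factor × covariate interactions, and factor × factor interactions.

The deployed commercial personalization system this stands in for does not
disclose its model class, exploration scheme, or learning rate; no fidelity
beyond the interface (separate per-factor decisions, delayed scalar reward,
contextual features) is claimed.

## Analysis pipeline

* **Balance.** Absolute standardized differences: binary
  |p₁−p₂|/√((p₁(1−p₁)+p₂(1−p₂))/2), continuous |m₁−m₂|/√((s₁²+s₂²)/2);
  imbalance flagged above 0.1.
* **Primary effect.** Patient-level mean adherence (0–100 scale) regressed
  on arm + stratification indicators + adjustment covariates (default:
  education, partner status, number of medications — the covariates that
  tend to imbalance at n = 60), with HC3 sandwich standard errors.  For a
  one-summary-per-patient outcome this equals an identity-link GEE with
  independent working correlation; HC3 was chosen over HC1 for its better
  small-sample type-I control (verified at ~4% empirical size, n = 60).  A
  daily-record GEE with exchangeable working correlation is available for
  raw logs.  Collinear covariates are dropped with a warning; two-sided
  α = 0.05 throughout, no multiplicity correction for the exploratory
  subgroups (interaction p-values from the pooled arm × subgroup term).
* **Sensitivity filters.** Omit study days 1–14 (observer effects);
  censor each patient at the start of their first ≥30-day disconnection run.
* **Daily adjusted R².** Per study day, OLS of the adherence fraction on
  the six factor indicators across message-arm patients;
  adjusted R² = 1 − (1−R²)(n−1)/(n−p−1) with p = 6.  Days with fewer than
  max(5, p+2) = 8 observations are skipped; zero-variance days report 0
  with a degenerate flag.
* **Factor-day and sequence tables.** Mean (SD) adherence on factor
  send-days and the day after (final-day sends have no successor), and
  means within the four prior-day × same-day inclusion strata (day 1
  excluded; empty strata are missing, never zero).
* **Optimal-adherence models.** Among factor-on patient-days, log-link
  binomial regression of next-day optimal adherence (fraction = 1) on
  baseline covariates, unadjusted for patient-level clustering (the
  convention at this sample size); a modified-Poisson fit with robust
  errors is the flagged fallback on non-convergence.  Risk ratios are
  banded <1, 1.01–1.50, ≥1.50.
* **Responsiveness clustering.** The response matrix holds each
  message-arm patient's mean same-day adherence conditional on each
  factor's presence; cells with <25 observations are replaced by the column
  mean of adequately observed cells and flagged.  Rows are centered
  (removing each patient's overall adherence level so clusters reflect
  differential responsiveness, not baseline adherence), columns
  standardized, then k-means with k = 3 and 50 restarts; clusters are
  relabeled in decreasing size order so the largest (the natural referent)
  is always cluster 1.
* **Membership models.** One baseline contrast at a time, bivariate
  multinomial logistic regression with the largest cluster as referent;
  any zero contingency cell yields a "too small to compute" sentinel
  rather than a divergent estimate.

## Replicate studies and their scope

`bandittrial.studies` packages the operating-characteristic studies:
type-I error (500 null trials of 60 × 180; the non-adaptive fast path is
used because under a null generator decisions are independent of adherence,
leaving the arm contrast's distribution unchanged), power at the design
assumptions (10-point effect, patient-level SD 12.5, analytic noncentral-t
power as the oracle), selection drift toward a single planted factor,
the adjusted-R² learning signature, and planted-phenotype recovery (ARI).

Two quantitative limits of the default study conditions are worth stating
plainly.  First, day-level adjusted R² is intrinsically small here: an
oracle policy that sends each patient exactly their positive-effect factors
attains ≈ 0.056 (vs ≈ 0.014 under a random policy), so the learnable rise
between the day-31–60 and day-150–180 windows (≈ +0.04 at best, ≈ +0.03
achieved) is comparable to the per-seed window noise (SD ≈ 0.06); the rise
is robustly positive on average but individual replicates fluctuate.
Second, planted-phenotype recovery is information-limited: with
between-patient heterogeneity matching the ~25–30-point SD of six-month
mean adherence, patients near the adherence ceiling are nearly
uninformative about their differential responsiveness and collapse onto the
uniform-responder pattern.  K-means on noiseless expected response rows
reaches only ARI ≈ 0.75, and oracle-centroid classification of the
180-day empirical rows ≈ 0.3; observed recovery at default separation is
ARI ≈ 0.25, degrading to ≈ 0 as `effect_scale → 0`.  Recovery of
well-separated planted profiles is exact (ARI = 1), which isolates the
limitation to the information content of the data, not the pipeline.

What the synthetic cohort does not emulate: covariate correlations (only
marginals are matched), enrollment staggering and calendar time, dropout
and consent withdrawal, dose timing within a day, informative (adherence-
dependent) disconnection, and HbA1c outcome trajectories.  Passing tests
establish the pipeline's internal correctness and frequentist calibration
under this generator — not that the planted effect sizes describe any real
population.

## Reproducibility

Every stage is a pure function of its configuration and seed: trials are
byte-identical across reruns, logs round-trip through CSV/JSON with `NA`
for missing, and the run manifest records the config, seed, and SHA-256 of
every output file.
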