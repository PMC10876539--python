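# bandittrial

An in-silico reinforcement-learning text-messaging trial for medication
adherence — simulator, personalization engine, and the full trial analysis,
in one seedable pipeline.

## The problem

Daily text messages can support medication adherence in chronic disease,
but generic content helps only modestly; what a patient responds to is
individual and drifts over time.  One proposed design couples electronic
pill bottles (which measure daily adherence passively) to a **contextual
bandit** that composes each day's message from five behavioral factors —
framing (neutral/positive/negative), observed feedback on the prior week's
pill-bottle record ("history"), social reinforcement, reminder-vs-
informational content, and a reflective question — and learns, from the
next day's adherence as reward, which factors to include for whom.

`bandittrial` is for methodologists who want to study that design's
statistics end to end: it simulates a 60-patient, 6-month two-arm trial
(stratified permuted-block randomization; message arm vs no-message
control) over a cohort with planted responsiveness phenotypes, runs a
per-factor epsilon-greedy linear contextual bandit with delayed,
importance-weighted reward updates, and reproduces every analysis stage of
such a trial:

* baseline balance via absolute standardized differences
  (binary: |p₁−p₂| / √((p₁(1−p₁)+p₂(1−p₂))/2); flag at 0.1);
* the primary effect — patient-level mean adherence (0–100) on arm +
  strata + covariates with HC3 sandwich errors (equivalently an
  identity-link GEE on the patient summary) — plus subgroup estimates with
  interaction p-values and the 14-day / 30-day-gap sensitivity filters;
* the learning diagnostics: the daily adjusted-R² trajectory of adherence
  on the six factor indicators (adj R² = 1 − (1−R²)(n−1)/(n−p−1), p = 6),
  factor-day and prior-day × same-day sequence tables, and ranked model
  feature importances;
* responsiveness heterogeneity: per-factor log-binomial models of optimal
  next-day adherence (relative risks), k-means phenotyping of the
  per-patient conditional-response matrix (≥25-observation rule, mean
  imputation below it), and multinomial cluster-membership models.

The synthetic generator is first-class, tested code: Bernoulli-per-dose
adherence on the logistic scale with per-patient baseline propensity,
three planted responsiveness clusters (expected 9:4:16 among ~29
message-arm patients), consecutive-day carryover effects, and
missing-at-random pill-bottle disconnection.  See `docs/methods.md` for
the model, every default, and the design rationale.

## Worked example

```bash
bandittrial run-trial --out demo --seed 7
# trial complete: 5220 messages, 10580 observed patient-days -> demo

bandittrial analyze primary --log demo
# arm effect: 9.7 pp (95% CI -2.3, 21.7; p = 0.113; n = 60)

bandittrial analyze responsiveness --log demo --out demo_analysis
# cluster sizes: {1: 18, 2: 8, 3: 3} -> demo_analysis
```

The first command simulates the full trial (29 message-arm patients × 180
days = 5220 composed messages; 10580 of the 10800 patient-days produced a
pill-bottle reading, the rest were disconnected) and writes diff-able CSV
logs plus a manifest with content hashes — rerunning with the same seed is
byte-identical.  The second fits the primary model: in this replicate the
message arm's adjusted mean adherence is 9.7 percentage points higher than
control, with a 95% interval crossing zero — at n = 60 with
between-patient SDs of ~25–30 points, single replicates are expected to be
noisy around the planted uplift.  The third writes the daily adjusted-R²
series, factor-day and sequence tables, the response matrix, cluster
assignments (here 18/8/3 across the three recovered groups), and
membership odds ratios.

The same pipeline is available as a library:

```python
from bandittrial import TrialConfig, run_trial, estimate_primary

log = run_trial(TrialConfig(seed=7))
est = estimate_primary(log)
print(est.point, est.ci_low, est.ci_high)
```

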