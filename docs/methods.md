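# Methods

## Problem and model

The package analyzes cohorts of *preprint–article pairs*: RCTs whose results
were first posted as a preprint and later published in a peer-reviewed
journal. For each document version, five critical binary outcomes are
recorded as per-arm 2×2 counts (events / number analyzed in intervention and
control arms). The scientific question is whether the two versions report
the same results, answered per trial through a discrepancy taxonomy and at
cohort level through tallies and a stratified characteristics table.

### Effect estimate

The effect measure is the risk ratio. For a table (a, n1; c, n2),

    RR     = (a/n1) / (c/n2)
    se_log = sqrt(1/a − 1/n1 + 1/c − 1/n2)
    CI     = exp(log RR ∓ z_{1−α/2} · se_log)

with α = 0.05 by default (95% CI). Zero-cell policy: when exactly one of a,
c is zero, 0.5 is added to all four cells of the table (each denominator
becomes n + 1) — the conventional continuity correction of meta-analysis
tooling — and the estimate is flagged `corrected`; when both are zero the
effect is inestimable and carries no point or interval. An interval endpoint
exactly equal to 1 counts as *not* significant (closed-interval convention;
conservative, and ties are measure-zero in practice). These are deliberate
pins: published cohort analyses of this kind rarely print their CI method,
so the choice is documented here and frozen in tests. If one needed to match
a specific original analysis exactly, the CI method would have to be matched
to that analysis's tooling.

Direction is polarity-aware: clinical improvement is a benefit outcome
(RR > 1 favors the intervention); WHO-CPS ≥ 7, mortality, and the two
adverse-event outcomes are harms (RR < 1 favors the intervention). A point
of exactly 1 is directionless.

### Discrepancy taxonomy

Outcomes are matched across documents by the closed five-outcome vocabulary
(no fuzzy name matching — the vocabulary *is* the outcome identity), giving
statuses matched / added-in-article / deleted-in-article with the set
conservation laws |matched| + |deleted| = |preprint| and |matched| + |added|
= |article|. For matched outcomes:

- **estimate change** is operationalized as any change in per-arm event
  counts or numbers analyzed. The continuous article/preprint point-estimate
  ratio is reported alongside for magnitude inspection but does not gate the
  flag — no "minor change" threshold is imposed, because any such threshold
  would be arbitrary.
- **direction change** and **significance change** come from the effect
  predicates and are only assessed when both sides are estimable; a
  double-zero table on either side suppresses them rather than erroring the
  trial (the count discrepancy itself remains detectable).
- **conclusion change** is annotation-first: when the record carries an
  extracted qualitative judgment it is used verbatim; otherwise the fallback
  heuristic is direction change AND significance change, the most
  conservative reading of "the overall conclusion changed".

A trial is **consistent** iff nothing was added or deleted and every matched
outcome has identical counts. Consequently the flag hierarchy direction ⇒
estimate-change and significance ⇒ estimate-change holds by construction
(any direction/significance change requires differing counts).

### Cohort summaries

Categorical characteristics are frequencies with integer percents, rounded
half-up — the rule that reproduces integer percentage columns such as 83/109
→ 76%. Continuous characteristics (sample size; preprint-to-publication
delay in civil days, preferring each document's online date over its print
date) are medians with IQRs by linear interpolation at fractional order
position (n−1)·p, the numpy/spreadsheet default; the convention is pinned in
tests since published tables rarely state theirs. The characteristics table
is stratified into all / consistent / added-or-deleted / estimate-change;
the last two may overlap (one trial can sit in both), so the summary never
forces a partition. Preprint-post periods bucket the preprint date relative
to 2020-03-01 at exact 6- and 12-month calendar boundaries (2020-09-01,
2021-03-01), left-inclusive — the boundary handling is a documented choice.

Flow accounting is the identity included = identified − Σ exclusions,
constructor-enforced with non-negative counts.

## Synthetic cohort generator

`generate_cohort(SyntheticConfig)` emulates the data a real extraction would
produce. Per trial: categorical characteristics are drawn from Table-1-like
default distributions (the marginal proportions of a 109-trial reference
cohort); a preprint date is uniform over the first ~25 pandemic months and
the publication delay log-normal with median 121 days and σ = 0.65 (giving
an IQR near 75–190 days); the reported outcome set is Bernoulli per outcome
(mortality 0.85, serious AEs 0.65, any AEs 0.60, clinical improvement 0.55,
WHO-CPS 0.40 — safety and mortality outcomes are near-ubiquitous in
treatment RCTs, the progression scale less so), redrawn if empty. Per
outcome: arm sizes log-uniform in [25, 250] (small trials common, a right
tail of large ones; total trial size then has median ≈ 160 and IQR ≈
90–280), control risk uniform in [0.05, 0.40], true RR log-uniform in
[0.5, 1.6], and event counts independent binomials per arm.

The article starts as a verbatim copy of the preprint; then, independently
per outcome, **at most one** injection is applied (keeping the ground truth
unambiguous):

- event perturbation (prob 0.018): one arm's events shifted by
  Poisson(1) + 1 — strictly positive, so the flag is always true when
  applied — clamped to [0, n], pushed the other way if clamping voided it;
- denominator perturbation (0.010): ±1–5 on one arm's n, events re-clamped;
- deletion (0.0185); direction flip (0.003): article counts resampled from
  the same binomial laws until the point estimate crosses 1, with a budget
  of 100 attempts — infeasible flips (e.g. inestimable or exactly-null
  preprints) are logged and skipped so generation always terminates;
- addition (0.066) applies to each vocabulary outcome absent from the
  preprint, drawn fresh for the article.

The per-outcome defaults are calibrated so a default 109-trial draw lands
near realistic per-trial discrepancy rates (~13% of trials with an outcome
added, ~6% deleted, ~8% with a count change, ~1% with a direction flip)
given the default outcome-inclusion probabilities: e.g. with a mean of ≈1.95
absent outcomes per trial, P(any added) = 1 − (1 − 0.066)^1.95 ≈ 0.125. All
randomness flows from the single config seed (numpy `default_rng`), making
the generate → classify → summarize chain byte-reproducible.

Every trial × outcome slot is logged (`InjectionLog`), including untouched
ones, so ground-truth per-trial flags and the exact per-trial addition
probability 1 − (1 − p_add)^k (k = outcomes absent from the preprint) are
recomputable from the log alone. `recover_injection_rates` compares detected
with ground-truth flags; agreement is exact for additions, deletions and
count perturbations by construction, and for flips because the generator
verifies both sides before logging one.

What the generator does **not** emulate: interim-versus-final analyses
(excluded upstream in real cohorts), time-to-event outcomes,
characteristic–discrepancy correlations (characteristics are drawn
independently of injections, so stratified summaries of synthetic cohorts
show no real structure), and peer-review-induced text changes. Passing tests
therefore demonstrate the pipeline's bookkeeping and estimator correctness,
not that real cohorts behave like the simulation. Note also that an
event-count perturbation on an outcome whose RR sits near 1 can incidentally
move the point across 1; detected direction changes are checked against
logged flips only for flip-only cohorts.

`make_discrepancy_cohort` is a separate, fully deterministic builder: it
constructs a cohort with an *exact* discrepancy composition (defaults: 109
trials — 81 consistent, 14 with an added outcome, 6 with a deleted one, 9
with a count change of which one flips direction and one overlaps the added
group; no significance or conclusion changes) and characteristic levels
apportioned by largest remainder to hit the reference marginals exactly. It
is the fixture for the cohort-arithmetic tests and the acceptance script.

## Numerical and design notes

- Dates are ISO-8601 civil dates; delays ignore time zones. A negative delay
  (article predating preprint) warns but is reported as-is.
- Unknown categorical values are rejected, never coerced — silent coercion
  would corrupt the stratified summaries.
- The CI is clamped (by at most one ulp) to bracket the point, guarding the
  bracket invariant against floating rounding at extreme counts.
- Problem sizes in the test suite and acceptance script (500-trial
  null-injection cohort, 1000-trial recovery cohorts, ~1000-table oracle
  grid) were chosen to make binomial standard errors small while keeping the
  whole suite comfortably fast.
- The CLI is a thin shell over the library: data to files, tallies to
  stdout, logs to stderr; usage errors exit 2, validation failures exit 1
  with row coordinates.

## Limitations

- The five-outcome vocabulary sidesteps free-text outcome matching; applying
  the pipeline to other outcome sets requires extending the vocabulary.
- No meta-analytic pooling, no between-stratum hypothesis tests, and no
  spin/conclusion text mining — conclusions enter only as extracted
  annotations.
- The risk ratio is the only implemented measure; the estimate type is
  enumerated so odds or hazard ratios could be added without schema changes.
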