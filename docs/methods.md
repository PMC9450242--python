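# Methods

## The estimation problem

A two-phase epidemiological design screens an entire cohort cheaply
(phase 1) and administers expensive structured diagnostic interviews only
to those above screening cut-offs (phase 2).  Roughly half of those
selected are then never interviewed — unreachable or unwilling — so the
naive interviewed-case count underestimates prevalence, while treating
everyone un-interviewed as unknown wastes the screening information.  The
package implements the estimator used in adolescent psychiatric
epidemiology for this design, together with a synthetic-cohort generator
that makes every stage testable against known ground truth.

## The estimator and its assumptions

Within a gender stratum of `N` screened adolescents, with `i` interviewed,
`d` of them diagnosed, and `L` selected but lost to interview:

```
p = 100 · (d + L · d / i) / N
```

Two assumptions carry the formula:

1. **Screen-negative ⇒ no diagnosis.**  Anyone below every relevant
   cut-off contributes to `N` only.  With imperfect screen sensitivity
   this makes the estimator *strictly downward biased* — a property the
   test suite asserts by simulation (sensitivity 0.8, sign test across
   200 cohorts) rather than merely documents.
2. **Screen-positive exchangeability.**  The selected-but-lost carry the
   same diagnosis distribution as the interviewed, since both scored above
   cut-off.  Under this assumption plus participation independent of true
   status, the estimator is unbiased; the suite verifies mean error within
   3 Monte-Carlo standard errors over 200 simulated cohorts of n = 949.

The combined estimate is the *unweighted mean* of the two gender strata,
adjusting for their unequal sizes (girls outnumber boys ~5:4 in the
emulated design).  No variance machinery is attached: the method is a
point-estimation rule, and confidence intervals would require modelling
the selection process beyond what the two assumptions state.

For psychiatric modules the interview base `i` is per module: only the
modules indicated by screening are administered (more than three indicated
modules triggers the full 16-module interview), so each module row has its
own denominator.

### Cohort-1 gambling/gaming imputation

One school-year cohort was never screened for gambling/gaming at baseline;
its members were screened late, and only if contacted for a substance-use
or psychiatric interview.  That late-screened subgroup is selection-biased
(contact required a positive substance/psychiatric screen).  The never-
screened remainder is therefore imputed from the *other* cohort's
comparable subpopulation — those screened but not interviewed with the
substance/psychiatric instruments — at that reference group's estimated
category fractions.  The imputed pseudo-counts are fractional and carried
at full precision; they are never rounded to whole cases, which is why
estimated prevalences need not match observed case counts.

## Diagnostic banding

* Substance, per ICD-10 logic: ≥ 3 of 6 dependence criteria ⇒ dependence
  (which supersedes a harmful-use flag); harmful flag without dependence ⇒
  harmful use; otherwise 1–2 criteria ⇒ sub-threshold ("diagnostic
  orphans"); else none.  The ≥ 3 threshold is the standard ICD-10 rule.
* Gambling severity from the NODS total (0–10): 1–2 at-risk, 3–4 problem,
  5+ pathological.  The instrument-standard maximum of 10 is assumed.
* Gaming severity from the IGDS total (9–45): 17–20 at-risk, 21+
  pathological.
* A person-level "any substance" category is the severity maximum across
  the 11 substance groups; "any psychiatric" is a disjunction over the 16
  modules, with unadministered modules counting negative (consistent with
  assumption 1).

"Above the cut-off" is implemented as ≥ for the named screening cut-offs,
because the stated cut-off scores (AUDIT 6, DUDIT 2, SURNC 5) are
themselves selecting.  Percentile cut-offs use the nearest-rank rule: the
smallest observed score with at least the target percentage of the sample
strictly below it, so scoring ≥ the threshold places a participant in the
most severe tail; a degenerate (all-equal) distribution flags the whole
sample with a logged warning.

## Comorbidity

Type-level comorbidity (SUD × psychiatric × gambling × gaming) extends the
two assumptions to pairs: screen-negative on either member ⇒ not comorbid;
both-interviewed pairs are counted directly; selected-for-both but
incompletely interviewed pairs are extrapolated at the both-interviewed
joint rate.  Case definitions combine dependence + harmful use (not
sub-threshold), problem + pathological gambling (not at-risk), and
pathological gaming only.  Conditional rates are `100·c/p`, computed only
when at least 12 comorbid pairs were observed (a reliability rule of
thumb); below that the function returns an explicit not-computed marker.

Dyads of specific disorders use confirmed data only (no lost-to-interview
extrapolation).  A participant counts in a dyad's denominator when both
members are confirmed — interviewed, or screen-negative and hence imputed
negative; selected-but-lost and never-screened participants are excluded.
Alcohol use disorder stays separate while all other substance groups
collapse to a drug-use-disorder indicator; ADHD and ADD are combined.
Association is the phi coefficient with significance from the chi-square
statistic `n·phi²` on 1 df, two-sided, without continuity correction —
the conventional Pearson-phi test; no multiple-testing correction is
applied, matching the source procedure.  Bands: phi > 0.30 substantial,
\> 0.20 considerable, otherwise moderate when p < alpha (default 0.05).
Under independence the moderate band is exactly the test's type-I error,
which the suite verifies at alpha within binomial error.

## The synthetic-cohort generator

A latent Gaussian threshold model: each disorder gets one standard-normal
liability, correlated across disorders by a configurable matrix (default:
uniform 0.2, the simplest positive-dependence structure that is PSD at any
dimension and has an analytic bivariate orthant oracle,
`joint_probability`).  Liabilities are thresholded at per-gender quantiles
matching configured true prevalences; substance liabilities carry three
ordered tiers (dependence / harmful / sub-threshold), gambling three and
gaming two severity tiers.

Default conditions emulate the study: 528 girls / 421 boys; cohort 1 at
460/949 of the sample with the gambling/gaming screening gap;
participation 54.9% (girls) and 46.0% (boys) among the selected,
independent of true status; true prevalences seeded from the study's
estimated values.  Screen sensitivity defaults to 0.95 per domain
(inclusive low-cut-off screening); false-positive rates (substance 0.06,
per-syndrome psychiatric 0.10, gambling 0.33, gaming 0.12) were chosen
once so that expected selection volumes land near the study's (≈ 273
substance, ≈ 766 psychiatric, ≈ 254 gambling, ≈ 100 gaming interviews
selected).

Screening scores are rendered consistent with the fixed cut-offs: a
screen-positive draw guarantees AUDIT ≥ 6, a screen-negative draw keeps
all three substance scales below their cut-offs, so configured
sensitivity/specificity hold *exactly at the cut-offs*.  The two
percentile-based supplementary scales are handled differently: the
psychosomatic-problems score is pure noise (Poisson), contributing only
benign false positives, while the delinquency score — the sole screening
route to the antisocial-personality module — gets a large boost for true
ASPD cases at the psychiatric sensitivity, without which that module's
prevalence could never be recovered.  Interview outcomes reproduce the
latent truth: criterion counts drawn inside the band matching the true
tier, module flags equal to the true indicators, NODS/IGDS totals drawn
inside the true severity band.  Dependence never remits past-year;
harmful use remits with probability 0.3 (defaults chosen as plausible,
with past-year rates otherwise half the lifetime ones).

What the generator does **not** emulate: item-level instrument responses,
the contact process (attempt counts), longitudinal dynamics, and any
dependence of participation on severity (available as a hook but off by
default).  Passing recovery tests therefore show the *estimator* is sound
under the stated assumptions — not that real attrition is ignorable.

## Numerical choices

* Display rounding is half-up to one decimal; all internal arithmetic and
  all emitted `value` fields are unrounded, since published composite
  cells mix rounded and unrounded stratum inputs (tolerances of ±0.1 pp
  for one-decimal and ±0.5 pp for integer-printed figures absorb this).
* The estimator returns 0 when `d = 0` regardless of `L`, refuses when an
  interview base is below the configurable minimum (default 1), and logs
  a warning below 10.
* Problem sizes in the test suite: 200 replicate cohorts (n = 949) for the
  unbiasedness and bias-direction checks, 500 replicates for type-I
  control, exhaustive scans for every scoring band and for all 2×2 tables
  with total ≤ 30.  These sizes give Monte-Carlo standard errors well
  below the asserted tolerances.

## Known limitations

* Gender is modelled as the study's binary because every estimator is
  stratified on it; the schema reserves no third stratum.
* The per-row lost-to-interview counts printed alongside the source
  tables are not reconstructible from selected-minus-interviewed counts;
  this package always derives `L = selected − interviewed` from its own
  data and treats published stratum prevalences purely as worked-example
  inputs.
* How partially-answered screening scales were scored is unstated in the
  source; `cronbach_alpha` (covariance form) uses complete cases only and
  logs the dropped count.
* Whether percentile cut-offs were derived per gender or on the full
  sample is unstated; the full screened sample is used.
* The mapping from a severe psychosomatic-problems score to specific
  psychiatric modules is not specified by the design; this package
  indicates the depression and generalised-anxiety modules, the two
  general emotional syndromes, and delinquency indicates ASPD.
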