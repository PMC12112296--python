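# Methods

`faerspv` implements the desk workflow of a spontaneous-report
disproportionality study of renal adverse events under combined checkpoint
inhibitor (ICI) and acid-suppressant (PPI / H2RA / P-CAB) therapy. This note
records the statistical model, the conventions chosen where the field admits
several, and what the synthetic-data validation does and does not show.

## Analysis unit and deduplication

The analysis unit is the *deduplicated case*: one patient-event case
(CASEID) may be submitted as several report versions (PRIMARYID). Per
CASEID the surviving version maximizes (FDA_DT, PRIMARYID)
lexicographically — the most recently received version wins; equal receipt
dates are broken by the higher PRIMARYID. A version with a missing FDA_DT
ranks below any dated version: we prefer the version the FDA demonstrably
received latest. Deduplication is idempotent and the survivor count always
equals the number of distinct CASEIDs.

Within a case, drug entries are collapsed on (ingredient, role) keeping the
earliest start date, and reactions on the normalized preferred term, so a
case can contribute at most one count per PT and one count to any-event
tallies.

Partial dates (4/6/8-digit fields) carry an explicit precision tag; nothing
is imputed. Impossible calendar dates are treated as missing.

## Exposure classification

Drug-class dictionaries (ingredients plus brand synonyms, lower-case,
salt-suffix-stripped matching) define four study classes. Classification
priority is COMBO > MONO > OTHER:

* a class *matches* when at least one of its drugs carries a suspect role —
  PS only, or PS/SS under the default `ps_ss` strictness. The default
  accepts a secondary-suspect partner because a two-drug combination report
  can designate only one primary suspect; `ps_only` reproduces a strictly
  primary-suspect search.
* COMBO requires a matching ICI and a matching acid-suppressant class
  (PPI > H2RA > P-CAB priority if several are present);
* MONO requires exactly one study class present in the case *in any role*,
  keeping monotherapy reference groups uncontaminated — an ICI case with a
  concomitant-role PPI is neither COMBO (partner not suspect) nor ICI_MONO
  (contaminated) and falls to OTHER;
* the regimen sub-label (PD-1 / PD-L1 / CTLA-4 / ICI_combination) comes
  from the molecular targets of the suspect-role ICIs.

Classification is deterministic and invariant to drug-list order; the
vectorized and per-case implementations are property-tested for agreement.

## Event definition

The renal adverse event is a configurable set of MedDRA preferred terms
(union of SMQ lists, SOC subtrees and manual additions; exact string match
after case/whitespace normalization, no hierarchy walk, since the licensed
dictionary cannot be shipped). The packaged default list is a
reconstruction around the published renal signal terms and is meant to be
replaced by a user-supplied full list in production use.

## Disproportionality statistics

For each exposure group and PT, the 2×2 table counts cases with/without
the event inside the group (a, b) and in the reference set (c, d) — either
the full remaining database or another group.

* **ROR** = (a·d)/(b·c) with Wald 95% CI
  exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.959964 (not rounded). The
  Haldane–Anscombe +0.5 correction is applied to all four cells only when a
  zero cell occurs; large-count tables are uncorrected so printed values
  match raw cross-products. Display rounding (2 dp) happens only at
  serialization; audit files keep full precision.
* **IC** (BCPNN information component) = log2((O+s)/(E+s)) with O = a,
  E = (a+b)(a+c)/n computed from within-analysis margins, and shrink
  parameter s = 0.5. IC025 uses the closed-form credibility approximation
  IC − 3.3(O+s)^(−1/2) − 2.4(O+s)^(−3/2); a Monte-Carlo mode samples the
  observed-to-expected posterior Gamma(O+s, rate E+s) and takes the
  empirical 2.5th percentile. The two agree within 0.15 bits for O ≥ 3
  (acceptance-tested).
* **Positive signal**: n ≥ 3 AND ROR lower bound > 1 AND IC025 > 0. Both
  metrics must agree; no multiple-testing adjustment is applied across PTs
  (the dual thresholds serve that role, as is standard in this literature).

Head-to-head comparisons reuse the same machinery with one group as
exposure and another as reference, reporting a two-sided Wald p-value.

## Time to onset

TTO = earliest day-precision event date among matched reactions (falling
back to the case-level EVENT_DT, which is where the source dialect stores
it) minus the earliest day-precision start date among study-class
suspect-role drugs. Same-day onset (0 days) is valid; a strictly negative
interval is excluded as a temporal inconsistency; any missing or partial
date excludes the case as missing data. Exclusions are tagged outcomes and
the tally is conserved.

Summaries report the median (midpoint of central order statistics for even
n) and hinges computed as medians of the lower/upper halves *excluding* the
overall median when n is odd. Quartile conventions differ across software;
this median-exclusive convention is fixed and recorded in output metadata.
Group distributions are compared with the Kruskal–Wallis test (midranks,
tie-corrected, chi-square reference); the all-values-identical degenerate
case returns H = 0, p = 1. The test statistic itself is delegated to
scipy.stats.kruskal and is verified in the tests against a brute-force
midrank computation.

## Risk-factor screening

Within the combination cohort the outcome is "case reports a renal PT"
versus not — the only denominator expressible from spontaneous reports.
Each factor is screened alone by maximum-likelihood logistic regression
(hand-written IRLS/Newton: log-likelihood tolerance 1e-8, at most 50
iterations) with Wald 95% intervals and p-values, matching standard
pharmacovigilance reporting. Complete cases only; `n_used` is reported.
Separation (a level with all or no events, non-convergence, or |coef| > 15)
flags the level non-estimable instead of reporting an exploded estimate.
Age and weight are screened as continuous by default with configurable
bands, since the published encodings of such factors are rarely stated.
For a binary factor the fitted odds ratio equals the sample cross-product
ratio to 1e-6, which ties this module to the disproportionality module and
is acceptance-tested. statsmodels serves as an independent cross-check in
the test suite, never as the implementation.

## Synthetic-report generator

The generator is first-class, tested code: it emits the five
dollar-delimited tables with a ground-truth manifest so every stage can be
validated without redistributing any real extract.

Per case: group fixed by configuration; drugs from group-specific agent
mixes (suspect roles arranged so classification recovers the group
exactly); each catalogue PT an independent Bernoulli with probability
base_rate × multiplier(group, pt), capped at 1 with a manifest warning;
TTO log-normal per group; EVENT_DT = START_DT + TTO (capped at 10,000 days
to keep dates within a plausible reporting horizon — far above every
configured quartile); FDA_DT trails the event by 7–120 days; duplicates
re-emit a case under a lower PRIMARYID with an earlier or tied FDA_DT;
dates truncate day → month → year → missing at configured rates;
demographic margins (sex, region, reporter, age and its missingness,
outcomes, renal-malignancy indication) follow published per-group reporting
patterns at desk scale. Default group sizes are 4,000 / 8,000 / 400 /
40,000 (ICI / PPI / combination / background); default onset medians are
42 / 805 / 21 / 120 days; default planted multipliers follow the published
per-PT signal pattern (strongest tubulointerstitial-nephritis signal in the
combination group) plus elevated hallmark immune-related AEs (colitis,
pneumonitis, hepatitis, hypothyroidism, rash) in ICI-containing groups.

Multipliers act on per-PT Bernoulli *rates*, not odds; at the rare rates
used the distinction is negligible, and the analytic `expected_table`
(and the closed-form expected ROR derived from it) is exact under the
model, so recovery tolerances are honest. A count-level
`simulate_contingency` draws binomial 2×2 tables under the same law for
replicate studies; it coincides with the full generator whenever no
agent-specific multipliers are configured, which the tests verify in
distribution.

What the generator does *not* emulate: the ~25k-PT marginal structure of a
real database (the catalogue is tens of PTs, so co-reporting fractions run
lower than published), reporting-rate drift over time, correlated
polypharmacy beyond the study classes, and indication-driven confounding.
Passing tests therefore demonstrate correctness of the pipeline's counting
and estimation under a known model — not robustness to real-world reporting
biases, which no desk-scale simulation can establish.

## Problem sizes used in validation

The test suite and the acceptance script scale the simulations to desk
size as the package's own choice: planted-signal recovery runs one
100,000-case quarter end to end (three planted combination-group signals
among an otherwise null ~30-PT catalogue); the null false-positive surface
uses 100 seeds at the count level of the same model; reporting-rate
recovery uses 200 binomial replicates at 50,000 exposure cases per
multiplier; rank-test calibration uses 1,000 null replicates.

## Known limitations

* Signal thresholds are screening devices; positive signals are reporting
  associations, not incidence or causality.
* Headline group denominators of published full-archive analyses are not
  reconstructable from printed tables alone, so absolute RORs from real
  archives are reproduced in procedure, not in value.
* Exact-string PT matching misses lexical variants a licensed MedDRA
  hierarchy walk would catch.
* No dose, duration or cumulative-exposure modelling; no multivariable
  adjustment (the univariate screen is the published design).
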