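# Methods

This note documents the models and procedures implemented in `faerspv`,
the defaults chosen where the design was open, and what the synthetic
validation does and does not establish about real spontaneous-report
data.

## Data model and cohort construction

A FAERS *case* (CASEID) may be reported several times; each submission
is a *report version* (PRIMARYID) spread over six quarterly ASCII
tables. The reader locates columns by name (case-insensitive), not
position, because the public schema drifts across quarters; unknown
columns ride along in a raw-field mapping so files round-trip exactly.
Dates are kept as partial dates (year / year-month / full) with no
imputation at the I/O layer; ages are normalized to years using the
unit code (YR×1, DEC×10, MON÷12, WK÷52.18, DY÷365.25 — a documented
convention, since reporting practice does not fix one; a numeric age
with a blank unit is taken as years, an unknown unit makes age
missing).

Deduplication is the FDA variable-matching rule: per CASEID keep the
report with the latest FDA_DT, breaking ties by largest PRIMARYID.
Comparison uses the key (year, month-or-0, day-or-0), so a version with
missing date components sorts before any fully dated one, and
PRIMARYIDs compare numerically when all digits. The selection is a pure
maximum — idempotent and invariant to input order — and after it one
report represents one case, which is why downstream "case-level"
analyses simply operate on deduplicated reports.

The background is then restricted to reports whose indication set
intersects the configured indication PTs (default: Psoriasis and
Psoriatic arthropathy; exact PT match, case-insensitive). Each kept
report carries a subgroup tag (psoriasis / psa / both); subgroup scans
treat "both" as a member of either subgroup. Exposure to a study drug
is dictionary-driven and deliberately conservative: a report is exposed
when some drug row with role PS or SS matches a configured generic or
brand name, either as the whole normalized DRUGNAME/PROD_AI or as a
whole word inside it (so "TOFACITINIB CITRATE" matches, "NOTTOFACITINIBX"
does not). Fuzzy matching is out of scope; misspellings are handled by
extending the user dictionary, trading recall for reproducibility.

## Disproportionality statistics

All counting is at the report unit: a report contributes at most once
to a drug–term cell regardless of how many times a PT is mentioned,
which the data model enforces by storing reactions as sets. For each
drug × term at a level (PT, SOC via the primary-SOC map, SMQ via
membership sets; unmapped PTs are kept in an explicit UNMAPPED bucket
so totals are conserved), the 2×2 table against the indication-
restricted background yields

* ROR = ad/bc with the 1.96 normal Wald interval on the log scale and
  the Haldane–Anscombe +0.5 continuity correction applied to all four
  cells whenever any cell is zero (both point estimate and interval).
  A table with an entirely empty margin has no defined odds ratio and
  is reported as NaN, never an exception.
* IC = log2((a+½)/(E+½)), E = (a+b)(a+c)/N — a shrunk
  observed-to-expected ratio whose +½ offsets keep every case finite
  and pull small-count estimates toward 0. Credible bounds use the
  standard closed-form approximation (IC025 = IC − 3.3(a+½)^−½ −
  2(a+½)^−3/2; IC975 = IC + 2.4(a+½)^−½ − ½(a+½)^−3/2). An exact
  alternative takes log2 of the 2.5%/97.5% quantiles of
  Gamma(a+½, rate E+½), the posterior form the approximation was
  fitted to; a grid sweep shows the two never differ by more than
  ≈0.0493 bits for a ≥ 3, which is why the approximation is the
  default and the gamma form serves as the internal oracle. The
  offset and CI method are configurable should a study require
  different shrinkage constants.

A pair is *evaluated* when n = a ≥ 3 and *positive* when additionally
ROR025 > 1 and IC025 > 0. No multiple-testing correction is applied
(none is conventional for this screening design); the scan table
carries all cells and bounds so FDR procedures can be applied
downstream. Within a drug, scan rows sort by IC025 descending with
ties broken by (n descending, term ascending) for deterministic output.
The comparator for every scan is all other reports within the
indication-restricted background, not all of FAERS — consistent with
restricting the question to "disproportionate within this disease
population".

## Time to onset and descriptive statistics

Time to onset is days(EVENT_DT − START_DT) + 0.5, using the earliest
full-precision start date among the report's drug rows matching the
study drug (therapy rows link to drug rows via the drug sequence
number). Both dates must have day precision — partial dates are not
midpoint-imputed — and negative intervals are treated as data errors
and excluded with a log line rather than clamped. Onset distributions
are summarized by median and IQR after trimming to the middle 90%
(values within [P5, P95]). One quantile convention — linear
interpolation — is used everywhere in the package.

Characteristics tables count cases per drug for sex, age bands (<18,
18–44, 45–64, 65–74, >74), reporting countries (top 3), reporter
occupation, report year and outcome codes, with missing always counted
as its own row and percentages over total cases. Two-sided exact
binomial tests (p0 = 0.5, missing excluded) compare female vs male,
age ≥ pooled median vs below, and US vs non-US.

## Sensitivity models

The pooled dataset takes every case exposed to exactly one of the three
study drugs (cases matching several study-drug dictionaries are excluded
and counted); covariates come from the case's retained deduplicated
report. Cases missing sex, age or country are excluded and counted.
Age is dichotomized at the pooled median age, computed over pooled
cases with a known age; country is US vs non-US; reference levels are
male, below-median age, non-US.

For a drug and a SOC outcome, Model 1 regresses the outcome indicator
on exposure alone (its exp(coefficient) is algebraically the collapsed
2×2 odds ratio); Model 2 adds sex and age group; Models 3–5 fit
exposure + factor + exposure×factor, reporting the interaction odds
ratio — in the saturated model exactly the ratio of stratum-specific
odds ratios.

The fitter is Newton/IRLS written for this package because its contract
is part of the design: the deviance path is recorded and must be
monotone non-increasing (enforced by step-halving), convergence is
declared when the largest coefficient change falls below 1e-10 (tight
enough that the Model-1 identity holds to ~1e-10 relative), constant
covariates are dropped as intercept-aliased with a warning, and
coefficients diverging past |β| > 15 are flagged as (quasi-)separation
rather than silently penalized. No regularization is applied by
default. Wald intervals are used throughout, matching conventional
adjusted-ROR reporting; statsmodels GLM serves as an independent
cross-check in the test suite, not as the implementation.

## The synthetic reporting system

The generator emulates the statistical structure the pipeline assumes,
with known truth for every stage:

* Each case takes one suspect drug (PS role with probability 0.9, else
  SS) drawn from a 10-drug universe — the three study drugs plus seven
  background biologics/antirheumatics typical of this disease area —
  with mixture weights defaulting to a realistic market split; 0–3
  concomitant drugs with role C are noise that exposure flagging must
  ignore. Brand vs generic naming and PROD_AI presence are randomized
  to exercise dictionary matching.
* Given the suspect drug g, each of 20 vocabulary PTs occurs
  independently with probability baseline·θ(g, PT), capped at 1 (a
  configuration whose product exceeds 1 is rejected). The default
  baseline is 0.02 per PT, plus a common "Drug ineffective" filler
  (baseline 0.25) that also guarantees every report has ≥1 reaction.
  θ = 1 everywhere is the null; the toy PT→SOC/SMQ ontology shipped
  with the generator (synthetic, not MedDRA content) supports rollup.
  PT co-occurrence is *not* modeled — events are conditionally
  independent — which suffices for the statistics under test but does
  not emulate syndromic reporting.
* Demographics: sex (65% female), age ~ Normal(56, 14) clipped to
  12–95 (median ≈ 57 years), country mix (78% US), reporter occupation
  mix, outcome codes — each with configurable missing-completely-at-
  random rates (informative missingness is out of scope). A small
  fraction of ages is expressed in months to exercise unit conversion.
* Dates: the event date is uniform over the Q4-2014..Q3-2024 window,
  therapy start = event − onset with onset ~ round(LogNormal(median 60
  d, σ = 1)), receipt = event + reporting delay. 10% of event/start
  dates degrade to month precision and 5% of event dates go missing,
  so time-to-onset code sees realistic gaps.
* Indications: 80% of cases carry the cohort indications (43% psoriasis
  / 52% PsA / 5% both, matching the reported indication split of this
  population), the rest carry off-cohort indications so the restriction
  stage does real work; indication strings are randomly upper-cased to
  exercise case-insensitive matching.
* Duplicates: 10% of cases gain 1–3 extra versions sharing the CASEID
  with strictly larger PRIMARYIDs and later-or-equal FDA_DT (equal with
  probability ≈0.3 to exercise the PRIMARYID tie-break); version
  perturbations touch only the reporter field. The ledger records the
  version the FDA rule retains, derived from the rule's definition at
  generation time.

The ledger stores every case's kept-version attributes and the realized
case × PT event matrix, so expected cell counts, stage counts and
demographic mixes are exact, not approximate. `expected_ror` gives the
analytic odds ratio implied by θ and the exposure mix ((pe/(1−pe)) /
(pu/(1−pu)) with pu the weight-averaged comparator rate); for rare
events it approaches θ.

## Validation studies and problem sizes

`faerspv.studies` (used by the analysis drivers, the test suite and
`scripts/acceptance.py`) runs:

* statistic oracle — 1,000 random tables, cells 0–500: ROR against a
  direct evaluation (agreement to 1e-12), approximate vs gamma IC
  bounds (≤0.05 bits for a ≥ 3);
* counting oracle — a 2,000-report corpus through file serialization,
  re-parsing and the full cohort pipeline, with every PT/SOC/SMQ cell
  recounted by an independent plain-dict reimplementation from the raw
  files: zero mismatches required;
* dedup — injected duplicates (rate 0.1, up to 4 versions/case) on a
  2,000-case corpus: uniqueness, exact rule agreement, idempotence;
* signal calibration — a 50,000-case null corpus scanned over 200
  drug–PT pairs (false-positive rate of the joint rule; empirically
  ≈0.5–1%, far below the 5% each bound contributes, because the
  shrunk IC bound is conservative at these counts), and ten implanted
  θ = 4 associations at baseline 0.02 (sensitivity; empirically 100%
  at these counts);
* ROR coverage — 200 replicates per θ ∈ {2, 4, 8} at 50,000 cases,
  each replicate an independent random substream drawing exposure and
  the target PT from the generator's model and feeding the same
  table/CI code as the scan; coverage is assessed over all 600
  replicates (per-arm values are also reported). At 200 replicates an
  arm's Monte-Carlo SD is ≈1.6 percentage points, so the pooled figure
  is the stable summary;
* regression — exact Model-1 and saturated-interaction identities on
  random tables, and 500 simulations of sex→exposure, sex→outcome
  confounding (n = 3,000/replicate, true conditional OR 1.5) checking
  that the Model-2 interval covers the truth at its nominal rate;
* time to onset — the formula's fixed-point cases, middle-90% trim
  retention on 10,000 continuous samples, and recovery of the
  configured onset median through the full pipeline at 20,000 cases
  (≈5,000 usable onsets; sampling error of the median ≈1 day).

Problem sizes were chosen so each study's Monte-Carlo error is small
relative to what it checks while the whole battery runs in well under a
minute.

What passing does **not** show about real FAERS data: the generator's
independence assumptions (no PT co-occurrence, no drug co-prescription
structure, MCAR missingness, no masking/competition between signals, no
reporting-rate drift over calendar time) are simplifications, so these
studies validate the *computation* — counting, deduplication, statistics
and their calibration under the stated model — not the epidemiological
robustness of disproportionality analysis itself, which remains
hypothesis-generating and is not an incidence or causal estimate.

## Numerical and degenerate-input conventions

* Quantiles: linear interpolation, everywhere.
* Zero cells: Haldane–Anscombe +0.5 for ROR; the IC needs no extra
  handling (the +½ shrinkage offsets cover a = 0).
* Degenerate margins: NaN estimates marked unevaluated, never raised.
* Empty cohort after restriction: warning, empty outputs.
* Unparseable dates/ages/codes: missing with a logged warning; lines
  with the wrong field count: skipped and counted, not fatal.
* Ranking ties: (IC025 desc, n desc, term asc) within drug.
* Logistic fits: zero start, monotone deviance via step-halving,
  |β| > 15 flags separation, constant columns dropped, Wald z = 1.96.

## Known limitations

* Person-time is unavailable in spontaneous reports; no annualized
  reporting-rate denominators are computed — only report counts.
* LLT→PT coding, HLT/HLGT levels and weighted/algorithmic SMQs are out
  of scope; the hierarchy is PT → primary SOC plus flat SMQ sets with
  an optional narrow/broad scope column (default: both).
* The CLI and pipeline expect one extract per directory; multi-quarter
  studies pass several directories.
* EBGM/MGPS, PRR and Bayesian neural-network formulations are not
  implemented; the scan table is designed so such statistics could be
  added downstream from the same cells.
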