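# Methods

## Scope and data model

`faersig` screens one index drug against the full background of a
FAERS-style spontaneous-report corpus. The unit of analysis after
deduplication is the case (one surviving report version per `CASEID`);
the unit of counting for disproportionality is the unique (report, PT)
pair. Pair counting means a cohort of ~1,000 reports typically carries
several thousand adverse events, SOC-level counts are plain sums of
member-PT pair counts, and SOC "proportions" are shares of total events,
not of reports. Repeated identical PTs inside one report are collapsed
before counting.

Deduplication keeps, within a `CASEID`, the report maximizing
`(FDA_DT, PRIMARYID)` lexicographically — the FDA-recommended rule. It is
idempotent and order-stable (output ascending by caseid).

## Disproportionality statistics

For a cell (a, b, c, d) with `N = a+b+c+d` and expectation
`E = (a+b)(a+c)/N`:

**ROR** `= ad/(bc)` with the Woolf CI
`exp(ln ROR ± 1.96 √(1/a+1/b+1/c+1/d))`. **PRR**
`= [a/(a+b)]/[c/(c+d)]` with CI
`exp(ln PRR ± 1.96 √(1/a − 1/(a+b) + 1/c − 1/(c+d)))`. Tables containing
a zero receive the Haldane–Anscombe +0.5 on all four cells for the two
ratios only; with the correction disabled a zero cell yields a NaN
marker rather than an exception. The chi-square is computed on the raw
counts with the Yates continuity correction
`N(|ad−bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)]`, clamped at zero; the
classical "PRR ≥ 2 and χ² > 4" criterion was defined with Yates, and the
uncorrected variant is available behind a flag.

**BCPNN information component.** The original Bayesian model places Beta
posteriors on the joint reporting proportion and the two margins, with
the joint prior count tied to the margins so the prior IC is centred at
zero (`γ = γ11 (N+α)(N+β) / ((a+b+α1)(a+c+β1))`, defaults
`α1 = β1 = γ11 = 1`, `α = β = 2`). We return the *exact* posterior
moments of `IC = log2(p_xy/(p_x p_y))` via digamma/trigamma functions —
for a Beta(r, s) marginal, `E[ln p] = ψ(r) − ψ(r+s)` and
`Var[ln p] = ψ′(r) − ψ′(r+s)` — and `IC025 = E[IC] − 2√Var[IC]`. The
historical first-order closed form (logs of the ratio of expectations)
is available via `approx=True`; it deviates from the exact mean by
~`1/(2a ln 2)`, which matters at small a. The exact moments are what
Monte-Carlo sampling of the same posterior reproduces, which is how the
implementation is validated. The **Norén variant** is
`IC = log2((a+½)/(E+½))` with
`IC025 = IC − 3.3(a+½)^{−1/2} − 2(a+½)^{−3/2}`. Both variants are always
computed; the combined criterion uses one of them (default: the Bate
form, matching the `E − 2SD` style of published PT tables).

**MGPS.** The relative reporting rate λ of each cell carries the
two-component gamma mixture prior
`λ ~ p·Gamma(α₁, β₁) + (1−p)·Gamma(α₂, β₂)` (shape/rate) with
`a | λ ~ Poisson(λE)`. The marginal is a mixture of negative binomials;
hyperparameters are fitted by maximizing the summed log marginal over
*all* drug–event cells of the corpus (cells with `a ≥ 1`; no
stratification — stratification metadata is not part of this design)
with L-BFGS-B in (log, log, log, log, logit) space, box-bounded to
`[e^{-10}, e^{10}]`, from the classical initialization
(0.2, 0.1, 2, 4, 1/3). The hyperparameters are weakly identified — on a
pure-noise corpus the two components trade off along a likelihood ridge
— but the *induced* prior (marginal likelihood per cell, shrinkage
scores, prior mean) is stable, and that is what tests assert. The
posterior is the mixture
`Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E)` with Q from the
component marginals; `EBGM = exp(E[ln λ])` via digamma, and `EBGM05`
solves the mixture CDF at 0.05 by bracketed root-finding.

**Combined criterion.** A PT is a signal when all of: `a ≥ 3` (the
conventional minimum-case rule), ROR 95% CI lower bound > 1, PRR ≥ 2
with χ² > 4, IC025 > 0, EBGM05 > 2. No multiple-testing control is
applied — the four-criteria conjunction *is* the screen, as is standard
in this literature; the per-method criteria trace is emitted for every
cell so the decision is auditable.

A useful consistency check implemented as a test: for large cells the
shrunken log2 observed-to-expected and log2 EBGM coincide. Note the
shrinkage estimators are monotone in `a` only while the margins dominate
the cell; when one cell makes up most of its own margins, `E` grows
roughly quadratically in `a` and the shrunken scores legitimately fall.

## Time to onset

Onset is the whole-day difference between the adverse-event date (DEMO)
and the earliest complete therapy start date for the index drug (THER,
linked through the drug sequence number). Partial dates (`YYYY`,
`YYYYMM`) and negative intervals are excluded and tallied — attrition
counts always close. Day-0 onsets are imputed to 0.5 day (configurable)
so the positive-support Weibull likelihood is defined.

The Weibull fit maximizes the likelihood (scipy's MLE with the location
fixed at zero); 95% CIs are Wald intervals on the *log*-parameter scale
from the observed information (central finite differences), which
guarantees positive bounds; profile-likelihood intervals are available
as an option and agree with Wald to a few percent at realistic n. The
empirical median and IQR are reported from the data, not the fitted law
— for a heavily right-skewed reporting distribution the two differ
substantially (for scale 187.21 d and shape 0.73 the *fitted* median is
`α(ln 2)^{1/β} ≈ 113.3 d`). Failure typing uses the shape CI: upper
bound < 1 → early failure (decreasing reporting hazard), CI spanning 1 →
random, lower bound > 1 → wear-out.

The binned onset distribution uses the conventional edges 0–30, 31–60,
61–90, 91–180, 181–360, >360 days (only the first and last two bins are
canonical in the literature; the intermediate edges are a configurable
convention). The cumulative curve is the right-continuous ECDF of
reported onsets — spontaneous reports carry no at-risk denominators, so
no survival estimator is appropriate.

The sex comparison is a Wilcoxon rank-sum test on the full onset
distributions with midranks: exact enumeration of all
`C(n₁+n₂, n₁)` assignments when both groups have ≤ 10 records (with
every pooled value tied this correctly returns p = 1), otherwise the
tie-corrected normal approximation without continuity correction.

## Descriptives

Percentages use the deduplicated report count as denominator and
half-up 2-decimal rounding (`Decimal`, not banker's rounding). Missing
categories always appear as "Not specified" rows; in this kind of data
>80% unknown sex/age is itself a finding. Outcome rows count
report–outcome pairs and need not sum to 100% (a report may carry
several outcomes or none). Age quartiles use linear interpolation;
age groups are <18, 18–44, 45–64, ≥65. Country tables are truncated to
the top N (default 5) as is conventional.

## Synthetic corpus

The generator emulates the *structure* of a post-marketing cohort for a
recently approved specialty drug, with defaults fixed once as the study
conditions:

- 10% of reports name the index drug as primary suspect; ~1% of
  background reports carry it as a concomitant (exercising the role
  filter).
- Sex missing 82.84%, age missing 85.44%; among known sexes ~73.5%
  female; ages ~N(49.66, 16.23²) clipped to 16–87.
- Report years 2020–2024 with weights rising to ~39% in the final year;
  consumer/pharmacist/physician reporters 78.29/7.24/14.47%; US-heavy
  geography; outcome codes drawn independently per report at
  LT 1.4% / HO 29.6% / DS 0.3% / DE 9.9% / OT 32.2%, with "serious"
  defined as carrying any outcome row.
- Event terms: 50 synthetic PTs with power-law marginal rates summing to
  3.5 expected events per report (matching ~3.5 events/case in published
  cohorts of this type); every PT occurs independently of drug at its
  marginal rate, except planted terms, which index cases report at
  `min(λ·p, 0.95)`. With a single planted term, pair-counting makes the
  population ROR equal λ exactly; with several, each is attenuated by a
  few percent through the inflated index margin.
- Onsets: Weibull per observed-sex stratum, defaults scale 187.21 d
  (female/unknown) and 82.5 d (male), shape 0.73 — the male/female scale
  ratio mirrors the roughly twofold onset-median gap reported for such
  cohorts. The ledger stores both the continuous draw (for
  distributional checks) and the integer day-arithmetic onset with the
  0→0.5 imputation (what linkage must recover).
- Data defects: 45% missing event dates, 10% partial therapy start
  dates, 1% negative intervals; 15% of cases emitted in 2–3 versions
  with increasing `FDA_DT`/`PRIMARYID` (30% of duplicate groups share
  `FDA_DT` so only the `PRIMARYID` tie-break is observable).

What the generator does **not** emulate: MedDRA hierarchy beyond a flat
PT→SOC map, correlated event co-occurrence, country-specific reporting
propensities, drug–drug interactions, secular trends within a year, or
the empirical-vs-fitted median discrepancy of real cohorts (real
reporting data are not exactly Weibull; the generator's are). Passing
tests therefore demonstrate correctness of the machinery under the
declared generative model, not calibration to any real cohort — the
headline statistics of a real analysis depend on the full background
database and cannot be reproduced from synthetic data.

## Numerical choices and problem sizes

- MGPS optimizer: L-BFGS-B, bounded transforms; `converged` reflects the
  optimizer status and non-convergence returns the best point with a
  flag rather than raising.
- EBGM05 root-finding brackets the mixture CDF between extreme gamma
  quantiles of both components; tolerances 1e-12.
- Weibull information matrix: central differences with step 1e-5 on the
  log scale.
- Rank-sum exact/approximate switch at group size 10
  (`C(20,10) ≈ 1.8×10⁵` enumerations at most).
- Tie-breaks in ranked tables: frequency desc, then ROR desc, then label
  asc (ROR first for intensity ranking) — rankings are byte-stable
  across reruns.
- Validation sizes chosen to keep the full suite fast while leaving
  comfortable statistical margins: estimator oracles on 12-cell grids
  with 10⁶ Monte-Carlo draws; Weibull recovery with 200 refits at
  n = 397; signal operating characteristics over 20 corpora of 20,000
  reports (planted terms reach several hundred index cases each, well
  above the ≥50 regime the recovery claim is stated for).

## Known limitations

- No fuzzy drug-name normalization: suspect selection is
  case-insensitive substring matching over name fields plus the PS role
  code.
- The comparator is all other reports in the ingested corpus; no
  restriction windows, no stratified expectations.
- No censoring model for onset times; reports without a complete date
  pair simply leave the analysis (tallied).
- Wald CIs rely on asymptotic normality of the log-parameters; at n in
  the low hundreds coverage runs ~95–97%, slightly conservative for the
  shape.
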