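# Methods

This note records the statistical model behind `cuvigil`, the conventions
and numerical choices the implementation fixes, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Case model and ingestion

The unit of analysis is the individual case safety report (ICSR): one
patient, one or more reaction preferred terms (PTs, plain uppercase strings
— no MedDRA hierarchy is consulted), one or more drug entries each carrying
a role code (primary suspect / secondary suspect / concomitant /
interacting) and its own indication PTs, demographics, a receipt year, and
regulatory outcome codes.

FAERS quarterly `$`-delimited tables are one reader dialect; the canonical
store is JSON-lines with one report object per line, chosen so fixtures stay
hand-writable. Reader error semantics are strict where corruption would be
silent (duplicate column headers abort) and lenient where it is localized
(lines with the wrong field count are skipped and counted; DRUG/REAC/INDI/
OUTC rows keyed to a case absent from DEMO are counted as orphans).

Conventions fixed here and used throughout:

- **Deduplication.** One report per `case_id`: highest version wins, ties
  broken by latest receipt year, then last input position. FAERS practice
  varies across eras; the rule is fixed so audits are comparable.
- **Age units.** DEC×10, YR×1, MON÷12, WK÷52.1775, DY÷365.25, HR÷8766
  (Julian-year conventions, stated so tests are bit-stable). Results above
  130 years become missing with a warning; unknown units are missing, never
  an exception.
- **Seriousness.** Derived as "any outcome other than *other*/*non-serious*
  present", unless an explicit flag is supplied, which wins.
- **Report year.** The receipt (FDA) date defines the year; the event date
  is the fallback. Which date field a published trend used is generally
  ambiguous, so this is a documented default, not a claim.
- **Continents.** ISO-3166 alpha-2 mapped by UN M49 region, with North and
  South America collapsed into a single *Americas* group.

## Filtration funnel

Four stages, in fixed order, each audited per drug (entered / kept /
dropped): (1) a drug entry maps to a canonical chelator through a
case- and punctuation-insensitive synonym table; (2) at least one mapped
entry carries an indication; (3) the mapped entries' indications are not all
explicitly excluded (rheumatoid arthritis, cystinuria, lead poisoning by
default); (4) a mapped entry carries the target indication
(HEPATO-LENTICULAR DEGENERATION) with the primary-suspect role.

Two deliberate choices: indications are evaluated **per drug entry**, so a
co-medication's indication can never qualify the chelator's report; and
unrecognized indications that are neither target nor excluded fall through
to stage 4 (they lack the target term) rather than being treated as
exclusions — stage 3 is reserved for the explicit exclusion list so the
audit separates "known other use" from "not the confirmed indication".
A report naming both chelators as qualifying primary suspects enters both
cohorts by default (configurable), counted once per drug.

## Contingency tables and comparator

Counting unit is the report: a = cohort reports containing the event term,
b = the rest of the cohort, c/d analogously on the comparator;
E = (a+b)(a+c)/N is the expected count under independence and is the shared
baseline for both Bayesian statistics.

The default comparator is **all reports not naming the drug**. This is the
classical disproportionality background, and it matters: the funnel removes
drug reports with other or missing indications, and leaving those
drug-exposed reports inside the comparator contaminates the event margin
with the drug's own reporting profile, biasing every statistic toward the
null. A "supplied set minus the cohort" comparator remains available, and
every rendered table names the comparator it used, because signal values
are meaningless without it.

## The four statistics

- **ROR** ad/bc and **PRR** [a/(a+b)]/[c/(c+d)], both with Wald log-scale
  95% intervals. Tables containing a zero cell get the Haldane–Anscombe
  +0.5 on all four cells for these two ratios only, and the row is marked.
- **Chi-square.** Yates-corrected by default (used for the drug ×
  seriousness association); the uncorrected Pearson statistic is used inside
  the classical PRR signal rule (PRR ≥ 2, χ² ≥ 4, a ≥ 3).
- **IC (BCPNN-style).** IC = log₂((a+0.5)/(E+0.5)); the posterior of the
  relative reporting rate is Gamma(a+0.5, E+0.5) and IC025 is the log₂ of
  its 2.5% quantile, computed exactly. The familiar closed form
  IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) is available as a flag and agrees
  with the exact bound within 0.15 bits for a ≥ 3 over E ∈ [0.1, 10³] (this
  is asserted by the test suite). The original two-Beta/Dirichlet BCPNN
  parameterization is intentionally out of scope; the observed/expected form
  keeps IC and EBGM on one definition of E.
- **Gamma-Poisson shrinker.** Prior on λ: P·Gamma(α₁, β₁) +
  (1−P)·Gamma(α₂, β₂). The marginal of a is the matching two-component
  negative-binomial mixture; the five hyperparameters are fitted by
  maximizing the summed marginal log-likelihood over all drug–event tables
  (L-BFGS-B on log/logit-transformed parameters, five restarts: the
  classical start (0.2, 0.1, 2.0, 4.0, 1/3) plus four dispersed seeded
  points; best log-likelihood wins, ties to the earliest restart; a fit is
  refused below 50 usable tables). The posterior is again a two-component
  gamma mixture with components (αᵢ+a, βᵢ+E); EBGM = 2^{E[log₂ λ|a]} via
  E[ln λ] = ψ(shape) − ln(rate) per component, and EB05/EB95 solve the
  mixture CDF by bracketed root-finding (relative tolerance 10⁻¹⁰, bracket
  = the two component quantiles, padded against weight collapse).
- **Flags.** ROR+ iff CI low > 1 and a ≥ 3; PRR+ as above; IC+ iff
  IC025 > 0; EBGM+ iff EB05 ≥ 2. All thresholds configurable. No
  multiple-testing adjustment is applied — flagging is threshold-based by
  design, and the rendered tables say so.

### Numerical cross-checks

The closed-form posterior quantities are validated against independent
numerics: EBGM/EB05/EB95 against direct trapezoid integration of
prior × Poisson likelihood in t = ln λ (the substitution matters: the
small-shape component's λ^(α−1) singularity carries non-negligible E[ln λ]
mass at arbitrarily small λ, and the lower truncation must leave only
O(e^(α·t_min)) residual), and IC025 against a 10⁶-draw Monte-Carlo quantile.

### A known sensitivity of hyperparameter recovery

Recovery of the fitted prior is judged by posterior mean log-λ agreement on
a held-out (a, E) grid with a ≥ 1. Cells with a = 0 are excluded
deliberately: there E[ln λ | a=0] ≈ ψ(α̂)−ln(β̂+E) for the dominant
small-shape component, and ψ′(0.2) ≈ 26 amplifies the sampling error of α̂
(±0.01–0.02 at 10⁴ tables, even at the verified global optimum) into
0.1–0.6 nats — an intrinsic property of the estimand, not an optimizer
failure. EBGM-based decisions are unaffected in practice because a = 0
cells can never be flagged.

## Trend and outcome models

Yearly counts per drug (gaps zero-filled, missing-year reports counted and
excluded) enter a log-link Poisson regression with calendar year centered at
the span midpoint; IRR per year = exp(slope). With two drugs the model adds
a drug indicator and Year×Drug interaction; the second drug's IRR uses the
delta method on the summed coefficients. The exploratory logistic models
(seriousness, hospitalization) use sex (reference female) and age in years,
dropping and counting reports with missing values listwise.

Both GLMs use an in-module IRLS solver (convergence when the max absolute
coefficient change < 10⁻¹⁰, cap 100 iterations) so that data lying exactly
on the model surface are reproduced to full precision — the doubling series
(3, 6, 12, 24, 48) yields IRR exactly 2 — and quasi-complete separation in
the logistic model is reported as an error once coefficients pass 15 on the
logit scale. Wald intervals are used throughout; the test suite cross-checks
coefficients and standard errors against statsmodels GLM.

## Synthetic generator

`SyntheticTruth` fixes everything: reports per drug, a background
pseudo-drug for the comparator, baseline Bernoulli rates per event PT,
planted relative reporting rates λ per (drug, event) multiplying the
baseline (clipped at 1 with a warning), per-drug seriousness probabilities,
demographic/indication/reporter mixes, a per-year IRR shaping the yearly
intensity, and a duplicate-version injection fraction. The default scenario
mirrors the shape of a real two-chelator extract — ~250 and ~400 reports,
1990–2025 span, adult-dominant ages, seriousness 0.95 vs 0.55, yearly IRRs
1.035 and 1.119 — purely as a smoke-test fixture, with no claim of matching
any real extract.

Simplifications to keep in mind when interpreting passing tests: events are
sampled independently per report (no reaction co-occurrence), indications
are single-valued per report, duplicates differ only in version and one
mutated field, and aggregated (VigiAccess-style) semantics are nothing more
than sums of the generated case-level counts. Reports whose event draw comes
up empty receive a filler PT outside the analysis vocabulary so that
vocabulary marginals stay exactly baseline × λ. Null calibration and power
are therefore statements about this idealized reporting process; real
spontaneous-report data add duplication across case ids, reporting waves,
and term-preference drift that the generator does not model.

## Validation study sizes

The packaged experiments (shared by the test suite and
`scripts/acceptance.py`) use: a 784-point (a, E) grid for the IC bound
agreement; 200 random small tables (a ≤ 20, E ≤ 10) for the EBGM oracle;
10,000 simulated pairs for hyperparameter recovery; 20 seeds × 2000 reports
per drug for null calibration (flag rate of IC025 > 0 with all λ = 1) and
for power (one pair planted at λ = 10 on a 0.01 baseline, detection by all
four criteria); and 200 replicates of two 30-year series for trend-CI
coverage. These sizes give the binomial/Monte-Carlo error of each summary a
comfortable margin relative to its acceptance band while keeping a full run
around one minute. The power experiment evaluates EBGM under the classical
prior rather than a per-run fit, since a single run's 48 tables are below
the 50-table fitting guard.

## Limitations

- Disproportionality quantifies reporting, not risk: no exposure
  denominator, no causal or comparative interpretation.
- No stratified expected counts (age/sex/year) in the shrinker; no
  regression-adjusted or duplicate-robust variants.
- Published per-drug signal tables from any specific FAERS snapshot are not
  numerically reproducible without that snapshot and its comparator counts;
  validation is therefore property-based (oracles, calibration, recovery)
  rather than table-matching.
- Probabilistic record linkage across different case ids, legacy fixed-width
  LAERS files and E2B XML are out of scope.
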