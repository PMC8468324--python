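# Methods

This note documents the models implemented in `bodywage`, the synthetic
data-generating process used to validate them, and the numerical and design
choices that were genuinely open.

## 1. The analysis

The package studies how body shape relates to income in a CGSS-style
(Chinese General Social Survey) civilian, non-agricultural labor-market
sample, separately by gender. Body shape is measured by BMI
(weight/height², kg/m²) and by gender-specific quantile classes:
respondents below their gender's 30% BMI quantile are *underweight*, above
the 70% quantile *overweight*, and in between *normal* (a 20/80 variant is
available as a robustness toggle; ties at a cutpoint classify as normal,
i.e. the normal band is the closed interval between the cutpoints).

### Cohort rules

Applied in order, with an exclusion log: age restricted to 18–60; missing
BMI dropped and BMI restricted to [10, 40]; income above CNY 1,000,000
top-coded to 1,000,000 (records kept); soldiers (ISCO-08 major group 0)
and agricultural workers (group 6) excluded. Non-positive incomes are
dropped before taking logs (logged as their own rule) since ln(income) is
the dependent variable. Filtering is idempotent.

### Wage equations

The baseline model is

    ln(income) = α + β₁·BMI + β₂·Demographics + β₃·Socioeconomic
               + β₄·Regional + β₅·Fixed + ε

with demographics (hukou migration status, ethnicity, marital status,
log age, number of children, education as indicator block),
socioeconomic status (party, union, medical insurance, self-assessed
social status), eight logged province-level regional covariates, and
area (east/central/west) and survey-year fixed effects. All linear fits
report heteroskedasticity-robust HC1 standard errors; factor blocks use
the lowest sorted level as reference; rank-deficient columns are dropped
via pivoted QR and always reported, never silently.

Variants:

* **Centered interaction.** β₁(BMI−B̄MI) + β₂(ISEI−ĪSEI) +
  β₃(BMI−B̄MI)(ISEI−ĪSEI); means are computed on the estimation sample
  after all filtering, so the centered columns have exactly mean zero and
  β₁, β₃ are invariant to location shifts of either variable. The
  occupational gradient of the BMI effect is β₁ + β₃·ΔISEI.
* **Heckman two-step.** Probit of employment on the full sample (the
  default synthetic design excludes `children` from the outcome
  equation as the exclusion restriction), then OLS on selected rows with
  the inverse Mills ratio appended. Standard errors are HC1 without the
  Murphy–Topel correction — adequate for the bias-comparison use here,
  understated in general. If no exclusion restriction is supplied the fit
  proceeds but is flagged (identification off functional form only).
  When every row is selected the Mills ratio is set to its limit (zero)
  and the second step reduces to OLS.
* **2SLS.** BMI instrumented by its (gender × province × occupation)
  cell mean, own observation included by default (a leave-one-out option
  exists). Implemented by projection: the endogenous column is regressed
  on [exogenous, instrument], second-stage coefficients use the projected
  column, and the HC1 sandwich uses structural residuals. A robust
  first-stage F (squared t of the excluded instrument) is reported. The
  implementation is cross-checked in the tests against statsmodels'
  sandbox IV2SLS on identical matrices.
* **Quantile regression.** statsmodels `QuantReg` (IRLS) per τ; the
  contract is check-loss optimality, verified against brute-force line
  search on small instances.
* **Ordered logit.** Proportional-odds ML (`OrderedModel`, logit link);
  thresholds returned strictly increasing; McFadden pseudo-R² against the
  closed-form thresholds-only null; |coefficient| > 20 flagged as
  possible separation.
* **Occupation-stratified fits.** Overweight/underweight indicators
  (normal = reference) within three strata: managers/professionals/
  technicians {1,2,3}, clerks/services–sales {4,5}, and craft/operators/
  elementary {7,8,9}. The middle/upper grouping of clerks is ambiguous in
  the source material; the grouping is configurable and this default is
  fixed for reproducibility.

### Income-gap decomposition

For reference group N (normal) and comparison group O within one gender,
with occupations j = 1…8:

    ĪN − ĪO = Σⱼ [ PⱼO·X̄ⱼO(β̂ⱼN − β̂ⱼO)     (1) coefficient gap
               + PⱼO·(X̄ⱼN − X̄ⱼO)β̂ⱼN       (2) endowment gap
               + (PⱼN − P̂ⱼO)·ĪⱼN           (4) structure due to covariates
               + (P̂ⱼO − PⱼO)·ĪⱼN ]         (5) structure due to attainment

where P̂ⱼO is the counterfactual structure: a multinomial logit of
occupation on covariates is fitted on the reference group and its
predicted probabilities are averaged over the comparison group's rows.
Parts (4) + (5) equal the between-occupation part (PⱼN − PⱼO)·ĪⱼN exactly,
and the whole table is exactly additive whenever each cell satisfies the
OLS-with-intercept identity ĪⱼG = X̄ⱼG·β̂ⱼG — this algebra is tested on
random instances to 1e-8 and on a pencil-and-paper fixture to 1e-12.

Numerical choices:

* Within-cell covariates are the wage-equation controls minus fixed
  effects constant within a cell; the default set is (bmi, isei, edu,
  married).
* Cells below 30 rows (or below the parameter count) fall back to the
  group's pooled coefficients with the intercept re-centered on the cell
  so the OLS identity — and hence exact additivity — is preserved; the
  cell is flagged in the output.
* The multinomial-logit base category is the last occupation group
  (elementary); irrelevant to results since only averaged probabilities
  are used.
* Percentage shares divide unrounded part totals by the decomposed total
  (not the raw gap); rounding happens only in `decomposition_report`
  (3 decimals for parts, 2 for percentages).
* The package also ships the published per-occupation part values of the
  reference CGSS analysis as a data constant; feeding them through the
  same aggregation arithmetic reproduces the printed row totals exactly
  and the printed column totals within the accumulated rounding of
  3-decimal inputs (8 × 0.0005 = 0.004).

## 2. The synthetic generator

Real CGSS microdata are access-restricted, so every estimator is
validated on a generator with known ground truth. What it emulates:

* two genders with distinct anthropometry — height normal, weight
  log-normal, calibrated to the published descriptive means (women
  1.60 m / 55.34 kg, men 1.71 m / 66.16 kg, hence mean BMI ≈ 21.6 / 22.6);
  weight dispersion is chosen so BMI falls inside the (10, 40) trim
  window for ≥ 99% of draws;
* eight ISCO-08 occupation groups with the published per-gender shares.
  Attainment is a multinomial logit on (education, BMI) whose intercepts
  are calibrated by iterative proportional fitting **on the realized
  covariate draw**, so marginal shares match the configured targets to
  Monte-Carlo precision while attainment still depends on body shape —
  this is what gives decomposition Parts (4)/(5) a nonzero truth;
* ISEI drawn around occupation-specific means (managers ≈ 58,
  professionals ≈ 65, … elementary ≈ 22, sd 6, clipped to [16, 90]);
* log income from a per-gender, per-occupation linear equation. The
  default truth carries the published signs and magnitudes: BMI
  coefficient −0.010 for women, +0.017 for men; centered BMI×ISEI
  interaction −0.00046 / −0.00019; positive health loading; neighborhood
  socialization negative for women, friend socialization positive for
  men. Occupation intercepts rise with occupational rank; residual sd
  0.70 gives fit statistics in the published range;
* provinces (default 30, split into three regions) carrying fixed logged
  macro covariates and small log-weight offsets (sd 0.04). The
  province-level BMI variation is deliberate: it is what gives the
  cell-mean instrument a real first stage;
* optional probit selection into employment whose index includes BMI
  (without this, selection would not bias the BMI coefficient and the
  Heckman comparison would be vacuous) and `children` as the excluded
  variable, with error correlation ρ;
* optional endogeneity: a latent individual confounder added to weight
  (so BMI = weight/height² stays exact) and to log income. It averages
  out within large instrument cells, so the cell-mean instrument stays
  valid up to an own-observation leakage of order 1/cell-size;
* ordinal health and socialization items from proportional-odds latent
  models with configurable thresholds.

Named configurations freeze the study conditions for each experiment:
`default_paperlike_config` (the defaults above), `recovery_demo_config`
(all side channels of the BMI effect off, so the OLS estimand equals the
configured coefficient), `endogeneity_demo_config` (confounder on,
attainment independent of BMI, 10 provinces), `selection_demo_config`
(ρ configurable, default 0.6), and `decomposition_demo_config` (wage
truth spanned by the decomposition covariates, with nonzero
overweight/underweight wage shifts: women −0.06/−0.01, men +0.03/−0.10).

An **analytic oracle** (`oracle_decomposition`) computes the decomposition
from the true coefficients and the true attainment model on a large
simulated covariate draw — no estimation anywhere — and is the target for
the end-to-end recovery test.

What the generator does **not** emulate, hence what passing tests do not
show about real data: the CGSS multi-stage sampling design and weights;
measurement error in self-reported height/weight; age/cohort profiles of
income; within-province heterogeneity of the macro covariates; any real
correlation structure between education, marriage, children and BMI
beyond the modeled channels. Parameter-recovery results validate the
estimators, not the substantive magnitudes on CGSS data.

## 3. Problem sizes and tolerances

Simulation sizes were chosen to keep each experiment's Monte-Carlo error
well below the effect being measured: sign-pattern checks at ~20,000
records per gender; bias comparisons (OLS vs 2SLS, OLS vs Heckman) at 200
replicates of n = 5,000; CI-coverage and mean-recovery at 500 replicates
of n = 5,000; decomposition recovery averaged over 10 replicates of
n = 60,000 against an oracle at n = 400,000, compared at 4 Monte-Carlo
standard errors. Exact identities are asserted at 1e-8 (additivity),
1e-9 (share normalization), and 1e-12 (fixed arithmetic fixtures).

## 4. Known limitations

* The 2SLS cell-mean instrument with the own observation included
  carries a small-sample bias toward OLS of roughly the within-cell noise
  share divided by cell size (visible but dominated in the bias
  experiments); leave-one-out removes it and is available as an option.
* Heckman standard errors ignore first-stage estimation noise.
* No bootstrap or analytic standard errors for decomposition parts; the
  table is a point decomposition.
* Quantile fits inherit `QuantReg`'s IRLS convergence behavior; on tiny
  degenerate designs the optimum may be non-unique (the tests compare
  objective values, not coefficients, for that reason).
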