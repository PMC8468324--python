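# bodywage

Body shape and income on survey microdata: who pays an obesity penalty,
who collects a weight premium, and how much of the income gap between
body-shape groups runs through occupational structure.

The package is written for labor/health economists and epidemiologists
working with CGSS-style (Chinese General Social Survey) microdata — one
row per respondent with height, weight, income, ISCO-08 occupation, ISEI
occupational status, demographics, socioeconomic status and province-level
covariates. Since such microdata are access-restricted, the package ships
a synthetic generator with known ground truth so that the whole analysis
chain is testable end to end.

## What it computes

**Cohort preparation** — BMI = weight/height² (kg, m); sample limited to
ages 18–60, BMI ∈ [10, 40], incomes top-coded at CNY 1,000,000, soldiers
and farmers excluded (with an exclusion log); gender-specific BMI quantile
classes (underweight / normal / overweight at 30/70, robustness at 20/80);
and the cell-mean BMI instrument over (gender × province × occupation)
cells.

**Wage models** — for ln(income), per gender:

    ln(income) = α + β₁·BMI + β₂·Demographics + β₃·Socioeconomic
               + β₄·Regional + β₅·Fixed + ε

by OLS with HC1 robust errors, Heckman two-step selection correction,
2SLS with the cell-mean instrument, a centered BMI×ISEI interaction
(marginal BMI effect β₁ + β₃·ΔISEI), occupation-stratified regressions on
body-shape indicators, quantile regression, and proportional-odds models
for the health and socialization pathways.

**Income-gap decomposition** — a Brown-style decomposition of the mean
log-income gap between body-shape groups into a within-occupation
coefficient part (1), an endowment part (2), and between-occupation
structural parts (4)+(5), where the counterfactual occupational structure
P̂ⱼ comes from a multinomial logit fitted on the reference group and
averaged over the comparison group. The table is exactly additive and
Part (4) + Part (5) equals the structural part (PⱼN − PⱼO)·ĪⱼN by
construction.

## Worked example

```python
import bodywage as bw
from bodywage import decomposition as dec
from bodywage.pipeline import ATTAINMENT_COVARIATES, DECOMPOSITION_COVARIATES

cfg = bw.decomposition_demo_config(n=30_000, seed=7)
df, truth = bw.generate_population(cfg)
cohort, log, thresholds = bw.prepare_cohort(df)

sub = cohort[cohort.gender == "female"]
ref = sub[sub.body_shape == "normal"]
comp = sub[sub.body_shape == "overweight"]
s_n = dec.fit_within_occupation_models(ref, DECOMPOSITION_COVARIATES, bw.OCC_GROUPS)
s_o = dec.fit_within_occupation_models(comp, DECOMPOSITION_COVARIATES, bw.OCC_GROUPS)
cf = dec.counterfactual_structure(ref, comp, ATTAINMENT_COVARIATES, bw.OCC_GROUPS)
table = dec.brown_decompose(s_n, s_o, cf)
print(dec.decomposition_report(table))
```

prints (seed 7):

```
                                             part1   part2   part4  part5  total
Managers                                     0.019  -0.012   0.125 -0.093  0.039
Professionals                                0.006  -0.003   0.206  0.041  0.250
...
Total                                        0.071   0.017   0.026  0.005  0.119
Percentage                                  59.800  14.360  21.920  3.930
```

Read: normal-weight women out-earn overweight women by 0.119 log points
in this synthetic cohort. 59.8% of that gap comes from different wage
coefficients within occupations (the obesity penalty proper — this
cohort was generated with a −0.06 overweight wage shift plus a −0.010
BMI gradient), 14.4% from different covariate endowments, and the
remaining ~26% from occupational structure, of which Part (4) is the
share explained by covariates and Part (5) the share due to different
attainment coefficients.

There is also a CLI for one-shot runs:

```bash
bodywage simulate --n 30000 --seed 1 --out sim.csv
bodywage all --seed 1 --out results/ --quantiles 30,70
bodywage all --seed 1 --out results80/ --quantiles 20,80   # robustness
```

which writes the cohort, exclusion log, descriptive table, tidy model
coefficient tables, stratified/quantile coefficient tables, decomposition
tables (CSV + JSON) and a manifest with content hashes.

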