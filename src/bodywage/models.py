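"""Wage-equation estimators over survey microdata.

All estimators share one contract: a :class:`ModelSpec` names the dependent
variable, the continuous regressors, and the categorical factors (entered
as indicator blocks with one reference level each); every fit returns a
:class:`FitResult` with a coefficient map, heteroskedasticity-robust (HC1)
standard errors, the number of rows used, and a fit statistic.

Families:

* OLS for the baseline log-income equation
  ln(income) = a + b1*BMI + b2*Demographics + b3*Socioeconomic
               + b4*Regional + b5*Fixed + e
* centered BMI x ISEI interaction (within-group deviations), whose marginal
  BMI effect is b1 + b3 * dISEI;
* occupation-stratified regressions on overweight/underweight indicators;
* quantile regression (check-loss);
* Heckman two-step selection correction (probit + inverse Mills ratio);
* two-stage least squares with the cell-mean BMI instrument;
* proportional-odds (ordered logit) models for health and socialization
  outcomes, and OLS pathway models adding a mediator to the income
  equation.

Estimation of standard families is delegated to statsmodels (OLS, Probit,
QuantReg, OrderedModel, MNLogit); the Heckman two-step and the 2SLS
projection algebra are assembled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.regression.quantile_regression import QuantReg

__all__ = [
    "DEMOGRAPHICS",
    "SOCIOECONOMIC",
    "REGIONAL",
    "FIXED_FACTORS",
    "ModelSpec",
    "FitResult",
    "CenteredInteraction",
    "build_design",
    "fit_wage_ols",
    "build_centered_interaction",
    "marginal_bmi_effect",
    "fit_stratified_bodyshape",
    "fit_quantile",
    "fit_heckman_two_step",
    "fit_iv2sls",
    "fit_ordered_logit",
    "fit_pathway_income",
    "DEFAULT_STRATA",
    "tidy",
]

logger = logging.getLogger(__name__)

# Control-variable blocks of the income equation.
DEMOGRAPHICS: Tuple[str, ...] = ("migration", "race", "married", "children", "ln_age")
SOCIOECONOMIC: Tuple[str, ...] = ("party", "union", "med_ins", "social_status")
REGIONAL: Tuple[str, ...] = (
    "ln_pgdp", "ln_pop", "ln_unemployed", "ln_benefits",
    "ln_consumption", "ln_health_inst", "ln_hospitals", "ln_technicians",
)
# Factors entered as indicator blocks (reference = lowest sorted level);
# "region" is the east/central/west area fixed effect.
FIXED_FACTORS: Tuple[str, ...] = ("region", "year")

#: Occupation strata for the occupational-heterogeneity regressions:
#: managers/professionals/technicians; clerks/services-sales; blue collar.
DEFAULT_STRATA: Mapping[str, Tuple[int, ...]] = {
    "managers_professionals_technicians": (1, 2, 3),
    "clerks_services_sales": (4, 5),
    "craft_operators_elementary": (7, 8, 9),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description shared by all estimator families."""

    dependent: str
    regressors: Tuple[str, ...]
    factors: Tuple[str, ...] = ()
    estimator: str = "ols"
    robust: bool = True
    taus: Tuple[float, ...] = (0.5,)
    instrument: Optional[str] = None
    endogenous: Optional[str] = None

    def __post_init__(self) -> None:
        if self.dependent in self.regressors:
            raise ValueError("dependent variable cannot be a regressor")
        for t in self.taus:
            if not 0.0 < t < 1.0:
                raise ValueError(f"quantile tau must lie in (0, 1), got {t}")


@dataclass
class FitResult:
    """Uniform result container across estimator families."""

    params: pd.Series
    bse: pd.Series
    nobs: int
    fit_stat: float                      # adjusted R^2 or pseudo R^2
    fit_stat_name: str = "adj_r2"
    dropped: List[str] = field(default_factory=list)
    mills_coef: Optional[float] = None
    mills_se: Optional[float] = None
    first_stage_f: Optional[float] = None
    thresholds: Optional[np.ndarray] = None
    tau: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def tvalue(self, name: str) -> float:
        return float(self.params[name] / self.bse[name])


@dataclass
class CenteredInteraction:
    """Centering record for the BMI x ISEI interaction model."""

    bmi_mean: float
    isei_mean: float
    data: pd.DataFrame  # estimation sample with bmi_c, isei_c, bmi_isei_c


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    data: pd.DataFrame,
    regressors: Sequence[str],
    factors: Sequence[str] = (),
    add_const: bool = True,
) -> Tuple[pd.DataFrame, List[str]]:
    """Numeric design matrix with intercept, factor dummies, and a
    rank check.

    Factor levels are sorted; the lowest level is the reference.  Factors
    constant on the sample contribute no columns.  Rank-deficient columns
    are dropped and reported (never silently) via the second return value.
    """
    parts = []
    if add_const:
        parts.append(pd.Series(1.0, index=data.index, name="const"))
    for r in regressors:
        parts.append(pd.to_numeric(data[r], errors="coerce").rename(r))
    for f in factors:
        levels = np.sort(data[f].dropna().unique())
        for lev in levels[1:]:
            parts.append((data[f] == lev).astype(float).rename(f"{f}[{lev}]"))
    X = pd.concat(parts, axis=1)

    dropped: List[str] = []
    arr = X.to_numpy(dtype=float)
    # QR with pivoting: columns whose R diagonal is ~0 are collinear
    _, rr = np.linalg.qr(arr)
    diag = np.abs(np.diag(rr))
    tol = max(arr.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if (diag < tol).any():
        from scipy.linalg import qr as scipy_qr

        _, rr, piv = scipy_qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rr))
        rank = int((diag > tol).sum())
        keep_idx = sorted(piv[:rank])
        dropped = [X.columns[i] for i in range(X.shape[1]) if i not in keep_idx]
        if dropped:
            logger.warning("dropping collinear columns: %s", dropped)
        X = X.iloc[:, keep_idx]
    return X, dropped


def _estimation_frame(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.dependent, *spec.regressors, *spec.factors]
    return data.dropna(subset=[c for c in cols if c in data.columns])


# ---------------------------------------------------------------------------
# OLS and friends
# ---------------------------------------------------------------------------

def fit_wage_ols(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Least squares with HC1-robust standard errors."""
    df = _estimation_frame(data, spec)
    X, dropped = build_design(df, spec.regressors, spec.factors)
    if len(df) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} rows for {X.shape[1]} regressors"
        )
    y = pd.to_numeric(df[spec.dependent], errors="coerce")
    model = sm.OLS(y.to_numpy(), X.to_numpy())
    res = model.fit(cov_type="HC1" if spec.robust else "nonrobust")
    return FitResult(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        nobs=int(res.nobs),
        fit_stat=float(res.rsquared_adj),
        dropped=dropped,
    )


def build_centered_interaction(
    data: pd.DataFrame,
    bmi_col: str = "bmi",
    isei_col: str = "isei",
) -> CenteredInteraction:
    """Centered BMI, ISEI and product columns on the estimation sample.

    Centering uses the sample means after all filtering, so the centered
    columns have mean zero on the estimation sample and the product term's
    coefficient is invariant to location shifts in either variable.
    """
    df = data.dropna(subset=[bmi_col, isei_col]).copy()
    if df[bmi_col].std() == 0 or df[isei_col].std() == 0:
        raise ValueError("BMI and ISEI must have positive variance")
    mb = float(df[bmi_col].mean())
    mi = float(df[isei_col].mean())
    df["bmi_c"] = df[bmi_col] - mb
    df["isei_c"] = df[isei_col] - mi
    df["bmi_isei_c"] = df["bmi_c"] * df["isei_c"]
    return CenteredInteraction(bmi_mean=mb, isei_mean=mi, data=df)


def marginal_bmi_effect(fit: FitResult, delta_isei: float) -> float:
    """BMI effect on log income at an ISEI displacement: b1 + b3 * dISEI."""
    if "bmi_isei_c" not in fit.params.index:
        raise ValueError("fit has no centered BMI x ISEI interaction term")
    b1 = fit.params["bmi_c"] if "bmi_c" in fit.params.index else fit.params["bmi"]
    return float(b1 + fit.params["bmi_isei_c"] * delta_isei)


def fit_stratified_bodyshape(
    data: pd.DataFrame,
    spec: ModelSpec,
    strata: Mapping[str, Tuple[int, ...]] = DEFAULT_STRATA,
    occ_col: str = "occ_isco1",
    shape_col: str = "body_shape",
) -> Dict[str, FitResult]:
    """Per-stratum regressions with overweight/underweight indicators.

    ``spec.regressors`` are the controls; overweight and underweight
    indicators (normal = reference) are prepended.  Strata with a single
    body-shape class, or too few rows, are flagged and skipped.
    """
    results: Dict[str, FitResult] = {}
    for name, occs in strata.items():
        sub = data[data[occ_col].isin(occs)].copy()
        sub = sub.dropna(subset=[shape_col])
        if sub.empty or sub[shape_col].nunique() < 2:
            results[name] = FitResult(
                params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                nobs=len(sub), fit_stat=np.nan, flags=["skipped"],
            )
            continue
        sub["overweight"] = (sub[shape_col] == "overweight").astype(float)
        sub["underweight"] = (sub[shape_col] == "underweight").astype(float)
        stratum_spec = ModelSpec(
            dependent=spec.dependent,
            regressors=("overweight", "underweight", *spec.regressors),
            factors=spec.factors,
            robust=spec.robust,
        )
        try:
            results[name] = fit_wage_ols(sub, stratum_spec)
        except ValueError as exc:
            results[name] = FitResult(
                params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                nobs=len(sub), fit_stat=np.nan, flags=[f"skipped: {exc}"],
            )
    return results


# ---------------------------------------------------------------------------
# quantile regression
# ---------------------------------------------------------------------------

def check_loss(y: np.ndarray, yhat: np.ndarray, tau: float) -> float:
    """Pinball loss evaluated at a candidate fit (used in tests/diagnostics)."""
    u = np.asarray(y) - np.asarray(yhat)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile(
    data: pd.DataFrame, spec: ModelSpec, taus: Optional[Sequence[float]] = None
) -> Dict[float, FitResult]:
    """Quantile (check-loss) regression at each requested tau."""
    taus = tuple(taus) if taus is not None else spec.taus
    for t in taus:
        if not 0.0 < t < 1.0:
            raise ValueError(f"tau must lie in (0, 1), got {t}")
    df = _estimation_frame(data, spec)
    X, dropped = build_design(df, spec.regressors, spec.factors)
    y = pd.to_numeric(df[spec.dependent], errors="coerce").to_numpy()
    out: Dict[float, FitResult] = {}
    for t in taus:
        res = QuantReg(y, X.to_numpy()).fit(q=t, max_iter=5000, p_tol=1e-8)
        out[t] = FitResult(
            params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            nobs=int(res.nobs),
            fit_stat=float(res.prsquared),
            fit_stat_name="pseudo_r2",
            dropped=dropped,
            tau=t,
        )
    return out


# ---------------------------------------------------------------------------
# Heckman two-step
# ---------------------------------------------------------------------------

def fit_heckman_two_step(
    data: pd.DataFrame,
    selection_spec: ModelSpec,
    outcome_spec: ModelSpec,
) -> FitResult:
    """Heckman's two-step selection correction.

    Step 1: probit of the binary selection indicator on the selection
    regressors over the full sample.  Step 2: OLS of the outcome on its
    regressors plus the inverse Mills ratio, over selected rows only, with
    HC1 errors (no Murphy–Topel correction).  The selection equation should
    include at least one variable excluded from the outcome equation; if it
    does not, estimates are identified off functional form only and a flag
    is recorded.
    """
    flags: List[str] = []
    excl = set(selection_spec.regressors) - set(outcome_spec.regressors)
    if not excl:
        flags.append("no_exclusion_restriction")
        logger.warning("Heckman: no exclusion restriction; identification "
                       "rests on the nonlinearity of the Mills ratio")

    sel_df = data.dropna(
        subset=[selection_spec.dependent, *selection_spec.regressors]
    )
    Xs, _ = build_design(sel_df, selection_spec.regressors, selection_spec.factors)
    s = pd.to_numeric(sel_df[selection_spec.dependent]).to_numpy()
    if set(np.unique(s)) - {0, 1}:
        raise ValueError("selection outcome must be binary 0/1")
    if s.min() == 1:
        # everyone selected: the Mills ratio degenerates to its limit 0
        # and the second step reduces to plain OLS
        flags.append("no_selection_variation")
        mills = np.zeros(len(sel_df))
    elif s.max() == 0:
        raise ValueError("no selected rows; outcome equation cannot be fit")
    else:
        probit = sm.Probit(s, Xs.to_numpy()).fit(disp=0, maxiter=200)
        if not probit.mle_retvals.get("converged", True):
            raise RuntimeError("selection probit did not converge")
        xb = Xs.to_numpy() @ probit.params
        mills = stats.norm.pdf(xb) / np.clip(stats.norm.cdf(xb), 1e-300, None)
    sel_df = sel_df.assign(_mills=mills)

    selected = sel_df[s == 1].dropna(
        subset=[outcome_spec.dependent, *outcome_spec.regressors]
    )
    Xo, dropped = build_design(selected, outcome_spec.regressors, outcome_spec.factors)
    Xo = Xo.assign(inverse_mills=selected["_mills"])
    y = pd.to_numeric(selected[outcome_spec.dependent]).to_numpy()
    res = sm.OLS(y, Xo.to_numpy()).fit(cov_type="HC1")
    params = pd.Series(res.params, index=Xo.columns)
    bse = pd.Series(res.bse, index=Xo.columns)
    return FitResult(
        params=params,
        bse=bse,
        nobs=int(res.nobs),
        fit_stat=float(res.rsquared_adj),
        dropped=dropped,
        mills_coef=float(params["inverse_mills"]),
        mills_se=float(bse["inverse_mills"]),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# two-stage least squares
# ---------------------------------------------------------------------------

def fit_iv2sls(
    data: pd.DataFrame,
    spec: ModelSpec,
    instrument: Optional[str] = None,
    endogenous: str = "bmi",
) -> FitResult:
    """2SLS with one endogenous regressor and one (or more) instruments.

    The endogenous column is projected on [exogenous regressors,
    instrument]; second-stage coefficients use the projected column, and
    HC1 standard errors use the structural residuals (computed from the
    original, unprojected regressors).  Reports a first-stage robust
    F-statistic for instrument strength.
    """
    instrument = instrument or spec.instrument
    if instrument is None:
        raise ValueError("an instrument column is required")
    df = data.dropna(
        subset=[spec.dependent, endogenous, instrument, *spec.regressors]
    )
    exog_names = [r for r in spec.regressors if r != endogenous]
    X_ex, dropped = build_design(df, exog_names, spec.factors)
    z = pd.to_numeric(df[instrument]).to_numpy()
    if np.std(z) == 0:
        raise ValueError("instrument is constant")
    x_end = pd.to_numeric(df[endogenous]).to_numpy()
    y = pd.to_numeric(df[spec.dependent]).to_numpy()

    Z = np.column_stack([X_ex.to_numpy(), z])
    # instrument must add information beyond the exogenous block
    if np.linalg.matrix_rank(Z) <= X_ex.shape[1]:
        raise ValueError("instrument is collinear with the exogenous regressors")

    # first stage (robust F for the excluded instrument)
    fs = sm.OLS(x_end, Z).fit(cov_type="HC1")
    t_inst = fs.params[-1] / fs.bse[-1]
    first_stage_f = float(t_inst**2)

    X = np.column_stack([X_ex.to_numpy(), x_end])
    xhat_end = Z @ np.linalg.lstsq(Z, x_end, rcond=None)[0]
    Xhat = np.column_stack([X_ex.to_numpy(), xhat_end])
    beta, *_ = np.linalg.lstsq(Xhat, y, rcond=None)
    resid = y - X @ beta  # structural residuals
    n, k = X.shape
    XtX_inv = np.linalg.pinv(Xhat.T @ Xhat)
    meat = (Xhat * (resid**2)[:, None]).T @ Xhat
    cov = XtX_inv @ meat @ XtX_inv * (n / (n - k))
    names = list(X_ex.columns) + [endogenous]
    return FitResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        nobs=n,
        fit_stat=float(1 - resid.var() / y.var()),
        fit_stat_name="r2_structural",
        dropped=dropped,
        first_stage_f=first_stage_f,
    )


# ---------------------------------------------------------------------------
# ordered logit and pathway models
# ---------------------------------------------------------------------------

def _null_loglike(y: np.ndarray) -> float:
    """Log-likelihood of the thresholds-only ordered model (closed form)."""
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(counts * np.log(p)))


def fit_ordered_logit(
    data: pd.DataFrame, outcome: str, spec: ModelSpec
) -> FitResult:
    """Proportional-odds model by maximum likelihood.

    The outcome must be ordinal with >= 2 observed categories; thresholds
    are returned strictly increasing.  Robust (HC1-type sandwich) standard
    errors; pseudo R^2 is McFadden's against the thresholds-only model.
    """
    df = data.dropna(subset=[outcome, *spec.regressors])
    y = pd.to_numeric(df[outcome]).astype(int)
    if y.nunique() < 2:
        raise ValueError("ordinal outcome has a single observed category")
    X, dropped = build_design(df, spec.regressors, spec.factors, add_const=False)
    model = OrderedModel(y.to_numpy(), X.to_numpy(), distr="logit")
    res = model.fit(method="lbfgs", maxiter=1000, disp=0)
    k = X.shape[1]
    params = pd.Series(res.params[:k], index=X.columns)
    bse = pd.Series(res.bse[:k], index=X.columns)
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    pseudo_r2 = float(1.0 - res.llf / _null_loglike(y.to_numpy()))
    flags = []
    if np.any(np.abs(params) > 20):
        flags.append("possible_separation")
    return FitResult(
        params=params,
        bse=bse,
        nobs=int(res.nobs),
        fit_stat=pseudo_r2,
        fit_stat_name="pseudo_r2",
        dropped=dropped,
        thresholds=np.asarray(thresholds),
        flags=flags,
    )


def fit_pathway_income(
    data: pd.DataFrame, mediator: str, spec: ModelSpec
) -> FitResult:
    """Income equation with a mediator (health / socialization) added."""
    if mediator not in data.columns:
        raise ValueError(f"mediator column {mediator!r} not present")
    pathway_spec = ModelSpec(
        dependent=spec.dependent,
        regressors=(mediator, *spec.regressors),
        factors=spec.factors,
        robust=spec.robust,
    )
    return fit_wage_ols(data, pathway_spec)


# ---------------------------------------------------------------------------
# tidy export
# ---------------------------------------------------------------------------

def tidy(results: Mapping[str, FitResult]) -> pd.DataFrame:
    """Stack fits into a tidy (model, term, estimate, se, n) table."""
    rows = []
    for model_id, fit in results.items():
        for term in fit.params.index:
            rows.append(
                {
                    "model": model_id,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "n": fit.nobs,
                    "fit_stat": fit.fit_stat,
                    "fit_stat_name": fit.fit_stat_name,
                }
            )
    return pd.DataFrame(rows)
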