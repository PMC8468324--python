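"""Estimator contracts: exact recovery, invariants, bias corrections, and
independent cross-checks (brute force, closed forms, statsmodels' sandbox
IV as an external oracle for the in-package 2SLS)."""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

import bodywage as bw
from bodywage import models as md

from conftest import SHORT_SPEC, clean_config


def _toy_frame(n=400, seed=0, beta=(1.0, 0.5, -0.3), noise=0.0):
    rng = np.random.default_rng(seed)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    y = beta[0] + beta[1] * x1 + beta[2] * x2 + noise * rng.normal(size=n)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def test_ols_zero_noise_exact():
    df = _toy_frame(noise=0.0)
    fit = md.fit_wage_ols(df, md.ModelSpec(dependent="y", regressors=("x1", "x2")))
    assert fit.params["const"] == pytest.approx(1.0, abs=1e-10)
    assert fit.params["x1"] == pytest.approx(0.5, abs=1e-10)
    assert fit.params["x2"] == pytest.approx(-0.3, abs=1e-10)
    # robust and classical errors coincide (both ~ 0) without noise
    assert fit.bse.max() < 1e-8


def test_ols_residuals_orthogonal_to_regressors():
    df = _toy_frame(noise=1.0, seed=3)
    spec = md.ModelSpec(dependent="y", regressors=("x1", "x2"))
    fit = md.fit_wage_ols(df, spec)
    X, _ = md.build_design(df, spec.regressors)
    resid = df["y"].to_numpy() - X.to_numpy() @ fit.params.to_numpy()
    dots = X.to_numpy().T @ resid
    assert np.max(np.abs(dots)) / len(df) < 1e-8


def test_ols_sign_pattern_paperlike(paperlike_cohort):
    """Female BMI coefficient negative, male positive, both > 2 robust SEs
    from zero on paper-like synthetic data."""
    cohort, *_ = paperlike_cohort
    for gender, sign in (("female", -1), ("male", 1)):
        fit = md.fit_wage_ols(cohort[cohort["gender"] == gender], SHORT_SPEC)
        assert np.sign(fit.params["bmi"]) == sign
        assert abs(fit.tvalue("bmi")) > 2


def test_ols_mean_recovery_and_coverage():
    """Across replicates with true BMI coefficient -0.010: the mean
    estimate sits within Monte-Carlo error of the truth and nominal 95%
    CIs cover the truth between 90% and 99% of the time."""
    reps, n, truth_beta = 500, 5_000, -0.010
    est, covered = [], 0
    for r in range(reps):
        df, _ = bw.generate_population(clean_config(n=n, seed=10_000 + r))
        coh, _, _ = bw.prepare_cohort(df)
        fit = md.fit_wage_ols(coh[coh["gender"] == "female"], SHORT_SPEC)
        b, se = fit.params["bmi"], fit.bse["bmi"]
        est.append(b)
        covered += abs(b - truth_beta) < 1.96 * se
    mc_se = np.std(est, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(est) - truth_beta) < 4 * mc_se
    assert 0.90 <= covered / reps <= 0.99


def test_rank_deficient_column_dropped_and_flagged():
    df = _toy_frame()
    df["x3"] = 2 * df["x1"]
    fit = md.fit_wage_ols(df, md.ModelSpec(dependent="y", regressors=("x1", "x2", "x3")))
    assert fit.dropped  # never silent
    assert len(fit.params) == 3


def test_too_few_rows_raises():
    df = _toy_frame(n=3)
    with pytest.raises(ValueError):
        md.fit_wage_ols(df, md.ModelSpec(dependent="y", regressors=("x1", "x2")))


# ---------------------------------------------------------------------------
# centered interaction
# ---------------------------------------------------------------------------

def test_centered_columns_have_mean_zero(paperlike_cohort):
    cohort, *_ = paperlike_cohort
    inter = md.build_centered_interaction(cohort)
    assert abs(inter.data["bmi_c"].mean()) < 1e-9
    assert abs(inter.data["isei_c"].mean()) < 1e-9


def test_interaction_translation_invariance():
    rng = np.random.default_rng(5)
    n = 2_000
    df = pd.DataFrame({
        "bmi": rng.normal(22, 3, n),
        "isei": rng.normal(40, 10, n),
    })
    df["ln_income"] = (
        10 - 0.01 * df["bmi"] + 0.02 * df["isei"]
        - 5e-4 * (df["bmi"] - df["bmi"].mean()) * (df["isei"] - df["isei"].mean())
        + 0.3 * rng.normal(size=n)
    )
    spec = md.ModelSpec(dependent="ln_income",
                        regressors=("bmi_c", "isei_c", "bmi_isei_c"))
    fit1 = md.fit_wage_ols(md.build_centered_interaction(df).data, spec)
    shifted = df.assign(isei=df["isei"] + 100.0)
    fit2 = md.fit_wage_ols(md.build_centered_interaction(shifted).data, spec)
    assert fit1.params["bmi_c"] == pytest.approx(fit2.params["bmi_c"], abs=1e-10)
    assert fit1.params["bmi_isei_c"] == pytest.approx(fit2.params["bmi_isei_c"], abs=1e-12)


def test_interaction_recovery_on_generated_truth():
    """Centered-interaction coefficient recovered within its CI at n=20,000."""
    cfg = clean_config(n=20_000, seed=77)
    truth_gamma = -0.00046
    cfg = dataclasses.replace(
        cfg,
        wage={g: dataclasses.replace(cfg.wage[g], bmi_isei=truth_gamma)
              for g in ("female", "male")},
    )
    df, _ = bw.generate_population(cfg)
    coh, _, _ = bw.prepare_cohort(df)
    sub = coh[coh["gender"] == "female"]
    inter = md.build_centered_interaction(sub)
    spec = md.ModelSpec(
        dependent="ln_income",
        regressors=("bmi_c", "isei_c", "bmi_isei_c", *md.DEMOGRAPHICS,
                    *md.SOCIOECONOMIC),
        factors=("edu",),
    )
    fit = md.fit_wage_ols(inter.data, spec)
    assert abs(fit.params["bmi_isei_c"] - truth_gamma) < 3 * fit.bse["bmi_isei_c"]


def test_zero_variance_interaction_input_raises():
    df = pd.DataFrame({"bmi": [22.0] * 10, "isei": np.arange(10.0)})
    with pytest.raises(ValueError):
        md.build_centered_interaction(df)


def test_marginal_bmi_effect_hand_arithmetic():
    """b1 + b3 * dISEI reproduces hand-computed occupational gradients."""
    def fake_fit(b1, b3):
        return md.FitResult(
            params=pd.Series({"bmi_c": b1, "bmi_isei_c": b3}),
            bse=pd.Series({"bmi_c": 0.0, "bmi_isei_c": 0.0}),
            nobs=0, fit_stat=0.0,
        )

    assert md.marginal_bmi_effect(fake_fit(-0.008, -0.00046), 0) == pytest.approx(-0.008)
    assert md.marginal_bmi_effect(fake_fit(-0.008, -0.00046), 20) == pytest.approx(-0.0172)
    assert md.marginal_bmi_effect(fake_fit(0.016, -0.00019), -20) == pytest.approx(0.0198)
    plain = md.FitResult(params=pd.Series({"bmi": -0.01}),
                         bse=pd.Series({"bmi": 0.0}), nobs=0, fit_stat=0.0)
    with pytest.raises(ValueError):
        md.marginal_bmi_effect(plain, 10)


# ---------------------------------------------------------------------------
# stratified body-shape fits
# ---------------------------------------------------------------------------

def _stratified_frame(rng, n, over_effect_high=0.0):
    occ = rng.choice([1, 2, 3, 4, 5, 7, 8, 9], n)
    shape = rng.choice(["normal", "overweight", "underweight"], n, p=[0.4, 0.3, 0.3])
    x = rng.normal(size=n)
    high = np.isin(occ, (1, 2, 3))
    y = 10 + 0.3 * x + over_effect_high * (shape == "overweight") * high
    y = y + 0.5 * rng.normal(size=n)
    return pd.DataFrame({
        "ln_income": y, "occ_isco1": occ, "body_shape": shape, "x": x,
    })


def test_stratified_zero_effect_within_2se():
    """With no true body-shape effect, stratum coefficients fall within
    2 SEs of zero in at least 90% of replicates."""
    rng = np.random.default_rng(0)
    spec = md.ModelSpec(dependent="ln_income", regressors=("x",))
    hits = total = 0
    for _ in range(100):
        fits = md.fit_stratified_bodyshape(_stratified_frame(rng, 1_500), spec)
        for f in fits.values():
            for term in ("overweight", "underweight"):
                total += 1
                hits += abs(f.params[term]) < 2 * f.bse[term]
    assert hits / total >= 0.90


def test_stratified_sign_pattern_by_construction():
    rng = np.random.default_rng(1)
    spec = md.ModelSpec(dependent="ln_income", regressors=("x",))
    fits = md.fit_stratified_bodyshape(
        _stratified_frame(rng, 30_000, over_effect_high=-0.2), spec
    )
    high = fits["managers_professionals_technicians"]
    other = fits["craft_operators_elementary"]
    assert high.params["overweight"] < -2 * high.bse["overweight"]
    assert abs(other.params["overweight"]) < 3 * other.bse["overweight"]


def test_empty_stratum_skipped_with_flag():
    rng = np.random.default_rng(2)
    df = _stratified_frame(rng, 500)
    df = df[~df["occ_isco1"].isin((4, 5))]
    spec = md.ModelSpec(dependent="ln_income", regressors=("x",))
    fits = md.fit_stratified_bodyshape(df, spec)
    assert any("skipped" in fl for fl in fits["clerks_services_sales"].flags)


# ---------------------------------------------------------------------------
# quantile regression
# ---------------------------------------------------------------------------

def test_quantile_median_matches_brute_force_line_search():
    """On 5 points, the tau = 0.5 fit attains the minimal check loss found
    by exhaustive search over all lines through data-point pairs."""
    pts = [(0.0, 1.0), (1.0, 2.2), (2.0, 2.8), (3.0, 4.5), (4.0, 4.9)]
    df = pd.DataFrame(pts, columns=["x", "y"])
    fit = md.fit_quantile(df, md.ModelSpec(dependent="y", regressors=("x",)),
                          taus=[0.5])[0.5]
    yhat = fit.params["const"] + fit.params["x"] * df["x"]
    fitted_loss = md.check_loss(df["y"].to_numpy(), yhat.to_numpy(), 0.5)

    best = np.inf
    for (x1, y1), (x2, y2) in itertools.combinations(pts, 2):
        slope = (y2 - y1) / (x2 - x1)
        icept = y1 - slope * x1
        loss = md.check_loss(df["y"].to_numpy(),
                             icept + slope * df["x"].to_numpy(), 0.5)
        best = min(best, loss)
    assert fitted_loss == pytest.approx(best, abs=1e-6)


def test_quantile_median_close_to_ols_under_symmetric_noise():
    df = _toy_frame(n=20_000, seed=9, noise=1.0)
    spec = md.ModelSpec(dependent="y", regressors=("x1", "x2"))
    ols = md.fit_wage_ols(df, spec)
    q = md.fit_quantile(df, spec, taus=[0.5])[0.5]
    assert np.allclose(q.params, ols.params, atol=0.05)


def test_quantile_objective_beats_ols_solution():
    df = _toy_frame(n=3_000, seed=11, noise=1.5)
    spec = md.ModelSpec(dependent="y", regressors=("x1", "x2"))
    ols = md.fit_wage_ols(df, spec)
    X, _ = md.build_design(df, spec.regressors)
    for tau in (0.25, 0.5, 0.75):
        qfit = md.fit_quantile(df, spec, taus=[tau])[tau]
        loss_q = md.check_loss(df["y"], X.to_numpy() @ qfit.params.to_numpy(), tau)
        loss_ols = md.check_loss(df["y"], X.to_numpy() @ ols.params.to_numpy(), tau)
        assert loss_q <= loss_ols + 1e-6


def test_quantile_tau_out_of_range_raises():
    df = _toy_frame()
    with pytest.raises(ValueError):
        md.fit_quantile(df, md.ModelSpec(dependent="y", regressors=("x1",)),
                        taus=[1.2])


# ---------------------------------------------------------------------------
# Heckman two-step
# ---------------------------------------------------------------------------

def _heckman_specs():
    sel = md.ModelSpec(dependent="employed",
                       regressors=("bmi", "edu", "married", "children"))
    out = md.ModelSpec(dependent="ln_income", regressors=("bmi", "edu", "married"))
    return sel, out


def _raw_gender(df, gender):
    g = df[df["gender"] == gender].copy()
    g["bmi"] = g["weight_kg"] / g["height_m"] ** 2
    g["ln_income"] = np.log(g["income_cny"].where(g["income_cny"] > 0))
    return g


def test_heckman_rho_zero_matches_ols():
    """Without error correlation, the two-step estimates match plain OLS
    and the Mills coefficient is near zero."""
    cfg = bw.selection_demo_config(n=40_000, seed=6, rho=0.0)
    df, _ = bw.generate_population(cfg)
    g = _raw_gender(df, "male")
    sel, out = _heckman_specs()
    heck = md.fit_heckman_two_step(g, sel, out)
    ols = md.fit_wage_ols(g.dropna(subset=["ln_income"]), out)
    assert abs(heck.params["bmi"] - ols.params["bmi"]) < 2 * ols.bse["bmi"]
    assert abs(heck.mills_coef) < 3 * heck.mills_se


def test_heckman_all_selected_degenerates_to_ols():
    df = _toy_frame(n=2_000, seed=13, noise=0.5)
    df["employed"] = 1
    df["z"] = np.random.default_rng(0).normal(size=len(df))
    sel = md.ModelSpec(dependent="employed", regressors=("x1", "z"))
    out = md.ModelSpec(dependent="y", regressors=("x1", "x2"))
    heck = md.fit_heckman_two_step(df, sel, out)
    ols = md.fit_wage_ols(df, out)
    assert heck.nobs == ols.nobs
    assert abs(heck.params["x1"] - ols.params["x1"]) < 0.05


def test_heckman_without_exclusion_flags():
    df = _toy_frame(n=1_000, seed=14, noise=0.5)
    df["employed"] = (df["x1"] + np.random.default_rng(1).normal(size=len(df)) > 0).astype(int)
    spec = md.ModelSpec(dependent="y", regressors=("x1", "x2"))
    sel = md.ModelSpec(dependent="employed", regressors=("x1", "x2"))
    heck = md.fit_heckman_two_step(df, sel, spec)
    assert "no_exclusion_restriction" in heck.flags


def test_heckman_rejects_nonbinary_selection():
    df = _toy_frame(n=200)
    df["employed"] = np.arange(len(df)) % 3
    sel = md.ModelSpec(dependent="employed", regressors=("x1",))
    out = md.ModelSpec(dependent="y", regressors=("x2",))
    with pytest.raises(ValueError):
        md.fit_heckman_two_step(df, sel, out)


# ---------------------------------------------------------------------------
# 2SLS
# ---------------------------------------------------------------------------

def test_iv_with_instrument_equal_to_regressor_equals_ols(paperlike_cohort):
    cohort, *_ = paperlike_cohort
    sub = cohort[cohort["gender"] == "female"].copy()
    sub["self_inst"] = sub["bmi"]
    ols = md.fit_wage_ols(sub, SHORT_SPEC)
    iv = md.fit_iv2sls(sub, SHORT_SPEC, instrument="self_inst")
    assert iv.params["bmi"] == pytest.approx(ols.params["bmi"], abs=1e-8)


def test_iv_constant_instrument_raises(paperlike_cohort):
    cohort, *_ = paperlike_cohort
    sub = cohort[cohort["gender"] == "female"].copy()
    sub["bad"] = 1.0
    with pytest.raises(ValueError):
        md.fit_iv2sls(sub, SHORT_SPEC, instrument="bad")


def test_iv_matches_statsmodels_sandbox_oracle():
    """In-package 2SLS coefficients agree with statsmodels' sandbox IV2SLS
    (an independent implementation) on the same data."""
    from statsmodels.sandbox.regression.gmm import IV2SLS as SM_IV2SLS

    df, _ = bw.generate_population(bw.endogeneity_demo_config(n=6_000, seed=31))
    coh, _, _ = bw.prepare_cohort(df)
    sub = coh[coh["gender"] == "male"]
    fit = md.fit_iv2sls(sub, SHORT_SPEC, instrument="bmi_instrument")

    sub2 = sub.dropna(subset=["ln_income", "bmi", "bmi_instrument",
                              *SHORT_SPEC.regressors])
    X, _ = md.build_design(sub2, SHORT_SPEC.regressors, SHORT_SPEC.factors)
    exog_cols = [c for c in X.columns if c != "bmi"]
    Z = pd.concat([X[exog_cols], sub2["bmi_instrument"]], axis=1)
    sm_fit = SM_IV2SLS(sub2["ln_income"].to_numpy(), X.to_numpy(),
                       Z.to_numpy()).fit()
    ours = fit.params.reindex(X.columns).to_numpy()
    assert np.allclose(ours, sm_fit.params, atol=1e-8)


def test_iv_reports_first_stage_strength():
    df, _ = bw.generate_population(bw.endogeneity_demo_config(n=6_000, seed=32))
    coh, _, _ = bw.prepare_cohort(df)
    fit = md.fit_iv2sls(coh[coh["gender"] == "female"], SHORT_SPEC,
                        instrument="bmi_instrument")
    assert fit.first_stage_f > 10  # conventional relevance bar


# ---------------------------------------------------------------------------
# ordered logit
# ---------------------------------------------------------------------------

def _ordinal_frame(n, seed, over_coef=-0.2, under_coef=-0.1):
    rng = np.random.default_rng(seed)
    over = (rng.random(n) < 0.3).astype(float)
    under = ((rng.random(n) < 3 / 7) & (over == 0)).astype(float)
    latent = over_coef * over + under_coef * under + rng.logistic(size=n)
    y = 1 + np.searchsorted([-2.5, -1.2, 0.3, 1.8], latent)
    return pd.DataFrame({"health": y, "overweight": over, "underweight": under})


def test_ordered_logit_recovers_simulated_coefficients():
    df = _ordinal_frame(20_000, seed=8)
    spec = md.ModelSpec(dependent="_", regressors=("overweight", "underweight"))
    fit = md.fit_ordered_logit(df, "health", spec)
    assert abs(fit.params["overweight"] - (-0.2)) < 3 * fit.bse["overweight"]
    assert np.all(np.diff(fit.thresholds) > 0)


def test_ordered_logit_collapsing_top_categories_stable():
    df = _ordinal_frame(20_000, seed=9)
    spec = md.ModelSpec(dependent="_", regressors=("overweight", "underweight"))
    full = md.fit_ordered_logit(df, "health", spec)
    merged = df.copy()
    merged["health"] = merged["health"].clip(upper=4)
    part = md.fit_ordered_logit(merged, "health", spec)
    assert abs(full.params["overweight"] - part.params["overweight"]) < 0.06


def test_ordered_logit_single_category_raises():
    df = pd.DataFrame({"health": [3] * 50, "overweight": np.arange(50) % 2})
    spec = md.ModelSpec(dependent="_", regressors=("overweight",))
    with pytest.raises(ValueError):
        md.fit_ordered_logit(df, "health", spec)


# ---------------------------------------------------------------------------
# pathway models
# ---------------------------------------------------------------------------

def test_pathway_positive_mediator_sign(paperlike_cohort):
    """Health enters the income equation positively for both genders."""
    cohort, *_ = paperlike_cohort
    for gender in ("female", "male"):
        fit = md.fit_pathway_income(cohort[cohort["gender"] == gender],
                                    "health", SHORT_SPEC)
        assert fit.params["health"] > 0
        assert fit.tvalue("health") > 2


def test_pathway_independent_mediator_near_zero():
    rng = np.random.default_rng(4)
    hits = 0
    reps = 60
    for r in range(reps):
        df = _toy_frame(n=800, seed=500 + r, noise=1.0)
        df["m"] = rng.integers(1, 6, len(df))
        fit = md.fit_pathway_income(
            df, "m", md.ModelSpec(dependent="y", regressors=("x1", "x2"))
        )
        hits += abs(fit.params["m"]) < 2 * fit.bse["m"]
    assert hits / reps >= 0.90
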