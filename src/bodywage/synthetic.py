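"""Synthetic CGSS-like survey microdata with known ground truth.

The Chinese General Social Survey (CGSS) microdata behind body-shape/income
studies are access-restricted, so this module generates survey-shaped tables
with the same structure: two genders with distinct anthropometry, eight
ISCO-08 major occupation groups (agricultural group 6 and soldiers excluded),
ISEI occupational status scores, log-income driven by a known linear wage
equation, and optional selection-into-employment and BMI-endogeneity
mechanisms.  Every generated table comes with a :class:`GroundTruth` object
recording the exact parameters used, so downstream estimators can be tested
for parameter recovery instead of eyeballed.

Key mechanisms
--------------
* Occupational attainment is a multinomial logit on (education, BMI) whose
  intercepts are calibrated so that marginal occupation shares match the
  configured per-gender shares.  Attainment therefore depends on body shape,
  which gives the between-occupation parts of the income-gap decomposition a
  nonzero truth.
* Height is normal and weight log-normal per gender, with per-province
  log-weight offsets.  The province-level BMI variation is what gives the
  (gender, province, occupation) cell-mean instrument its first stage.
* Selection into employment is a probit whose index includes BMI and at
  least one variable (children) excluded from the wage equation, with error
  correlation rho against the wage disturbance.
* Endogeneity is a latent individual-level confounder loading on both
  weight (hence BMI, keeping BMI = weight/height^2 exact) and log income;
  it averages out within large instrument cells, so the cell-mean
  instrument stays valid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "OCC_GROUPS",
    "REGIONAL_COLUMNS",
    "GeneratorConfig",
    "AnthropometryParams",
    "WageParams",
    "SelectionConfig",
    "EndogeneityConfig",
    "OrdinalOutcome",
    "GroundTruth",
    "ConfigError",
    "generate_population",
    "default_paperlike_config",
    "decomposition_demo_config",
    "recovery_demo_config",
    "endogeneity_demo_config",
    "selection_demo_config",
    "oracle_decomposition",
]

#: ISCO-08 major groups retained in the civilian non-agricultural sample.
OCC_GROUPS: Tuple[int, ...] = (1, 2, 3, 4, 5, 7, 8, 9)

#: Province-level logged macro covariates (regional controls).
REGIONAL_COLUMNS: Tuple[str, ...] = (
    "ln_pgdp",
    "ln_pop",
    "ln_unemployed",
    "ln_benefits",
    "ln_consumption",
    "ln_health_inst",
    "ln_hospitals",
    "ln_technicians",
)

GENDERS: Tuple[str, str] = ("female", "male")

ALLOWED_YEARS: Tuple[int, ...] = (2010, 2011, 2012, 2013, 2015, 2017)


class ConfigError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class AnthropometryParams:
    """Per-gender height (normal, metres) and weight (log-normal, kg)."""

    height_mean: float
    height_sd: float
    log_weight_mean: float
    log_weight_sd: float


@dataclass(frozen=True)
class WageParams:
    """True log-income equation for one gender.

    ln(income) = a_occ + bmi*BMI + isei*ISEI
                 + bmi_isei*(BMI - mean BMI)(ISEI - mean ISEI)
                 + edu*EDU + married*MARRIED
                 + overweight*1[over] + underweight*1[under]
                 + health*(health - 3) + nb_social*(nb - 4) + fr_social*(fr - 4)
                 + ln_pgdp*(ln PGDP - mean) + eps
    """

    occupation_intercepts: Mapping[int, float]
    bmi: float
    isei: float
    bmi_isei: float
    edu: float
    married: float
    overweight: float
    underweight: float
    health: float = 0.0
    nb_social: float = 0.0
    fr_social: float = 0.0
    ln_pgdp: float = 0.0


@dataclass(frozen=True)
class SelectionConfig:
    """Probit selection into employment with wage-error correlation rho."""

    enabled: bool = False
    const: float = 2.2
    bmi: float = -0.08
    edu: float = 0.15
    married: float = 0.20
    children: float = -0.25  # excluded from the wage equation
    rho: float = 0.0


@dataclass(frozen=True)
class EndogeneityConfig:
    """Latent confounder loading on BMI (via weight) and on log income."""

    enabled: bool = False
    bmi_loading: float = 1.5
    income_loading: float = 0.15


@dataclass(frozen=True)
class OrdinalOutcome:
    """Proportional-odds latent model for an ordinal survey item.

    latent = over*1[overweight] + under*1[underweight] + logistic error;
    the observed category is 1 + #(thresholds below latent).
    """

    coeffs: Mapping[str, Tuple[float, float]]  # gender -> (over, under)
    thresholds: Tuple[float, ...]

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class GeneratorConfig:
    n: int
    seed: int
    gender_split: float  # proportion female
    anthropometry: Mapping[str, AnthropometryParams]
    occupation_shares: Mapping[str, Mapping[int, float]]
    isei_map: Mapping[int, Tuple[float, float]]
    wage: Mapping[str, WageParams]
    noise_sd: float
    years: Tuple[int, ...] = ALLOWED_YEARS
    n_provinces: int = 30
    province_weight_sd: float = 0.04
    attainment_edu: Mapping[int, float] = field(default_factory=dict)
    attainment_bmi: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    selection: SelectionConfig = SelectionConfig()
    endogeneity: EndogeneityConfig = EndogeneityConfig()
    ordinal_params: Mapping[str, OrdinalOutcome] = field(default_factory=dict)
    shape_quantiles: Tuple[float, float] = (0.30, 0.70)
    edu_probs: Tuple[float, ...] = (0.03, 0.12, 0.33, 0.27, 0.25)
    married_rate: float = 0.75
    migration_rate: float = 0.25
    han_rate: float = 0.92
    union_rate: float = 0.20
    party_rate: float = 0.13
    med_ins_rate: float = 0.90
    children_lambda: float = 0.8

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"n must be positive, got {self.n}")
        if not 0.0 < self.gender_split < 1.0:
            raise ConfigError("gender_split must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if abs(self.selection.rho) >= 1:
            raise ConfigError("|rho| must be < 1")
        if not set(self.years) <= set(ALLOWED_YEARS):
            raise ConfigError(f"years must be within {ALLOWED_YEARS}")
        if self.n_provinces <= 0:
            raise ConfigError("n_provinces must be positive")
        qlo, qhi = self.shape_quantiles
        if not 0.0 < qlo < qhi < 1.0:
            raise ConfigError("shape_quantiles must satisfy 0 < low < high < 1")
        for g in GENDERS:
            a = self.anthropometry[g]
            if a.height_sd <= 0 or a.log_weight_sd <= 0:
                raise ConfigError(f"{g}: anthropometry sds must be positive")
            shares = self.occupation_shares[g]
            if set(shares) != set(OCC_GROUPS):
                raise ConfigError(f"{g}: occupation shares must cover {OCC_GROUPS}")
            total = sum(shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{g}: occupation shares sum to {total}, not 1")
            if any(s < 0 for s in shares.values()):
                raise ConfigError(f"{g}: occupation shares must be nonnegative")
        for occ, (_, sd) in self.isei_map.items():
            if sd <= 0:
                raise ConfigError(f"ISEI sd for occupation {occ} must be positive")
        for name, spec in self.ordinal_params.items():
            t = np.asarray(spec.thresholds, dtype=float)
            if not np.all(np.diff(t) > 0):
                raise ConfigError(f"ordinal thresholds for {name} must increase")


@dataclass
class GroundTruth:
    """Realized generator parameters for parameter-recovery tests."""

    config: GeneratorConfig
    wage: Mapping[str, WageParams]
    bmi_mean: Mapping[str, float]          # per-gender realized sample means
    isei_mean: Mapping[str, float]
    ln_pgdp_mean: float
    shape_cutpoints: Mapping[str, Tuple[float, float]]
    attainment_intercepts: Mapping[str, Dict[int, float]]
    attainment_edu: Mapping[int, float]
    attainment_bmi: Mapping[str, Mapping[int, float]]
    selection: SelectionConfig
    endogeneity: EndogeneityConfig
    province_table: pd.DataFrame

    # canonical wage-regressor order used by cell_design / cell_coefficients
    WAGE_COLUMNS = (
        "const",
        "bmi",
        "isei",
        "bmi_isei_ct",
        "edu",
        "married",
        "overweight",
        "underweight",
        "health_c",
        "nb_social_c",
        "fr_social_c",
        "ln_pgdp_c",
    )

    def cell_design(self, df: pd.DataFrame, gender: str) -> pd.DataFrame:
        """Exact generating design matrix for one gender (any occupation cell).

        Within a single occupation cell, regressing ln income on these
        columns recovers :meth:`cell_coefficients` exactly when noise_sd = 0.
        """
        sub = df[df["gender"] == gender]
        mb, mi = self.bmi_mean[gender], self.isei_mean[gender]
        c_lo, c_hi = self.shape_cutpoints[gender]
        bmi = sub["weight_kg"] / sub["height_m"] ** 2
        X = pd.DataFrame(index=sub.index)
        X["const"] = 1.0
        X["bmi"] = bmi
        X["isei"] = sub["isei"]
        X["bmi_isei_ct"] = (bmi - mb) * (sub["isei"] - mi)
        X["edu"] = sub["edu"]
        X["married"] = sub["married"]
        X["overweight"] = (bmi > c_hi).astype(float)
        X["underweight"] = (bmi < c_lo).astype(float)
        X["health_c"] = sub["health"] - 3.0
        X["nb_social_c"] = sub["nb_social"] - 4.0
        X["fr_social_c"] = sub["fr_social"] - 4.0
        X["ln_pgdp_c"] = sub["ln_pgdp"] - self.ln_pgdp_mean
        return X

    def cell_coefficients(self, gender: str, occ: int) -> pd.Series:
        """True coefficients aligned with :meth:`cell_design` columns."""
        w = self.wage[gender]
        vals = [
            w.occupation_intercepts[occ],
            w.bmi,
            w.isei,
            w.bmi_isei,
            w.edu,
            w.married,
            w.overweight,
            w.underweight,
            w.health,
            w.nb_social,
            w.fr_social,
            w.ln_pgdp,
        ]
        return pd.Series(vals, index=list(self.WAGE_COLUMNS))


# ---------------------------------------------------------------------------
# attainment calibration
# ---------------------------------------------------------------------------

def _calibrate_attainment(
    z: np.ndarray,
    slopes: np.ndarray,
    target: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> np.ndarray:
    """Find multinomial-logit intercepts a such that the sample-average
    choice probabilities equal ``target`` (iterative proportional fitting).

    z: (n, k) covariates; slopes: (k, J); target: (J,) summing to 1.
    Categories with target share 0 get intercept -inf (never chosen).
    """
    J = target.shape[0]
    a = np.where(target > 0, np.log(np.maximum(target, 1e-300)), -np.inf)
    base = z @ slopes  # (n, J)
    for _ in range(max_iter):
        u = base + a
        u -= u.max(axis=1, keepdims=True)
        p = np.exp(u)
        p /= p.sum(axis=1, keepdims=True)
        phat = p.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(target > 0, np.log(target / np.maximum(phat, 1e-300)), 0.0)
        a = a + step
        if np.max(np.abs(step[target > 0])) < tol:
            break
    # normalize against the last positive category for identifiability
    ref = np.max(np.where(target > 0)[0])
    return a - a[ref]


def _choice_probs(z: np.ndarray, slopes: np.ndarray, a: np.ndarray) -> np.ndarray:
    u = z @ slopes + a
    u -= u.max(axis=1, keepdims=True)
    p = np.exp(u)
    p /= p.sum(axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_population(config: GeneratorConfig) -> Tuple[pd.DataFrame, GroundTruth]:
    """Generate ``config.n`` survey records plus the realized ground truth.

    Deterministic in (config, config.seed): identical inputs give
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    # --- province table (regional logged covariates + weight offsets) ---
    P = config.n_provinces
    base_levels = {
        "ln_pgdp": 10.8,
        "ln_pop": 8.2,
        "ln_unemployed": 5.5,
        "ln_benefits": 4.5,
        "ln_consumption": 9.5,
        "ln_health_inst": 8.0,
        "ln_hospitals": 7.5,
        "ln_technicians": 11.0,
    }
    prov = pd.DataFrame({"province": np.arange(P)})
    for col, mu in base_levels.items():
        prov[col] = mu + 0.5 * rng.standard_normal(P)
    prov["weight_offset"] = config.province_weight_sd * rng.standard_normal(P)
    # provinces split into the three macro regions by thirds
    thirds = np.array_split(np.arange(P), 3)
    region_of = np.empty(P, dtype=object)
    for name, idx in zip(("east", "central", "west"), thirds):
        region_of[idx] = name
    prov["region"] = region_of

    # --- individuals ---
    female = rng.random(n) < config.gender_split
    gender = np.where(female, "female", "male")
    year = rng.choice(np.asarray(config.years), size=n)
    province = rng.integers(0, P, size=n)
    age = rng.integers(18, 61, size=n).astype(float)

    height = np.empty(n)
    log_w = np.empty(n)
    for g in GENDERS:
        m = gender == g
        a = config.anthropometry[g]
        height[m] = a.height_mean + a.height_sd * rng.standard_normal(m.sum())
        log_w[m] = a.log_weight_mean + a.log_weight_sd * rng.standard_normal(m.sum())
    height = np.clip(height, 1.30, 2.10)
    weight = np.exp(log_w + prov["weight_offset"].to_numpy()[province])

    # latent confounder: shifts weight so that BMI moves by bmi_loading * c
    confounder = rng.standard_normal(n)
    if config.endogeneity.enabled:
        weight = weight + config.endogeneity.bmi_loading * confounder * height**2
        weight = np.maximum(weight, 25.0)
    bmi = weight / height**2

    edu = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.edu_probs))
    married = (rng.random(n) < config.married_rate).astype(int)
    migration = (rng.random(n) < config.migration_rate).astype(int)
    race = (rng.random(n) < config.han_rate).astype(int)
    union = (rng.random(n) < config.union_rate).astype(int)
    party = (rng.random(n) < config.party_rate).astype(int)
    med_ins = (rng.random(n) < config.med_ins_rate).astype(int)
    children = np.minimum(rng.poisson(config.children_lambda, size=n), 4)
    social_status = 1 + rng.binomial(9, 0.45, size=n)

    # --- occupational attainment (multinomial logit, calibrated shares) ---
    occ = np.empty(n, dtype=int)
    occ_arr = np.asarray(OCC_GROUPS)
    attainment_intercepts: Dict[str, Dict[int, float]] = {}
    bmi_mean: Dict[str, float] = {}
    for g in GENDERS:
        m = gender == g
        bmi_mean[g] = float(bmi[m].mean()) if m.any() else float("nan")
        z = np.column_stack(
            [edu[m] - edu[m].mean(), bmi[m] - bmi[m].mean()]
        )
        slopes = np.column_stack(
            [
                [config.attainment_edu.get(j, 0.0) for j in OCC_GROUPS],
                [config.attainment_bmi.get(g, {}).get(j, 0.0) for j in OCC_GROUPS],
            ]
        ).T  # (2, J)
        target = np.array([config.occupation_shares[g][j] for j in OCC_GROUPS])
        a = _calibrate_attainment(z, slopes, target)
        attainment_intercepts[g] = dict(zip(OCC_GROUPS, a))
        probs = _choice_probs(z, slopes, a)
        cum = probs.cumsum(axis=1)
        draw = rng.random(m.sum())
        occ[m] = occ_arr[(draw[:, None] > cum).sum(axis=1)]

    isei_mu = np.array([config.isei_map[j][0] for j in OCC_GROUPS])
    isei_sd = np.array([config.isei_map[j][1] for j in OCC_GROUPS])
    occ_idx = np.searchsorted(occ_arr, occ)
    isei = np.clip(
        isei_mu[occ_idx] + isei_sd[occ_idx] * rng.standard_normal(n), 16.0, 90.0
    )
    isei_mean = {g: float(isei[gender == g].mean()) for g in GENDERS}

    # --- body-shape classification (definitional 30/70 within gender) ---
    qlo, qhi = config.shape_quantiles
    cutpoints: Dict[str, Tuple[float, float]] = {}
    over = np.zeros(n, dtype=float)
    under = np.zeros(n, dtype=float)
    for g in GENDERS:
        m = gender == g
        if not m.any():
            continue
        c_lo, c_hi = np.quantile(bmi[m], [qlo, qhi])
        cutpoints[g] = (float(c_lo), float(c_hi))
        over[m] = (bmi[m] > c_hi).astype(float)
        under[m] = (bmi[m] < c_lo).astype(float)

    # --- ordinal outcomes (proportional-odds latent) ---
    ordinals: Dict[str, np.ndarray] = {}
    for name, spec in config.ordinal_params.items():
        latent = np.zeros(n)
        for g in GENDERS:
            m = gender == g
            c_over, c_under = spec.coeffs.get(g, (0.0, 0.0))
            latent[m] = c_over * over[m] + c_under * under[m]
        latent = latent + rng.logistic(size=n)
        thr = np.asarray(spec.thresholds, dtype=float)
        ordinals[name] = 1 + np.searchsorted(thr, latent)
    for name, default_cats in (
        ("health", 5),
        ("health_impact", 5),
        ("nb_social", 7),
        ("fr_social", 7),
    ):
        if name not in ordinals:  # neutral midpoint when unspecified
            ordinals[name] = np.full(n, (default_cats + 1) // 2)

    # --- wage equation ---
    ln_pgdp = prov["ln_pgdp"].to_numpy()[province]
    ln_pgdp_mean = float(ln_pgdp.mean())
    if config.selection.enabled:
        rho = config.selection.rho
        u_sel = rng.standard_normal(n)
        eps = config.noise_sd * (
            rho * u_sel + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        )
    else:
        u_sel = np.zeros(n)
        eps = config.noise_sd * rng.standard_normal(n)

    lny = np.empty(n)
    for g in GENDERS:
        m = gender == g
        w = config.wage[g]
        intercepts = np.array([w.occupation_intercepts[j] for j in OCC_GROUPS])
        lny[m] = (
            intercepts[occ_idx[m]]
            + w.bmi * bmi[m]
            + w.isei * isei[m]
            + w.bmi_isei * (bmi[m] - bmi_mean[g]) * (isei[m] - isei_mean[g])
            + w.edu * edu[m]
            + w.married * married[m]
            + w.overweight * over[m]
            + w.underweight * under[m]
            + w.health * (ordinals["health"][m] - 3.0)
            + w.nb_social * (ordinals["nb_social"][m] - 4.0)
            + w.fr_social * (ordinals["fr_social"][m] - 4.0)
            + w.ln_pgdp * (ln_pgdp[m] - ln_pgdp_mean)
        )
    if config.endogeneity.enabled:
        lny = lny + config.endogeneity.income_loading * confounder
    lny = lny + eps

    # --- selection into employment ---
    if config.selection.enabled:
        s = config.selection
        index = (
            s.const
            + s.bmi * bmi
            + s.edu * edu
            + s.married * married
            + s.children * children
            + u_sel
        )
        employed = (index > 0).astype(int)
    else:
        employed = np.ones(n, dtype=int)

    income = np.exp(lny)
    income = np.where(employed == 1, income, np.nan)
    labor_income = income * np.exp(-0.02 + 0.10 * rng.standard_normal(n))

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "gender": gender,
            "year": year,
            "province": province,
            "region": prov["region"].to_numpy()[province],
            "age": age,
            "height_m": height,
            "weight_kg": weight,
            "income_cny": income,
            "labor_income_cny": labor_income,
            "occ_isco1": occ,
            "isei": isei,
            "edu": edu,
            "migration": migration,
            "race": race,
            "married": married,
            "children": children,
            "union": union,
            "party": party,
            "med_ins": med_ins,
            "social_status": social_status,
        }
    )
    for col in REGIONAL_COLUMNS:
        df[col] = prov[col].to_numpy()[province]
    for name in ("health", "health_impact", "nb_social", "fr_social"):
        df[name] = ordinals[name]
    df["employed"] = employed

    truth = GroundTruth(
        config=config,
        wage=config.wage,
        bmi_mean=bmi_mean,
        isei_mean=isei_mean,
        ln_pgdp_mean=ln_pgdp_mean,
        shape_cutpoints=cutpoints,
        attainment_intercepts=attainment_intercepts,
        attainment_edu=dict(config.attainment_edu),
        attainment_bmi={g: dict(config.attainment_bmi.get(g, {})) for g in GENDERS},
        selection=config.selection,
        endogeneity=config.endogeneity,
        province_table=prov,
    )
    return df, truth


# ---------------------------------------------------------------------------
# default configurations
# ---------------------------------------------------------------------------

# Occupation shares per gender (column "All" of the CGSS descriptive table).
_FEMALE_SHARES = {1: 0.0485, 2: 0.1171, 3: 0.0968, 4: 0.1225,
                  5: 0.3294, 7: 0.1095, 8: 0.0740, 9: 0.1022}
_MALE_SHARES = {1: 0.0897, 2: 0.0873, 3: 0.0997, 4: 0.0677,
                5: 0.2080, 7: 0.2002, 8: 0.1417, 9: 0.1057}

_ISEI_MAP = {1: (58.0, 6.0), 2: (65.0, 6.0), 3: (50.0, 6.0), 4: (45.0, 6.0),
             5: (35.0, 6.0), 7: (30.0, 6.0), 8: (31.0, 6.0), 9: (22.0, 6.0)}

_OCC_PREMIUM = {1: 0.45, 2: 0.35, 3: 0.22, 4: 0.10, 5: 0.00,
                7: 0.05, 8: 0.08, 9: -0.25}

_ATTAINMENT_EDU = {1: 0.55, 2: 0.90, 3: 0.55, 4: 0.45, 5: 0.00,
                   7: -0.35, 8: -0.30, 9: -0.70}
# Overweight women shift out of high-rank occupations; overweight men
# shift slightly into managerial/manual-strength groups.
_ATTAINMENT_BMI = {
    "female": {1: -0.02, 2: -0.04, 3: -0.03, 4: -0.02, 5: 0.00,
               7: 0.02, 8: 0.03, 9: 0.04},
    "male": {1: 0.03, 2: 0.00, 3: 0.01, 4: 0.01, 5: 0.00,
             7: -0.01, 8: 0.00, 9: -0.03},
}

_ORDINALS = {
    # health worsens away from normal weight for both genders
    "health": OrdinalOutcome(
        coeffs={"female": (-0.198, -0.106), "male": (-0.171, -0.165)},
        thresholds=(-2.5, -1.2, 0.3, 1.8),
    ),
    "health_impact": OrdinalOutcome(
        coeffs={"female": (-0.043, -0.135), "male": (0.035, -0.147)},
        thresholds=(-2.5, -1.2, 0.3, 1.8),
    ),
    # overweight women socialize more with neighbors; thin men less with friends
    "nb_social": OrdinalOutcome(
        coeffs={"female": (0.077, -0.091), "male": (-0.014, 0.017)},
        thresholds=(-2.0, -1.2, -0.5, 0.2, 0.9, 1.7),
    ),
    "fr_social": OrdinalOutcome(
        coeffs={"female": (-0.066, 0.040), "male": (0.068, -0.112)},
        thresholds=(-2.0, -1.2, -0.5, 0.2, 0.9, 1.7),
    ),
}


def _wage_params(
    base: float,
    bmi: float,
    bmi_isei: float,
    over: float,
    under: float,
    health: float,
    nb: float,
    fr: float,
) -> WageParams:
    return WageParams(
        occupation_intercepts={j: base + _OCC_PREMIUM[j] for j in OCC_GROUPS},
        bmi=bmi,
        isei=0.010,
        bmi_isei=bmi_isei,
        edu=0.08,
        married=0.05,
        overweight=over,
        underweight=under,
        health=health,
        nb_social=nb,
        fr_social=fr,
        ln_pgdp=0.10,
    )


def default_paperlike_config(n: int = 30_000, seed: int = 0) -> GeneratorConfig:
    """Study-condition defaults.

    Anthropometry targets the CGSS descriptive means (female 1.60 m /
    55.34 kg, male 1.71 m / 66.16 kg), occupation shares the published
    per-gender structure, and the wage equation carries the published sign
    pattern: BMI coefficient -0.010 for women and +0.017 for men, with a
    negative centered BMI x ISEI interaction for both genders.
    """
    anthropometry = {
        # log-normal weight: E[W] = exp(mu + sd^2/2)
        "female": AnthropometryParams(1.60, 0.055, float(np.log(55.34) - 0.145**2 / 2), 0.145),
        "male": AnthropometryParams(1.71, 0.060, float(np.log(66.16) - 0.150**2 / 2), 0.150),
    }
    # continuous BMI gradient (published main-model specification); the
    # overweight/underweight wage shifts are zero here and exercised by
    # decomposition_demo_config instead
    wage = {
        "female": _wage_params(
            9.45, -0.010, -0.00046, over=0.0, under=0.0,
            health=0.06, nb=-0.03, fr=0.0,
        ),
        "male": _wage_params(
            9.20, 0.017, -0.00019, over=0.0, under=0.0,
            health=0.07, nb=0.0, fr=0.05,
        ),
    }
    return GeneratorConfig(
        n=n,
        seed=seed,
        gender_split=0.48,
        anthropometry=anthropometry,
        occupation_shares={"female": _FEMALE_SHARES, "male": _MALE_SHARES},
        isei_map=_ISEI_MAP,
        wage=wage,
        noise_sd=0.70,
        attainment_edu=_ATTAINMENT_EDU,
        attainment_bmi=_ATTAINMENT_BMI,
        ordinal_params=_ORDINALS,
    )


def decomposition_demo_config(n: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """Paper-like config whose wage truth is spanned by the decomposition
    covariates (bmi, isei, edu, married) plus the body-shape wage shifts:
    interaction, pathway and regional loadings are zeroed so the analytic
    oracle is exact, and the overweight/underweight shifts are nonzero so
    the coefficient part of the gap has a nonzero truth."""
    cfg = default_paperlike_config(n=n, seed=seed)
    shape = {"female": (-0.06, -0.01), "male": (0.03, -0.10)}
    wage = {
        g: dataclasses.replace(
            cfg.wage[g], bmi_isei=0.0, health=0.0, nb_social=0.0,
            fr_social=0.0, ln_pgdp=0.0,
            overweight=shape[g][0], underweight=shape[g][1],
        )
        for g in GENDERS
    }
    return dataclasses.replace(cfg, wage=wage)


def recovery_demo_config(n: int = 20_000, seed: int = 0) -> GeneratorConfig:
    """Paper-like config with every side channel of the BMI -> income
    effect switched off (no attainment-BMI sorting, no interaction, no
    health/socialization or regional loadings), so the OLS estimand for
    the BMI coefficient equals the configured truth (-0.010 women,
    +0.017 men) exactly."""
    cfg = default_paperlike_config(n=n, seed=seed)
    wage = {
        g: dataclasses.replace(
            cfg.wage[g], bmi_isei=0.0, health=0.0, nb_social=0.0,
            fr_social=0.0, ln_pgdp=0.0,
        )
        for g in GENDERS
    }
    return dataclasses.replace(
        cfg, wage=wage, attainment_bmi={g: {} for g in GENDERS}
    )


def endogeneity_demo_config(
    n: int = 5_000, seed: int = 0, n_provinces: int = 10
) -> GeneratorConfig:
    """Config with the BMI-endogeneity mechanism on and occupational
    attainment independent of BMI, so the cell-mean instrument's only
    income channel is BMI itself (regional covariates are controlled)."""
    cfg = default_paperlike_config(n=n, seed=seed)
    wage = {
        g: dataclasses.replace(cfg.wage[g], ln_pgdp=0.0) for g in GENDERS
    }
    return dataclasses.replace(
        cfg,
        n_provinces=n_provinces,
        province_weight_sd=0.06,
        attainment_bmi={g: {} for g in GENDERS},
        endogeneity=EndogeneityConfig(enabled=True),
        wage=wage,
    )


def selection_demo_config(
    n: int = 5_000, seed: int = 0, rho: float = 0.6
) -> GeneratorConfig:
    """Config with probit selection into employment (index includes BMI,
    `children` excluded from the wage equation) and error correlation rho;
    attainment is independent of BMI so omitted occupation premia do not
    contaminate the BMI-coefficient bias comparison."""
    cfg = default_paperlike_config(n=n, seed=seed)
    return dataclasses.replace(
        cfg,
        attainment_bmi={g: {} for g in GENDERS},
        selection=SelectionConfig(enabled=True, rho=rho),
    )


# ---------------------------------------------------------------------------
# analytic oracle for the income-gap decomposition
# ---------------------------------------------------------------------------

ORACLE_COVARIATES: Tuple[str, ...] = ("bmi", "isei", "edu", "married")


def oracle_decomposition(
    config: GeneratorConfig,
    gender: str,
    comparison: str = "overweight",
    n_oracle: int = 400_000,
    seed: int = 12345,
):
    """Ground-truth decomposition computed from the generator's parameters.

    Uses the *true* within-occupation wage coefficients and the *true*
    attainment model evaluated on a large simulated covariate draw (so the
    only error is Monte-Carlo in the covariate averages, shrinking as
    n_oracle grows).  Requires a config whose wage truth is spanned by
    (bmi, isei, edu, married) plus the body-shape shifts — see
    :func:`decomposition_demo_config`.
    """
    from . import decomposition as dec

    for g in GENDERS:
        w = config.wage[g]
        if any((w.bmi_isei, w.health, w.nb_social, w.fr_social, w.ln_pgdp)):
            raise ValueError(
                "oracle requires wage truth spanned by the decomposition "
                "covariates; use decomposition_demo_config()"
            )
    if config.selection.enabled or config.endogeneity.enabled:
        raise ValueError("oracle requires selection and endogeneity off")

    big = dataclasses.replace(config, n=n_oracle, seed=seed)
    df, truth = generate_population(big)
    sub = df[df["gender"] == gender].copy()
    bmi = sub["weight_kg"] / sub["height_m"] ** 2
    c_lo, c_hi = truth.shape_cutpoints[gender]
    label = np.where(bmi > c_hi, "overweight",
                     np.where(bmi < c_lo, "underweight", "normal"))
    sub["bmi"] = bmi
    sub["body_shape"] = label

    w = config.wage[gender]
    shift = {"normal": 0.0, "overweight": w.overweight, "underweight": w.underweight}

    def group_stats(name: str) -> dec.OccupationGroupStats:
        grp = sub[sub["body_shape"] == name]
        shares, xbars, betas, means = {}, {}, {}, {}
        for j in OCC_GROUPS:
            cell = grp[grp["occ_isco1"] == j]
            shares[j] = len(cell) / len(grp)
            xbar = pd.Series(
                [1.0] + [cell[c].mean() for c in ORACLE_COVARIATES],
                index=["const", *ORACLE_COVARIATES],
            )
            beta = pd.Series(
                [w.occupation_intercepts[j] + shift[name],
                 w.bmi, w.isei, w.edu, w.married],
                index=["const", *ORACLE_COVARIATES],
            )
            xbars[j], betas[j] = xbar, beta
            means[j] = float(xbar @ beta)
        return dec.OccupationGroupStats(
            occupations=list(OCC_GROUPS),
            shares=pd.Series(shares),
            xbar=pd.DataFrame(xbars).T,
            beta=pd.DataFrame(betas).T,
            mean_lny=pd.Series(means),
        )

    stats_n = group_stats("normal")
    stats_o = group_stats(comparison)

    # true attainment probabilities averaged over the comparison group
    comp = sub[sub["body_shape"] == comparison]
    z = np.column_stack(
        [
            comp["edu"].to_numpy()
            - df.loc[df["gender"] == gender, "edu"].mean(),
            comp["bmi"].to_numpy() - truth.bmi_mean[gender],
        ]
    )
    slopes = np.column_stack(
        [
            [truth.attainment_edu.get(j, 0.0) for j in OCC_GROUPS],
            [truth.attainment_bmi[gender].get(j, 0.0) for j in OCC_GROUPS],
        ]
    ).T
    a = np.array([truth.attainment_intercepts[gender][j] for j in OCC_GROUPS])
    probs = _choice_probs(z, slopes, a).mean(axis=0)
    counterfactual = dec.CounterfactualStructure(
        shares=pd.Series(probs, index=list(OCC_GROUPS)), model=None
    )
    return dec.brown_decompose(stats_n, stats_o, counterfactual)
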