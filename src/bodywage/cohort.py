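"""Cohort construction: filters, BMI, body-shape classes, instrument.

Turns raw survey microdata (one row per respondent, CSV schema of
:mod:`bodywage.synthetic`) into the analysis cohort used by the wage models
and the income-gap decomposition:

* sample restrictions — working-age 18–60, BMI within (10, 40), income
  top-coded at CNY 1,000,000, soldiers (ISCO 0) and farmers (ISCO 6)
  excluded — applied in that order, with an exclusion log;
* gender-specific BMI quantile classification into underweight / normal /
  overweight (30/70 by default, 20/80 as the robustness variant);
* the cell-mean BMI instrument: the mean BMI of the respondent's
  (gender, province, occupation) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FilterRules",
    "BodyShapeThresholds",
    "InstrumentTable",
    "compute_bmi",
    "apply_sample_filters",
    "classify_body_shape",
    "build_instrument",
    "prepare_cohort",
]

logger = logging.getLogger(__name__)

EXCLUDED_OCCUPATIONS: Tuple[int, ...] = (0, 6)  # soldiers, agricultural workers


@dataclass(frozen=True)
class FilterRules:
    """Sample restrictions, applied in declaration order."""

    age_min: float = 18.0
    age_max: float = 60.0
    bmi_min: float = 10.0
    bmi_max: float = 40.0
    income_cap: float = 1_000_000.0
    excluded_occupations: Tuple[int, ...] = EXCLUDED_OCCUPATIONS


@dataclass(frozen=True)
class BodyShapeThresholds:
    """Gender-specific BMI cutpoints from empirical quantiles."""

    gender: str
    q_low: float
    q_high: float
    c_low: float
    c_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.q_low < self.q_high < 1.0:
            raise ValueError("quantile probabilities must satisfy 0 < low < high < 1")
        if self.c_low > self.c_high:
            raise ValueError("c_low must not exceed c_high")

    def label(self, bmi: float) -> str:
        if bmi < self.c_low:
            return "underweight"
        if bmi > self.c_high:
            return "overweight"
        return "normal"  # closed interval [c_low, c_high]


@dataclass
class InstrumentTable:
    """Cell-mean BMI per (gender, province, occupation) cell."""

    cells: pd.DataFrame  # columns: gender, province, occ_isco1, mean_bmi, n
    singleton_cells: pd.DataFrame = field(default_factory=pd.DataFrame)


def compute_bmi(weight: float, height: float):
    """BMI in kg/m^2 from weight (kg) and height (m).

    Accepts scalars or array-likes; nonpositive inputs raise ValueError.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w[~np.isnan(w)] <= 0) or np.any(h[~np.isnan(h)] <= 0):
        raise ValueError("weight and height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def apply_sample_filters(
    records: pd.DataFrame,
    rules: FilterRules = FilterRules(),
    income_col: str = "income_cny",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sample restrictions; return (filtered table, exclusion log).

    Order: age window -> BMI window (missing BMI dropped) -> income
    top-coding (records kept, values capped) -> occupation exclusion.
    The log counts removals (or, for top-coding, capped records) per rule.
    Filtering is idempotent.
    """
    df = records.copy()
    log_rows = []

    n0 = len(df)
    keep = (df["age"] >= rules.age_min) & (df["age"] <= rules.age_max)
    df = df[keep]
    log_rows.append(("age_window", n0 - len(df)))

    if "bmi" in df.columns:
        bmi = df["bmi"]
    else:
        bmi = df["weight_kg"] / df["height_m"] ** 2
    n0 = len(df)
    keep = bmi.notna() & (bmi >= rules.bmi_min) & (bmi <= rules.bmi_max)
    df = df[keep]
    log_rows.append(("bmi_window", n0 - len(df)))

    capped = int((df[income_col] > rules.income_cap).sum())
    df = df.copy()
    df.loc[df[income_col] > rules.income_cap, income_col] = rules.income_cap
    log_rows.append(("income_top_code", capped))

    n0 = len(df)
    df = df[~df["occ_isco1"].isin(rules.excluded_occupations)]
    log_rows.append(("occupation_exclusion", n0 - len(df)))

    log = pd.DataFrame(log_rows, columns=["rule", "n_removed"])
    return df, log


def classify_body_shape(
    bmi: pd.Series,
    gender: pd.Series,
    q_low: float = 0.30,
    q_high: float = 0.70,
) -> Tuple[pd.Series, Dict[str, BodyShapeThresholds]]:
    """Label each record underweight/normal/overweight within gender.

    Cutpoints are the empirical (q_low, q_high) quantiles of BMI computed
    separately per gender (linear interpolation between order statistics);
    ties at a cutpoint classify as normal.  Missing BMI values are ignored
    for quantile computation and labelled NaN.
    """
    if not 0.0 < q_low < q_high < 1.0:
        raise ValueError("require 0 < q_low < q_high < 1")
    labels = pd.Series(pd.NA, index=bmi.index, dtype="object")
    thresholds: Dict[str, BodyShapeThresholds] = {}
    for g in pd.unique(gender.dropna()):
        m = (gender == g) & bmi.notna()
        if m.sum() < 3:
            logger.warning("gender %s has <3 BMI values; skipped", g)
            continue
        c_low, c_high = np.quantile(bmi[m].to_numpy(), [q_low, q_high])
        thr = BodyShapeThresholds(str(g), q_low, q_high, float(c_low), float(c_high))
        thresholds[str(g)] = thr
        vals = bmi[m]
        lab = np.where(
            vals < thr.c_low,
            "underweight",
            np.where(vals > thr.c_high, "overweight", "normal"),
        )
        labels.loc[m] = lab
    return labels, thresholds


def build_instrument(
    records: pd.DataFrame,
    leave_one_out: bool = False,
) -> Tuple[InstrumentTable, pd.Series]:
    """Cell-mean BMI instrument over (gender, province, occupation) cells.

    Each record's instrument is the mean BMI of its cell, the respondent's
    own BMI included by default (``leave_one_out=True`` removes it, which
    requires cell size >= 2).  Records with a missing cell key get NaN and
    a logged warning; singleton cells are flagged in the table.
    """
    keys = ["gender", "province", "occ_isco1"]
    bmi = records["bmi"] if "bmi" in records else records["weight_kg"] / records["height_m"] ** 2
    valid = records[keys].notna().all(axis=1) & bmi.notna()
    if (~valid).any():
        logger.warning(
            "%d records missing instrument cell keys; excluded", int((~valid).sum())
        )
    work = records.loc[valid, keys].copy()
    work["bmi"] = bmi[valid]

    grouped = work.groupby(keys)["bmi"]
    cells = grouped.agg(mean_bmi="mean", n="size").reset_index()
    if leave_one_out:
        cell_sum = grouped.transform("sum")
        cell_n = grouped.transform("size")
        if (cell_n < 2).any():
            raise ValueError("leave-one-out instrument needs cell sizes >= 2")
        per_record = (cell_sum - work["bmi"]) / (cell_n - 1)
    else:
        per_record = grouped.transform("mean")

    instrument = pd.Series(np.nan, index=records.index, name="bmi_instrument")
    instrument.loc[valid] = per_record
    table = InstrumentTable(cells=cells, singleton_cells=cells[cells["n"] == 1])
    return table, instrument


def prepare_cohort(
    records: pd.DataFrame,
    rules: FilterRules = FilterRules(),
    q_low: float = 0.30,
    q_high: float = 0.70,
    income_col: str = "income_cny",
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, BodyShapeThresholds]]:
    """Full preparation: filters, derived variables, labels, instrument.

    Returns (cohort, exclusion log, per-gender thresholds).  Derived
    columns: ``bmi``, ``ln_income``, ``ln_age``, ``body_shape``,
    ``bmi_instrument``.  Records without observed positive income (e.g.
    not employed) are dropped before taking logs, and the drop is logged.
    """
    df = records.copy()
    df["bmi"] = compute_bmi(df["weight_kg"], df["height_m"])
    df, log = apply_sample_filters(df, rules, income_col=income_col)

    n0 = len(df)
    df = df[df[income_col].notna() & (df[income_col] > 0)]
    log = pd.concat(
        [log, pd.DataFrame([("nonpositive_income", n0 - len(df))],
                           columns=["rule", "n_removed"])],
        ignore_index=True,
    )

    df = df.copy()
    df["ln_income"] = np.log(df[income_col])
    df["ln_age"] = np.log(df["age"])
    labels, thresholds = classify_body_shape(df["bmi"], df["gender"], q_low, q_high)
    df["body_shape"] = labels
    _, instrument = build_instrument(df)
    df["bmi_instrument"] = instrument
    return df, log, thresholds
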