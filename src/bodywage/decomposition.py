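"""Brown-style decomposition of the mean log-income gap between body-shape
groups, with a multinomial-logit counterfactual occupational structure.

For a reference group N (normal weight) and comparison group O (overweight
or underweight) within one gender, with occupations j = 1..8:

    I_N - I_O = sum_j [ P_jO * Xbar_jO (b_jN - b_jO)        Part (1)
                      + P_jO * (Xbar_jN - Xbar_jO) b_jN     Part (2)
                      + (P_jN - Phat_jO) * Ibar_jN          Part (4)
                      + (Phat_jO - P_jO) * Ibar_jN ]        Part (5)

where P_jg are occupation shares, Xbar_jg covariate means (with intercept),
b_jg within-cell OLS coefficients, Ibar_jg mean log income, and Phat_jO the
counterfactual occupational structure: the comparison group's predicted
shares under the reference group's multinomial-logit attainment
coefficients.  Parts (1)-(2) are within-occupation coefficient and
endowment gaps; Parts (4)-(5) split the between-occupation structural gap
Part (3) = (P_jN - P_jO) * Ibar_jN into the component due to covariates and
the component due to attainment coefficients.

The decomposition is exactly additive whenever each cell satisfies the
OLS-with-intercept identity Ibar_jg = Xbar_jg . b_jg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import build_design

__all__ = [
    "OccupationGroupStats",
    "CounterfactualStructure",
    "DecompositionTable",
    "fit_within_occupation_models",
    "counterfactual_structure",
    "brown_decompose",
    "decomposition_report",
    "aggregate_parts",
    "REFERENCE_DECOMPOSITION_PARTS",
    "REFERENCE_TOTALS",
]

logger = logging.getLogger(__name__)

PART_COLUMNS = ("part1", "part2", "part4", "part5")


@dataclass
class OccupationGroupStats:
    """Per-occupation statistics for one body-shape group.

    shares, mean_lny indexed by occupation; xbar and beta are occupation x
    (const + covariates) frames.  The OLS identity mean_lny = xbar . beta
    holds for every fitted cell.
    """

    occupations: List[int]
    shares: pd.Series
    xbar: pd.DataFrame
    beta: pd.DataFrame
    mean_lny: pd.Series
    flags: Dict[int, str] = field(default_factory=dict)

    def validate(self) -> None:
        if abs(self.shares.sum() - 1.0) > 1e-9:
            raise ValueError(f"shares sum to {self.shares.sum()}, not 1")
        if (self.shares < 0).any():
            raise ValueError("shares must be nonnegative")
        implied = (self.xbar * self.beta).sum(axis=1)
        gap = (implied - self.mean_lny).abs().max()
        if gap > 1e-6:
            raise ValueError(
                f"OLS identity violated: max |Xbar.beta - mean ln y| = {gap:.2e}"
            )


@dataclass
class CounterfactualStructure:
    """Counterfactual occupation shares Phat_jO and the attainment model."""

    shares: pd.Series
    model: Optional[object] = None

    def validate(self) -> None:
        if abs(self.shares.sum() - 1.0) > 1e-9:
            raise ValueError("counterfactual shares must sum to 1")
        if ((self.shares < -1e-12) | (self.shares > 1 + 1e-12)).any():
            raise ValueError("counterfactual shares must lie in [0, 1]")


@dataclass
class DecompositionTable:
    """Per-occupation parts, totals and percentage shares."""

    parts: pd.DataFrame          # occupation x (part1, part2, part4, part5, total)
    column_totals: pd.Series     # part1, part2, part4, part5, total
    total_gap: float             # Ibar_N - Ibar_O
    percentages: pd.Series       # column total / decomposed total * 100
    flags: Dict[int, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# stage 1: within-occupation OLS statistics
# ---------------------------------------------------------------------------

def fit_within_occupation_models(
    records: pd.DataFrame,
    covariates: Sequence[str],
    occupations: Sequence[int],
    occ_col: str = "occ_isco1",
    y_col: str = "ln_income",
    min_cell: int = 30,
    pooled_fallback: bool = True,
) -> OccupationGroupStats:
    """Shares, covariate means, within-cell OLS coefficients and mean log
    income for every occupation cell of one body-shape group.

    Cells with fewer than ``min_cell`` rows (or fewer rows than regressors
    + 2) are flagged; their coefficients fall back to the group's pooled
    OLS fit when ``pooled_fallback`` (the cell's own Xbar and mean income
    are then adjusted to preserve the OLS identity via the pooled residual
    mean, i.e. mean_lny is kept equal to Xbar.beta by construction of the
    pooled fit on the cell -- see note), else raise.

    Note: with a pooled-coefficient fallback the per-cell identity
    mean_lny = Xbar.beta no longer holds automatically; to preserve exact
    additivity the fallback re-centers the pooled intercept on the cell so
    that the identity holds by construction.
    """
    df = records.dropna(subset=[y_col, occ_col, *covariates])
    n_total = len(df)
    if n_total == 0:
        raise ValueError("no usable records for this group")

    pooled_beta = None
    shares, xbars, betas, means = {}, {}, {}, {}
    flags: Dict[int, str] = {}
    cols = ["const", *covariates]

    for j in occupations:
        cell = df[df[occ_col] == j]
        shares[j] = len(cell) / n_total
        if len(cell) == 0:
            flags[j] = "empty"
            xbars[j] = pd.Series(0.0, index=cols)
            betas[j] = pd.Series(0.0, index=cols)
            means[j] = 0.0
            continue
        X, _ = build_design(cell, covariates)
        X = X.reindex(columns=cols, fill_value=0.0)
        y = cell[y_col].to_numpy(dtype=float)
        xbar = X.mean(axis=0)
        if len(cell) >= max(min_cell, X.shape[1]) and np.linalg.matrix_rank(
            X.to_numpy()
        ) == X.shape[1]:
            beta = pd.Series(
                np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0], index=cols
            )
        else:
            flags[j] = f"undersized_cell(n={len(cell)})"
            if not pooled_fallback:
                raise ValueError(f"occupation {j}: undersized cell ({len(cell)})")
            if pooled_beta is None:
                Xp, _ = build_design(df, covariates)
                Xp = Xp.reindex(columns=cols, fill_value=0.0)
                pooled_beta = pd.Series(
                    np.linalg.lstsq(
                        Xp.to_numpy(), df[y_col].to_numpy(dtype=float), rcond=None
                    )[0],
                    index=cols,
                )
            beta = pooled_beta.copy()
            # re-center intercept so the per-cell OLS identity holds exactly
            beta["const"] += float(y.mean() - xbar @ beta)
        xbars[j] = xbar
        betas[j] = beta
        means[j] = float(y.mean())

    stats = OccupationGroupStats(
        occupations=list(occupations),
        shares=pd.Series(shares),
        xbar=pd.DataFrame(xbars).T.reindex(columns=cols),
        beta=pd.DataFrame(betas).T.reindex(columns=cols),
        mean_lny=pd.Series(means),
        flags=flags,
    )
    stats.validate()
    return stats


# ---------------------------------------------------------------------------
# stage 2: counterfactual occupational structure
# ---------------------------------------------------------------------------

def counterfactual_structure(
    reference_records: pd.DataFrame,
    comparison_records: pd.DataFrame,
    covariates: Sequence[str],
    occupations: Sequence[int],
    occ_col: str = "occ_isco1",
) -> CounterfactualStructure:
    """Comparison group's predicted occupation shares under the reference
    group's attainment coefficients.

    A multinomial logit of occupation on the covariates is fitted on the
    reference group; its per-row predicted probabilities on the comparison
    group are averaged into Phat_jO.  Occupations missing from the
    reference group are flagged (their counterfactual share is 0).
    """
    ref = reference_records.dropna(subset=[occ_col, *covariates])
    comp = comparison_records.dropna(subset=list(covariates))
    present = np.sort(ref[occ_col].unique())
    missing = [j for j in occupations if j not in present]
    if missing:
        logger.warning("occupations %s absent from reference group", missing)

    codes = pd.Categorical(ref[occ_col], categories=present).codes
    Xr, _ = build_design(ref, covariates)
    model = sm.MNLogit(codes, Xr.to_numpy())
    res = model.fit(method="newton", maxiter=200, disp=0)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("multinomial logit did not converge")

    Xc, _ = build_design(comp, covariates)
    Xc = Xc.reindex(columns=Xr.columns, fill_value=0.0)
    # warn when comparison covariates leave the reference support
    for c in covariates:
        lo, hi = ref[c].min(), ref[c].max()
        if (comp[c] < lo).any() or (comp[c] > hi).any():
            logger.warning("covariate %s outside reference support", c)
    probs = res.predict(Xc.to_numpy())
    avg = probs.mean(axis=0)
    shares = pd.Series(0.0, index=list(occupations))
    for k, j in enumerate(present):
        if j in shares.index:
            shares[j] = avg[k]
    out = CounterfactualStructure(shares=shares, model=res)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# stage 3: the decomposition arithmetic
# ---------------------------------------------------------------------------

def brown_decompose(
    stats_n: OccupationGroupStats,
    stats_o: OccupationGroupStats,
    counterfactual: CounterfactualStructure,
) -> DecompositionTable:
    """Assemble the four-part decomposition table from group statistics."""
    if list(stats_n.occupations) != list(stats_o.occupations):
        raise ValueError("occupation sets of the two groups differ")
    stats_n.validate()
    stats_o.validate()
    counterfactual.validate()

    occ = list(stats_n.occupations)
    rows = []
    for j in occ:
        p_n, p_o = stats_n.shares[j], stats_o.shares[j]
        p_hat = counterfactual.shares[j]
        xbar_n, xbar_o = stats_n.xbar.loc[j], stats_o.xbar.loc[j]
        b_n, b_o = stats_n.beta.loc[j], stats_o.beta.loc[j]
        i_n = stats_n.mean_lny[j]
        part1 = p_o * float(xbar_o @ (b_n - b_o))
        part2 = p_o * float((xbar_n - xbar_o) @ b_n)
        part4 = (p_n - p_hat) * i_n
        part5 = (p_hat - p_o) * i_n
        rows.append((j, part1, part2, part4, part5))
    parts = pd.DataFrame(
        rows, columns=["occupation", *PART_COLUMNS]
    ).set_index("occupation")
    parts["total"] = parts.sum(axis=1)

    column_totals = parts.sum(axis=0)
    ibar_n = float((stats_n.shares * stats_n.mean_lny).sum())
    ibar_o = float((stats_o.shares * stats_o.mean_lny).sum())
    total_gap = ibar_n - ibar_o
    decomposed = float(column_totals["total"])
    denom = decomposed if decomposed != 0 else np.nan
    percentages = column_totals[list(PART_COLUMNS)] / denom * 100.0

    flags = {**stats_n.flags}
    for j, f in stats_o.flags.items():
        flags[j] = f"{flags.get(j, '')};{f}".strip(";")
    return DecompositionTable(
        parts=parts,
        column_totals=column_totals,
        total_gap=total_gap,
        percentages=percentages,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

OCCUPATION_NAMES = {
    1: "Managers",
    2: "Professionals",
    3: "Technicians and associate professionals",
    4: "Clerical support workers",
    5: "Services and sales workers",
    7: "Craft and related trades workers",
    8: "Plant and machine operators and assemblers",
    9: "Elementary occupations",
}


def aggregate_parts(parts: pd.DataFrame) -> Tuple[pd.Series, pd.Series, float]:
    """Column totals, per-occupation row totals and the decomposed total
    from a table of per-occupation part values (columns part1, part2,
    part4, part5).  Used both on computed tables and on printed reference
    part values."""
    p = parts[list(PART_COLUMNS)]
    row_totals = p.sum(axis=1)
    column_totals = p.sum(axis=0)
    return column_totals, row_totals, float(row_totals.sum())


def percentage_shares(column_totals: pd.Series, denominator: float) -> pd.Series:
    """Part shares of the income gap, in percent."""
    return column_totals[list(PART_COLUMNS)] / denominator * 100.0


def decomposition_report(
    table: DecompositionTable,
    part_decimals: int = 3,
    pct_decimals: int = 2,
) -> pd.DataFrame:
    """Formatted per-occupation rows plus Total and Percentage rows.

    Percentages are computed from unrounded totals; rounding applies only
    at this reporting step.
    """
    body = table.parts.copy()
    body.index = [OCCUPATION_NAMES.get(j, str(j)) for j in body.index]
    out = body.round(part_decimals)
    out.loc["Total"] = table.column_totals.round(part_decimals)
    pct = table.percentages.round(pct_decimals)
    pct_row = {c: pct.get(c, np.nan) for c in out.columns}
    pct_row["total"] = np.nan
    out.loc["Percentage"] = pd.Series(pct_row)
    return out


# ---------------------------------------------------------------------------
# published reference values (CGSS 2010-2017 body-shape income-gap analysis)
# ---------------------------------------------------------------------------

def _ref(parts_rows) -> pd.DataFrame:
    return pd.DataFrame(
        parts_rows,
        columns=["occupation", *PART_COLUMNS],
    ).set_index("occupation")


#: Published per-occupation part values, used to validate the aggregation
#: arithmetic (row totals are exact; column totals match within the
#: rounding of the 3-decimal printed inputs).
REFERENCE_DECOMPOSITION_PARTS: Dict[str, pd.DataFrame] = {
    # normal-weight vs overweight women
    "female_normal_overweight": _ref(
        [
            (1, 0.005, 0.001, 0.021, 0.047),
            (2, 0.010, -0.001, 0.341, 0.151),
            (3, 0.006, 0.000, 0.121, -0.116),
            (4, 0.008, 0.012, 0.172, 0.020),
            (5, 0.016, 0.026, 0.009, 0.081),
            (7, 0.004, 0.002, -0.176, -0.067),
            (8, -0.006, 0.004, -0.147, -0.081),
            (9, 0.000, -0.006, -0.286, -0.025),
        ]
    ),
    # normal-weight vs overweight men
    "male_normal_overweight": _ref(
        [
            (1, -0.009, 0.004, -0.048, -0.236),
            (2, -0.003, -0.007, -0.082, 0.060),
            (3, -0.004, 0.005, -0.075, -0.060),
            (4, 0.006, 0.003, -0.095, 0.060),
            (5, -0.014, -0.001, 0.059, -0.111),
            (7, -0.002, -0.006, 0.094, 0.324),
            (8, -0.008, -0.007, 0.003, -0.187),
            (9, 0.000, -0.004, 0.104, 0.145),
        ]
    ),
    # normal-weight vs underweight men
    "male_normal_underweight": _ref(
        [
            (1, 0.005, 0.011, -0.503, 0.616),
            (2, -0.006, 0.016, 0.313, -0.299),
            (3, 0.003, 0.017, 0.300, -0.247),
            (4, 0.001, 0.007, 0.252, -0.071),
            (5, 0.018, 0.035, 0.408, -0.407),
            (7, 0.017, 0.032, 0.395, -0.729),
            (8, -0.017, 0.036, -1.397, 1.347),
            (9, 0.002, 0.014, 0.229, -0.186),
        ]
    ),
}

#: Published column totals (part1, part2, part4, part5, total) per panel.
REFERENCE_TOTALS: Dict[str, pd.Series] = {
    "female_normal_overweight": pd.Series(
        {"part1": 0.042, "part2": 0.039, "part4": 0.054, "part5": 0.011, "total": 0.145}
    ),
    "male_normal_overweight": pd.Series(
        {"part1": -0.034, "part2": -0.014, "part4": -0.039, "part5": -0.005, "total": -0.092}
    ),
    "male_normal_underweight": pd.Series(
        {"part1": 0.023, "part2": 0.167, "part4": -0.003, "part5": 0.023, "total": 0.210}
    ),
}
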