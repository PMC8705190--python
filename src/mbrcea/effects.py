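"""Treatment-effect estimators.

* Collapsed-period difference-in-differences (DiD) regression for cost
  outcomes: each participant contributes one baseline and one follow-up
  value, and the model Y = b0 + b1*Period + b2*Treatment + b3*Period*Treatment
  is fit by OLS with cluster-robust standard errors by participant.  The
  interaction coefficient b3 is the average treatment effect on the treated
  (ATT) and equals the four-cell-mean arithmetic identity exactly.
* One-sided ANCOVA for the questionnaire outcomes (six-month sick days,
  EQ-5D utility): follow-up regressed on baseline and arm.
* A parallel-trend check over the extended pre-index window: per-quarter arm
  means regressed on quarter with an arm x quarter interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import COST_COLUMNS, GCPS_ORDER
from .exceptions import CohortValidationError, ConfigError, DataCompletenessError

logger = logging.getLogger(__name__)

#: significance ladder used in printed reports
def significance_marker(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "†"
    return ""


@dataclass
class DiDEstimate:
    outcome: str
    att: float
    se: float
    p_value: float
    n_treated: int
    n_control: int
    period_means: pd.DataFrame  # rows: arm, cols: baseline / followup


@dataclass
class AncovaEstimate:
    outcome: str
    effect: float
    se: float
    p_one_sided: float
    p_two_sided: float
    adjusted_means: dict


@dataclass
class TrendCheck:
    slope_treated: float
    slope_control: float
    slope_difference: float
    se: float
    p_value: float
    n_quarters: int
    series: pd.DataFrame  # per-quarter arm means, for plotting


def did_point_estimate(mean_t_base: float, mean_t_follow: float,
                       mean_c_base: float, mean_c_follow: float) -> float:
    """Four-cell difference-in-differences:
    (T_follow - T_base) - (C_follow - C_base)."""
    return (mean_t_follow - mean_t_base) - (mean_c_follow - mean_c_base)


def did_regression(aggregates: pd.DataFrame, arms: pd.Series,
                   cluster_robust: bool = True) -> DiDEstimate:
    """OLS DiD on the collapsed two-period table.

    ``aggregates`` holds one row per participant with ``baseline_sum`` and
    ``followup_sum`` for a single outcome (see
    :func:`mbrcea.cohort.aggregate_periods`); ``arms`` maps participant_id
    to arm.  Standard errors are cluster-robust by participant by default.
    """
    agg = aggregates.copy()
    if agg["outcome"].nunique() != 1:
        raise ConfigError("did_regression expects aggregates for a single outcome")
    if agg[["baseline_sum", "followup_sum"]].isna().any().any():
        bad = agg.loc[
            agg[["baseline_sum", "followup_sum"]].isna().any(axis=1),
            "participant_id",
        ]
        raise DataCompletenessError(
            f"participants missing a period value: {list(bad)[:5]}"
        )
    outcome = agg["outcome"].iloc[0]
    agg["arm"] = agg["participant_id"].map(arms)
    if agg["arm"].isna().any():
        raise CohortValidationError("aggregates contain ids without an arm label")

    long = agg.melt(
        id_vars=["participant_id", "arm"],
        value_vars=["baseline_sum", "followup_sum"],
        var_name="period_name",
        value_name="value",
    )
    long["period"] = (long["period_name"] == "followup_sum").astype(float)
    long["treated"] = (long["arm"] == "MBR").astype(float)
    long["interaction"] = long["period"] * long["treated"]
    X = sm.add_constant(long[["period", "treated", "interaction"]], prepend=True)
    model = sm.OLS(long["value"].astype(float), X)
    if cluster_robust:
        res = model.fit(cov_type="cluster",
                        cov_kwds={"groups": long["participant_id"]})
    else:
        res = model.fit()
    att = float(res.params["interaction"])
    means = long.pivot_table(index="arm", columns="period_name", values="value",
                             aggfunc="mean")
    means = means.rename(columns={"baseline_sum": "baseline",
                                  "followup_sum": "followup"})
    return DiDEstimate(
        outcome=outcome,
        att=att,
        se=float(res.bse["interaction"]),
        p_value=float(res.pvalues["interaction"]),
        n_treated=int((agg["arm"] == "MBR").sum()),
        n_control=int((agg["arm"] == "control").sum()),
        period_means=means,
    )


def ancova(baseline, followup, arms, higher_is_better: bool,
           outcome: str = "") -> AncovaEstimate:
    """Baseline-adjusted arm contrast at follow-up, with a one-sided p-value.

    ``higher_is_better`` fixes the direction in which the programme is
    hypothesised to help (True for EQ-5D, False for sick days).  The
    one-sided p halves the two-sided p when the estimated effect favours
    the programme arm, and is 1 minus that half otherwise.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    treated = (np.asarray(arms) == "MBR").astype(float)
    if len(baseline) != len(followup) or len(baseline) != len(treated):
        raise ConfigError("baseline, followup and arm labels must align")
    if treated.sum() < 2 or (1 - treated).sum() < 2:
        raise ConfigError("ANCOVA needs at least 2 participants per arm")

    if np.var(baseline) == 0:
        logger.info("zero baseline variance; falling back to a plain "
                    "two-sample arm comparison")
        X = sm.add_constant(pd.DataFrame({"treated": treated}), prepend=True)
        res = sm.OLS(followup, X).fit()
        b_coef = 0.0
    else:
        X = sm.add_constant(
            pd.DataFrame({"baseline": baseline, "treated": treated}),
            prepend=True,
        )
        res = sm.OLS(followup, X).fit()
        b_coef = float(res.params["baseline"])
    effect = float(res.params["treated"])
    p_two = float(res.pvalues["treated"])
    favours = effect > 0 if higher_is_better else effect < 0
    p_one = p_two / 2 if favours else 1 - p_two / 2
    grand_base = baseline.mean()
    intercept = float(res.params["const"])
    adj_c = intercept + b_coef * grand_base
    return AncovaEstimate(
        outcome=outcome,
        effect=effect,
        se=float(res.bse["treated"]),
        p_one_sided=p_one,
        p_two_sided=p_two,
        adjusted_means={"MBR": adj_c + effect, "control": adj_c},
    )


def trend_series(records: pd.DataFrame, panels: pd.DataFrame,
                 outcome: str = "bp", quarters=range(-16, 0),
                 by_impairment: bool = False) -> pd.DataFrame:
    """Per-quarter arm means of a cost outcome over the pre-index window,
    optionally stratified by minor/major impairment."""
    col = COST_COLUMNS[outcome]
    merged = panels.merge(
        records[["participant_id", "arm", "gcps_grade"]], on="participant_id"
    )
    merged = merged[merged["quarter_offset"].isin(list(quarters))]
    keys = ["arm", "quarter_offset"]
    if by_impairment:
        merged["impairment"] = np.where(
            merged["gcps_grade"].map(GCPS_ORDER) <= 2, "minor", "major"
        )
        keys = ["impairment"] + keys
    out = merged.groupby(keys, as_index=False)[col].mean()
    return out.rename(columns={col: "mean_cost"})


def parallel_trend_check(records: pd.DataFrame, panels: pd.DataFrame,
                         outcome: str = "bp",
                         quarters=range(-16, 0)) -> TrendCheck:
    """Test whether pre-index cost trends are parallel between arms.

    Per-quarter arm means are regressed on the quarter index with an
    arm x quarter interaction; the interaction slope is the estimated
    divergence in euros per quarter.
    """
    series = trend_series(records, panels, outcome, quarters)
    n_q = series.groupby("arm")["quarter_offset"].nunique()
    if (n_q < 3).any() or len(n_q) < 2:
        raise DataCompletenessError(
            "parallel-trend check needs >= 3 pre-index quarters in each arm"
        )
    df = series.copy()
    df["treated"] = (df["arm"] == "MBR").astype(float)
    df["interaction"] = df["treated"] * df["quarter_offset"]
    X = sm.add_constant(df[["quarter_offset", "treated", "interaction"]],
                        prepend=True)
    res = sm.OLS(df["mean_cost"], X).fit()
    slope_c = float(res.params["quarter_offset"])
    diff = float(res.params["interaction"])
    return TrendCheck(
        slope_treated=slope_c + diff,
        slope_control=slope_c,
        slope_difference=diff,
        se=float(res.bse["interaction"]),
        p_value=float(res.pvalues["interaction"]),
        n_quarters=int(n_q.min()),
        series=series,
    )
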