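"""Declarative scenario battery over the full pipeline.

A :class:`ScenarioSpec` names a population (per-protocol, intention-to-treat
or the unprocessed original cohort), whether to propensity-match, the
truncation threshold, the subgroup (all, minor/major impairment, or the
low/high-cost "profiteer" splits), the discount rate and the programme
cost.  :func:`run_scenario` executes the stages in a fixed order —
exclusions, matching, truncation, subgroup selection, period aggregation,
effect estimation, economics, bootstrap — and returns every intermediate
artefact in one bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort as ch
from .cohort import ExclusionAudit, GCPS_ORDER, aggregate_periods, apply_exclusions
from .economics import EconomicResult, icer
from .effects import AncovaEstimate, DiDEstimate, ancova, did_regression, significance_marker
from .exceptions import ConfigError, EmptyAnalysisSetError
from .matching import MatchResult, balance_table, fit_propensity, match_nearest
from .uncertainty import (
    BootstrapCloud,
    CEACCurve,
    CEPlaneSummary,
    bootstrap_cloud,
    ce_plane_summary,
    ceac,
)

logger = logging.getLogger(__name__)

POPULATIONS = ("per_protocol", "itt", "original")
SUBGROUPS = ("all", "minor", "major", "profiteer_low_cost", "profiteer_high_cost")

#: exclusion rules per population; the "original" scenario drops only the
#: participants with no billing at all, mirroring an analysis that skips
#: data preparation entirely
_POPULATION_RULES = {
    "per_protocol": ("no_billing_year", "sutva", "deductible", "non_exercising"),
    "itt": ("no_billing_year", "sutva", "deductible"),
    "original": ("no_billing_year",),
}


@dataclass(frozen=True)
class ScenarioSpec:
    name: str = "base_case"
    matching: str = "psm"               # {psm, none}
    population: str = "per_protocol"    # {per_protocol, itt, original}
    subgroup: str = "all"
    truncation_threshold: float | None = 14_000.0
    discount_rate: float = 0.03
    intervention_cost: float = 1500.0
    horizon_years: int = 2
    caliper: float = 0.1
    caliper_scale: str = "probability"

    def validate(self) -> None:
        if self.matching not in ("psm", "none"):
            raise ConfigError(f"unknown matching mode {self.matching!r}")
        if self.population not in POPULATIONS:
            raise ConfigError(f"unknown population {self.population!r}")
        if self.subgroup not in SUBGROUPS:
            raise ConfigError(f"unknown subgroup {self.subgroup!r}")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate must be >= 0")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    audit: ExclusionAudit
    balance: pd.DataFrame | None
    match: MatchResult | None
    did: dict                      # outcome -> DiDEstimate
    ancova: dict                   # outcome -> AncovaEstimate
    economics: EconomicResult
    cloud: BootstrapCloud
    ce_plane: CEPlaneSummary
    ceac: CEACCurve
    n_treated: int
    n_control: int
    analysis_set: pd.DataFrame = None  # final records entering estimation

    def effects_frame(self) -> pd.DataFrame:
        """Tabular report of all effect estimates with significance markers."""
        rows = []
        for name, est in self.did.items():
            pm = est.period_means
            rows.append({
                "outcome": name, "estimator": "DiD",
                "mbr_baseline": pm.loc["MBR", "baseline"],
                "mbr_followup": pm.loc["MBR", "followup"],
                "control_baseline": pm.loc["control", "baseline"],
                "control_followup": pm.loc["control", "followup"],
                "effect": est.att, "se": est.se, "p": est.p_value,
                "marker": significance_marker(est.p_value),
            })
        for name, est in self.ancova.items():
            rows.append({
                "outcome": name, "estimator": "ANCOVA",
                "mbr_baseline": np.nan, "mbr_followup": est.adjusted_means["MBR"],
                "control_baseline": np.nan,
                "control_followup": est.adjusted_means["control"],
                "effect": est.effect, "se": est.se, "p": est.p_one_sided,
                "marker": significance_marker(est.p_one_sided),
            })
        return pd.DataFrame(rows)


def split_by_impairment(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition by baseline GCPS grade: minor = grades I-II (functional
    chronic pain), major = III-IV (dysfunctional)."""
    score = records["gcps_grade"].map(GCPS_ORDER)
    return records[score <= 2].copy(), records[score >= 3].copy()


def profiteer_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Participants whose back pain improved: strictly lower STarT-Back raw
    score at follow-up and no regression on the GCPS grade."""
    follow_raw = pd.to_numeric(records["start_back_raw_followup"], errors="coerce")
    base_raw = pd.to_numeric(records["start_back_raw_baseline"], errors="coerce")
    g_base = records["gcps_grade"].map(GCPS_ORDER)
    g_follow = records["gcps_grade_followup"].map(GCPS_ORDER)
    missing = follow_raw.isna() | g_follow.isna()
    if missing.any():
        logger.info("profiteer filter: skipping %d participants with missing "
                    "follow-up instruments", int(missing.sum()))
    keep = (~missing) & (follow_raw < base_raw) & (g_follow <= g_base)
    return records[keep].copy()


def cost_quantile_split(records: pd.DataFrame, pre_costs: pd.Series,
                        bands: dict | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split by pooled pre-index total-cost quantile rank.

    With the default bands, participants between the 0.1 and 0.5 quantiles
    form the low-cost group, those above 0.5 up to 0.9 the high-cost group,
    and the extreme deciles are excluded.  The quantile position of the
    participant with rank i (1-based, ties broken by id) among n is
    (i - 0.5) / n.
    """
    if bands is None:
        bands = {"low": (0.1, 0.5), "high": (0.5, 0.9)}
    if len(records) < 10:
        raise ConfigError("cost-quantile split needs at least 10 participants")
    costs = pre_costs.reindex(records["participant_id"])
    if costs.isna().any():
        raise ConfigError("pre-treatment costs missing for some participants")
    if costs.nunique() == 1:
        logger.warning("all pre-treatment costs equal; quantile split is "
                       "degenerate, ties broken by participant id")
    order = costs.reset_index()
    order.columns = ["participant_id", "cost"]
    order = order.sort_values(["cost", "participant_id"], kind="mergesort")
    n = len(order)
    order["q"] = (np.arange(1, n + 1) - 0.5) / n
    lo_lo, lo_hi = bands["low"]
    hi_lo, hi_hi = bands["high"]
    low_ids = set(order.loc[(order["q"] >= lo_lo) & (order["q"] <= lo_hi),
                            "participant_id"])
    high_ids = set(order.loc[(order["q"] > hi_lo) & (order["q"] <= hi_hi),
                             "participant_id"])
    low = records[records["participant_id"].isin(low_ids)].copy()
    high = records[records["participant_id"].isin(high_ids)].copy()
    return low, high


def _require_both_arms(records: pd.DataFrame, stage: str) -> None:
    arms = records["arm"].value_counts()
    if arms.get("MBR", 0) == 0 or arms.get("control", 0) == 0:
        raise EmptyAnalysisSetError(
            f"stage {stage!r} left an empty treatment or control arm"
        )


def run_scenario(spec: ScenarioSpec, records: pd.DataFrame,
                 panels: pd.DataFrame, seed: int = 0,
                 bootstrap_b: int = 5000) -> ScenarioResult:
    """Execute the full pipeline for one scenario.

    Deterministic given ``spec`` and ``seed`` (the seed drives only the
    bootstrap).  Raises :class:`EmptyAnalysisSetError` naming the stage that
    emptied an arm.
    """
    spec.validate()
    current, audit = apply_exclusions(records, _POPULATION_RULES[spec.population])
    _require_both_arms(current, "exclusions")

    pre_costs_all = ch.pretreatment_sums(panels, "total")

    match = None
    balance = None
    if spec.matching == "psm":
        fit = fit_propensity(current, pre_costs_all)
        match = match_nearest(fit, spec.caliper, spec.caliper_scale)
        balance = balance_table(current, pre_costs_all, match)
        current = current[current["participant_id"].isin(match.matched_ids)]
        audit.add("psm", current)
        _require_both_arms(current, "psm")

    if spec.truncation_threshold is not None:
        current, step = ch.truncate_outliers(current, panels,
                                             spec.truncation_threshold)
        audit.steps.append(step)
        _require_both_arms(current, "truncation")

    if spec.subgroup in ("minor", "major"):
        minor, major = split_by_impairment(current)
        current = minor if spec.subgroup == "minor" else major
        audit.add(f"subgroup_{spec.subgroup}", current)
        _require_both_arms(current, f"subgroup_{spec.subgroup}")
    elif spec.subgroup in ("profiteer_low_cost", "profiteer_high_cost"):
        improved = profiteer_filter(current)
        low, high = cost_quantile_split(improved, pre_costs_all)
        current = low if spec.subgroup == "profiteer_low_cost" else high
        audit.add(f"subgroup_{spec.subgroup}", current)
        _require_both_arms(current, f"subgroup_{spec.subgroup}")

    ids = current["participant_id"]
    sub_panels = panels[panels["participant_id"].isin(ids)]
    arms = current.set_index("participant_id")["arm"]

    did = {}
    for outcome in ch.OUTCOMES:
        agg = aggregate_periods(sub_panels, outcome, spec.discount_rate)
        did[outcome] = did_regression(agg, arms)

    anc = {
        "sick_days": ancova(current["sick_days_baseline"],
                            current["sick_days_followup"], current["arm"],
                            higher_is_better=False, outcome="sick_days"),
        "eq5d": ancova(current["eq5d_baseline"], current["eq5d_followup"],
                       current["arm"], higher_is_better=True, outcome="eq5d"),
    }

    econ = icer(
        att_cost=did["total"].att,
        intervention_cost=spec.intervention_cost,
        delta_eq5d=anc["eq5d"].effect,
        horizon_years=spec.horizon_years,
        rate=spec.discount_rate,
    )

    total_agg = aggregate_periods(sub_panels, "total", spec.discount_rate)
    cloud = bootstrap_cloud(
        current, total_agg,
        intervention_cost=spec.intervention_cost,
        horizon_years=spec.horizon_years,
        rate=spec.discount_rate,
        B=bootstrap_b, seed=seed,
    )
    return ScenarioResult(
        spec=spec,
        audit=audit,
        balance=balance,
        match=match,
        did=did,
        ancova=anc,
        economics=econ,
        cloud=cloud,
        ce_plane=ce_plane_summary(cloud),
        ceac=ceac(cloud),
        n_treated=int((current["arm"] == "MBR").sum()),
        n_control=int((current["arm"] == "control").sum()),
        analysis_set=current.reset_index(drop=True),
    )


def spec_from_dict(d: dict) -> ScenarioSpec:
    known = set(ScenarioSpec.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown scenario key(s): {sorted(unknown)}")
    return ScenarioSpec(**d)
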