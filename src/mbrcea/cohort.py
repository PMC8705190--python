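"""Cohort domain model: typed CSV I/O, exclusion cascade, outlier truncation,
period aggregation and currency adjustment.

The analysis operates on two tables:

``participants``
    One row per insured person: treatment arm, baseline covariates
    (age, sex, GCPS grade, STarT-Back risk, Charlson comorbidity class),
    EQ-5D utility and six-month-recall sick days at baseline and at the
    24-month follow-up, and the boolean flags driving the exclusion cascade.

``panels``
    One row per participant per quarter relative to the individual index
    date.  Quarter 0 is the first post-index quarter; the baseline window
    is quarters -8..-1 (two years), the follow-up window 0..+7, and the
    extended pre-trend window reaches back to -16.  Costs are split into
    total, back-pain-specific (bp), and the inpatient/outpatient partition
    of the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CohortValidationError,
    ConfigError,
    DataCompletenessError,
    ReferentialError,
    SchemaError,
)

logger = logging.getLogger(__name__)

ARMS = ("MBR", "control")
GCPS_GRADES = ("I", "II", "III", "IV")
GCPS_ORDER = {g: i + 1 for i, g in enumerate(GCPS_GRADES)}
START_RISKS = (1, 2, 3)
CCI_CLASSES = ("0", "1-2", "3-4", ">=5")
SEXES = ("female", "male")

#: cost outcomes and their column names in the quarterly panel
OUTCOMES = ("total", "bp", "bp_inpatient", "bp_outpatient")
COST_COLUMNS = {
    "total": "total_cost",
    "bp": "bp_cost",
    "bp_inpatient": "bp_inpatient_cost",
    "bp_outpatient": "bp_outpatient_cost",
}

BASELINE_QUARTERS = tuple(range(-8, 0))
FOLLOWUP_QUARTERS = tuple(range(0, 8))
PRETREND_QUARTERS = tuple(range(-16, 0))

PARTICIPANT_COLUMNS = [
    "participant_id",
    "arm",
    "age",
    "sex",
    "gcps_grade",
    "start_back_risk",
    "cci_class",
    "eq5d_baseline",
    "eq5d_followup",
    "sick_days_baseline",
    "sick_days_followup",
    "start_back_raw_baseline",
    "start_back_raw_followup",
    "gcps_grade_followup",
    "completed_exercise",
    "enrolled",
    "invoice_years_with_billing",
    "sutva_violation",
    "deductible_only",
]

COST_PANEL_COLUMNS = [
    "participant_id",
    "quarter_offset",
    "total_cost",
    "bp_cost",
    "bp_inpatient_cost",
    "bp_outpatient_cost",
]

_BOOL_COLUMNS = ("completed_exercise", "enrolled", "sutva_violation", "deductible_only")

#: ordered exclusion rules: name -> predicate returning the KEEP mask
EXCLUSION_RULES = {
    "no_billing_year": lambda df: df["invoice_years_with_billing"] >= 4,
    "sutva": lambda df: ~df["sutva_violation"],
    "deductible": lambda df: ~df["deductible_only"],
    "non_exercising": lambda df: df["completed_exercise"],
}


@dataclass(frozen=True)
class ExclusionStep:
    """Counts remaining after one step of the exclusion cascade."""

    step: str
    n_overall: int
    n_mbr: int
    n_control: int
    n_removed: int = 0


@dataclass
class ExclusionAudit:
    """Ordered record of the data-preparation cascade (one row per step)."""

    steps: list[ExclusionStep] = field(default_factory=list)

    def add(self, step: str, records: pd.DataFrame, n_removed: int = 0) -> None:
        arm = records["arm"]
        self.steps.append(
            ExclusionStep(
                step=step,
                n_overall=len(records),
                n_mbr=int((arm == "MBR").sum()),
                n_control=int((arm == "control").sum()),
                n_removed=n_removed,
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.step, s.n_overall, s.n_mbr, s.n_control) for s in self.steps],
            columns=["step", "n_overall", "n_mbr", "n_control"],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing column(s): {', '.join(missing)}")


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    mapping = {True: True, False: False, "True": True, "False": False,
               "true": True, "false": False, 1: True, 0: False}
    out = series.map(mapping)
    if out.isna().any():
        row = int(out.index[out.isna()][0]) + 2
        raise CohortValidationError(
            f"column {column!r}: non-boolean value at row {row}"
        )
    return out.astype(bool)


def _require_range(df, column, lo, hi, what="participants"):
    bad = df.index[(df[column] < lo) | (df[column] > hi) | df[column].isna()]
    if len(bad):
        raise CohortValidationError(
            f"{what}: column {column!r} out of range [{lo}, {hi}] at row {int(bad[0]) + 2}"
        )


def _require_enum(df, column, allowed):
    bad = df.index[~df[column].isin(allowed)]
    if len(bad):
        raise CohortValidationError(
            f"column {column!r}: value {df.loc[bad[0], column]!r} not in "
            f"{allowed} at row {int(bad[0]) + 2}"
        )


def validate_participants(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a raw participants table. Returns a typed copy."""
    _check_columns(df, PARTICIPANT_COLUMNS, "participants")
    df = df.copy().reset_index(drop=True)
    df["participant_id"] = df["participant_id"].astype(str)
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise CohortValidationError(f"duplicate participant_id {dup!r}")
    _require_enum(df, "arm", ARMS)
    _require_enum(df, "sex", SEXES)
    _require_enum(df, "gcps_grade", GCPS_GRADES)
    _require_enum(df, "gcps_grade_followup", GCPS_GRADES)
    df["start_back_risk"] = pd.to_numeric(df["start_back_risk"]).astype(int)
    _require_enum(df, "start_back_risk", START_RISKS)
    df["cci_class"] = df["cci_class"].astype(str)
    _require_enum(df, "cci_class", CCI_CLASSES)
    df["age"] = pd.to_numeric(df["age"]).astype(int)
    _require_range(df, "age", 18, 120)
    for c in ("eq5d_baseline", "eq5d_followup"):
        df[c] = pd.to_numeric(df[c])
        _require_range(df, c, -0.6, 1.0)
    for c in ("sick_days_baseline", "sick_days_followup"):
        df[c] = pd.to_numeric(df[c]).astype(int)
        _require_range(df, c, 0, 183)
    for c in ("start_back_raw_baseline", "start_back_raw_followup",
              "invoice_years_with_billing"):
        df[c] = pd.to_numeric(df[c]).astype(int)
    _require_range(df, "invoice_years_with_billing", 0, 4)
    for c in _BOOL_COLUMNS:
        df[c] = _coerce_bool(df[c], c)
    return df[PARTICIPANT_COLUMNS]


def validate_costs(df: pd.DataFrame, known_ids=None) -> pd.DataFrame:
    """Validate and type a raw quarterly cost panel. Returns a typed copy."""
    _check_columns(df, COST_PANEL_COLUMNS, "costs")
    df = df.copy().reset_index(drop=True)
    df["participant_id"] = df["participant_id"].astype(str)
    df["quarter_offset"] = pd.to_numeric(df["quarter_offset"]).astype(int)
    for c in COST_COLUMNS.values():
        df[c] = pd.to_numeric(df[c])
        _require_range(df, c, 0.0, np.inf, what="costs")
    if known_ids is not None:
        unknown = set(df["participant_id"]) - set(known_ids)
        if unknown:
            raise ReferentialError(
                f"cost rows reference unknown participant id(s): "
                f"{sorted(unknown)[:5]}"
            )
    dup = df.duplicated(["participant_id", "quarter_offset"])
    if dup.any():
        raise CohortValidationError(
            f"duplicate (participant_id, quarter_offset) at row {int(df.index[dup][0]) + 2}"
        )
    gap = (df["bp_inpatient_cost"] + df["bp_outpatient_cost"] - df["bp_cost"]).abs()
    if (gap > 0.01).any():
        row = int(df.index[gap > 0.01][0]) + 2
        raise CohortValidationError(
            f"inpatient + outpatient back-pain cost differs from bp_cost at row {row}"
        )
    if (df["bp_cost"] > df["total_cost"] + 0.01).any():
        row = int(df.index[df["bp_cost"] > df["total_cost"] + 0.01][0]) + 2
        raise CohortValidationError(f"bp_cost exceeds total_cost at row {row}")
    cols = COST_PANEL_COLUMNS + [c for c in df.columns if c not in COST_PANEL_COLUMNS]
    return df[cols]


def read_cohort(path_participants, path_costs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a participants CSV and its quarterly cost panel CSV."""
    participants = validate_participants(pd.read_csv(path_participants))
    costs = validate_costs(
        pd.read_csv(path_costs), known_ids=participants["participant_id"]
    )
    return participants, costs


def write_cohort(participants: pd.DataFrame, costs: pd.DataFrame,
                 path_participants, path_costs) -> None:
    """Write the two cohort tables; inverse of :func:`read_cohort`."""
    participants[PARTICIPANT_COLUMNS].to_csv(path_participants, index=False)
    cols = COST_PANEL_COLUMNS + [c for c in costs.columns if c not in COST_PANEL_COLUMNS]
    costs[cols].to_csv(path_costs, index=False)


def apply_exclusions(records: pd.DataFrame, rules) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the ordered exclusion cascade, keeping input order.

    ``rules`` is an ordered iterable drawn from
    ``{"no_billing_year", "sutva", "deductible", "non_exercising"}``.
    The audit starts with the initial counts and appends one row per rule.
    """
    audit = ExclusionAudit()
    audit.add("initial", records)
    current = records
    for rule in rules:
        if rule not in EXCLUSION_RULES:
            raise ConfigError(
                f"unknown exclusion rule {rule!r}; known rules: "
                f"{sorted(EXCLUSION_RULES)}"
            )
        keep = EXCLUSION_RULES[rule](current)
        n_removed = int((~keep).sum())
        current = current.loc[keep]
        audit.add(rule, current, n_removed=n_removed)
    return current.copy(), audit


def pretreatment_sums(panels: pd.DataFrame, outcome: str = "bp",
                      quarters=BASELINE_QUARTERS) -> pd.Series:
    """Undiscounted per-participant sum of a cost outcome over given quarters."""
    if outcome not in COST_COLUMNS:
        raise ConfigError(f"unknown outcome {outcome!r}; known: {OUTCOMES}")
    window = panels[panels["quarter_offset"].isin(quarters)]
    counts = window.groupby("participant_id")["quarter_offset"].nunique()
    incomplete = counts[counts < len(quarters)]
    missing_ids = set(panels["participant_id"]) - set(counts.index)
    if len(incomplete) or missing_ids:
        bad = sorted(set(incomplete.index) | missing_ids)
        raise DataCompletenessError(
            f"participants missing pre-treatment quarters: {bad[:5]}"
        )
    return window.groupby("participant_id")[COST_COLUMNS[outcome]].sum()


def truncate_outliers(records: pd.DataFrame, panels: pd.DataFrame,
                      threshold: float) -> tuple[pd.DataFrame, ExclusionStep]:
    """Drop participants whose undiscounted 2-year pre-index back-pain-specific
    cost sum is at least ``threshold`` (the rule is inclusive).

    Returns the retained records and an audit row reporting the removal.
    """
    if threshold <= 0:
        raise ConfigError("truncation threshold must be positive")
    sums = pretreatment_sums(
        panels[panels["participant_id"].isin(records["participant_id"])], "bp"
    )
    outliers = set(sums.index[sums >= threshold])
    keep = ~records["participant_id"].isin(outliers)
    filtered = records.loc[keep].copy()
    arm = filtered["arm"]
    step = ExclusionStep(
        step=f"truncation_ge_{threshold:g}",
        n_overall=len(filtered),
        n_mbr=int((arm == "MBR").sum()),
        n_control=int((arm == "control").sum()),
        n_removed=int((~keep).sum()),
    )
    return filtered, step


def aggregate_periods(panels: pd.DataFrame, outcome: str,
                      discount_rate: float = 0.03) -> pd.DataFrame:
    """Collapse the quarterly panel to one baseline and one follow-up value
    per participant for one cost outcome.

    The baseline sum covers quarters -8..-1 undiscounted.  The follow-up sum
    discounts each follow-up year y in {1, 2} (quarters 0-3 and 4-7) by
    (1 + rate)^-y.  Collapsing the time series removes quarterly serial
    correlation from the difference-in-difference standard errors.
    """
    if outcome not in COST_COLUMNS:
        raise ConfigError(f"unknown outcome {outcome!r}; known: {OUTCOMES}")
    if discount_rate < 0:
        raise ConfigError("discount_rate must be >= 0")
    col = COST_COLUMNS[outcome]
    needed = set(BASELINE_QUARTERS) | set(FOLLOWUP_QUARTERS)
    window = panels[panels["quarter_offset"].isin(needed)]
    counts = window.groupby("participant_id")["quarter_offset"].nunique()
    if (counts < len(needed)).any():
        bad = sorted(counts.index[counts < len(needed)])
        raise DataCompletenessError(
            f"participants missing analysis quarters -8..+7: {bad[:5]}"
        )
    q = window["quarter_offset"]
    baseline = (
        window[q.isin(BASELINE_QUARTERS)].groupby("participant_id")[col].sum()
    )
    year1 = window[q.between(0, 3)].groupby("participant_id")[col].sum()
    year2 = window[q.between(4, 7)].groupby("participant_id")[col].sum()
    followup = year1 / (1 + discount_rate) + year2 / (1 + discount_rate) ** 2
    out = pd.DataFrame(
        {
            "participant_id": baseline.index,
            "outcome": outcome,
            "baseline_sum": baseline.values,
            "followup_sum": followup.reindex(baseline.index).values,
        }
    )
    return out.reset_index(drop=True)


def adjust_to_reference_euros(panels: pd.DataFrame, cpi_table: dict | None,
                              reference_year: int) -> pd.DataFrame:
    """Rescale every cost to reference-year euros with a consumer-price-index
    table ``{year: index}``.

    The panel must carry a ``calendar_year`` column when a table is supplied.
    An absent table is an identity transform (logged), for callers whose
    costs are already expressed in the reference year.
    """
    if cpi_table is None:
        logger.info("no CPI table supplied; costs left in nominal euros")
        return panels.copy()
    if "calendar_year" not in panels.columns:
        raise ConfigError(
            "CPI adjustment requires a 'calendar_year' column in the cost panel"
        )
    years = set(panels["calendar_year"].unique())
    missing = sorted(y for y in years if y not in cpi_table)
    if reference_year not in cpi_table:
        missing.append(reference_year)
    if missing:
        raise ConfigError(f"CPI table missing year(s): {missing}")
    out = panels.copy()
    factor = out["calendar_year"].map(
        {y: cpi_table[reference_year] / cpi_table[y] for y in years}
    )
    for col in COST_COLUMNS.values():
        out[col] = out[col] * factor
    return out
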