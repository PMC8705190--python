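"""Shared fixture builders: tiny handmade cohorts and a small synthetic one."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mbrcea.cohort import PARTICIPANT_COLUMNS
from mbrcea.simulate import SimulationConfig, generate_cohort

_DEFAULTS = dict(
    arm="MBR",
    age=55,
    sex="male",
    gcps_grade="II",
    start_back_risk=1,
    cci_class="0",
    eq5d_baseline=0.6,
    eq5d_followup=0.65,
    sick_days_baseline=30,
    sick_days_followup=20,
    start_back_raw_baseline=5,
    start_back_raw_followup=4,
    gcps_grade_followup="II",
    completed_exercise=True,
    enrolled=True,
    invoice_years_with_billing=4,
    sutva_violation=False,
    deductible_only=False,
)


def make_participant(pid: str, **over) -> dict:
    row = dict(participant_id=pid, **_DEFAULTS)
    row.update(over)
    return row


def make_records(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def flat_panel(pids, total=200.0, bp=100.0, inpatient_frac=0.2,
               quarters=range(-16, 8)) -> pd.DataFrame:
    """Constant-cost quarterly panel for the given participants."""
    qs = list(quarters)
    rows = []
    for pid in pids:
        for q in qs:
            t = total if np.isscalar(total) else total(q)
            b = bp if np.isscalar(bp) else bp(q)
            rows.append((pid, q, t, b, inpatient_frac * b,
                         (1 - inpatient_frac) * b))
    return pd.DataFrame(rows, columns=[
        "participant_id", "quarter_offset", "total_cost", "bp_cost",
        "bp_inpatient_cost", "bp_outpatient_cost",
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(n_per_arm=120, seed=11))
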