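"""Bootstrap uncertainty analysis: replicate clouds on the
cost-effectiveness plane, quadrant summaries and acceptability curves.

Participants are resampled with replacement independently within each arm.
Per replicate the incremental cost is the four-cell-mean DiD of the
discounted total cost plus the programme cost, and the QALY gain is the
follow-up-minus-baseline EQ-5D arm contrast scaled by horizon and discount
factor.  (The cell-mean DiD coincides exactly with the collapsed-period
regression coefficient, so no regression refit is needed per replicate.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import (
    DEFAULT_DISCOUNT_RATE,
    DEFAULT_HORIZON_YEARS,
    DEFAULT_INTERVENTION_COST,
    discount_factor,
    net_monetary_benefit,
)
from .exceptions import ConfigError, EmptyAnalysisSetError


@dataclass
class BootstrapCloud:
    incremental_cost: np.ndarray  # length B, euros
    qaly_gain: np.ndarray         # length B, QALYs
    B: int
    seed: int

    @property
    def replicates(self):
        return list(zip(self.incremental_cost, self.qaly_gain))


@dataclass
class CEPlaneSummary:
    ne: float
    se: float
    nw: float
    sw: float
    below_wtp: float
    wtp: float


@dataclass
class CEACCurve:
    lambda_grid: np.ndarray
    probability: np.ndarray

    def at(self, lam: float) -> float:
        i = int(np.argmin(np.abs(self.lambda_grid - lam)))
        if self.lambda_grid[i] != lam:
            raise ConfigError(f"lambda {lam} not on the grid")
        return float(self.probability[i])


def default_lambda_grid(stop: float = 50_000.0, step: float = 250.0) -> np.ndarray:
    """0..stop in `step` increments; includes the €20k and €30k anchors."""
    grid = np.arange(0.0, stop + step / 2, step)
    return np.union1d(grid, [20_000.0, 30_000.0])


def bootstrap_cloud(records: pd.DataFrame, cost_aggregates: pd.DataFrame,
                    intervention_cost: float = DEFAULT_INTERVENTION_COST,
                    horizon_years: int = DEFAULT_HORIZON_YEARS,
                    rate: float = DEFAULT_DISCOUNT_RATE,
                    B: int = 5000, seed: int = 0,
                    paired: bool = False,
                    pairs=None) -> BootstrapCloud:
    """Nonparametric bootstrap of (incremental cost, QALY gain).

    ``records`` must carry arm and the EQ-5D columns; ``cost_aggregates``
    is the discounted total-cost collapse from
    :func:`mbrcea.cohort.aggregate_periods` for the same participants.
    With ``paired=True`` (and ``pairs`` from matching) matched pairs are
    resampled jointly instead of individuals within arms.
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    merged = records.merge(cost_aggregates, on="participant_id", validate="1:1")
    # canonical order makes the cloud invariant to input row order
    merged = merged.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    cost_delta = (merged["followup_sum"] - merged["baseline_sum"]).to_numpy(float)
    eq_delta = (merged["eq5d_followup"] - merged["eq5d_baseline"]).to_numpy(float)
    treated = (merged["arm"] == "MBR").to_numpy()
    if treated.sum() == 0 or (~treated).sum() == 0:
        raise EmptyAnalysisSetError("bootstrap requires both arms nonempty")
    dfac = discount_factor(rate, horizon_years)
    rng = np.random.default_rng(seed)

    if paired:
        if not pairs:
            raise ConfigError("paired bootstrap requires matched pairs")
        idx = {pid: k for k, pid in enumerate(merged["participant_id"])}
        t_idx = np.array([idx[t] for t, _ in pairs])
        c_idx = np.array([idx[c] for _, c in pairs])
        n = len(pairs)
        draws = rng.integers(0, n, size=(B, n))
        ti, ci = t_idx[draws], c_idx[draws]
        dc = cost_delta[ti].mean(axis=1) - cost_delta[ci].mean(axis=1)
        de = eq_delta[ti].mean(axis=1) - eq_delta[ci].mean(axis=1)
    else:
        t_pos = np.flatnonzero(treated)
        c_pos = np.flatnonzero(~treated)
        ti = t_pos[rng.integers(0, len(t_pos), size=(B, len(t_pos)))]
        ci = c_pos[rng.integers(0, len(c_pos), size=(B, len(c_pos)))]
        dc = cost_delta[ti].mean(axis=1) - cost_delta[ci].mean(axis=1)
        de = eq_delta[ti].mean(axis=1) - eq_delta[ci].mean(axis=1)

    return BootstrapCloud(
        incremental_cost=dc + intervention_cost,
        qaly_gain=de * horizon_years * dfac,
        B=B,
        seed=seed,
    )


def ce_plane_summary(cloud: BootstrapCloud, wtp: float = 20_000.0) -> CEPlaneSummary:
    """Quadrant shares of the replicate cloud and the share cost-effective
    at ``wtp`` (positive net monetary benefit).  Boundary replicates count
    toward the positive side of each axis, so the four shares sum to 1."""
    if cloud.B == 0:
        raise ConfigError("empty cloud")
    e_pos = cloud.qaly_gain >= 0
    c_pos = cloud.incremental_cost >= 0
    n = float(cloud.B)
    nmb = net_monetary_benefit(cloud.incremental_cost, cloud.qaly_gain, wtp)
    return CEPlaneSummary(
        ne=float((e_pos & c_pos).sum() / n),
        se=float((e_pos & ~c_pos).sum() / n),
        nw=float((~e_pos & c_pos).sum() / n),
        sw=float((~e_pos & ~c_pos).sum() / n),
        below_wtp=float((nmb > 0).sum() / n),
        wtp=wtp,
    )


def ceac(cloud: BootstrapCloud, lambda_grid=None) -> CEACCurve:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    value, the fraction of replicates with positive net monetary benefit."""
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(
        lambda_grid, dtype=float
    )
    if (grid < 0).any():
        raise ConfigError("lambda grid values must be >= 0")
    nmb = grid[:, None] * cloud.qaly_gain[None, :] - cloud.incremental_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(lambda_grid=grid, probability=prob)


def percentile_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical percentile interval with linear interpolation
    between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ConfigError("cannot compute an interval from no values")
    if not 0.0 < level < 1.0:
        raise ConfigError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)
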