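"""Propensity-score estimation, greedy caliper matching and balance diagnostics.

The treatment arms of a Zelen-design programme are self-selected, so a
logistic propensity model (treatment on the baseline matching covariates:
sex, Charlson class, GCPS grade, STarT-Back risk, age, pre-index total
costs and pre-index sick days) is fit by maximum likelihood, and treated
participants are matched 1:1 to controls by nearest propensity score
without replacement, subject to a caliper.  Balance before and after
matching is summarised with standardised mean differences (SMD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit

from .exceptions import ConfigError, RankDeficiencyError, SeparationError
from .cohort import CCI_CLASSES, GCPS_ORDER

logger = logging.getLogger(__name__)

_CCI_SCORE = {c: i for i, c in enumerate(CCI_CLASSES)}

#: default matching covariates (continuous ones are standardised)
DEFAULT_COVARIATES = (
    "sex", "cci", "gcps", "start_back", "age", "pre_cost", "pre_sick_days",
)
_CONTINUOUS = {"age", "pre_cost", "pre_sick_days"}


@dataclass
class PropensityFit:
    coefficients: pd.Series
    scores: pd.Series          # participant_id -> P(treated), strictly in (0,1)
    arm: pd.Series             # participant_id -> arm label
    converged: bool
    n_iterations: int


@dataclass
class MatchResult:
    pairs: list                # list of (treated_id, control_id)
    unmatched_treated: list
    unmatched_control: list
    caliper: float
    caliper_scale: str

    @property
    def matched_ids(self) -> set:
        return {pid for pair in self.pairs for pid in pair}


def _design_matrix(records: pd.DataFrame, pre_costs: pd.Series,
                   covariates) -> pd.DataFrame:
    cols = {}
    idx = records["participant_id"]
    for cov in covariates:
        if cov == "sex":
            cols[cov] = (records["sex"] == "female").astype(float).values
        elif cov == "cci":
            cols[cov] = records["cci_class"].map(_CCI_SCORE).astype(float).values
        elif cov == "gcps":
            cols[cov] = records["gcps_grade"].map(GCPS_ORDER).astype(float).values
        elif cov == "start_back":
            cols[cov] = records["start_back_risk"].astype(float).values
        elif cov == "age":
            cols[cov] = records["age"].astype(float).values
        elif cov == "pre_cost":
            cols[cov] = pre_costs.reindex(idx).astype(float).values
        elif cov == "pre_sick_days":
            cols[cov] = records["sick_days_baseline"].astype(float).values
        else:
            raise ConfigError(f"unknown matching covariate {cov!r}")
    X = pd.DataFrame(cols, index=idx)
    for cov in covariates:
        if cov in _CONTINUOUS:
            sd = X[cov].std(ddof=1)
            if sd > 0:
                X[cov] = (X[cov] - X[cov].mean()) / sd
    return X


def _check_separation(X: pd.DataFrame, treated: np.ndarray) -> None:
    for cov in X.columns:
        t, c = X.loc[treated, cov], X.loc[~treated, cov]
        if t.min() > c.max() or c.min() > t.max():
            raise SeparationError(
                f"covariate {cov!r} perfectly separates the arms"
            )


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.values])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        cols = list(X.columns)
        collinear = [(c, "intercept") for c in cols if X[c].nunique() == 1]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X.values, rowvar=False)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    collinear.append((cols[i], cols[j]))
        raise RankDeficiencyError(
            f"propensity design matrix is rank deficient; collinear: {collinear}"
        )


def fit_propensity(records: pd.DataFrame, pre_costs: pd.Series,
                   covariates=DEFAULT_COVARIATES) -> PropensityFit:
    """Maximum-likelihood logistic model of treatment on the matching
    covariates.  Ordinal covariates enter as integer scores; continuous ones
    are standardised.  Deterministic given input order.

    ``pre_costs`` maps participant_id to the undiscounted pre-index total
    cost sum (see :func:`mbrcea.cohort.pretreatment_sums`).
    """
    if not covariates:
        raise ConfigError("covariate list must be nonempty")
    arm = records.set_index("participant_id")["arm"]
    treated = (records["arm"] == "MBR").values
    if treated.all() or (~treated).all():
        raise ConfigError("both arms must be represented to fit a propensity model")
    X = _design_matrix(records, pre_costs, covariates)
    _check_rank(X)
    _check_separation(X, treated)
    model = sm.Logit(treated.astype(float), sm.add_constant(X, prepend=True))
    res = model.fit(disp=0, maxiter=100, tol=1e-8)
    scores = pd.Series(res.predict(), index=X.index, name="propensity")
    eps = 1e-12
    scores = scores.clip(eps, 1 - eps)
    coefs = pd.Series(res.params.values,
                      index=["intercept", *X.columns])
    return PropensityFit(
        coefficients=coefs,
        scores=scores,
        arm=arm,
        converged=bool(res.mle_retvals.get("converged", True)),
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
    )


def effective_caliper(fit: PropensityFit, caliper: float,
                      caliper_scale: str) -> float:
    """Caliper on the chosen scale: the raw value on the probability scale,
    or caliper x pooled within-arm SD of the logit scores."""
    if caliper_scale == "probability":
        return caliper
    if caliper_scale == "logit_sd":
        lg = logit(fit.scores)
        t = lg[fit.arm.reindex(lg.index) == "MBR"]
        c = lg[fit.arm.reindex(lg.index) == "control"]
        pooled = np.sqrt(
            ((len(t) - 1) * t.var(ddof=1) + (len(c) - 1) * c.var(ddof=1))
            / (len(t) + len(c) - 2)
        )
        return caliper * float(pooled)
    raise ConfigError(f"unknown caliper_scale {caliper_scale!r}")


def match_nearest(fit: PropensityFit, caliper: float = 0.1,
                  caliper_scale: str = "probability") -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated units are processed in descending propensity order; each takes
    the closest remaining control by absolute score distance (on the scale
    the caliper is defined on), rejecting the pair if the distance exceeds
    the effective caliper.  Ties break toward the smaller control id, so
    the result is invariant to control-list order.
    """
    if caliper <= 0:
        raise ConfigError("caliper must be positive")
    arm = fit.arm.reindex(fit.scores.index)
    if (arm == "MBR").sum() == 0 or (arm == "control").sum() == 0:
        raise ConfigError("cannot match with an empty arm")
    cal = effective_caliper(fit, caliper, caliper_scale)
    values = logit(fit.scores) if caliper_scale == "logit_sd" else fit.scores

    treated = values[arm == "MBR"]
    # descending score; within equal scores ascending id, for determinism
    treated = treated.iloc[np.lexsort((treated.index.values, -treated.values))]
    controls = values[arm == "control"].sort_index()

    pairs = []
    available = controls.copy()
    for t_id, t_val in treated.items():
        if available.empty:
            break
        dist = (available - t_val).abs()
        best = dist.min()
        if best > cal:
            continue
        c_id = min(dist.index[dist == best])
        pairs.append((t_id, c_id))
        available = available.drop(c_id)
    matched_t = {t for t, _ in pairs}
    matched_c = {c for _, c in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_treated=sorted(set(treated.index) - matched_t),
        unmatched_control=sorted(set(controls.index) - matched_c),
        caliper=caliper,
        caliper_scale=caliper_scale,
    )


def _smd(m_t, m_c, v_t, v_c):
    pooled = np.sqrt((v_t + v_c) / 2.0)
    diff = abs(m_t - m_c)
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / pooled


def balance_table(records: pd.DataFrame, pre_costs: pd.Series,
                  match: MatchResult | None = None) -> pd.DataFrame:
    """Covariate balance before and (if a match is given) after matching.

    Continuous covariates: arm means, SMD = |mean_T - mean_C| / pooled SD,
    Welch t-test p-value.  Categorical covariates: per-level proportions
    with the proportion-scale SMD, chi-square p-value for the whole table.
    """
    continuous = {
        "age": records.set_index("participant_id")["age"].astype(float),
        "pre_cost": pre_costs.astype(float),
        "pre_sick_days": records.set_index("participant_id")[
            "sick_days_baseline"
        ].astype(float),
        "eq5d_baseline": records.set_index("participant_id")["eq5d_baseline"],
    }
    categorical = ("sex", "gcps_grade", "start_back_risk", "cci_class")
    arm = records.set_index("participant_id")["arm"]

    def stats_for(ids):
        sub_arm = arm.loc[ids]
        t_ids = sub_arm.index[sub_arm == "MBR"]
        c_ids = sub_arm.index[sub_arm == "control"]
        rows = []
        for name, series in continuous.items():
            t, c = series.loc[t_ids], series.loc[c_ids]
            smd = _smd(t.mean(), c.mean(), t.var(ddof=1), c.var(ddof=1))
            p = stats.ttest_ind(t, c, equal_var=False).pvalue if len(t) > 1 and len(c) > 1 else np.nan
            rows.append((name, "", t.mean(), c.mean(), smd, p))
        rec = records.set_index("participant_id")
        for name in categorical:
            series = rec[name].astype(str)
            t, c = series.loc[t_ids], series.loc[c_ids]
            tab = pd.crosstab(series.loc[list(t_ids) + list(c_ids)],
                              arm.loc[list(t_ids) + list(c_ids)])
            if tab.shape[0] > 1 and tab.shape[1] == 2 and (tab.values > 0).all():
                p = stats.chi2_contingency(tab).pvalue
            else:
                p = np.nan
            for level in sorted(series.unique()):
                pt = (t == level).mean()
                pc = (c == level).mean()
                smd = _smd(pt, pc, pt * (1 - pt), pc * (1 - pc))
                rows.append((name, level, pt, pc, smd, p))
        return pd.DataFrame(
            rows, columns=["covariate", "level", "mbr", "control", "smd", "p"]
        )

    before = stats_for(list(records["participant_id"]))
    before = before.rename(
        columns={c: f"{c}_before" for c in ("mbr", "control", "smd", "p")}
    )
    if match is None:
        return before
    after = stats_for(sorted(match.matched_ids))
    after = after.rename(
        columns={c: f"{c}_after" for c in ("mbr", "control", "smd", "p")}
    )
    return before.merge(after, on=["covariate", "level"])
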