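"""Survival stratification: median split, Kaplan-Meier, log-rank, Cox.

Samples are dichotomized at the median of a score or gene (strictly
above the median -> "high", ties to "low"), then compared with the
Kaplan-Meier product-limit estimator, the two-group log-rank test, and
Cox proportional-hazards regression with Breslow tie handling. Hazard
ratios carry 95% Wald confidence intervals exp(beta +/- 1.96 se), the
convention used for reported HRs. A censored record at time t remains
at risk for the event at t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "SurvivalCurve",
    "LogrankResult",
    "CoxResult",
    "GroupComparison",
    "dichotomize_at_median",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "compare_groups",
    "stratify_by_value",
]

Z95 = 1.96  # normal quantile for 95% Wald intervals, as printed in reports


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate tabulated at the distinct observed times."""

    table: pd.DataFrame  # columns: at_risk, events, censored, survival
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        tbl = self.table
        past = tbl.index[tbl.index <= t]
        return float(tbl.loc[past[-1], "survival"]) if len(past) else 1.0


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    """Cox partial-likelihood fit (Breslow ties).

    ``summary`` is indexed by covariate with columns beta, se, hr,
    ci_low, ci_high (HR scale, 95% Wald).
    """

    summary: pd.DataFrame
    converged: bool
    n: int
    n_events: int

    def hr(self, covariate: str | None = None) -> float:
        cov = covariate or self.summary.index[0]
        return float(self.summary.loc[cov, "hr"])


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValueError("no records")
    if np.any(time < 0):
        raise ValueError("negative survival times")
    if not np.all(np.isin(event, [0.0, 1.0])):
        raise ValueError("event indicator must be 0/1")
    return time, event


def dichotomize_at_median(values) -> pd.Series:
    """Median split: value > median -> "high", value <= median -> "low".

    Ties at the median go to "low", keeping the high group at most half
    the cohort and making the split deterministic.
    """
    values = pd.Series(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = float(values.median())
    return pd.Series(
        np.where(values.to_numpy() > med, "high", "low"),
        index=values.index,
        name="group",
    )


def km_estimate(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times appear in the table (they reduce the at-risk
    count) but contribute no multiplicative factor.
    """
    time, event = _as_arrays(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    et = kmf.event_table.copy()
    surv = kmf.survival_function_["KM_estimate"]
    tbl = pd.DataFrame(
        {
            "at_risk": et["at_risk"].astype(int),
            "events": et["observed"].astype(int),
            "censored": et["censored"].astype(int),
            "survival": surv.reindex(et.index).to_numpy(),
        }
    )
    tbl.index.name = "time"
    if 0.0 in tbl.index and tbl.loc[0.0, ["events", "censored"]].sum() == 0:
        tbl = tbl.drop(index=0.0)
    return SurvivalCurve(table=tbl, n=int(time.size), n_events=int(event.sum()))


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test (hypergeometric variance at each distinct
    event time); p from chi-square with 1 df."""
    time, event = _as_arrays(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.tolist()}")
    if event.sum() == 0:
        raise ValueError("no events observed in either group")
    a = group == levels[0]
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def cox_fit(records: pd.DataFrame, covariates, time_col: str = "time",
            event_col: str = "event") -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood maximization
    with Breslow tie handling; 95% Wald CIs on the HR scale.

    Monotone-likelihood fits (complete separation) are reported with
    ``converged=False`` rather than raised.
    """
    covariates = list(covariates)
    time, event = _as_arrays(records[time_col], records[event_col])
    if event.sum() == 0:
        raise ValueError("no events observed")
    X = records[covariates].to_numpy(dtype=float)
    if np.any(np.ptp(X, axis=0) == 0):
        const = [c for c, r in zip(covariates, np.ptp(X, axis=0)) if r == 0]
        raise ValueError(f"constant covariate(s): {const}")
    model = PHReg(time, X, status=event, ties="breslow")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
        beta = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        grad = np.asarray(model.score(beta), dtype=float)
    # Monotone likelihood (complete separation) flattens the gradient while
    # beta and its SE diverge, so the gradient criterion alone cannot catch
    # it; enormous |beta| or SE marks the fit as non-converged.
    converged = bool(
        np.all(np.isfinite(beta))
        and np.all(np.isfinite(se))
        and np.linalg.norm(grad) < 1e-5 * max(1.0, event.sum())
        and np.all(np.abs(beta) < 15.0)
        and np.all(se < 1e3)
    )
    with np.errstate(over="ignore"):  # divergent fits: CI bounds may be 0/inf
        summary = pd.DataFrame(
            {
                "beta": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - Z95 * se),
                "ci_high": np.exp(beta + Z95 * se),
            },
            index=pd.Index(covariates, name="covariate"),
        )
    return CoxResult(summary=summary, converged=converged,
                     n=int(time.size), n_events=int(event.sum()))


@dataclass(frozen=True)
class GroupComparison:
    """KM curves, log-rank test and univariable Cox HR for a binary split."""

    curves: dict
    logrank: LogrankResult
    cox: CoxResult
    group_sizes: dict = field(default_factory=dict)


def compare_groups(records: pd.DataFrame, group_col: str = "group",
                   time_col: str = "time", event_col: str = "event",
                   reference: str | None = None) -> GroupComparison:
    """Full two-group comparison of survival records.

    The Cox covariate is the indicator of the non-reference group, so
    with ``reference="low"`` the HR is high-vs-low (< 1 means the high
    group has lower hazard).
    """
    groups = records[group_col].astype(str)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    ref = reference if reference is not None else ("low" if "low" in levels else levels[0])
    other = [g for g in levels if g != ref][0]
    curves = {
        g: km_estimate(records.loc[groups == g, time_col],
                       records.loc[groups == g, event_col])
        for g in levels
    }
    lr = logrank_test(records[time_col], records[event_col], groups.to_numpy())
    df = records[[time_col, event_col]].copy()
    df[other] = (groups == other).astype(float).to_numpy()
    cox = cox_fit(df, [other], time_col=time_col, event_col=event_col)
    return GroupComparison(
        curves=curves, logrank=lr, cox=cox,
        group_sizes={g: int((groups == g).sum()) for g in levels},
    )


def stratify_by_value(records: pd.DataFrame, values: pd.Series,
                      time_col: str = "time", event_col: str = "event",
                      sample_col: str = "sample_id") -> GroupComparison:
    """Median-dichotomize ``values`` (a gene's expression or a score,
    indexed by sample id), attach the high/low labels to the survival
    records, and run the two-group comparison."""
    rec = records.set_index(sample_col) if sample_col in records.columns else records
    common = rec.index.intersection(values.index)
    if len(common) < 2:
        raise ValueError("fewer than 2 samples shared by records and values")
    rec = rec.loc[common].copy()
    rec["group"] = dichotomize_at_median(values.loc[common])
    return compare_groups(rec, time_col=time_col, event_col=event_col)
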