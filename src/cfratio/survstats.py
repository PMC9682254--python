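"""Survival estimation and comparison (Kaplan-Meier, log-rank, Cox).

Thin, validated wrappers around lifelines.  Times are months throughout;
no unit conversion is attempted.  Cox models use the Efron tie
correction and Newton-Raphson partial-likelihood maximization; a median
that the survival curve never reaches is reported as ``inf`` (printed as
"not reached" at the reporting layer), with its confidence interval from
inversion of the curve's log-log confidence band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times


@dataclass
class SurvivalData:
    """Right-censored survival outcomes: time >= 0 and event in {0, 1}."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.size != self.event.size:
            raise ValueError("time and event must have equal length")
        if np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
            raise ValueError("survival times must be finite and >= 0")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        self.event = self.event.astype(int)

    def __len__(self) -> int:
        return self.time.size


@dataclass
class KmEstimate:
    """Product-limit curve with Greenwood confidence band and median."""

    table: pd.DataFrame                 # time, at_risk, events, survival, ci_low, ci_high
    median: float                       # inf = not reached
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous; S(t) = 1 before the first event."""
        past = self.table[self.table["time"] <= t]
        return 1.0 if past.empty else float(past["survival"].iloc[-1])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (per-covariate rows)."""

    coef: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    log_likelihood: float
    ties: str = "efron"
    n: int = 0
    n_events: int = 0

    def to_json(self) -> str:
        rows = {
            cov: {
                "coef": float(self.coef[cov]),
                "hr": float(self.hr[cov]),
                "ci_lower": float(self.ci_lower[cov]),
                "ci_upper": float(self.ci_upper[cov]),
                "p": float(self.p[cov]),
            }
            for cov in self.coef.index
        }
        return json.dumps(
            {"covariates": rows, "log_likelihood": self.log_likelihood,
             "ties": self.ties, "n": self.n, "n_events": self.n_events},
            indent=2,
        )


def km_estimate(d: SurvivalData, alpha: float = 0.05) -> KmEstimate:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    The median is the earliest time with S(t) <= 0.5 (``inf`` when the
    curve never drops that far); its confidence interval comes from the
    points where the survival curve's confidence band crosses 0.5.
    """
    if len(d) < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(d.time, d.event)
    surv = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_
    ev = kmf.event_table
    table = pd.DataFrame({
        "time": surv.index.to_numpy(dtype=float),
        "at_risk": ev["at_risk"].to_numpy(dtype=int),
        "events": ev["observed"].to_numpy(dtype=int),
        "survival": surv.to_numpy(),
        "ci_low": ci.iloc[:, 0].to_numpy(),
        "ci_high": ci.iloc[:, 1].to_numpy(),
    }).reset_index(drop=True)
    median = float(kmf.median_survival_time_)
    med_ci = median_survival_times(kmf.confidence_interval_)
    lo = float(med_ci.iloc[0, 0])
    hi = float(med_ci.iloc[0, 1])
    return KmEstimate(table=table, median=median, median_ci=(lo, hi))


def logrank_test(d: SurvivalData, labels) -> LogrankResult:
    """Mantel-Cox log-rank test across 2+ groups (df = groups - 1)."""
    labels = pd.Series(np.asarray(labels), name="group")
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if d.event.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    keep = labels.notna().to_numpy()
    res = multivariate_logrank_test(d.time[keep], labels[keep], d.event[keep])
    return LogrankResult(statistic=float(res.test_statistic), df=len(groups) - 1,
                         p=float(res.p_value))


def cox_fit(d: SurvivalData, covariates: pd.DataFrame, alpha: float = 0.05) -> CoxFit:
    """Cox proportional-hazards regression (Efron ties, Newton-Raphson).

    Categorical covariate columns are expanded to treatment-coded dummy
    variables.  Constant covariates and monotone-likelihood (perfect
    separation) configurations are rejected with diagnostics rather than
    silently yielding unstable estimates.
    """
    covariates = pd.DataFrame(covariates).copy()
    covariates = pd.get_dummies(covariates, drop_first=True, dtype=float)
    for col in covariates.columns:
        if covariates[col].nunique(dropna=True) <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    n_events = int(d.event.sum())
    if n_events < covariates.shape[1]:
        raise ValueError(
            f"{n_events} events cannot support {covariates.shape[1]} covariates"
        )
    df = covariates.reset_index(drop=True)
    df["time"] = d.time
    df["event"] = d.event
    cph = CoxPHFitter(alpha=alpha)
    try:
        # precision bounds both the Newton step norm and the decrement; the
        # tight value buys one extra polishing step near the optimum
        cph.fit(df, duration_col="time", event_col="event",
                fit_options={"precision": 1e-14, "max_steps": 500})
    except ConvergenceError as exc:
        raise ValueError(f"Cox model failed to converge (possible monotone "
                         f"likelihood / perfect separation): {exc}") from exc
    summ = cph.summary
    hr_ci = np.exp(cph.confidence_intervals_)
    return CoxFit(
        coef=summ["coef"],
        hr=summ["exp(coef)"],
        ci_lower=hr_ci.iloc[:, 0],
        ci_upper=hr_ci.iloc[:, 1],
        p=summ["p"],
        log_likelihood=float(cph.log_likelihood_),
        ties="efron",
        n=len(d),
        n_events=n_events,
    )
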