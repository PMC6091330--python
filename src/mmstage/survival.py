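"""Time-to-event analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Overall survival is measured in months from the baseline PET/CT scan to
death (event) or last follow-up (right censoring).  Kaplan-Meier curves and
the log-rank test delegate to lifelines; the Cox model is fitted here by
Newton-Raphson on the partial likelihood with Breslow tie handling by
default (Efron available), since the tie convention is part of this
package's contract.

A Kaplan-Meier median that the curve never crosses is reported as the
distinguished value :data:`NOT_REACHED` (rendered ``"NR"``), never as
infinity or a missing value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps


__all__ = [
    "NOT_REACHED",
    "KMEstimate",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_os_table",
]


class _NotReached:
    """Sentinel for a survival median the curve never reaches."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NR"

    def __str__(self) -> str:
        return "NR"


NOT_REACHED = _NotReached()


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("no survival records")
    if times.shape != events.shape:
        raise ValueError("times and events differ in length")
    if (times < 0).any():
        raise ValueError("negative survival time")
    return times, events


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve.

    ``event_times``/``survival`` tabulate the step function at the distinct
    observed event times; ``median`` is the smallest t with S(t) <= 0.5 or
    :data:`NOT_REACHED`.
    """

    event_times: np.ndarray
    survival: np.ndarray
    median: object
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t); right-continuous step function with S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_display(self) -> str:
        return "NR" if self.median is NOT_REACHED else f"{self.median:g}"


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier estimate; censored-only input gives S = 1 and median NR."""
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    surv = np.array([float(kmf.predict(t)) for t in event_times])
    med = kmf.median_survival_time_
    median = NOT_REACHED if np.isinf(med) else float(med)
    return KMEstimate(
        event_times=event_times,
        survival=surv,
        median=median,
        n=len(times),
        n_events=int(events.sum()),
    )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float


def logrank_test(groups: Sequence[tuple]) -> LogRankResult:
    """Log-rank test across >= 2 groups of (times, events) pairs."""
    if len(groups) < 2:
        raise ValueError("log-rank needs at least two groups")
    all_t, all_e, all_g = [], [], []
    for gi, (times, events) in enumerate(groups):
        times, events = _validate(times, events)
        all_t.append(times)
        all_e.append(events)
        all_g.append(np.full(times.shape, gi))
    res = multivariate_logrank_test(
        np.concatenate(all_t), np.concatenate(all_g), np.concatenate(all_e)
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        degrees_of_freedom=len(groups) - 1,
        p_value=float(res.p_value),
    )


@dataclass(frozen=True)
class CoxFit:
    """Fitted proportional-hazards model (Wald inference, 95% CIs)."""

    names: tuple
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray  # on the HR scale
    ci_high: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    ties: str
    dropped: tuple = ()  # constant covariates removed from the design

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios,
                "se(coef)": self.se,
                "HR 95% low": self.ci_low,
                "HR 95% high": self.ci_high,
                "p": self.p_values,
            },
            index=list(self.names),
        )


def _cox_loglik(beta, times, events, X, ties):
    """Log partial likelihood with gradient and observed information matrix."""
    eta = X @ beta
    theta = np.exp(eta)
    loglik = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    order = np.argsort(-times)  # decreasing time: running risk-set sums
    t_sorted = times[order]
    s0 = 0.0
    s1 = np.zeros_like(beta)
    s2 = np.zeros((len(beta), len(beta)))
    i = 0
    nobs = len(times)
    # walk distinct times from largest to smallest, accumulating risk set
    while i < nobs:
        t = t_sorted[i]
        tie_idx = []
        while i < nobs and t_sorted[i] == t:
            j = order[i]
            s0 += theta[j]
            s1 += theta[j] * X[j]
            s2 += theta[j] * np.outer(X[j], X[j])
            if events[j]:
                tie_idx.append(j)
            i += 1
        d = len(tie_idx)
        if d == 0:
            continue
        xsum = X[tie_idx].sum(axis=0)
        loglik += eta[tie_idx].sum()
        if ties == "breslow":
            loglik -= d * np.log(s0)
            grad += xsum - d * s1 / s0
            hess += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        elif ties == "efron":
            td0 = sum(theta[j] for j in tie_idx)
            td1 = sum(theta[j] * X[j] for j in tie_idx)
            td2 = sum(theta[j] * np.outer(X[j], X[j]) for j in tie_idx)
            grad += xsum
            for r in range(d):
                f = r / d
                a0 = s0 - f * td0
                a1 = s1 - f * td1
                a2 = s2 - f * td2
                loglik -= np.log(a0)
                grad -= a1 / a0
                hess += a2 / a0 - np.outer(a1, a1) / a0**2
        else:
            raise ValueError(f"unknown tie handling {ties!r}")
    return loglik, grad, hess


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is a numeric design frame (one column per covariate; the
    caller encodes categorical factors as indicator columns, leaving the
    reference level out — its hazard ratio is 1 by construction).  Constant
    columns are dropped with a warning; non-convergence raises with
    diagnostics; coefficients drifting beyond |coef| > 15 trigger a
    separation warning.
    """
    times, events = _validate(times, events)
    if events.sum() == 0:
        raise ValueError("no events observed; partial likelihood is flat")
    X_df = pd.DataFrame(covariates).astype(float)
    if len(X_df) != len(times):
        raise ValueError("covariate rows do not match survival records")
    dropped = tuple(c for c in X_df.columns if X_df[c].nunique() <= 1)
    if dropped:
        warnings.warn(
            f"dropping constant covariate(s): {', '.join(map(str, dropped))}",
            stacklevel=2,
        )
        X_df = X_df.drop(columns=list(dropped))
    if X_df.shape[1] == 0:
        raise ValueError("no non-constant covariates to fit")
    names = tuple(str(c) for c in X_df.columns)
    # center for numerical stability; Cox estimates are translation-invariant
    X = X_df.to_numpy() - X_df.to_numpy().mean(axis=0)

    beta = np.zeros(X.shape[1])
    loglik, grad, hess = _cox_loglik(beta, times, events, X, ties)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular information matrix at iteration {it}; "
                "check the design for collinearity"
            ) from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _cox_loglik(new_beta, times, events, X, ties)
            halvings += 1
        delta = np.abs(new_ll - loglik)
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        # relative criterion: absolute gradient scales with n at fixed precision
        if delta < tol * (abs(loglik) + 1.0):
            converged = True
            break
    if not converged:
        raise ValueError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad|_max = {np.max(np.abs(grad)):.3g}, loglik = {loglik:.6g})"
        )
    if np.max(np.abs(beta)) > 15:
        warnings.warn(
            "very large coefficient magnitude; the likelihood may be "
            "monotone (separation) and Wald inference unreliable",
            stacklevel=2,
        )
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    z = 1.959963984540054
    hr = np.exp(beta)
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hazard_ratios=hr,
        ci_low=np.exp(beta - z * se),
        ci_high=np.exp(beta + z * se),
        p_values=p,
        log_partial_likelihood=float(loglik),
        n=len(times),
        n_events=int(events.sum()),
        n_iter=it,
        converged=converged,
        ties=ties,
        dropped=dropped,
    )


def univariate_os_table(
    df: pd.DataFrame,
    groupings: dict,
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Per-factor univariate overall-survival table.

    ``groupings`` maps a factor name to the column holding its levels.  For
    each factor the table lists, per level, n (%), the Kaplan-Meier median
    OS ("NR" when not reached) and one log-rank p-value across the factor's
    levels.  Factors with a single observed level are rejected.
    """
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"cohort has no column {col!r}")
    rows = []
    n_total = len(df)
    for factor, col in groupings.items():
        if col not in df.columns:
            raise ValueError(f"unknown grouping column {col!r}")
        levels = [lv for lv in df[col].dropna().unique()]
        if len(levels) < 2:
            raise ValueError(f"grouping {factor!r} has fewer than two levels")
        groups = []
        for lv in levels:
            sub = df[df[col] == lv]
            groups.append((sub[time_col].to_numpy(), sub[event_col].to_numpy()))
        lr = logrank_test(groups)
        for lv, (t, e) in zip(levels, groups):
            km = km_estimate(t, e)
            rows.append(
                {
                    "factor": factor,
                    "level": str(lv),
                    "n": len(t),
                    "pct": round(100.0 * len(t) / n_total, 1),
                    "median_os": km.median_display,
                    "logrank_p": round(lr.p_value, 4),
                }
            )
    return pd.DataFrame(rows)
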