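"""Survival comparison of methylation clusters.

Kaplan-Meier product-limit curves per cluster, the log-rank test, and
univariate/multivariate Cox proportional-hazards models with Wald
confidence intervals on the hazard-ratio scale.  Efron tie handling (the
default) is delegated to lifelines; a compact in-package Newton-Raphson
maximiser of the Breslow partial likelihood provides the alternative tie
method and the score statistic used to cross-check the log-rank test.
A scaled-Schoenfeld-residual slope test screens each fitted term for
proportional-hazards violations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test
from scipy import stats

__all__ = [
    "kaplan_meier",
    "log_rank",
    "CoxFit",
    "cox_fit",
    "cox_score_test",
    "breslow_cox",
    "ph_check",
]

logger = logging.getLogger(__name__)


def kaplan_meier(
    records: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    group_col: str | None = None,
) -> dict[object, pd.DataFrame]:
    """Product-limit survival curve per group.

    Returns, per group, a frame with columns time, survival, at_risk,
    events (censored times appear in the at-risk bookkeeping but do not
    drop the curve).
    """
    if group_col is None:
        groups = {"all": records}
    else:
        groups = {g: sub for g, sub in records.groupby(group_col, observed=True)}
    out = {}
    for g, sub in groups.items():
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        table = kmf.event_table
        out[g] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": table["at_risk"].to_numpy(),
                "events": table["observed"].to_numpy(),
            }
        ).reset_index(drop=True)
    return out


def log_rank(
    records: pd.DataFrame,
    group_col: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[float, int, float]:
    """Log-rank test across groups: (chi-square, df, p)."""
    groups = records[group_col]
    if groups.nunique() < 2:
        raise ValueError("need >=2 groups")
    if records[event_col].sum() < 1:
        raise ValueError("need >=1 event")
    res = multivariate_logrank_test(
        records[duration_col], groups, records[event_col]
    )
    df = int(groups.nunique() - 1)
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxFit:
    """Cox model result: one row per term (coef, HR, 95% CI, Wald p)."""

    table: pd.DataFrame
    endpoint: str
    adjustment: tuple
    n_used: int
    n_events: int
    ties: str
    converged: bool = True
    flags: list = field(default_factory=list)
    _fitter: object | None = None
    _train_df: pd.DataFrame | None = None

    def hazard_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])


def _encode(records: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric columns pass through; object/category columns get indicator
    contrasts against their first sorted level."""
    out = {}
    for col in cols:
        s = records[col]
        if pd.api.types.is_numeric_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = sorted(s.dropna().unique(), key=str)
            for lev in levels[1:]:
                out[f"{col}[{lev}]"] = (s == lev).astype(float)
    return pd.DataFrame(out, index=records.index)


def breslow_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, max_iter: int = 50, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton-Raphson maximiser of the Breslow-ties Cox partial likelihood.

    Returns (coef, covariance, converged).  With no tied event times this
    is the exact partial likelihood and must agree with Efron fits.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    X, time, event = X[order], np.asarray(time)[order], np.asarray(event)[order]
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        grad, hess = _breslow_derivs(X, time, event, beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)) or np.abs(beta_new).max() > 50:
            # monotone likelihood: estimates diverging
            beta = beta_new
            break
        if np.abs(step).max() < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    _, hess = _breslow_derivs(X, time, event, beta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def _breslow_derivs(X, time, event, beta):
    """Score vector and observed information of the Breslow partial likelihood."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    # suffix (risk-set) sums over subjects ordered by time
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d:
            xbar = s1[i] / s0[i]
            grad += X[d_idx].sum(axis=0) - d * xbar
            hess += d * (s2[i] / s0[i] - np.outer(xbar, xbar))
        i = j
    return grad, hess


def cox_score_test(x, time, event) -> tuple[float, float]:
    """Score test of a single covariate's Cox coefficient at beta=0.

    On tie-free data with a binary group covariate this is the two-group
    log-rank statistic.  Returns (chi-square, p on 1 df).
    """
    X = np.asarray(x, dtype=float)[:, None]
    order = np.argsort(np.asarray(time), kind="stable")
    X = X[order]
    t = np.asarray(time)[order]
    e = np.asarray(event)[order]
    grad, hess = _breslow_derivs(X, t, e, np.zeros(1))
    chi2 = float(grad[0] ** 2 / hess[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def cox_fit(
    records: pd.DataFrame,
    terms: list[str],
    duration_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
    endpoint: str = "disease-specific",
) -> CoxFit:
    """Fit a Cox proportional-hazards model on the listed terms.

    Complete cases only; categorical terms are indicator-encoded against
    their first sorted level.  ``ties`` is "efron" (lifelines) or
    "breslow" (in-package Newton-Raphson).  Non-convergence or monotone
    likelihood is flagged on the returned fit rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    data = records[[duration_col, event_col, *terms]].dropna()
    if data[event_col].sum() < 1:
        raise ValueError("need >=1 event")
    design = _encode(data, terms)
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant terms in design: {constant}")

    flags: list[str] = []
    converged = True
    fitter = None
    train_df = None
    if ties == "efron":
        df = pd.concat([data[[duration_col, event_col]], design], axis=1)
        train_df = df
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fitter.fit(df, duration_col=duration_col, event_col=event_col)
            for w in caught:
                if "convergence" in str(w.message).lower():
                    flags.append(str(w.message))
        except ConvergenceError as err:
            raise_flags = f"non-convergence: {err}"
            flags.append(raise_flags)
            converged = False
        if converged:
            summ = fitter.summary
            table = pd.DataFrame(
                {
                    "coef": summ["coef"],
                    "se": summ["se(coef)"],
                    "hr": np.exp(summ["coef"]),
                    "ci_lower": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
                    "ci_upper": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
                    "p": summ["p"],
                }
            )
        else:
            table = pd.DataFrame(
                np.nan,
                index=design.columns,
                columns=["coef", "se", "hr", "ci_lower", "ci_upper", "p"],
            )
    else:
        coef, cov, converged = breslow_cox(
            design.to_numpy(), data[duration_col].to_numpy(), data[event_col].to_numpy()
        )
        if not converged:
            flags.append("non-convergence or monotone likelihood (breslow)")
        se = np.sqrt(np.diag(cov))
        z = coef / se
        table = pd.DataFrame(
            {
                "coef": coef,
                "se": se,
                "hr": np.exp(coef),
                "ci_lower": np.exp(coef - 1.96 * se),
                "ci_upper": np.exp(coef + 1.96 * se),
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=design.columns,
        )
    return CoxFit(
        table=table,
        endpoint=endpoint,
        adjustment=tuple(terms),
        n_used=len(data),
        n_events=int(data[event_col].sum()),
        ties=ties,
        converged=converged,
        flags=flags,
        _fitter=fitter,
        _train_df=train_df,
    )


def ph_check(fit: CoxFit, records: pd.DataFrame | None = None) -> pd.DataFrame | None:
    """Scaled-Schoenfeld-residual slope test against event-time rank.

    Returns per-term chi-square and p plus a ``global`` row (sum of the
    per-term chi-squares on as many df — a screening approximation).
    Degenerate inputs (unconverged fit, <2 distinct event times) return
    None with a log entry.
    """
    if not fit.converged or fit._fitter is None:
        logger.info("ph_check skipped: fit not converged or not an Efron/lifelines fit")
        return None
    fitter: CoxPHFitter = fit._fitter
    events = fitter.event_observed
    if pd.Series(fitter.durations[events.astype(bool)]).nunique() < 2:
        logger.info("ph_check skipped: fewer than 2 distinct event times")
        return None
    res = proportional_hazard_test(fitter, fit._train_df, time_transform="rank")
    summ = res.summary
    out = summ[["test_statistic", "p"]].copy()
    global_stat = float(out["test_statistic"].sum())
    global_df = len(out)
    out.loc["global"] = [global_stat, float(stats.chi2.sf(global_stat, df=global_df))]
    return out
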