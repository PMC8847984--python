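"""Kaplan-Meier estimation, log-rank comparison, and Cox regression.

The Cox proportional-hazards model is fitted by Newton-Raphson
maximization of the partial likelihood with Efron handling of tied
event times (Breslow available), iterating to a gradient norm below
1e-8.  The score test at beta = 0 for a binary covariate reproduces the
classical log-rank statistic; that identity is exercised in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


@dataclass
class SurvivalFit:
    """Per-group product-limit estimates with a log-rank comparison."""

    curves: dict[str, pd.DataFrame]
    medians: dict[str, float | None]
    logrank_statistic: float | None
    logrank_p: float | None
    no_event_groups: list[str] = field(default_factory=list)


def _product_limit(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    for t in np.unique(times):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk, "n_events": d, "survival": s})
    return pd.DataFrame(rows)


def kaplan_meier(times, events, groups=None) -> SurvivalFit:
    """Product-limit estimate per group with an across-group log-rank test.

    The median is the first event time at which the survival function
    drops to 0.5 or below; when the curve never reaches 0.5 the median
    is reported as not reached (None), never extrapolated.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if (times <= 0).any():
        raise ValueError("survival times must be > 0")
    if groups is None:
        groups = np.array(["all"] * times.size)
    else:
        groups = np.asarray(groups)
    curves, medians, no_events = {}, {}, []
    for g in pd.unique(groups):
        mask = groups == g
        curve = _product_limit(times[mask], events[mask])
        curves[str(g)] = curve
        if not events[mask].any():
            no_events.append(str(g))
            medians[str(g)] = None
            continue
        reached = curve[curve["survival"] <= 0.5]
        medians[str(g)] = float(reached["time"].iloc[0]) if len(reached) else None
    stat = p = None
    if len(curves) > 1:
        stat, p = logrank_test(times, events, groups)
    return SurvivalFit(curves, medians, stat, p, no_events)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Multi-group log-rank test (chi-square with n_groups - 1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    O = np.zeros(g)
    E = np.zeros(g)
    V = np.zeros((g, g))
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        d = int(((times == t) & events).sum())
        if n <= 1:
            continue
        ng = np.array([(at_risk & (groups == lab)).sum() for lab in labels], dtype=float)
        dg = np.array(
            [((times == t) & events & (groups == lab)).sum() for lab in labels],
            dtype=float,
        )
        O += dg
        E += d * ng / n
        frac = ng / n
        mult = d * (n - d) / (n - 1) if n > 1 else 0.0
        V += mult * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    stat = max(stat, 0.0)
    p = float(_sps.chi2.sf(stat, df=g - 1)) if stat > 0 else 1.0
    return stat, p


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxResult:
    """Cox regression fit: per-covariate hazard ratios and Wald inference."""

    summary: pd.DataFrame
    model_type: str
    ties: str
    converged: bool
    n: int
    n_events: int
    log_likelihood: float
    separation_flag: bool = False
    coefficients: np.ndarray | None = None
    covariance: np.ndarray | None = None


def _cox_derivatives(beta, Z, times, events, ties="efron"):
    """Partial log-likelihood, gradient, and information at beta."""
    n, p = Z.shape
    eta = Z @ beta
    # cap to keep exp finite under monotone likelihood
    w = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events]):
        risk = times >= t
        dead = (times == t) & events
        m = int(dead.sum())
        s0 = w[risk].sum()
        s1 = Z[risk].T @ w[risk]
        s2 = (Z[risk] * w[risk, None]).T @ Z[risk]
        s0d = w[dead].sum()
        s1d = Z[dead].T @ w[dead]
        s2d = (Z[dead] * w[dead, None]).T @ Z[dead]
        ll += eta[dead].sum()
        grad += Z[dead].sum(axis=0)
        for l in range(m):
            frac = l / m if ties == "efron" else 0.0
            phi = s0 - frac * s0d
            psi = s1 - frac * s1d
            xi = s2 - frac * s2d
            ll -= np.log(phi)
            grad -= psi / phi
            info += xi / phi - np.outer(psi, psi) / phi**2
    return ll, grad, info


def cox_ph(
    covariates,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
    model_type: str = "univariate",
) -> CoxResult:
    """Fit a Cox proportional-hazards model.

    ``covariates`` is a DataFrame (rows aligned with ``times``); rows
    with missing covariate values are dropped with a log message.
    Zero-variance covariates are reported with HR = 1 and p = 1.
    Monotone likelihood (perfect separation) is flagged, and failure to
    reach the gradient tolerance within ``max_iter`` iterations is an
    error.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    Z = pd.DataFrame(covariates).astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ok = ~Z.isna().any(axis=1).to_numpy()
    if not ok.all():
        log.warning("cox_ph: dropping %d rows with missing covariates", int((~ok).sum()))
        Z, times, events = Z.loc[ok], times[ok], events[ok]
    names = list(Z.columns)
    Zv = Z.to_numpy()
    variable = Zv.std(axis=0) > 0
    beta = np.zeros(len(names))
    separation = False
    ll = np.nan
    cov = np.zeros((len(names), len(names)))
    if variable.any():
        Zs = Zv[:, variable]
        b = np.zeros(Zs.shape[1])
        ll, grad, info = _cox_derivatives(b, Zs, times, events, ties)
        it = 0
        while np.linalg.norm(grad) >= tol:
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    f"cox_ph failed to converge in {max_iter} iterations "
                    f"(|grad| = {np.linalg.norm(grad):.3g})"
                )
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            new_b = b + step
            new_ll, new_grad, new_info = _cox_derivatives(new_b, Zs, times, events, ties)
            halvings = 0
            while new_ll < ll - 1e-12 and halvings < 30:
                step = step / 2.0
                new_b = b + step
                new_ll, new_grad, new_info = _cox_derivatives(new_b, Zs, times, events, ties)
                halvings += 1
            b, ll, grad, info = new_b, new_ll, new_grad, new_info
            if np.linalg.norm(step) < 1e-10 * max(1.0, np.linalg.norm(b)):
                # rounding floor of the partial-likelihood sums reached
                break
            if np.abs(b).max() > 50:
                separation = True
                log.warning("cox_ph: monotone likelihood suspected (|beta| > 50)")
                break
        if np.abs(b).max() > 15:
            # a log-hazard ratio this large on any sane covariate scale
            # indicates monotone likelihood rather than a real effect
            separation = True
        beta[variable] = b
        try:
            cov_sub = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_sub = np.linalg.pinv(info)
        cov[np.ix_(variable, variable)] = cov_sub

    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z975 = _sps.norm.ppf(0.975)
    rows = []
    for i, name in enumerate(names):
        if not variable[i]:
            rows.append(
                {"covariate": name, "coef": 0.0, "hr": 1.0, "se": np.inf,
                 "ci_lower": 0.0, "ci_upper": np.inf, "p_value": 1.0}
            )
            continue
        zstat = beta[i] / se[i] if se[i] > 0 else 0.0
        with np.errstate(over="ignore"):
            rows.append(
                {
                    "covariate": name,
                    "coef": beta[i],
                    "hr": float(np.exp(beta[i])),
                    "se": se[i],
                    "ci_lower": float(np.exp(beta[i] - z975 * se[i])),
                    "ci_upper": float(np.exp(beta[i] + z975 * se[i])),
                    "p_value": float(2 * _sps.norm.sf(abs(zstat))) if se[i] > 0 else 1.0,
                }
            )
    return CoxResult(
        summary=pd.DataFrame(rows).set_index("covariate"),
        model_type=model_type,
        ties=ties,
        converged=not separation,
        n=len(times),
        n_events=int(events.sum()),
        log_likelihood=float(ll),
        separation_flag=separation,
        coefficients=beta,
        covariance=cov,
    )


def cox_score_test(covariates, times, events, ties: str = "breslow") -> tuple[float, float]:
    """Score (Rao) test of beta = 0.

    With Breslow tie handling and a binary covariate this equals the
    classical log-rank chi-square; on untied data Efron and Breslow
    coincide.
    """
    Z = pd.DataFrame(covariates).astype(float).to_numpy()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    _, grad, info = _cox_derivatives(np.zeros(Z.shape[1]), Z, times, events, ties)
    try:
        stat = float(grad @ np.linalg.solve(info, grad))
    except np.linalg.LinAlgError:
        stat = float(grad @ np.linalg.pinv(info) @ grad)
    p = float(_sps.chi2.sf(stat, df=Z.shape[1]))
    return stat, p


# ---------------------------------------------------------------------------
# composite report


def subtype_survival_report(
    fractions: pd.DataFrame,
    annotation,
    lesion_status: pd.Series | None = None,
    ties: str = "efron",
) -> dict:
    """KM by dominant subtype, univariate Cox per fraction, multivariate Cox.

    ``fractions`` is a samples x frame with MetA/MetB/MetC columns and a
    ``dominant`` column; ``annotation`` provides ``survival_time`` and
    ``event``.  The multivariate model combines the subtype call (MetA
    as reference) with the optional binary lesion status.
    """
    from metac.core.types import SUBTYPES

    ann = annotation.table
    shared = [s for s in fractions.index if s in ann.index]
    sub = fractions.loc[shared]
    surv = ann.loc[shared]
    usable = surv["survival_time"].notna().to_numpy()
    shared = [s for s, u in zip(shared, usable) if u]
    sub, surv = sub.loc[shared], surv.loc[shared]
    times = surv["survival_time"].to_numpy(float)
    events = surv["event"].to_numpy(bool)

    km = kaplan_meier(times, events, sub["dominant"].to_numpy())

    uni_rows = []
    for subtype in SUBTYPES:
        res = cox_ph(sub[[subtype]], times, events, ties=ties, model_type="univariate")
        row = res.summary.iloc[0]
        uni_rows.append(
            {"covariate": subtype, "hr": row["hr"], "p_value": row["p_value"],
             "ci_lower": row["ci_lower"], "ci_upper": row["ci_upper"]}
        )
    univariate = pd.DataFrame(uni_rows).set_index("covariate")

    design = pd.DataFrame(index=sub.index)
    for subtype in SUBTYPES[1:]:  # MetA is the reference class
        design[subtype] = (sub["dominant"] == subtype).astype(float)
    if lesion_status is not None:
        design["lesion"] = lesion_status.reindex(sub.index).astype(float)
    multivariate = cox_ph(design, times, events, ties=ties, model_type="multivariate")

    return {"km": km, "univariate": univariate, "multivariate": multivariate}
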