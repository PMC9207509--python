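"""Survival machinery and generic two-group / correlation statistics.

Kaplan--Meier estimation, the log-rank test and multivariate Cox regression
are delegated to ``lifelines`` (Efron tie handling); the time-dependent ROC
estimator — cumulative cases / dynamic controls with inverse-probability-of-
censoring weights from a Kaplan--Meier fit of the censoring distribution —
is implemented here. Binary ROC uses scikit-learn; rank statistics use scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times, restricted_mean_survival_time
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve


def _validate_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if not np.isfinite(times).all() or (times <= 0).any():
        raise ValueError("survival times must be finite and positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMFit:
    """Product-limit fit: event-time grid, estimates, Greenwood variances,
    median with 95% log-log CI, and numbers at risk."""

    timeline: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood variance of S(t)
    at_risk: np.ndarray
    median: float                 # inf when not reached
    median_ci: tuple
    fitter: KaplanMeierFitter = field(repr=False, default=None)

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)


def km_fit(times, events) -> KMFit:
    """Kaplan--Meier product-limit estimator.

    The median is the first time with S(t) <= 0.5 (inf if never reached);
    its 95% CI comes from the log(-log) transformed confidence band.
    """
    times, events = _validate_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    d = table["observed"].to_numpy(dtype=float)
    n = table["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n * (n - d) > 0, d / (n * (n - d)), 0.0)
    greenwood = surv**2 * np.cumsum(terms)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMFit(
        timeline=grid, survival=surv, variance=greenwood, at_risk=n,
        median=median, median_ci=(lo, hi), fitter=kmf,
    )


def km_median_or_rmst(times, events) -> float:
    """Median survival, falling back to restricted mean survival when the
    median is not reached (no events past S=0.5)."""
    fit = km_fit(times, events)
    if fit.median_reached:
        return fit.median
    horizon = float(np.max(np.asarray(times, dtype=float)))
    return float(restricted_mean_survival_time(fit.fitter, t=horizon))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups):
    """Standard O-E log-rank chi-square (df = n_groups - 1) -> (stat, p)."""
    times, events = _validate_surv(times, events)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    if events.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def logrank_z(times, events, mask):
    """Standardized two-group log-rank statistic (O-E)/sqrt(V) for the group
    flagged by ``mask``. Used by the maximally selected cutpoint scan."""
    times, events = _validate_surv(times, events)
    mask = np.asarray(mask, dtype=bool)
    order = np.argsort(times, kind="stable")
    t, e, m = times[order], events[order], mask[order]
    n = len(t)
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = at_risk.sum()
        n_1 = (at_risk & m).sum()
        d_tot = ((t == et) & (e == 1)).sum()
        d_1 = ((t == et) & (e == 1) & m).sum()
        O += d_1
        E += d_tot * n_1 / n_tot
        if n_tot > 1:
            V += d_tot * (n_1 / n_tot) * (1 - n_1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if V <= 0:
        return 0.0
    return float((O - E) / np.sqrt(V))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Multivariate Cox fit: per-covariate coefficient, HR, 95% CI and Wald
    p-value, plus log partial likelihood and a convergence flag."""

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool

    def hazard_ratio(self, covariate) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Cox regression with Efron tie handling (lifelines backend).

    Non-convergence or separation is flagged (``converged=False`` with an
    empty summary), never silently returned as estimates.
    """
    times, events = _validate_surv(times, events)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    df = cov.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="_time", event_col="_event")
        trouble = [w for w in caught if issubclass(w.category, ConvergenceWarning)]
        if trouble:
            raise ConvergenceError(str(trouble[0].message))
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
        empty = pd.DataFrame(columns=["coef", "hr", "ci_low", "ci_high", "p"])
        warnings.warn(f"Cox fit did not converge: {err}", UserWarning)
        return CoxFit(summary=empty, log_likelihood=np.nan, converged=False)
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": np.exp(s["coef lower 95%"]),
            "ci_high": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
    )


def cox_univariate(times, events, x, max_iter: int = 50, tol: float = 1e-9):
    """Single-covariate Cox fit by Newton--Raphson on the Efron partial
    likelihood, with step-halving. Returns (beta, se, p).

    This is the fast path behind the per-gene prognostic filter; the
    multivariate fit stays with lifelines.
    """
    times, events = _validate_surv(times, events)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate has zero variance")

    order = np.argsort(times, kind="stable")
    t, e, xv = times[order], events[order], x[order]
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        raise ValueError("no events")

    def loglik_grad_hess(beta):
        eta = beta * xv
        w = np.exp(eta - eta.max())  # stabilized; constants cancel per term
        logscale = eta.max()
        ll = g = h = 0.0
        for et in event_times:
            risk = t >= et
            dead = (t == et) & (e == 1)
            d = int(dead.sum())
            wr, xr = w[risk], xv[risk]
            wd, xd = w[dead], xv[dead]
            s0r, s1r, s2r = wr.sum(), (wr * xr).sum(), (wr * xr**2).sum()
            s0d, s1d, s2d = wd.sum(), (wd * xd).sum(), (wd * xd**2).sum()
            ll += beta * xd.sum()
            g += xd.sum()
            for l in range(d):
                f = l / d
                s0 = s0r - f * s0d
                s1 = s1r - f * s1d
                s2 = s2r - f * s2d
                ll -= np.log(s0) + logscale
                mean_term = s1 / s0
                g -= mean_term
                h += s2 / s0 - mean_term**2
        return ll, g, h

    beta = 0.0
    ll, g, h = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        if h <= 0:
            break
        step = g / h
        new_beta = beta + step
        new_ll, new_g, new_h = loglik_grad_hess(new_beta)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_g, new_h = loglik_grad_hess(new_beta)
            halvings += 1
        if abs(new_beta - beta) < tol:
            beta, ll, g, h = new_beta, new_ll, new_g, new_h
            converged = True
            break
        beta, ll, g, h = new_beta, new_ll, new_g, new_h
    if not converged and abs(g) > 1e-4:
        raise ConvergenceError(f"univariate Cox did not converge (score={g:.3g})")
    se = 1.0 / np.sqrt(h) if h > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return float(beta), float(se), float(p)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class TimeROC:
    """Time-dependent ROC: AUC(t) and sensitivity/specificity grids per
    horizon."""

    horizons: np.ndarray
    auc: np.ndarray
    curves: dict  # horizon -> DataFrame(threshold, sensitivity, specificity)


def _censoring_km(times, events):
    """KM fit of the censoring distribution G(t) (events flipped)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    def G(t, left=False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if left:
            t = t - 1e-10
        return np.clip(np.asarray(kmf.predict(t), dtype=float), 1e-12, 1.0)
    return G


def time_roc(times, events, marker, horizons) -> TimeROC:
    """Cumulative-case / dynamic-control AUC(t) with KM censoring weights.

    Cases at horizon ``t`` are subjects with an observed event at or before
    ``t``, weighted by 1/G(T_i-); controls are subjects still under
    observation past ``t``, weighted by 1/G(t), where G is the Kaplan--Meier
    estimate of the censoring survival function.
    """
    times, events = _validate_surv(times, events)
    marker = np.asarray(marker, dtype=float)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if (horizons > times.max()).any():
        raise ValueError("horizon beyond the last observed time")
    G = _censoring_km(times, events)

    aucs = []
    curves = {}
    for t in horizons:
        case = (times <= t) & (events == 1)
        ctrl = times > t
        if case.sum() == 0 or ctrl.sum() == 0:
            aucs.append(np.nan)
            curves[float(t)] = pd.DataFrame(
                columns=["threshold", "sensitivity", "specificity"]
            )
            continue
        w_case = 1.0 / G(times[case], left=True)
        w_ctrl = np.full(ctrl.sum(), 1.0 / float(G(t)))
        mc, mk = marker[case], marker[ctrl]
        # weighted concordance over all case/control pairs
        diff = mc[:, None] - mk[None, :]
        conc = (diff > 0) + 0.5 * (diff == 0)
        wmat = np.outer(w_case, w_ctrl)
        aucs.append(float((conc * wmat).sum() / wmat.sum()))
        thr = np.unique(marker)[::-1]
        sens = [(w_case * (mc > c)).sum() / w_case.sum() for c in thr]
        spec = [(w_ctrl * (mk <= c)).sum() / w_ctrl.sum() for c in thr]
        curves[float(t)] = pd.DataFrame(
            {"threshold": thr, "sensitivity": sens, "specificity": spec}
        )
    return TimeROC(horizons=horizons, auc=np.asarray(aucs), curves=curves)


def binary_roc(labels, marker):
    """AUC by concordant-pair counting (ties count 1/2) plus the ROC curve."""
    labels = np.asarray(labels).astype(int)
    marker = np.asarray(marker, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(marker) == 0:
        auc = 0.5  # all ties
        curve = pd.DataFrame({"fpr": [0.0, 1.0], "tpr": [0.0, 1.0]})
        return auc, curve
    auc = float(roc_auc_score(labels, marker))
    fpr, tpr, thr = roc_curve(labels, marker)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def wilcoxon_ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups have <= 10 untied observations, tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(x) <= 10 and len(y) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def spearman(x, y):
    """Spearman rank correlation -> (rho, p); zero-variance input is flagged
    as undefined (NaN) with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of n >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: Spearman rho undefined", UserWarning)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
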