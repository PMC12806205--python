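"""Core survival statistics.

Implements the estimators the whole pipeline rests on: Cox proportional
hazards with Efron tie handling (Newton-Raphson on the partial likelihood),
likelihood-ratio tests between nested Cox fits, the Kaplan-Meier
product-limit estimator with Greenwood standard errors, the multi-group
Mantel-Cox log-rank test, and Benjamini-Hochberg multiplicity adjustment.

All estimators are written against plain numpy arrays; times are in months
throughout the package but nothing here assumes a unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CoxFit",
    "KMCurve",
    "LogrankResult",
    "SurvData",
    "fit_cox",
    "lrt",
    "km_estimate",
    "logrank_test",
    "bh_adjust",
    "cox_score_test",
    "concordance_index",
]

# Wald CI multiplier for a 95% interval.
_Z95 = 1.96
_MAX_ABS_BETA = 15.0


class DegenerateCovariateError(ValueError):
    """A covariate column is constant (or otherwise uninformative)."""


class NotNestedError(ValueError):
    """LRT requested between fits that are not nested on the same data."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``hr = exp(coef)`` exactly; ``ci_low/ci_high`` are Wald intervals
    ``exp(coef +/- 1.96 * se)``.  ``loglik_null`` is the partial
    log-likelihood at beta = 0, used by :func:`lrt`.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    converged: bool
    n_iter: int = 0


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier curve on the grid of distinct event times.

    ``times`` starts at 0 with ``survival[0] = 1``; ``se`` is the Greenwood
    standard error.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    se: np.ndarray


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    df: int
    p: float
    groups: tuple
    observed: np.ndarray
    expected: np.ndarray


class SurvData:
    """Precomputed sort/tie structure for one (times, events) vector.

    Building this once and reusing it across many single-covariate fits
    (the per-gene screens) avoids re-sorting for every gene.
    """

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be equal-length 1-D arrays")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise ValueError("times must be finite and non-negative")
        uniq = np.unique(events)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("event flags must be 0/1")
        events = events.astype(np.int8)
        if events.sum() < 1:
            raise ValueError("need at least one event")

        order = np.argsort(times, kind="stable")
        self.order = order
        self.t = times[order]
        self.e = events[order]
        self.n = times.size
        # first index of the tied-time block each position belongs to; risk
        # set for an event at t is everyone from that block onward
        self.block_first = np.searchsorted(self.t, self.t, side="left")
        ev_pos = np.flatnonzero(self.e == 1)
        self.ev_pos = ev_pos
        ev_t = self.t[ev_pos]
        starts = np.flatnonzero(np.r_[True, ev_t[1:] != ev_t[:-1]])
        self.grp_starts = starts                      # into ev_pos
        self.grp_counts = np.diff(np.r_[starts, ev_pos.size])
        self.grp_risk_start = self.block_first[ev_pos[starts]]
        self.n_events = int(ev_pos.size)
        self.tied = bool(np.any(self.grp_counts > 1))


def _rev_cumsum(a):
    return np.cumsum(a[::-1], axis=0)[::-1]


def _efron_ll_grad_info(beta, X, sd: SurvData):
    """Partial log-likelihood, gradient, and information (−Hessian).

    ``X`` must already be sorted in ``sd`` order. Efron's correction is
    applied within tied event-time groups.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()            # invariant shift, avoids overflow
    w = np.exp(eta)

    rc0 = _rev_cumsum(w)
    rc1 = _rev_cumsum(w[:, None] * X)
    xx = X[:, :, None] * X[:, None, :]
    rc2 = _rev_cumsum(w[:, None, None] * xx)

    ev = sd.ev_pos
    S0 = rc0[sd.grp_risk_start]
    S1 = rc1[sd.grp_risk_start]
    S2 = rc2[sd.grp_risk_start]

    ll = float(eta[ev].sum())
    grad = X[ev].sum(axis=0)
    info = np.zeros((p, p))

    single = sd.grp_counts == 1
    if np.any(single):
        s0 = S0[single]
        s1 = S1[single]
        s2 = S2[single]
        ll -= float(np.log(s0).sum())
        psi = s1 / s0[:, None]
        grad -= psi.sum(axis=0)
        info += (s2 / s0[:, None, None]).sum(axis=0)
        info -= np.einsum("ki,kj->ij", psi, psi)

    if sd.tied:
        for g in np.flatnonzero(~single):
            d = int(sd.grp_counts[g])
            lo = sd.grp_starts[g]
            pos = ev[lo:lo + d]
            wd = w[pos]
            D0 = wd.sum()
            D1 = (wd[:, None] * X[pos]).sum(axis=0)
            D2 = (wd[:, None, None] * xx[pos]).sum(axis=0)
            s0, s1, s2 = S0[g], S1[g], S2[g]
            for l in range(d):
                f = l / d
                phi = s0 - f * D0
                psi = (s1 - f * D1) / phi
                ll -= float(np.log(phi))
                grad -= psi
                info += (s2 - f * D2) / phi - np.outer(psi, psi)

    return ll, grad, info


def _prepare_X(covariates, names):
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    p = X.shape[1]
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    else:
        names = tuple(names)
        if len(names) != p:
            raise ValueError("names length does not match covariate count")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateCovariateError(
                f"covariate '{names[j]}' is constant"
            )
    return X, names


def fit_cox(times, events, covariates, names=None, *, surv: SurvData | None = None,
            tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Efron tie handling; convergence when the gradient infinity-norm drops
    below ``tol`` (default 1e-8) or after ``max_iter`` Newton steps with
    step-halving.  Monotone likelihood (perfect separation) is reported by
    ``converged=False`` with coefficients capped at +/-15.

    Parameters
    ----------
    surv : optional precomputed :class:`SurvData` for (times, events),
        letting callers amortize the sort across many fits.
    """
    if surv is None:
        surv = SurvData(times, events)
    X, names = _prepare_X(covariates, names)
    if X.shape[0] != surv.n:
        raise ValueError("covariate rows do not match number of subjects")
    # center columns for conditioning; beta is shift-invariant
    Xc = X - X.mean(axis=0)
    Xs = Xc[surv.order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_ll_grad_info(beta, Xs, surv)
    loglik_null = ll
    converged = False
    capped = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_info = _efron_ll_grad_info(new_beta, Xs, surv)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _efron_ll_grad_info(new_beta, Xs, surv)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if np.any(np.abs(beta) > _MAX_ABS_BETA):
            beta = np.clip(beta, -_MAX_ABS_BETA, _MAX_ABS_BETA)
            ll, grad, info = _efron_ll_grad_info(beta, Xs, surv)
            capped = True
            break
    else:
        it = max_iter
    if not capped and np.max(np.abs(grad)) < tol:
        converged = True

    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci_low = np.exp(beta - _Z95 * se)
        ci_high = np.exp(beta + _Z95 * se)
    return CoxFit(
        names=names, coef=beta, se=se, z=z, p=pvals, hr=hr,
        ci_low=ci_low, ci_high=ci_high,
        loglik=float(ll), loglik_null=float(loglik_null),
        n=surv.n, n_events=surv.n_events,
        converged=converged and not capped, n_iter=it,
    )


def cox_score_test(times, events, covariate, *, surv: SurvData | None = None):
    """Cox score test of beta = 0 for a covariate vector (or matrix).

    For a single binary covariate on tie-free data this equals the
    two-group log-rank chi-square.  Returns (statistic, df, p).
    """
    if surv is None:
        surv = SurvData(times, events)
    X, _ = _prepare_X(covariate, None)
    Xc = (X - X.mean(axis=0))[surv.order]
    p = X.shape[1]
    _, grad, info = _efron_ll_grad_info(np.zeros(p), Xc, surv)
    stat = float(grad @ np.linalg.solve(info, grad))
    return stat, p, float(sps.chi2.sf(stat, p))


def lrt(nested: CoxFit, full: CoxFit):
    """Likelihood-ratio test between nested Cox fits.

    ``statistic = 2 (ll_full - ll_nested)``; df is the difference in the
    number of covariates; p from the chi-square upper tail.
    """
    if not set(nested.names).issubset(full.names):
        raise NotNestedError("nested covariates are not a subset of the full model")
    if (nested.n, nested.n_events) != (full.n, full.n_events):
        raise NotNestedError("fits are not on the same observations")
    df = len(full.names) - len(nested.names)
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < -1e-8:
        raise NotNestedError(
            f"full model log-likelihood below nested ({stat=}); models not nested"
        )
    stat = max(stat, 0.0)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(sps.chi2.sf(stat, df))


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood SE.

    All-censored input is valid and yields S identically 1 on a grid that
    then contains only t = 0.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size < 1:
        raise ValueError("need at least one subject")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n = t.size
    ev_times = np.unique(t[e == 1])
    surv = [1.0]
    grid = [0.0]
    at_risk = [n]
    gw = [0.0]          # Greenwood cumulative sum
    s = 1.0
    acc = 0.0
    for tt in ev_times:
        nk = int(np.sum(t >= tt))
        dk = int(np.sum((t == tt) & (e == 1)))
        s *= 1.0 - dk / nk
        if nk > dk:
            acc += dk / (nk * (nk - dk))
        else:
            acc = np.inf
        grid.append(float(tt))
        surv.append(s)
        at_risk.append(nk)
        gw.append(acc)
    surv_arr = np.array(surv)
    with np.errstate(invalid="ignore"):
        se = surv_arr * np.sqrt(np.array(gw))
    se = np.where(np.isfinite(se), se, 0.0)
    return KMCurve(times=np.array(grid), survival=surv_arr,
                   at_risk=np.array(at_risk), se=se)


def logrank_test(times, events, group_labels) -> LogrankResult:
    """Multi-group Mantel-Cox log-rank test (df = groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two non-empty groups")
    G = groups.size
    ev_times = np.unique(times[events == 1])
    O = np.zeros(G)
    E = np.zeros(G)
    V = np.zeros((G, G))
    member = labels[:, None] == groups[None, :]       # n x G
    for tt in ev_times:
        at_risk = times >= tt
        nk = at_risk.sum()
        ng = (at_risk[:, None] & member).sum(axis=0).astype(float)
        ev_here = (times == tt) & (events == 1)
        dk = ev_here.sum()
        dg = (ev_here[:, None] & member).sum(axis=0).astype(float)
        O += dg
        E += dk * ng / nk
        if nk > 1:
            c = dk * (nk - dk) / (nk - 1)
            V += c * (np.diag(ng * nk) - np.outer(ng, ng)) / nk**2
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = G - 1
    return LogrankResult(statistic=max(stat, 0.0), df=df,
                         p=float(sps.chi2.sf(max(stat, 0.0), df)),
                         groups=tuple(groups), observed=O, expected=E)


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def concordance_index(times, events, risk):
    """Harrell's C: fraction of comparable pairs ordered correctly by risk.

    A pair (i, j) is comparable when T_i < T_j and subject i had the event;
    concordant when risk_i > risk_j, with half credit for risk ties.
    Returns 0.5 when no pair is comparable.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    r = np.asarray(risk, dtype=float)
    lt = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = lt.sum()
    if n_pairs == 0:
        return 0.5
    conc = (r[:, None] > r[None, :]) & lt
    ties = (r[:, None] == r[None, :]) & lt
    return float((conc.sum() + 0.5 * ties.sum()) / n_pairs)
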