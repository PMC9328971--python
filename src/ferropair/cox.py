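"""Lightweight Cox proportional-hazards machinery.

The pipeline fits one single-covariate Cox model per candidate pair (the
univariate screen) and one per candidate risk-score threshold (the AIC
cutoff search), so per-fit overhead matters. This module implements a
Newton solver for the one-covariate partial likelihood with Efron tie
handling, plus the Breslow-tie log partial likelihood used by the
cross-validated LASSO rule and a minimal Kaplan-Meier step function used
for censoring weights. Multivariate fits go through lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_BETA_CAP = 20.0  # |beta| cap guarding against monotone likelihood (separation)


def _order_by_time(time, event, *arrays):
    """Sort descending by time (events before censorings at ties do not
    matter for the partial likelihood; risk sets are time > t handled via
    cumulative sums from the latest time)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")
    return (time[order], event[order]) + tuple(np.asarray(a, dtype=float)[order] for a in arrays)


@dataclass
class UnivariateCoxFit:
    beta: float
    se: float
    z: float
    p: float
    loglik: float
    loglik_null: float
    converged: bool

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def aic(self) -> float:
        """2k - 2 logPL with k = 1."""
        return 2.0 - 2.0 * self.loglik


def _distinct_desc(time) -> bool:
    """True when the (descending-sorted) times are strictly distinct."""
    return len(time) < 2 or bool(np.all(np.diff(time) < 0))


def _efron_terms(x, time, event, beta):
    """Log partial likelihood, gradient and Hessian (Efron ties), one covariate.

    Inputs must be sorted descending by time. Distinct event times take a
    fully vectorized path; ties fall back to a per-block loop.
    """
    eta = beta * x
    w = np.exp(eta)
    xw = x * w
    xxw = x * x * w
    # risk-set sums: cumulative over samples with time >= t
    cw, cxw, cxxw = np.cumsum(w), np.cumsum(xw), np.cumsum(xxw)

    if _distinct_desc(time):
        pos = np.flatnonzero(event == 1)
        phi, phi1, phi2 = cw[pos], cxw[pos], cxxw[pos]
        ratio = phi1 / phi
        loglik = float(eta[pos].sum() - np.log(phi).sum())
        grad = float(x[pos].sum() - ratio.sum())
        hess = float(-(phi2 / phi - ratio * ratio).sum())
        return loglik, grad, hess

    loglik = 0.0
    grad = 0.0
    hess = 0.0
    n = len(time)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        block = slice(i, j)
        d_idx = np.flatnonzero(event[block]) + i
        d = len(d_idx)
        if d:
            s_r, s_rx, s_rxx = cw[j - 1], cxw[j - 1], cxxw[j - 1]
            s_d, s_dx, s_dxx = w[d_idx].sum(), xw[d_idx].sum(), xxw[d_idx].sum()
            loglik += eta[d_idx].sum()
            grad += x[d_idx].sum()
            frac = np.arange(d) / d
            phi = s_r - frac * s_d
            phi1 = s_rx - frac * s_dx
            phi2 = s_rxx - frac * s_dxx
            loglik -= np.log(phi).sum()
            grad -= (phi1 / phi).sum()
            hess -= (phi2 / phi - (phi1 / phi) ** 2).sum()
        i = j
    return loglik, grad, hess


def cox_loglik_single(x, time, event, beta: float) -> float:
    """Efron-tie log partial likelihood of a one-covariate model at ``beta``."""
    time, event, x = _order_by_time(time, event, x)
    return _efron_terms(x, time, event, beta)[0]


def cox_fit_single(x, time, event, max_iter: int = 50, tol: float = 1e-9) -> UnivariateCoxFit:
    """Newton-Raphson fit of a single-covariate Cox PH model (Efron ties).

    The p-value is the two-sided Wald test on beta/se. Monotone-likelihood
    instances (perfect separation) are capped at |beta| = 20 and flagged
    unconverged.
    """
    time, event, x = _order_by_time(time, event, x)
    if event.sum() == 0:
        raise ValueError("no events; the Cox partial likelihood is undefined")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")

    beta = 0.0
    ll0, _, _ = _efron_terms(x, time, event, 0.0)
    ll = ll0
    converged = False
    hess = -1.0
    for _ in range(max_iter):
        ll, grad, hess = _efron_terms(x, time, event, beta)
        if hess >= 0:  # numerically flat; bail out
            break
        step = -grad / hess
        # step-halving to keep the likelihood non-decreasing
        new_beta = beta + step
        for _ in range(30):
            if abs(new_beta) > _BETA_CAP:
                new_beta = np.sign(new_beta) * _BETA_CAP
            ll_new = _efron_terms(x, time, event, new_beta)[0]
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if abs(new_beta - beta) < tol:
            beta = new_beta
            converged = abs(beta) < _BETA_CAP
            break
        beta = new_beta

    ll, _, hess = _efron_terms(x, time, event, beta)
    se = float(1.0 / np.sqrt(-hess)) if hess < 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    if converged:
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        # monotone likelihood: the Wald SE is unusable, report the LRT p
        p = float(stats.chi2.sf(2.0 * (ll - ll0), df=1))
    return UnivariateCoxFit(
        beta=float(beta), se=se, z=float(z), p=p,
        loglik=float(ll), loglik_null=float(ll0), converged=converged,
    )


@dataclass
class MultivariateCoxFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * len(self.beta) - 2.0 * self.loglik


def _efron_terms_multi(X, time, event, beta):
    """Log partial likelihood, gradient and Hessian (Efron ties), p covariates.

    Inputs must be sorted descending by time; X is (n, p).
    """
    eta = X @ beta
    w = np.exp(eta)
    xw = X * w[:, None]                      # (n, p)
    xxw = X[:, :, None] * X[:, None, :] * w[:, None, None]  # (n, p, p)
    cw = np.cumsum(w)
    cxw = np.cumsum(xw, axis=0)
    cxxw = np.cumsum(xxw, axis=0)

    p = X.shape[1]
    if _distinct_desc(time):
        pos = np.flatnonzero(event == 1)
        phi = cw[pos]
        psi = cxw[pos] / phi[:, None]
        loglik = float(eta[pos].sum() - np.log(phi).sum())
        grad = X[pos].sum(axis=0) - psi.sum(axis=0)
        hess = -(
            np.einsum("mij->ij", cxxw[pos] / phi[:, None, None]) - psi.T @ psi
        )
        return loglik, grad, hess

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    n = len(time)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = np.flatnonzero(event[i:j]) + i
        d = len(d_idx)
        if d:
            s_r, s_rx, s_rxx = cw[j - 1], cxw[j - 1], cxxw[j - 1]
            s_d = w[d_idx].sum()
            s_dx = xw[d_idx].sum(axis=0)
            s_dxx = xxw[d_idx].sum(axis=0)
            loglik += eta[d_idx].sum()
            grad += X[d_idx].sum(axis=0)
            for l in range(d):
                f = l / d
                phi = s_r - f * s_d
                psi = (s_rx - f * s_dx) / phi
                loglik -= np.log(phi)
                grad -= psi
                hess -= (s_rxx - f * s_dxx) / phi - np.outer(psi, psi)
        i = j
    return loglik, grad, hess


def cox_fit_multi(X, time, event, max_iter: int = 100, tol: float = 1e-9) -> MultivariateCoxFit:
    """Newton-Raphson fit of a multivariate Cox PH model (Efron ties).

    Step-halving keeps the partial likelihood non-decreasing; coefficients
    are capped at |beta| = 20 against monotone-likelihood directions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x covariates)")
    time, event, *cols = _order_by_time(time, event, *X.T)
    X = np.column_stack(cols) if cols else np.empty((len(time), 0))
    if event.sum() == 0:
        raise ValueError("no events; the Cox partial likelihood is undefined")

    p = X.shape[1]
    beta = np.zeros(p)
    ll0, _, _ = _efron_terms_multi(X, time, event, beta)
    ll = ll0
    converged = False
    hess = None
    for _ in range(max_iter):
        ll, grad, hess = _efron_terms_multi(X, time, event, beta)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular information matrix (collinear covariates)")
        new_beta = beta + step
        for _ in range(30):
            np.clip(new_beta, -_BETA_CAP, _BETA_CAP, out=new_beta)
            ll_new = _efron_terms_multi(X, time, event, new_beta)[0]
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = bool(np.max(np.abs(beta)) < _BETA_CAP)
            break
        beta = new_beta

    ll, _, hess = _efron_terms_multi(X, time, event, beta)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    return MultivariateCoxFit(
        beta=beta, se=se, loglik=float(ll), loglik_null=float(ll0), converged=converged
    )


def cox_loglik_breslow(X, time, event, beta) -> float:
    """Breslow-tie log partial likelihood for a multivariate linear predictor.

    Used by the Verweij-van Houwelingen cross-validation criterion for the
    LASSO path (coxnet itself optimizes the Breslow form).
    """
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    time, event, eta = _order_by_time(time, event, eta)
    w = np.exp(eta)
    cw = np.cumsum(w)
    if _distinct_desc(time):
        pos = np.flatnonzero(event == 1)
        return float(eta[pos].sum() - np.log(cw[pos]).sum())
    loglik = 0.0
    n = len(time)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = np.flatnonzero(event[i:j]) + i
        d = len(d_idx)
        if d:
            loglik += eta[d_idx].sum() - d * np.log(cw[j - 1])
        i = j
    return float(loglik)


def km_step(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate as a right-continuous step function.

    Returns (event_times, S(event_times)); S(t) for arbitrary t is the value
    at the largest event time <= t (1.0 before the first).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time[event == 1])
    n = len(time)
    s = 1.0
    surv = np.empty(len(uniq))
    for k, t in enumerate(uniq):
        at_risk = n - np.searchsorted(time, t, side="left")
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        surv[k] = s
    return uniq, surv


def km_eval(times_grid, surv, t, left: bool = False) -> np.ndarray:
    """Evaluate a KM step function at ``t`` (right-continuous by default;
    ``left=True`` gives the left limit S(t-))."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if len(times_grid) == 0:  # no events: S identically 1
        return np.ones_like(t)
    side = "left" if left else "right"
    idx = np.searchsorted(times_grid, t, side=side) - 1
    out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
    return out


def breslow_baseline(time, event, eta) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard H0 at event times,
    for a fitted linear predictor ``eta`` (uncentered).

    Baseline survival is S0(t) = exp(-H0(t)); a sample with linear predictor
    lp survives to t with probability S0(t) ** exp(lp).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = np.asarray(eta, dtype=float)
    order = np.argsort(time, kind="stable")
    time, event, eta = time[order], event[order], eta[order]
    w = np.exp(eta)
    uniq = np.unique(time[event == 1])
    h0 = np.empty(len(uniq))
    total = w.sum()
    cum = 0.0
    ptr = 0
    for k, t in enumerate(uniq):
        while ptr < len(time) and time[ptr] < t:
            total -= w[ptr]
            ptr += 1
        d = int(((time == t) & (event == 1)).sum())
        cum += d / total
        h0[k] = cum
    return uniq, h0
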