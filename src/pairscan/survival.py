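"""Survival machinery: Kaplan-Meier, log-rank, and Cox regression.

The Cox model maximizes the Efron-tie partial likelihood by Newton-Raphson
with step halving, converging on a gradient norm below 1e-8. Monotone
likelihoods (complete separation) are detected by runaway coefficients and
reported with the coefficient capped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["km_curve", "logrank_test", "cox_ph", "CoxResult"]

_BETA_CAP = 15.0


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Returns one row per distinct event time: time, n_risk, n_event,
    survival, se (Greenwood). With no events the curve is flat at 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    gw = 0.0  # Greenwood sum
    n = time.size
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += event[j]
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            if at_risk > d:
                gw += d / (at_risk * (at_risk - d))
            se = s * np.sqrt(gw)
            rows.append((t, at_risk, d, s, se))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival", "se"])


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test. Returns (chi-square statistic, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {levels.size}")
    g1 = group == levels[1]
    obs = 0.0
    exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs - exp) ** 2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def _efron_loglik_grad_hess(
    beta: np.ndarray, time: np.ndarray, event: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, gradient, and Hessian.

    Subjects are pre-sorted by ascending time; events grouped by tied time.
    """
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wx = X * w[:, None]

    # suffix sums over the risk set {j : t_j >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.zeros((n, p, p))
    outer = wx[:, :, None] * X[:, None, :]
    s2 = np.cumsum(outer[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        t = time[i]
        j = i
        idx = []
        while j < n and time[j] == t:
            if event[j]:
                idx.append(j)
            j += 1
        d = len(idx)
        if d > 0:
            idx = np.asarray(idx)
            tie_w = w[idx].sum()
            tie_wx = wx[idx].sum(axis=0)
            tie_wxx = outer[idx].sum(axis=0)
            ll += eta[idx].sum()
            grad += X[idx].sum(axis=0)
            for r in range(d):
                f = r / d
                denom = s0[i] - f * tie_w
                num1 = s1[i] - f * tie_wx
                num2 = s2[i] - f * tie_wxx
                ll -= np.log(denom)
                grad -= num1 / denom
                hess -= num2 / denom - np.outer(num1, num1) / denom**2
        i = j
    return float(ll), grad, hess


@dataclass
class CoxResult:
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    hazard_ratios: np.ndarray
    loglik: float
    converged: bool
    monotone_flag: bool
    names: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hazard_ratios,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=self.names,
        )


def cox_ph(
    time,
    event,
    X: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional hazards fit with Efron tie handling.

    Requires at least one event. Newton-Raphson with step halving until the
    gradient norm drops below ``tol``. A coefficient escaping beyond +-15
    indicates a monotone likelihood (complete separation); it is capped and
    flagged rather than raised.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    if event.sum() == 0:
        raise ValueError("no events: Cox model inestimable")
    order = np.argsort(time, kind="mergesort")
    time, event, X = time[order], event[order], X[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik_grad_hess(beta, time, event, X)
    converged = False
    monotone = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, time, event, X)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, time, event, X)
            halvings += 1
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > _BETA_CAP):
            monotone = True
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            ll, grad, hess = _efron_loglik_grad_hess(beta, time, event, X)
            break
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return CoxResult(
        beta, se, z, pvals, np.exp(beta), ll, converged, monotone, list(names)
    )
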