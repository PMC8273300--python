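"""Cox proportional-hazards machinery: Breslow partial likelihood, analytic
gradient/Hessian, and an unpenalized Newton fitter with observed-information
standard errors. This is the shared engine behind marginal screening, the
MCP-penalized selector, the post-selection refit and the total-effect fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxDesign", "CoxFit", "log_partial_likelihood", "gradient_hessian", "fit_cox"]


def _revcumsum(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.flip(np.cumsum(np.flip(a, axis=axis), axis=axis), axis=axis)


class CoxDesign:
    """Covariate matrix plus survival outcome, pre-sorted by observed time.

    Risk sets R_i = {l : T_l >= T_i} are handled through the index of the
    first member of each tie group (``first``): with subjects sorted by time
    ascending, the risk set of subject i is the suffix starting at
    ``first[i]``. Breslow's convention is used for tied event times.
    """

    def __init__(self, covariates: np.ndarray, time: np.ndarray, event: np.ndarray):
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if covariates.shape[0] != len(time) or len(time) != len(event):
            raise ValueError("covariates, time and event must agree in length")
        if np.any(time < 0):
            raise ValueError("negative times are not allowed")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be binary")
        order = np.argsort(time, kind="stable")
        self.order = order
        self.X = np.ascontiguousarray(covariates[order])
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.first = np.searchsorted(self.time, self.time, side="left").astype(np.int64)
        self.event_idx = np.flatnonzero(self.event).astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return len(self.event_idx)


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray          # inverse observed information
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool


def log_partial_likelihood(design: CoxDesign, coef: np.ndarray) -> float:
    """Breslow log partial likelihood l_n(Q) = sum_events {eta_i - log sum_{l in R_i} exp(eta_l)}."""
    coef = np.asarray(coef, dtype=float)
    eta = design.X @ coef
    shift = eta.max() if len(eta) else 0.0
    s0 = _revcumsum(np.exp(eta - shift))
    e = design.event_idx
    if len(e) == 0:
        return 0.0
    return float(np.sum(eta[e] - (np.log(s0[design.first[e]]) + shift)))


def gradient_hessian(design: CoxDesign, coef: np.ndarray):
    """Analytic gradient and Hessian of the log partial likelihood.

    The Hessian of a concave partial likelihood is negative semi-definite;
    it is returned as-is (not negated).
    """
    coef = np.asarray(coef, dtype=float)
    X = design.X
    eta = X @ coef
    shift = eta.max() if len(eta) else 0.0
    w = np.exp(eta - shift)
    s0 = _revcumsum(w)
    s1 = _revcumsum(w[:, None] * X)
    e = design.event_idx
    q = design.q
    if len(e) == 0:
        return np.zeros(q), np.zeros((q, q))
    f = design.first[e]
    mu = s1[f] / s0[f, None]                      # (ne, q) risk-set means
    grad = X[e].sum(axis=0) - mu.sum(axis=0)
    s2 = _revcumsum(np.einsum("i,ij,ik->ijk", w, X, X))
    hess = -(np.einsum("ejk,e->jk", s2[f], 1.0 / s0[f]) - mu.T @ mu)
    return grad, hess


def fit_cox(
    design: CoxDesign,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Newton-Raphson maximization of the partial likelihood with step-halving.

    Raises if there are no events or more covariate columns than events
    (non-identifiable), or if the observed information is singular.
    """
    if design.n_events == 0:
        raise ValueError("no events: partial likelihood is flat")
    if design.q >= design.n_events:
        raise ValueError("at least as many covariates as events; fit is not identifiable")
    b = np.zeros(design.q) if init is None else np.asarray(init, dtype=float).copy()
    ll = log_partial_likelihood(design, b)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = gradient_hessian(design, b)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError("singular observed information matrix") from err
        # Step-halving keeps the ascent monotone.
        scale = 1.0
        for _ in range(40):
            cand = b + scale * step
            ll_new = log_partial_likelihood(design, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        b = cand
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0) and np.max(np.abs(scale * step)) < 1e-6:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        grad, _ = gradient_hessian(design, b)
        if np.max(np.abs(grad)) > 1e-4 * (design.n_events + 1):
            raise RuntimeError("Cox Newton iterations did not converge")
    _, hess = gradient_hessian(design, b)
    cov = np.linalg.inv(-hess)
    cov = 0.5 * (cov + cov.T)
    return CoxFit(coef=b, cov=cov, se=np.sqrt(np.diag(cov)), loglik=ll,
                  n_iter=it, converged=True)
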