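"""MCP-penalized Cox regression (Step 2).

Selects S2 = {k : beta_hat_k != 0} by maximizing the penalized log partial
likelihood l_n(Q) - sum_k P_lambda(beta_k) over the screened mediators, with
the exposure and the adjustment covariate(s) left unpenalized. P_lambda is
the minimax concave penalty (MCP)

    P_lambda(t) = lambda|t| - t^2 / (2a)   for |t| <= a*lambda,
                  a*lambda^2 / 2           otherwise,   a > 1,

which applies soft-thresholding near zero but leaves large coefficients
essentially unpenalized (nearly unbiased selection).

The solver follows the ncvreg recipe: an outer IRLS loop builds a diagonal
quadratic approximation of the partial likelihood; inner cyclic coordinate
descent applies the MCP firm-thresholding update with adaptive rescaling of
the concavity parameter (a_eff = a / v_j), which keeps every one-dimensional
subproblem strictly convex whatever the working curvature v_j. Penalized
columns are standardized to unit variance internally; coefficients are
reported on the original scale. The lambda path is descending with warm
starts; lambda is chosen by BIC on the partial likelihood by default
(deterministic), or by K-fold cross-validated partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._fast import cox_eta_gradient, mcp_cox_solve
from .cox import CoxDesign, fit_cox

__all__ = ["McpPenalty", "McpCoxFit", "MCPCoxPH", "mcp_value_deriv",
           "lambda_path", "fit_mcp_cox", "select_lambda"]


@dataclass
class McpPenalty:
    lam: float
    a: float = 3.0

    def __post_init__(self):
        if self.a <= 1:
            raise ValueError("MCP shape parameter a must exceed 1")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def mcp_value_deriv(t: float, pen: McpPenalty):
    """MCP value and derivative at coefficient t.

    P(t) = lam|t| - t^2/(2a) inside the knot |t| = a*lam, constant a*lam^2/2
    beyond; derivative (lam - |t|/a) sign(t) inside, 0 beyond.
    """
    lam, a = pen.lam, pen.a
    at = abs(t)
    if at <= a * lam:
        val = lam * at - t * t / (2.0 * a)
        der = (lam - at / a) * np.sign(t)
    else:
        val = a * lam * lam / 2.0
        der = 0.0
    return float(val), float(der)


@dataclass
class McpCoxFit:
    lambdas: np.ndarray            # descending grid
    coef_path: np.ndarray          # (q, n_lambda) on the original scale
    loglik_path: np.ndarray
    df_path: np.ndarray            # nonzero penalized count per lambda
    criterion_path: np.ndarray
    lambda_opt: float
    coef: np.ndarray               # coefficients at lambda_opt
    n_unpenalized: int
    selected: np.ndarray = field(default=None)  # 0-based penalized-column positions

    def __post_init__(self):
        if self.selected is None:
            i = int(np.argmin(np.abs(self.lambdas - self.lambda_opt)))
            self.selected = np.flatnonzero(self.coef_path[self.n_unpenalized:, i] != 0.0)

    def path_frame(self):
        """Path diagnostics: lambda, nonzero count, partial likelihood,
        criterion value."""
        import pandas as pd
        return pd.DataFrame({"lam": self.lambdas, "df": self.df_path,
                             "loglik": self.loglik_path,
                             "criterion": self.criterion_path})


def _standardize(design: CoxDesign, n_unpen: int):
    X = design.X.copy()
    scale = np.ones(X.shape[1])
    sd = X[:, n_unpen:].std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) penalized column")
    scale[n_unpen:] = sd
    X[:, n_unpen:] /= sd
    # centering leaves the partial likelihood invariant, improves conditioning
    X -= X.mean(axis=0)
    return np.ascontiguousarray(X), scale


def _null_eta_gradient(design: CoxDesign, Xs: np.ndarray, n_unpen: int):
    """Fit the unpenalized-only model and return the eta-space gradient there."""
    if n_unpen > 0:
        null_fit = fit_cox(CoxDesign(Xs[:, :n_unpen], design.time, design.event.astype(int)))
        eta = Xs[:, :n_unpen] @ null_fit.coef
        b0 = null_fit.coef
    else:
        eta = np.zeros(design.n)
        b0 = np.zeros(0)
    g, _ = cox_eta_gradient(eta, design.event.astype(np.float64), design.first, design.event_idx)
    return g, b0


def lambda_path(design: CoxDesign, n_unpen: int, n_lambda: int = 50,
                ratio: float = 0.05):
    """Descending log-spaced lambda grid from lambda_max (the smallest lambda
    at which every penalized coefficient is zero, i.e. the largest absolute
    null-model score over standardized penalized columns, scaled by 1/n)."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be >= 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    Xs, _ = _standardize(design, n_unpen)
    if Xs.shape[1] == n_unpen:
        raise ValueError("no penalized columns")
    g, _ = _null_eta_gradient(design, Xs, n_unpen)
    lam_max = np.max(np.abs(Xs[:, n_unpen:].T @ g)) / design.n
    lam_max *= 1.000001  # guard: exact zero model at the grid head
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def fit_mcp_cox(
    design: CoxDesign,
    n_unpen: int,
    a: float = 3.0,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 50,
    ratio: float = 0.05,
    criterion: str = "bic",
    cv_folds: int = 5,
    cv_seed: int = 0,
    tol: float = 1e-7,
    dfmax: int | None = None,
) -> McpCoxFit:
    """Fit the MCP-penalized Cox path with warm starts and pick lambda.

    ``n_unpen`` leading columns of the design (exposure + adjustment) are
    never penalized. Raises on designs with fewer than 2 events.

    ``dfmax`` truncates the path once the active set outgrows the sparse,
    identifiable regime; the default is n_events/5 (the liberal end of the
    events-per-variable rule for Cox models). Model selection only ever
    picks far sparser fits, so truncation does not affect the chosen model.
    """
    if design.n_events < 2:
        raise ValueError("need at least 2 events for penalized selection")
    McpPenalty(0.0, a)  # validates a
    if lambdas is None:
        lambdas = lambda_path(design, n_unpen, n_lambda, ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    Xs, scale = _standardize(design, n_unpen)
    q = Xs.shape[1]
    delta = design.event.astype(np.float64)
    _, b_null = _null_eta_gradient(design, Xs, n_unpen)

    if dfmax is None:
        dfmax = max(5, design.n_events // 10)  # classical events-per-variable rule
    coef_path = np.zeros((q, len(lambdas)))
    loglik = np.zeros(len(lambdas))
    df = np.zeros(len(lambdas), dtype=int)
    b = np.zeros(q)
    b[:n_unpen] = b_null
    capped = 0
    n_used = 0
    # Path exploration runs at the conventional loose tolerance of penalized
    # path solvers; only the criterion-chosen model is polished to `tol`.
    path_tol = max(tol, 1e-4)
    ne = max(design.n_events, 8)
    df_weight = {"bic": np.log(ne), "aic": 2.0,
                 "hq": 2.0 * np.log(np.log(ne))}.get(criterion)
    best_crit = np.inf
    past_min = 0
    for i, lam in enumerate(lambdas):
        status = mcp_cox_solve(Xs, delta, design.first, design.event_idx, b,
                               n_unpen, lam, a, 150, path_tol)
        if status < 0:
            capped += 1
        if not np.all(np.isfinite(b)) or np.max(np.abs(b)) > 1e3:
            raise RuntimeError("MCP-penalized fit diverged (unbounded coefficients)")
        coef_path[:, i] = b
        loglik[i] = _ll(design, Xs, b)
        df[i] = int(np.count_nonzero(b[n_unpen:]))
        n_used = i + 1
        if df[i] > dfmax:
            break
        if df_weight is not None:
            # stop once the criterion is decisively (and persistently) past
            # its minimum
            crit_i = -2.0 * loglik[i] + df_weight * df[i]
            if crit_i < best_crit:
                best_crit = crit_i
                past_min = 0
            elif crit_i > best_crit + 30.0:
                past_min += 1
                if past_min >= 2:
                    break
            else:
                past_min = 0
    if capped:
        warnings.warn(f"MCP coordinate descent hit the sweep cap at {capped} "
                      f"of {n_used} lambda values", RuntimeWarning)
    lambdas = lambdas[:n_used]
    coef_path = coef_path[:, :n_used]
    loglik = loglik[:n_used]
    df = df[:n_used]
    coef_path_orig = coef_path / scale[:, None]

    crit = _criterion_path(design, Xs, coef_path, df, loglik, criterion,
                           n_unpen, a, lambdas, cv_folds, cv_seed, ratio, path_tol)
    i_opt = select_lambda_index(lambdas, crit)
    # polish the chosen model to full tolerance (warm-started)
    b_opt = coef_path[:, i_opt].copy()
    status = mcp_cox_solve(Xs, delta, design.first, design.event_idx, b_opt,
                           n_unpen, float(lambdas[i_opt]), a, 2000, tol)
    if status < 0:
        warnings.warn("MCP polish at the selected lambda hit the sweep cap",
                      RuntimeWarning)
    coef_path[:, i_opt] = b_opt
    coef_path_orig[:, i_opt] = b_opt / scale
    loglik[i_opt] = _ll(design, Xs, b_opt)
    df[i_opt] = int(np.count_nonzero(b_opt[n_unpen:]))
    return McpCoxFit(
        lambdas=lambdas, coef_path=coef_path_orig, loglik_path=loglik,
        df_path=df, criterion_path=crit, lambda_opt=float(lambdas[i_opt]),
        coef=coef_path_orig[:, i_opt], n_unpenalized=n_unpen,
        selected=np.flatnonzero(coef_path[n_unpen:, i_opt] != 0.0),
    )


def _ll(design: CoxDesign, Xs: np.ndarray, b: np.ndarray) -> float:
    """Partial likelihood at standardized-scale coefficients (scale-free)."""
    from .cox import _revcumsum
    eta = Xs @ b
    shift = eta.max()
    s0 = _revcumsum(np.exp(eta - shift))
    e = design.event_idx
    return float(np.sum(eta[e] - (np.log(s0[design.first[e]]) + shift)))


def _criterion_path(design, Xs, coef_path, df, loglik, criterion, n_unpen, a,
                    lambdas, cv_folds, cv_seed, ratio, tol):
    ne = max(design.n_events, 8)
    if criterion == "bic":
        return -2.0 * loglik + np.log(ne) * df
    if criterion == "aic":
        return -2.0 * loglik + 2.0 * df
    if criterion == "hq":
        # Hannan-Quinn: between AIC and BIC in selection strictness
        return -2.0 * loglik + 2.0 * np.log(np.log(ne)) * df
    if criterion != "cv":
        raise ValueError(f"unknown lambda-selection criterion {criterion!r}")
    # K-fold cross-validated partial likelihood (Verweij-van Houwelingen):
    # cv contribution of fold f = ll_full(coef_-f) - ll_train(coef_-f).
    rng = np.random.default_rng(cv_seed)
    folds = rng.permutation(design.n) % cv_folds
    delta = design.event.astype(np.float64)
    cvll = np.zeros(len(lambdas))
    for f in range(cv_folds):
        keep = folds != f
        sub = CoxDesign(design.X[keep], design.time[keep], design.event[keep].astype(int))
        Xs_sub = Xs[keep]
        b = np.zeros(Xs.shape[1])
        for i, lam in enumerate(lambdas):
            mcp_cox_solve(np.ascontiguousarray(Xs_sub), delta[keep], sub.first,
                          sub.event_idx, b, n_unpen, lam, a, 1000, tol)
            cvll[i] += _ll(design, Xs, b) - _ll(sub, Xs_sub, b)
    return -cvll  # minimized, like BIC


def select_lambda_index(lambdas: np.ndarray, criterion_values: np.ndarray) -> int:
    """Index of the criterion minimizer; ties resolved toward larger lambda."""
    return int(np.argmin(criterion_values))


def select_lambda(fit: McpCoxFit) -> float:
    return float(fit.lambdas[select_lambda_index(fit.lambdas, fit.criterion_path)])


class MCPCoxPH(BaseEstimator):
    """MCP-penalized Cox model with unpenalized leading columns.

    fit(X, y) where the first ``n_unpenalized`` columns of X are structural
    (exposure, adjustment) and y is a (time, event) pair of arrays.
    """

    def __init__(self, a: float = 3.0, n_lambda: int = 50, ratio: float = 0.05,
                 criterion: str = "bic", n_unpenalized: int = 0):
        self.a = a
        self.n_lambda = n_lambda
        self.ratio = ratio
        self.criterion = criterion
        self.n_unpenalized = n_unpenalized

    def fit(self, X, y) -> "MCPCoxPH":
        time, event = y
        design = CoxDesign(X, time, event)
        res = fit_mcp_cox(design, self.n_unpenalized, a=self.a,
                          n_lambda=self.n_lambda, ratio=self.ratio,
                          criterion=self.criterion)
        self.result_ = res
        self.coef_ = res.coef
        self.lambda_ = res.lambda_opt
        self.support_ = res.selected
        return self
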