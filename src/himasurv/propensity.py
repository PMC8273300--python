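"""Propensity-score estimation (Step 0).

The propensity score pi_i = Pr(X_i = 1 | Z_i) is estimated by maximum-
likelihood logistic regression of the binary exposure on the measured
confounders (intercept always included). Downstream mediation models receive
a single adjustment covariate: either pi itself or its logit, the fitted
linear predictor theta0 + theta' Z_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator

__all__ = ["PropensityFit", "PropensityScore", "fit_propensity", "attach_covariate"]

_CLIP = 1e-6
_SEPARATION_BOUND = 30.0


@dataclass
class PropensityFit:
    theta0: float
    theta: np.ndarray
    scores: np.ndarray            # pi_i in (0, 1)
    linear_predictor: np.ndarray  # logit pi_i
    covariate_form: str           # "score" | "logit"
    converged: bool

    def covariate(self, form: str | None = None) -> np.ndarray:
        form = self.covariate_form if form is None else form
        if form == "score":
            return self.scores
        if form in ("logit", "logit-score"):
            return self.linear_predictor
        raise ValueError(f"unknown covariate form {form!r}")


class PropensityScore(BaseEstimator):
    """Logistic-regression propensity model, sklearn-style.

    Parameters
    ----------
    covariate_form : {"score", "logit"}
        Which transform `transform` emits as the adjustment covariate. The
        mediation equations use the score pi_i itself; the simulation study
        and the applied analysis use the logit.
    """

    def __init__(self, covariate_form: str = "score"):
        self.covariate_form = covariate_form

    def fit(self, Z: np.ndarray, x: np.ndarray) -> "PropensityScore":
        fit = fit_propensity(np.asarray(x), np.asarray(Z), form=self.covariate_form)
        self.theta0_ = fit.theta0
        self.theta_ = fit.theta
        self.scores_ = fit.scores
        self.linear_predictor_ = fit.linear_predictor
        self.fit_ = fit
        return self

    def transform(self, Z: np.ndarray) -> np.ndarray:
        lp = self.theta0_ + np.atleast_2d(Z) @ self.theta_
        if self.covariate_form == "score":
            return 1.0 / (1.0 + np.exp(-lp))
        return lp


def fit_propensity(X: np.ndarray, Z: np.ndarray, form: str = "score") -> PropensityFit:
    """Maximum-likelihood logistic fit of exposure on confounders.

    Uses Newton iterations (statsmodels); with the intercept included the
    score equations force sum(pi_i) == sum(X_i) at the optimum. Perfect or
    quasi-separation is reported with a warning and the scores are clipped
    away from {0, 1} rather than silently diverging.
    """
    X = np.asarray(X, dtype=float).ravel()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(X):
        raise ValueError("X and Z must have the same number of subjects")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("exposure must be binary 0/1")
    if X.min() == X.max():
        raise ValueError("both exposure arms must be represented")
    design = sm.add_constant(Z, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("confounder matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels' own separation chatter
        model = sm.Logit(X, design)
        separated = False
        try:
            res = model.fit(method="newton", maxiter=200, tol=1e-10, disp=False)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under (quasi-)separation; a
            # gradient method still yields finite, clippable scores.
            separated = True
            res = model.fit(method="bfgs", maxiter=500, disp=False)
    params = np.asarray(res.params, dtype=float)
    lp = design @ params
    if separated or np.max(np.abs(lp)) > _SEPARATION_BOUND:
        warnings.warn(
            "possible separation in the propensity model: extreme fitted "
            "linear predictors; scores clipped", RuntimeWarning)
    scores = np.clip(1.0 / (1.0 + np.exp(-lp)), _CLIP, 1.0 - _CLIP)
    return PropensityFit(
        theta0=float(params[0]), theta=params[1:], scores=scores,
        linear_predictor=lp, covariate_form=form,
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def attach_covariate(dataset, fit: PropensityFit | None, mode: str = "ps",
                     form: str | None = None) -> np.ndarray:
    """Return the (n, c) adjustment-covariate block for the requested mode:
    the propensity score/logit column ("ps"), the raw confounders ("z"), or
    an empty block ("naive")."""
    n = dataset.n_subjects
    if mode == "naive":
        return np.empty((n, 0))
    if mode == "z":
        return dataset.confounders
    if mode != "ps":
        raise ValueError(f"unknown adjustment mode {mode!r}")
    if fit is None:
        raise ValueError("PS mode requires a fitted propensity model")
    col = fit.covariate(form)
    if len(col) != n:
        raise ValueError("propensity scores do not match dataset length")
    return col[:, None]
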