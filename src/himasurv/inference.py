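"""Per-mediator effect estimation and significance testing (Step 3).

For every mediator k kept by the penalized selection (k in S2):

* ``alpha_hat_k`` — OLS coefficient of the exposure in M_k ~ 1 + X + adj;
* ``beta_hat_k``  — log-hazard coefficient of M_k in one unpenalized Cox
  refit with columns (X, adj, M_k for all k in S2);
* Sobel test of H0: alpha_k beta_k = 0 with the first-order delta-method SE
  sqrt(beta^2 se_alpha^2 + alpha^2 se_beta^2);
* joint significance test: p = max(p_alpha, p_beta), each a two-sided
  normal test of its path coefficient;
* Bonferroni adjustment over |S2|: P_k = min(P_raw_k * |S2|, 1);
* hazard ratio exp(alpha beta) with Wald CI on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cox import CoxDesign, CoxFit, fit_cox

__all__ = [
    "MediationRecord", "TotalEffect", "fit_alpha", "refit_beta", "sobel_test",
    "joint_test", "bonferroni_adjust", "indirect_hr", "estimate_total_effect",
    "build_records",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class MediationRecord:
    mediator: int                 # 1-based id
    alpha_hat: float
    alpha_se: float
    beta_hat: float
    beta_se: float
    indirect: float               # alpha_hat * beta_hat (log-hazard scale)
    sobel_se: float
    p_sobel_raw: float
    p_alpha: float
    p_beta: float
    p_joint_raw: float
    p_sobel: float                # Bonferroni-adjusted
    p_joint: float
    hr: float
    hr_ci: tuple

    def significant(self, test: str = "joint", threshold: float = 0.05) -> bool:
        p = self.p_joint if test == "joint" else self.p_sobel
        return p < threshold


@dataclass
class TotalEffect:
    log_hr: float
    se: float
    hr: float
    ci: tuple


def fit_alpha(dataset, adjustment: np.ndarray, k: int):
    """OLS of mediator k (1-based) on intercept, exposure and adjustment;
    returns (alpha_hat, alpha_se)."""
    if not 1 <= k <= dataset.n_mediators:
        raise ValueError("mediator index out of range")
    x = np.asarray(dataset.exposure, dtype=float)
    if x.min() == x.max():
        raise ValueError("exposure has no variation")
    A = np.column_stack([np.ones(len(x)), x, adjustment])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("collinear design in the exposure->mediator regression")
    y = dataset.mediators[:, k - 1]
    AtA_inv = np.linalg.inv(A.T @ A)
    coef = AtA_inv @ (A.T @ y)
    resid = y - A @ coef
    dof = len(x) - A.shape[1]
    sigma2 = float(resid @ resid) / dof
    return float(coef[1]), float(np.sqrt(sigma2 * AtA_inv[1, 1]))


def refit_beta(dataset, adjustment: np.ndarray, s2: np.ndarray):
    """Unpenalized Cox refit on (X, adjustment, M_k for k in S2).

    Returns ``(betas, beta_ses, fit)`` where betas/beta_ses align with the
    (1-based) ids in ``s2`` and ``fit`` carries the direct effect of the
    exposure in its leading coefficient.
    """
    s2 = np.asarray(s2, dtype=int)
    x = np.asarray(dataset.exposure, dtype=float)
    n_events = int(np.sum(dataset.event))
    n_unpen = 1 + adjustment.shape[1]
    if len(s2) + n_unpen + 1 >= n_events:
        raise ValueError("too many selected mediators for the number of events")
    cols = [x[:, None], adjustment]
    if len(s2):
        cols.append(dataset.mediators[:, s2 - 1])
    design = CoxDesign(np.hstack(cols), dataset.time, dataset.event)
    fit = fit_cox(design)
    betas = fit.coef[n_unpen:]
    ses = fit.se[n_unpen:]
    return betas, ses, fit


def sobel_test(alpha_hat, alpha_se, beta_hat, beta_se, second_order: bool = False):
    """Sobel SE and two-sided normal p-value for H0: alpha*beta = 0."""
    if alpha_se <= 0 or beta_se <= 0:
        raise ValueError("standard errors must be positive")
    var = beta_hat**2 * alpha_se**2 + alpha_hat**2 * beta_se**2
    if second_order:
        var += alpha_se**2 * beta_se**2
    se = float(np.sqrt(var))
    z = abs(alpha_hat * beta_hat) / se
    return se, float(2.0 * stats.norm.sf(z))


def joint_test(p_alpha: float, p_beta: float) -> float:
    """Joint-significance p-value: the larger of the two path p-values."""
    return max(p_alpha, p_beta)


def bonferroni_adjust(p_raw: float, s2_size: int) -> float:
    """P_k = min(P_raw_k * |S2|, 1)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if s2_size < 1:
        raise ValueError("|S2| must be at least 1")
    return min(p_raw * s2_size, 1.0)


def indirect_hr(indirect: float, sobel_se: float):
    """Hazard ratio exp(alpha*beta) with a Wald 95% CI on the log scale."""
    hr = float(np.exp(indirect))
    half = _Z975 * sobel_se
    return hr, (float(np.exp(indirect - half)), float(np.exp(indirect + half)))


def estimate_total_effect(dataset, adjustment: np.ndarray) -> TotalEffect:
    """Cox fit of the outcome on exposure + adjustment only (total effect)."""
    x = np.asarray(dataset.exposure, dtype=float)
    if x.min() == x.max():
        raise ValueError("exposure has no variation")
    design = CoxDesign(np.column_stack([x, adjustment]), dataset.time, dataset.event)
    fit = fit_cox(design)
    log_hr, se = float(fit.coef[0]), float(fit.se[0])
    return TotalEffect(log_hr=log_hr, se=se, hr=float(np.exp(log_hr)),
                       ci=(float(np.exp(log_hr - _Z975 * se)),
                           float(np.exp(log_hr + _Z975 * se))))


def build_records(dataset, adjustment: np.ndarray, s2: np.ndarray,
                  second_order_sobel: bool = False):
    """Assemble one MediationRecord per mediator in S2 plus the refit itself.

    Returns ``(records, refit)``; with S2 empty, records is empty and refit is
    the direct-effect-only Cox fit.
    """
    s2 = np.asarray(s2, dtype=int)
    if len(s2) == 0:
        _, _, fit = refit_beta(dataset, adjustment, s2)
        return [], fit
    betas, beta_ses, fit = refit_beta(dataset, adjustment, s2)
    records = []
    m = len(s2)
    for j, k in enumerate(s2):
        a_hat, a_se = fit_alpha(dataset, adjustment, int(k))
        b_hat, b_se = float(betas[j]), float(beta_ses[j])
        indirect = a_hat * b_hat
        sob_se, p_sob = sobel_test(a_hat, a_se, b_hat, b_se, second_order_sobel)
        p_a = float(2.0 * stats.norm.sf(abs(a_hat) / a_se))
        p_b = float(2.0 * stats.norm.sf(abs(b_hat) / b_se))
        p_j = joint_test(p_a, p_b)
        hr, ci = indirect_hr(indirect, sob_se)
        records.append(MediationRecord(
            mediator=int(k), alpha_hat=a_hat, alpha_se=a_se, beta_hat=b_hat,
            beta_se=b_se, indirect=indirect, sobel_se=sob_se,
            p_sobel_raw=p_sob, p_alpha=p_a, p_beta=p_b, p_joint_raw=p_j,
            p_sobel=bonferroni_adjust(p_sob, m), p_joint=bonferroni_adjust(p_j, m),
            hr=hr, hr_ci=ci,
        ))
    return records, fit
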