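"""Sure independence screening (Step 1).

Reduces the p mediators to d = ceil(2n / log n) candidates ranked by marginal
association p-values. The factor 2 (rather than the usual n/log n) doubles
the retained set because a mediator must survive both the exposure->mediator
and mediator->outcome paths.

Modes
-----
outcome   Wald p-value of M_k in the Cox model (X, adjustment, M_k) — the
          default, matching "P-values for the response variable".
exposure  p-value of the exposure coefficient in the linear model
          M_k ~ X + adjustment — the path used in the applied analysis.
union     top ceil(d/2) from each path, merged, topped up to d by the best
          remaining min-p ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._fast import marginal_cox_wald
from .cox import CoxDesign

__all__ = ["ScreeningResult", "SISScreener", "screening_size", "screen_mediators"]


def screening_size(n: int) -> int:
    """d = ceil(2n / ln n); requires n >= 3 so that ln n > 1."""
    if n < 3:
        raise ValueError("screening size is defined for n >= 3")
    return int(math.ceil(2.0 * n / math.log(n)))


@dataclass
class ScreeningResult:
    selected: np.ndarray        # 1-based mediator ids, size min(d, p)
    pvalues: np.ndarray         # (p,) marginal p-values under `mode`
    mode: str
    d: int
    pvalues_exposure: np.ndarray | None = None  # populated in union mode

    @property
    def selected_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.pvalues), dtype=bool)
        mask[self.selected - 1] = True
        return mask

    def to_frame(self):
        """Screening report: mediator id, mode, p-value, selected flag."""
        import pandas as pd
        return pd.DataFrame({
            "mediator": np.arange(1, len(self.pvalues) + 1),
            "mode": self.mode,
            "pvalue": self.pvalues,
            "selected": self.selected_mask,
        })


def _rank_smallest(pvals: np.ndarray, d: int) -> np.ndarray:
    """Indices (0-based) of the d smallest p-values, ties broken by lower index."""
    order = np.lexsort((np.arange(len(pvals)), pvals))
    return np.sort(order[:d])


def _outcome_pvalues(dataset, adjustment: np.ndarray, max_iter=8, tol=1e-6) -> np.ndarray:
    """Per-mediator Wald p-values in the marginal Cox model (X, adj, M_k)."""
    common = np.column_stack([np.asarray(dataset.exposure, dtype=float), adjustment])
    design = CoxDesign(common, dataset.time, dataset.event)
    med_sorted = np.ascontiguousarray(dataset.mediators[design.order])
    z, ok = marginal_cox_wald(
        np.ascontiguousarray(design.X), med_sorted, design.first,
        design.event_idx, max_iter, tol,
    )
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals[~ok] = 1.0  # non-convergent fits are kept, flagged uninformative
    return pvals


def _exposure_pvalues(dataset, adjustment: np.ndarray) -> np.ndarray:
    """Per-mediator p-values of alpha_k in the OLS M_k ~ 1 + X + adj,
    computed in one vectorized pass."""
    n = dataset.n_subjects
    A = np.column_stack([np.ones(n), np.asarray(dataset.exposure, dtype=float), adjustment])
    q = A.shape[1]
    if n <= q:
        raise ValueError("too few subjects for the exposure-path regression")
    AtA_inv = np.linalg.inv(A.T @ A)
    coef = AtA_inv @ (A.T @ dataset.mediators)          # (q, p)
    resid = dataset.mediators - A @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / (n - q)
    se = np.sqrt(np.maximum(sigma2 * AtA_inv[1, 1], 1e-300))
    z = coef[1] / se
    return 2.0 * stats.norm.sf(np.abs(z))


def screen_mediators(dataset, adjustment: np.ndarray | None = None,
                     mode: str = "outcome", d: int | None = None) -> ScreeningResult:
    """Rank mediators by marginal p-value and keep the top min(d, p)."""
    p = dataset.n_mediators
    if d is None:
        d = screening_size(dataset.n_subjects)
    if adjustment is None:
        adjustment = np.empty((dataset.n_subjects, 0))
    d_eff = min(d, p)
    if mode == "outcome":
        pvals = _outcome_pvalues(dataset, adjustment)
        sel = _rank_smallest(pvals, d_eff)
        return ScreeningResult(sel + 1, pvals, mode, d)
    if mode == "exposure":
        pvals = _exposure_pvalues(dataset, adjustment)
        sel = _rank_smallest(pvals, d_eff)
        return ScreeningResult(sel + 1, pvals, mode, d)
    if mode == "union":
        p_out = _outcome_pvalues(dataset, adjustment)
        p_exp = _exposure_pvalues(dataset, adjustment)
        half = math.ceil(d_eff / 2)
        chosen = set(_rank_smallest(p_out, min(half, p)).tolist())
        chosen |= set(_rank_smallest(p_exp, min(half, p)).tolist())
        combined = np.minimum(p_out, p_exp)
        for idx in np.lexsort((np.arange(p), combined)):
            if len(chosen) >= d_eff:
                break
            chosen.add(int(idx))
        sel = np.sort(np.fromiter(chosen, dtype=np.int64))[:d_eff]
        return ScreeningResult(sel + 1, p_out, mode, d, pvalues_exposure=p_exp)
    raise ValueError(f"unknown screening mode {mode!r}")


class SISScreener(BaseEstimator):
    """Sure-independence-screening feature selector over mediator columns."""

    def __init__(self, mode: str = "outcome", d: int | None = None):
        self.mode = mode
        self.d = d

    def fit(self, dataset, adjustment=None) -> "SISScreener":
        res = screen_mediators(dataset, adjustment, mode=self.mode, d=self.d)
        self.result_ = res
        self.selected_ = res.selected
        self.support_ = res.selected_mask
        self.pvalues_ = res.pvalues
        return self

    def transform(self, M: np.ndarray) -> np.ndarray:
        return np.atleast_2d(M)[:, self.support_]
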