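"""Synthetic data generator for the simulation study.

The data-generating process mimics an epigenome-wide observational study of a
binary exposure (e.g. smoking), high-dimensional continuous mediators (e.g.
DNA-methylation levels) and a right-censored survival outcome, with ten
baseline confounders driving exposure, mediators and hazard simultaneously:

1. Confounders ``Z``: five i.i.d. Bernoulli(0.3) plus five equicorrelated
   standard normals (pairwise covariance 0.3).
2. Exposure ``X ~ Bernoulli(expit(theta' Z))`` (no intercept).
3. Mediators ``M_k = c_k + alpha_k X + phi' Z + e_k`` with ``c_k ~ U(0,1)``,
   ``e_k ~ N(0,1)``, and one shared confounder loading ``phi`` across all k
   (which induces the ~0.5 pairwise correlation among null mediators).
4. Death time ``D`` exponential with hazard
   ``lambda0 * exp(gamma X + beta' M + varphi' Z)``.
5. Censoring ``C ~ U(0, c0)`` with ``c0`` calibrated by Monte-Carlo
   root-finding to hit a target censoring fraction; ``T = min(D, C)``,
   ``delta = 1{D <= C}``.

Only mediators with ``alpha_k * beta_k != 0`` (indices 1-4 under the default
coefficient vectors) carry a true indirect effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "SimConfig",
    "MediationDataset",
    "generate_confounders",
    "generate_exposure",
    "generate_mediators",
    "generate_survival",
    "calibrate_censoring",
    "generate_dataset",
]

# Default coefficient vectors of the simulation design (first entries; the
# remaining alpha/beta entries are zero).
_THETA = (0.2, 0.3, 0.3, 0.5, 0.6, 0.2, 0.3, 0.3, 0.5, 0.6)
_ALPHA_HEAD = (0.5, 0.6, 0.5, 0.6, 0.5, 0.5, 0.0, 0.0)
_BETA_HEAD = (0.6, 0.6, 0.5, 0.5, 0.0, 0.0, 0.5, 0.5)
_PHI_MEDIATOR = (0.3, 0.0, 0.4, 0.2, 0.5, 0.0, 0.4, 0.2, 0.5, 0.3)
_PHI_OUTCOME = (0.0, 0.2, 0.2, 0.3, 0.2, 0.3, 0.0, 0.2, 0.3, 0.2)


def _expand(head: Sequence[float], p: int) -> np.ndarray:
    out = np.zeros(p)
    k = min(len(head), p)
    out[:k] = np.asarray(head, dtype=float)[:k]
    return out


@dataclass
class SimConfig:
    """Parameters of the simulation data-generating process.

    Defaults reproduce the published study conditions; ``n_mediators`` is the
    only size knob routinely lowered for desk-scale runs (the screening size
    depends only on ``n_subjects``, so selection dynamics are preserved).
    """

    n_subjects: int = 500
    n_mediators: int = 10_000
    theta: np.ndarray = field(default_factory=lambda: np.asarray(_THETA))
    alpha_true: Optional[np.ndarray] = None   # filled per n_mediators
    beta_true: Optional[np.ndarray] = None
    phi_mediator: np.ndarray = field(default_factory=lambda: np.asarray(_PHI_MEDIATOR))
    phi_outcome: np.ndarray = field(default_factory=lambda: np.asarray(_PHI_OUTCOME))
    gamma: float = 0.5
    baseline_hazard: float = 0.5
    bern_prob: float = 0.3
    normal_corr: float = 0.3
    target_censoring: float = 0.15
    c0: Optional[float] = None                # pre-calibrated censoring bound
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_mediators < 1:
            raise ValueError("n_mediators must be positive")
        if not 0.0 < self.bern_prob < 1.0:
            raise ValueError("bern_prob must lie in (0, 1)")
        if not 0.0 <= self.target_censoring < 1.0:
            raise ValueError("target_censoring must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi_mediator = np.asarray(self.phi_mediator, dtype=float)
        self.phi_outcome = np.asarray(self.phi_outcome, dtype=float)
        p = self.n_mediators
        if self.alpha_true is None:
            self.alpha_true = _expand(_ALPHA_HEAD, p)
        else:
            self.alpha_true = np.asarray(self.alpha_true, dtype=float)
        if self.beta_true is None:
            self.beta_true = _expand(_BETA_HEAD, p)
        else:
            self.beta_true = np.asarray(self.beta_true, dtype=float)
        if len(self.alpha_true) != p or len(self.beta_true) != p:
            raise ValueError("alpha_true/beta_true must have length n_mediators")

    @property
    def true_indices(self) -> np.ndarray:
        """1-based indices of mediators with alpha_k * beta_k != 0."""
        return np.flatnonzero(self.alpha_true * self.beta_true != 0.0) + 1

    @property
    def true_products(self) -> np.ndarray:
        prod = self.alpha_true * self.beta_true
        return prod[prod != 0.0]

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class MediationDataset:
    """One simulated (or loaded) dataset in subject-major layout."""

    exposure: np.ndarray          # (n,) binary
    mediators: np.ndarray         # (n, p)
    confounders: np.ndarray       # (n, m)
    time: np.ndarray              # (n,) observed time T = min(D, C)
    event: np.ndarray             # (n,) failure indicator delta
    true_indices: Optional[np.ndarray] = None   # 1-based mediator ids
    true_products: Optional[np.ndarray] = None  # alpha_k * beta_k for those ids
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.exposure)
        self.exposure = np.asarray(self.exposure)
        self.mediators = np.atleast_2d(np.asarray(self.mediators, dtype=float))
        self.confounders = np.atleast_2d(np.asarray(self.confounders, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (self.mediators.shape[0] == self.confounders.shape[0]
                == len(self.time) == len(self.event) == n):
            raise ValueError("inconsistent dimensions across dataset fields")
        if np.any(self.time < 0):
            raise ValueError("observed times must be nonnegative")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be binary")
        if self.true_indices is not None:
            ti = np.asarray(self.true_indices)
            if ti.size and (ti.min() < 1 or ti.max() > self.n_mediators):
                raise ValueError("truth indices must lie in 1..p")

    @property
    def n_subjects(self) -> int:
        return len(self.exposure)

    @property
    def n_mediators(self) -> int:
        return self.mediators.shape[1]

    @property
    def censoring_rate(self) -> float:
        return float(1.0 - np.mean(self.event))


def generate_confounders(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the n x 10 confounder matrix (5 Bernoulli + 5 equicorrelated normal)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rho = cfg.normal_corr
    cov = np.full((5, 5), rho)
    np.fill_diagonal(cov, 1.0)
    # Equicorrelation is PD iff rho in (-1/4, 1); reject anything else early.
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("normal_corr yields a non-positive-definite covariance")
    zb = (rng.random((n, 5)) < cfg.bern_prob).astype(float)
    zn = rng.multivariate_normal(np.zeros(5), cov, size=n, method="cholesky")
    return np.hstack([zb, zn])


def generate_exposure(Z: np.ndarray, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli exposure with logistic success probability expit(theta' Z)."""
    Z = np.atleast_2d(Z)
    theta = np.asarray(theta, dtype=float)
    if Z.shape[1] != len(theta):
        raise ValueError("theta length must match number of confounder columns")
    prob = expit(Z @ theta)
    return (rng.random(Z.shape[0]) < prob).astype(np.int64)


def generate_mediators(
    X: np.ndarray,
    Z: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    columns: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mediator matrix M_k = c_k + alpha_k X + phi' Z + e_k.

    The confounder loading ``phi`` is shared across mediators, so all columns
    carry one common ``phi' Z`` component. ``columns`` restricts generation to
    a subset of 0-based mediator indices (used by the censoring pilot, which
    only needs the columns with nonzero beta).
    """
    X = np.asarray(X, dtype=float)
    Z = np.atleast_2d(Z)
    n = len(X)
    if Z.shape[0] != n:
        raise ValueError("X and Z must have the same number of subjects")
    idx = np.arange(cfg.n_mediators) if columns is None else np.asarray(columns)
    c = rng.uniform(0.0, 1.0, size=len(idx))
    shared = Z @ cfg.phi_mediator
    e = rng.standard_normal((n, len(idx)))
    return c[None, :] + X[:, None] * cfg.alpha_true[idx][None, :] + shared[:, None] + e


def _linear_predictor(X, M, Z, cfg, columns=None):
    beta = cfg.beta_true if columns is None else cfg.beta_true[columns]
    return cfg.gamma * np.asarray(X, dtype=float) + M @ beta + Z @ cfg.phi_outcome


def generate_survival(
    X: np.ndarray,
    M: np.ndarray,
    Z: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    c0: Optional[float] = None,
    columns: Optional[np.ndarray] = None,
):
    """Exponential death times under the proportional-hazards model, with
    independent U(0, c0) censoring. Returns ``(time, event)``; with ``c0``
    None no censoring is applied."""
    lp = _linear_predictor(X, M, Z, cfg, columns)
    u = rng.uniform(size=len(lp))
    # Exact inversion of the exponential survival function.
    death = -np.log(u) / (cfg.baseline_hazard * np.exp(lp))
    if c0 is None:
        return death, np.ones(len(lp), dtype=np.int64)
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    cens = rng.uniform(0.0, c0, size=len(lp))
    time = np.minimum(death, cens)
    event = (death <= cens).astype(np.int64)
    return time, event


def calibrate_censoring(
    cfg: SimConfig,
    target: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    pilot_n: int = 20_000,
    tol: float = 0.005,
) -> float:
    """Find the uniform-censoring bound c0 giving the target censoring rate.

    A pilot sample of death times D is simulated once; conditional on D the
    censoring probability under C ~ U(0, c0) is exactly E[min(D/c0, 1)], a
    continuous decreasing function of c0, which is solved by Brent's method.
    """
    if target is None:
        target = cfg.target_censoring
    if not 0.0 < target < 1.0:
        raise ValueError("target censoring must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cols = np.flatnonzero(cfg.beta_true != 0.0)
    Z = generate_confounders(pilot_n, cfg, rng)
    X = generate_exposure(Z, cfg.theta, rng)
    M = generate_mediators(X, Z, cfg, rng, columns=cols)
    death, _ = generate_survival(X, M, Z, cfg, rng, c0=None, columns=cols)

    def rate(c0):
        return float(np.mean(np.minimum(death / c0, 1.0))) - target

    lo, hi = 1e-12, float(np.max(death))
    # rate(lo) ~ 1 - target > 0; expand hi until the bracket is valid.
    for _ in range(200):
        if rate(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("censoring calibration failed to bracket the root")
    c0 = brentq(rate, lo, hi, xtol=1e-10, rtol=1e-12)
    if abs(rate(c0)) > tol:
        raise RuntimeError("censoring calibration did not reach tolerance")
    return float(c0)


def generate_dataset(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> MediationDataset:
    """Assemble one full dataset (confounders, exposure, mediators, survival)
    with its ground-truth manifest. Deterministic given ``cfg.seed`` (or the
    supplied generator)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    Z = generate_confounders(n, cfg, rng)
    X = generate_exposure(Z, cfg.theta, rng)
    M = generate_mediators(X, Z, cfg, rng)
    c0 = cfg.c0
    if c0 is None and cfg.target_censoring > 0:
        c0 = calibrate_censoring(cfg, cfg.target_censoring, np.random.default_rng(rng.integers(2**31)))
    time, event = generate_survival(X, M, Z, cfg, rng, c0=c0)
    return MediationDataset(
        exposure=X, mediators=M, confounders=Z, time=time, event=event,
        true_indices=cfg.true_indices, true_products=cfg.true_products,
        seed=cfg.seed,
    )
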