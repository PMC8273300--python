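"""End-to-end orchestration (Steps 0-3) and the replicated simulation study.

Three adjustment modes are compared throughout:

* ``ps``    — Step 0 propensity score; the single PS covariate (logit form by
              default, matching the published simulation setup) enters every
              downstream model;
* ``z``     — all confounder columns enter directly;
* ``naive`` — no confounder adjustment anywhere.

The simulation study replays the published design: replicated datasets, the
full pipeline per mode, selection accuracy (TPR / FP / FDP against the true
mediator set) and conditional indirect-effect estimation (mean and MSE of
alpha_hat*beta_hat over replications in which each mediator was selected
into S2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import inference
from .cox import CoxDesign
from .mcp import fit_mcp_cox
from .propensity import attach_covariate, fit_propensity
from .screening import screen_mediators, screening_size
from .synthetic import MediationDataset, SimConfig, calibrate_censoring, generate_dataset

__all__ = ["PipelineConfig", "PipelineResult", "SelectionMetrics", "MediationAnalysis",
           "run_pipeline", "evaluate_selection", "run_simulation_study"]


@dataclass
class PipelineConfig:
    mode: str = "ps"                  # ps | z | naive
    test: str = "joint"               # joint | sobel | both
    screen: str = "outcome"           # outcome | exposure | union
    threshold: float = 0.05
    ps_form: str = "logit"            # logit | score (PS mode only)
    mcp_a: float = 3.0
    n_lambda: int = 50
    lambda_ratio: float = 0.05
    criterion: str = "bic"
    second_order_sobel: bool = False

    def __post_init__(self):
        if self.mode not in ("ps", "z", "naive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.test not in ("joint", "sobel", "both"):
            raise ValueError(f"unknown test {self.test!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    s1: np.ndarray                    # screened mediator ids (1-based)
    s2: np.ndarray                    # selected mediator ids (1-based)
    records: list                     # MediationRecord per k in S2
    significant: dict                 # test -> sorted 1-based id array
    total_effect: inference.TotalEffect
    direct_effect: float              # exposure log-HR in the refit
    counts: dict                      # p -> |S1| -> |S2| -> #significant
    propensity: object = None
    screening: object = None          # ScreeningResult

    def records_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        df = pd.DataFrame(rows, columns=[f.name for f in dataclasses.fields(inference.MediationRecord)])
        return df


def run_pipeline(dataset: MediationDataset, config: PipelineConfig | None = None) -> PipelineResult:
    """Steps 0-3 on one dataset under the configured adjustment mode."""
    cfg = config or PipelineConfig()
    # Step 0: adjustment covariate
    ps_fit = None
    if cfg.mode == "ps":
        ps_fit = fit_propensity(dataset.exposure, dataset.confounders, form=cfg.ps_form)
    adj = attach_covariate(dataset, ps_fit, mode=cfg.mode, form=cfg.ps_form)
    # Step 1: sure independence screening
    screen = screen_mediators(dataset, adj, mode=cfg.screen)
    s1 = screen.selected
    # Step 2: MCP-penalized Cox on the screened mediators
    x = np.asarray(dataset.exposure, dtype=float)
    n_unpen = 1 + adj.shape[1]
    design = CoxDesign(np.hstack([x[:, None], adj, dataset.mediators[:, s1 - 1]]),
                       dataset.time, dataset.event)
    mcp = fit_mcp_cox(design, n_unpen, a=cfg.mcp_a, n_lambda=cfg.n_lambda,
                      ratio=cfg.lambda_ratio, criterion=cfg.criterion)
    s2 = np.sort(s1[mcp.selected])
    # Step 3: refit, path estimates, tests
    records, refit = inference.build_records(dataset, adj, s2, cfg.second_order_sobel)
    total = inference.estimate_total_effect(dataset, adj)
    significant = {
        t: np.array(sorted(r.mediator for r in records if r.significant(t, cfg.threshold)),
                    dtype=int)
        for t in ("joint", "sobel")
    }
    res = PipelineResult(
        s1=s1, s2=s2, records=records, significant=significant,
        total_effect=total, direct_effect=float(refit.coef[0]),
        counts={"p": dataset.n_mediators, "s1": len(s1), "s2": len(s2),
                "significant_joint": len(significant["joint"]),
                "significant_sobel": len(significant["sobel"])},
    )
    res.propensity = ps_fit
    res.screening = screen
    return res


@dataclass
class SelectionMetrics:
    tp: int
    fp: int
    tpr: float
    fdp: float


def evaluate_selection(selected, truth) -> SelectionMetrics:
    """Per-replication selection accuracy against the true mediator set.

    FDP uses the 0/0 -> 0 convention: an empty selection has FDP 0.
    """
    truth = set(int(t) for t in truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    selected = set(int(s) for s in selected)
    tp = len(selected & truth)
    fp = len(selected - truth)
    return SelectionMetrics(tp=tp, fp=fp, tpr=tp / len(truth),
                            fdp=fp / max(tp + fp, 1))


def run_simulation_study(
    sim_cfg: SimConfig,
    pipeline_configs: dict[str, PipelineConfig] | None = None,
    reps: int = 200,
    master_seed: int = 1,
    collect_records: bool = False,
):
    """Replicated study: per mode, averaged TPR/FP/FDP per test plus
    conditional indirect-effect estimation for the coefficient cells.

    The censoring bound c0 is calibrated once per study; each replication
    draws from an independent substream spawned from ``master_seed``, so
    results are deterministic in the master seed and independent of ordering.

    Returns ``(selection_table, estimation_table, raw)`` where the tables are
    tidy DataFrames and ``raw`` holds per-replication quantities.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if pipeline_configs is None:
        pipeline_configs = {"ps": PipelineConfig(mode="ps")}
    cfg = sim_cfg
    if cfg.c0 is None and cfg.target_censoring > 0:
        c0 = calibrate_censoring(cfg, rng=np.random.default_rng(
            np.random.SeedSequence([master_seed, 777]).generate_state(1)[0] % (2**31)))
        cfg = cfg.replace(c0=c0)
    truth = set(int(t) for t in cfg.true_indices)
    # track every mediator with a nonzero alpha or beta, plus two pure nulls
    prods = cfg.alpha_true * cfg.beta_true
    tracked = list(np.flatnonzero((cfg.alpha_true != 0) | (cfg.beta_true != 0)) + 1)
    tracked += [t for t in range(len(prods), len(prods) - 3, -1)
                if t not in tracked and t >= 1][:2]

    streams = np.random.SeedSequence(master_seed).spawn(reps)
    sel_rows = []
    est_acc = {m: {k: [] for k in tracked} for m in pipeline_configs}
    records_raw = []
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        data = generate_dataset(cfg.replace(seed=int(ss.generate_state(1)[0] % (2**31))), rng=rng)
        for mode_name, pcfg in pipeline_configs.items():
            res = run_pipeline(data, pcfg)
            for test in ("joint", "sobel"):
                met = evaluate_selection(res.significant[test], truth)
                sel_rows.append({"rep": r, "mode": mode_name, "test": test,
                                 "tp": met.tp, "fp": met.fp, "tpr": met.tpr,
                                 "fdp": met.fdp})
            by_id = {rec.mediator: rec for rec in res.records}
            for k in tracked:
                if k in by_id:
                    est_acc[mode_name][k].append(by_id[k].indirect)
            if collect_records:
                records_raw.append((r, mode_name, res))
    sel_df = pd.DataFrame(sel_rows)
    selection_table = (sel_df.groupby(["mode", "test"])[["tpr", "fp", "fdp"]]
                       .mean().reset_index())
    est_rows = []
    for mode_name in pipeline_configs:
        for k in tracked:
            vals = np.asarray(est_acc[mode_name][k], dtype=float)
            true_prod = float(prods[k - 1])
            est_rows.append({
                "mode": mode_name, "mediator": k,
                "alpha": float(cfg.alpha_true[k - 1]), "beta": float(cfg.beta_true[k - 1]),
                "true_product": true_prod, "n_selected": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "mse": float(np.mean((vals - true_prod) ** 2)) if len(vals) else np.nan,
            })
    estimation_table = pd.DataFrame(est_rows)
    raw = {"selection": sel_df, "records": records_raw, "c0": cfg.c0}
    return selection_table, estimation_table, raw


class MediationAnalysis(BaseEstimator):
    """sklearn-style front end to the full mediation pipeline.

    ``fit(M, y, exposure=..., confounders=...)`` runs Steps 0-3 where M is the
    (n, p) mediator matrix and y a (time, event) pair; fitted attributes
    expose the screened set, the selected set, the per-mediator records and
    the significant mediators under the configured test.
    """

    def __init__(self, mode: str = "ps", test: str = "joint", screen: str = "outcome",
                 threshold: float = 0.05, ps_form: str = "logit", mcp_a: float = 3.0,
                 n_lambda: int = 50, lambda_ratio: float = 0.05, criterion: str = "bic"):
        self.mode = mode
        self.test = test
        self.screen = screen
        self.threshold = threshold
        self.ps_form = ps_form
        self.mcp_a = mcp_a
        self.n_lambda = n_lambda
        self.lambda_ratio = lambda_ratio
        self.criterion = criterion

    def _config(self) -> PipelineConfig:
        return PipelineConfig(mode=self.mode, test=self.test, screen=self.screen,
                              threshold=self.threshold, ps_form=self.ps_form,
                              mcp_a=self.mcp_a, n_lambda=self.n_lambda,
                              lambda_ratio=self.lambda_ratio, criterion=self.criterion)

    def fit(self, M, y, exposure=None, confounders=None) -> "MediationAnalysis":
        if exposure is None:
            raise ValueError("exposure is required")
        time, event = y
        n = len(time)
        if confounders is None:
            confounders = np.empty((n, 0))
        data = MediationDataset(exposure=np.asarray(exposure), mediators=np.asarray(M),
                                confounders=np.asarray(confounders),
                                time=np.asarray(time), event=np.asarray(event))
        res = run_pipeline(data, self._config())
        self.result_ = res
        self.screened_ = res.s1
        self.selected_ = res.s2
        self.records_ = res.records
        self.significant_ = res.significant[self.test if self.test != "both" else "joint"]
        self.total_effect_ = res.total_effect
        return self
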