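"""Delimited-text input/output with schema validation.

Canonical on-disk layout: one TSV with subjects in rows and columns
``time``, ``event``, ``exposure``, confounders (``Z1..Zm``) and mediators
(``M1..Mp``); a JSON manifest carries the ground truth for simulated data.
A probe-major matrix (mediators in rows, as methylation tables are usually
shipped) can be loaded with ``transpose=True``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MediationDataset

__all__ = ["DatasetSchema", "read_dataset", "write_dataset", "write_results", "read_manifest"]


@dataclass
class DatasetSchema:
    time: str = "time"
    event: str = "event"
    exposure: str = "exposure"
    mediator_prefix: str = "M"
    mediator_columns: list | None = None
    confounder_prefix: str = "Z"
    confounder_columns: list | None = None
    delimiter: str = "\t"
    na_token: str = "NA"


def _resolve_columns(df: pd.DataFrame, explicit, prefix: str, reserved: set) -> list:
    if explicit is not None:
        missing = [c for c in explicit if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        return list(explicit)
    cols = [c for c in df.columns
            if c.startswith(prefix) and c not in reserved and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def read_dataset(path, schema: DatasetSchema | None = None):
    """Read and validate a dataset; rows missing any required field are
    excluded (with the count reported), malformed values are rejected.

    Returns ``(MediationDataset, info)`` where info records exclusions and
    column resolution.
    """
    schema = schema or DatasetSchema()
    path = Path(path)
    df = pd.read_csv(path, sep=schema.delimiter, na_values=[schema.na_token])
    for col in (schema.time, schema.event, schema.exposure):
        n_found = int((df.columns == col).sum())
        if n_found != 1:
            raise ValueError(f"required column {col!r} present {n_found} times")
    med_cols = _resolve_columns(df, schema.mediator_columns, schema.mediator_prefix,
                                {schema.time, schema.event, schema.exposure})
    conf_cols = _resolve_columns(df, schema.confounder_columns, schema.confounder_prefix,
                                 {schema.time, schema.event, schema.exposure})
    if not med_cols:
        raise ValueError("no mediator columns found")
    required = [schema.time, schema.event, schema.exposure] + conf_cols + med_cols
    complete = df[required].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    df = df.loc[complete]
    if df.empty:
        raise ValueError("no complete rows remain after exclusions")
    event = df[schema.event].to_numpy()
    if not np.isin(event, (0, 1)).all():
        bad = df.index[~np.isin(event, (0, 1))][:5].tolist()
        raise ValueError(f"event column must be 0/1; offending rows (0-based): {bad}")
    exposure = df[schema.exposure].to_numpy()
    if not np.isin(exposure, (0, 1)).all():
        raise ValueError("exposure column must be binary 0/1")
    time = df[schema.time].to_numpy(dtype=float)
    if np.any(time < 0):
        raise ValueError("time column contains negative values")
    data = MediationDataset(
        exposure=exposure.astype(np.int64),
        mediators=df[med_cols].to_numpy(dtype=float),
        confounders=df[conf_cols].to_numpy(dtype=float) if conf_cols else np.empty((len(df), 0)),
        time=time, event=event.astype(np.int64),
    )
    info = {"n_excluded": n_excluded, "n_subjects": data.n_subjects,
            "mediator_columns": med_cols, "confounder_columns": conf_cols}
    return data, info


def write_dataset(dataset: MediationDataset, path, schema: DatasetSchema | None = None,
                  manifest_path=None) -> None:
    """Write a dataset as TSV plus an optional JSON truth manifest."""
    schema = schema or DatasetSchema()
    p = dataset.n_mediators
    m = dataset.confounders.shape[1]
    df = pd.DataFrame({schema.time: dataset.time, schema.event: dataset.event,
                       schema.exposure: dataset.exposure})
    for j in range(m):
        df[f"{schema.confounder_prefix}{j + 1}"] = dataset.confounders[:, j]
    med = pd.DataFrame(dataset.mediators,
                       columns=[f"{schema.mediator_prefix}{k + 1}" for k in range(p)],
                       index=df.index)
    pd.concat([df, med], axis=1).to_csv(path, sep=schema.delimiter, index=False)
    if manifest_path is not None:
        manifest = {
            "true_indices": [int(i) for i in (dataset.true_indices if dataset.true_indices
                                              is not None else [])],
            "alpha_beta_products": [float(v) for v in (dataset.true_products if
                                                       dataset.true_products is not None else [])],
            "seed": dataset.seed,
            "n_subjects": dataset.n_subjects,
            "n_mediators": p,
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))


_RECORD_COLUMNS = ["mediator", "alpha_hat", "beta_hat", "alpha_se", "beta_se",
                   "indirect", "sobel_se", "p_sobel_raw", "p_joint_raw",
                   "p_sobel", "p_joint", "hr", "hr_ci_low", "hr_ci_high"]


def write_results(records, out_dir, total_effect=None, metrics: dict | None = None) -> dict:
    """Write per-mediator records as TSV and a JSON summary; returns the paths.

    Numbers are stored at full precision; a display copy rounded to 4
    decimals accompanies them (``records_display.tsv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["hr_ci_low"], d["hr_ci_high"] = d.pop("hr_ci")
        rows.append({k: d[k] for k in _RECORD_COLUMNS})
    df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    records_path = out / "records.tsv"
    df.to_csv(records_path, sep="\t", index=False)
    df.round(4).to_csv(out / "records_display.tsv", sep="\t", index=False)
    summary = dict(metrics or {})
    if total_effect is not None:
        summary["total_effect"] = dataclasses.asdict(total_effect)
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, default=float))
    return {"records": records_path, "summary": summary_path}


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
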