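"""Flat-file serialization for summaries, models and predictions.

Stage-1 summaries travel as long-format CSV (one row per experiment x grid
point); trained models as versioned JSON with raw parameter arrays.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .inference import TrainingConfig, TrainingState
from .kernels import KernelHyperparams
from .screen_data import CommonGrid, ExperimentKey
from .stage1 import LatentSummary

__all__ = [
    "write_summaries",
    "read_summaries",
    "write_model",
    "read_model",
    "read_target_keys",
]

MODEL_FORMAT_VERSION = 1


def write_summaries(summaries: dict[ExperimentKey, LatentSummary], path) -> None:
    rows = []
    for key in sorted(summaries):
        s = summaries[key]
        for i in range(len(s.z_mean)):
            rows.append(
                {
                    "cell_line": key.cell_line,
                    "drug_a": key.drug_pair[0],
                    "drug_b": key.drug_pair[1],
                    "grid_index": i,
                    "z_mean": s.z_mean[i],
                    "z_var": s.z_var[i],
                    "f_mean": s.f_mean[i],
                    "f_var": s.f_var[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summaries(path) -> tuple[dict[ExperimentKey, LatentSummary], CommonGrid]:
    df = pd.read_csv(path)
    required = {"cell_line", "drug_a", "drug_b", "grid_index", "z_mean", "z_var",
                "f_mean", "f_var"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    n = int(df["grid_index"].max()) + 1
    k = int(round(np.sqrt(n)))
    if k * k != n:
        raise ValueError(f"grid size {n} is not a perfect square")
    grid = CommonGrid(k=k)
    out: dict[ExperimentKey, LatentSummary] = {}
    for (cell, da, db), g in df.groupby(["cell_line", "drug_a", "drug_b"]):
        key = ExperimentKey.canonical(str(cell), str(da), str(db))
        g = g.sort_values("grid_index")
        if len(g) != n:
            raise ValueError(f"experiment {key} has {len(g)} rows, expected {n}")
        out[key] = LatentSummary(
            key=key,
            z_mean=g["z_mean"].to_numpy(),
            z_var=g["z_var"].to_numpy(),
            f_mean=g["f_mean"].to_numpy(),
            f_var=g["f_var"].to_numpy(),
        )
    return out, grid


def write_model(state: TrainingState, path) -> None:
    h = state.hyperparams
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "hyperparams": {
            "raw_ell": h.raw_ell,
            "raw_sigma": h.raw_sigma,
            "L_d": h.L_d.tolist(),
            "raw_v_d": h.raw_v_d.tolist(),
            "L_c": h.L_c.tolist(),
            "raw_v_c": h.raw_v_c.tolist(),
        },
        "config": {
            "r_c": state.config.r_c,
            "r_d": state.config.r_d,
            "variant": state.config.variant,
            "use_measurement_error": state.config.use_measurement_error,
            "learning_rate": state.config.learning_rate,
            "seed": state.config.seed,
        },
        "trace": [float(v) for v in state.trace],
        "converged": state.converged,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> TrainingState:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    hp = payload["hyperparams"]
    h = KernelHyperparams(
        raw_ell=float(hp["raw_ell"]),
        raw_sigma=float(hp["raw_sigma"]),
        L_d=np.asarray(hp["L_d"], dtype=float),
        raw_v_d=np.asarray(hp["raw_v_d"], dtype=float),
        L_c=np.asarray(hp["L_c"], dtype=float),
        raw_v_c=np.asarray(hp["raw_v_c"], dtype=float),
    )
    cfg = TrainingConfig(**payload["config"])
    return TrainingState(
        hyperparams=h,
        trace=list(payload.get("trace", [])),
        converged=bool(payload.get("converged", False)),
        config=cfg,
    )


def read_target_keys(path) -> list[ExperimentKey]:
    df = pd.read_csv(path)
    for col in ("cell_line", "drug_a", "drug_b"):
        if col not in df.columns:
            raise ValueError(f"target table missing column {col!r}")
    return [
        ExperimentKey.canonical(str(r.cell_line), str(r.drug_a), str(r.drug_b))
        for r in df.itertuples()
    ]
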