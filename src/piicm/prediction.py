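"""Dose-response reconstruction, evaluation metrics and validation harnesses.

Predicted latent values are pushed through the bounding transform and added
to the monotherapy-only Bliss surface to reconstruct held-out dose-response
surfaces; performance is measured with inverse-variance-weighted RMSE and
Pearson correlation, with seeded train/test splitting and rank selection by
k-fold cross-validation over experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .inference import TrainingConfig, TrainingState, predictive_posterior, train
from .screen_data import CommonGrid, ExperimentKey, ScreenMatrices
from .stage1 import _g_transform

__all__ = [
    "PredictedSurface",
    "EvaluationReport",
    "reconstruct_dose_response",
    "evaluation_metrics",
    "train_test_split",
    "cross_validate_ranks",
    "bliss_baseline",
    "aggregate_transform_params",
]

P0_CLAMP = 1e-6


@dataclass
class PredictedSurface:
    """Reconstructed surface f_hat = p0_hat + delta_hat for one experiment."""

    key: ExperimentKey
    grid: CommonGrid
    p0_hat: np.ndarray
    delta_hat: np.ndarray
    f_hat: np.ndarray
    zeta_mean: np.ndarray
    zeta_var: np.ndarray | None = None


@dataclass
class EvaluationReport:
    wrmse: float
    pearson_r: float | None
    n_points: int
    per_experiment: dict[ExperimentKey, float] = field(default_factory=dict)


def reconstruct_dose_response(
    zeta_mean: np.ndarray,
    p0_hat: np.ndarray,
    b1: float,
    b2: float,
    key: ExperimentKey | None = None,
    grid: CommonGrid | None = None,
    zeta_var: np.ndarray | None = None,
) -> PredictedSurface:
    """Apply the bounding transform pointwise and add the Bliss surface.

    ``p0_hat`` values at 0 or 1 are clamped (with a warning) since the
    transform goes through the log-odds of p0.
    """
    if b1 <= 0 or b2 <= 0:
        raise ValueError("transform parameters b1, b2 must be positive")
    zeta_mean = np.asarray(zeta_mean, dtype=float)
    p0_hat = np.asarray(p0_hat, dtype=float)
    if np.any(p0_hat <= 0.0) or np.any(p0_hat >= 1.0):
        warnings.warn("p0_hat outside (0, 1); clamping for the log-odds transform")
        p0_hat = np.clip(p0_hat, P0_CLAMP, 1.0 - P0_CLAMP)
    delta = _g_transform(zeta_mean, p0_hat, b1, b2)
    return PredictedSurface(
        key=key, grid=grid, p0_hat=p0_hat, delta_hat=delta,
        f_hat=p0_hat + delta, zeta_mean=zeta_mean, zeta_var=zeta_var,
    )


def evaluation_metrics(
    predicted: np.ndarray,
    observed: np.ndarray,
    observed_var: np.ndarray,
    per_experiment: Mapping[ExperimentKey, np.ndarray] | None = None,
) -> EvaluationReport:
    """Inverse-variance-weighted RMSE (weights normalized to sum to one) plus
    unweighted Pearson correlation as a secondary metric."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    observed_var = np.asarray(observed_var, dtype=float)
    if predicted.shape != observed.shape or predicted.shape != observed_var.shape:
        raise ValueError("predicted/observed/variance lengths differ")
    if predicted.size == 0:
        raise ValueError("empty test set")
    if np.any(observed_var <= 0):
        raise ValueError("observed variances must be positive")
    w = 1.0 / observed_var
    w = w / w.sum()
    wrmse = float(np.sqrt(np.sum(w * (predicted - observed) ** 2)))
    if predicted.size > 1 and np.std(predicted) > 0 and np.std(observed) > 0:
        pearson = float(np.corrcoef(predicted, observed)[0, 1])
    else:
        pearson = None  # undefined for constant vectors; flagged, not faked
    per_exp: dict[ExperimentKey, float] = {}
    if per_experiment:
        for key, idx in per_experiment.items():
            wi = 1.0 / observed_var[idx]
            wi = wi / wi.sum()
            per_exp[key] = float(
                np.sqrt(np.sum(wi * (predicted[idx] - observed[idx]) ** 2))
            )
    return EvaluationReport(
        wrmse=wrmse, pearson_r=pearson, n_points=int(predicted.size),
        per_experiment=per_exp,
    )


def train_test_split(
    experiments: Sequence[ExperimentKey], test_fraction: float, seed: int = 0
) -> tuple[list[ExperimentKey], list[ExperimentKey]]:
    """Seeded random split over experiments; test size is floored."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    keys = list(experiments)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_test = int(np.floor(test_fraction * len(keys)))
    test = [keys[i] for i in order[:n_test]]
    train_keys = [keys[i] for i in order[n_test:]]
    return train_keys, test


def _latent_wrmse_for_holdout(
    screen: ScreenMatrices,
    train_keys: Sequence[ExperimentKey],
    held_out: Sequence[ExperimentKey],
    config: TrainingConfig,
) -> float:
    masked = screen.with_mask(train_keys)
    state = train(masked, config)
    preds = predictive_posterior(state, masked, held_out)
    n = screen.n
    pred, obs, var = [], [], []
    for key in held_out:
        j = screen.column_index(key)
        pred.append(preds[key][0])
        obs.append(screen.Z[:, j])
        var.append(screen.S[:, j])
    report = evaluation_metrics(
        np.concatenate(pred), np.concatenate(obs), np.concatenate(var)
    )
    return report.wrmse


def cross_validate_ranks(
    screen: ScreenMatrices,
    train_keys: Sequence[ExperimentKey],
    r_c_grid: Sequence[int],
    r_d_grid: Sequence[int],
    folds: int = 5,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> tuple[tuple[int, int], dict[tuple[int, int], float]]:
    """Select (r_c, r_d) by k-fold CV over experiments on latent wRMSE.

    Folds are assigned at the experiment level; ties break toward smaller
    r_d, then smaller r_c.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    base = config or TrainingConfig()
    n_c = len(screen.cell_lines)
    n_ext = screen.n_extended_pairs
    for r_c in r_c_grid:
        if r_c > n_c:
            raise ValueError(f"r_c={r_c} exceeds the number of cell lines {n_c}")
    for r_d in r_d_grid:
        if r_d > n_ext:
            raise ValueError(f"r_d={r_d} exceeds the extended pair count {n_ext}")
    rng = np.random.default_rng(seed)
    keys = list(train_keys)
    order = rng.permutation(len(keys))
    fold_of = np.arange(len(keys)) % folds
    assignments = {keys[order[i]]: fold_of[i] for i in range(len(keys))}

    table: dict[tuple[int, int], float] = {}
    for r_c in r_c_grid:
        for r_d in r_d_grid:
            scores = []
            for fold in range(folds):
                held = [k for k in keys if assignments[k] == fold]
                kept = [k for k in keys if assignments[k] != fold]
                if not held or not kept:
                    continue
                cfg = TrainingConfig(
                    r_c=r_c, r_d=r_d, variant=base.variant,
                    use_measurement_error=base.use_measurement_error,
                    learning_rate=base.learning_rate,
                    cg_tolerance_factor=base.cg_tolerance_factor,
                    cg_max_iterations=base.cg_max_iterations,
                    max_steps=base.max_steps, patience=base.patience,
                    min_rel_improvement=base.min_rel_improvement,
                    seed=base.seed,
                )
                scores.append(_latent_wrmse_for_holdout(screen, kept, held, cfg))
            table[(r_c, r_d)] = float(np.mean(scores))
    best = min(table, key=lambda rc_rd: (table[rc_rd], rc_rd[1], rc_rd[0]))
    return best, table


def bliss_baseline(
    p0_surfaces: Mapping[ExperimentKey, np.ndarray], grid: CommonGrid
) -> dict[ExperimentKey, PredictedSurface]:
    """Non-interaction baseline: f_hat = p0_hat exactly (delta_hat = 0)."""
    out = {}
    for key, p0 in p0_surfaces.items():
        p0 = np.clip(np.asarray(p0, dtype=float), P0_CLAMP, 1.0 - P0_CLAMP)
        out[key] = PredictedSurface(
            key=key, grid=grid, p0_hat=p0, delta_hat=np.zeros_like(p0),
            f_hat=p0.copy(), zeta_mean=np.zeros_like(p0),
        )
    return out


def aggregate_transform_params(fits: Sequence) -> tuple[float, float]:
    """Unweighted mean of per-experiment posterior means of (b1, b2)."""
    if not fits:
        raise ValueError("no training fits to aggregate transform parameters from")
    b1 = float(np.mean([fit.flat("b1").mean() for fit in fits]))
    b2 = float(np.mean([fit.flat("b2").mean() for fit in fits]))
    return b1, b2
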