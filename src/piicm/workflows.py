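"""End-to-end pipelines tying the stages together.

These are the orchestration paths used by the CLI and the validation
studies: fit every experiment of a screen in stage 1, assemble the stage-2
matrices, train the multi-output model with held-out experiments masked, and
reconstruct + score dose-response surfaces against the held-out experiments'
own stage-1 estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .inference import TrainingConfig, TrainingState, predictive_posterior, train
from .prediction import (
    aggregate_transform_params,
    evaluation_metrics,
    reconstruct_dose_response,
    train_test_split,
)
from .screen_data import (
    CommonGrid,
    ExperimentKey,
    Screen,
    ScreenMatrices,
    assemble_matrices,
)
from .simulate import simulate_viability_screen
from .stage1 import (
    LatentSummary,
    SamplerConfig,
    Stage1Fit,
    fit_single_experiment,
    latent_summary_on_grid,
    p0_star_on_grid,
)

__all__ = [
    "fit_screen_stage1",
    "assemble_from_fits",
    "EndToEndResult",
    "run_end_to_end_seed",
]


def fit_screen_stage1(
    screen: Screen,
    grid: CommonGrid,
    config: SamplerConfig | None = None,
    keys: Sequence[ExperimentKey] | None = None,
) -> tuple[dict[ExperimentKey, Stage1Fit], dict[ExperimentKey, LatentSummary]]:
    """Fit every (or the given) combination experiment and summarize on the grid."""
    config = config or SamplerConfig()
    keys = list(keys) if keys is not None else sorted(screen.combinations)
    fits: dict[ExperimentKey, Stage1Fit] = {}
    summaries: dict[ExperimentKey, LatentSummary] = {}
    for key in keys:
        fit = fit_single_experiment(screen, key, mode="full", config=config, grid_k=grid.k)
        fits[key] = fit
        summaries[key] = latent_summary_on_grid(fit, grid)
    return fits, summaries


def assemble_from_fits(
    summaries: Mapping[ExperimentKey, LatentSummary], grid: CommonGrid
) -> ScreenMatrices:
    cells = sorted({k.cell_line for k in summaries})
    pairs = sorted({k.drug_pair for k in summaries})
    return assemble_matrices(summaries, cells, pairs, grid)


@dataclass
class EndToEndResult:
    """Held-out metrics of one simulated-screen replicate."""

    seed: int
    latent_wrmse: dict[str, float]  # variant -> wRMSE against stage-1 z means
    dose_response_wrmse: dict[str, float]  # variant/baseline -> wRMSE against F
    dose_response_pearson: dict[str, float | None]
    held_out: list[ExperimentKey] = field(default_factory=list)


def run_end_to_end_seed(
    seed: int,
    n_c: int = 3,
    n_d: int = 4,
    k: int = 4,
    interaction: str = "synergy_in_block",
    test_fraction: float = 0.25,
    stage1_config: SamplerConfig | None = None,
    variants: Sequence[str] = ("invariant", "non_invariant"),
    r_c: int = 2,
    r_d: int = 2,
    max_steps: int = 300,
) -> EndToEndResult:
    """One replicate of the simulation study.

    Simulates a raw viability screen, runs the full two-stage pipeline with a
    random subset of experiments held out, and scores reconstructed
    dose-response surfaces against the held-out experiments' own stage-1
    estimates (their F / S_F summaries), alongside the monotherapy-only
    Bliss baseline.
    """
    stage1_config = stage1_config or SamplerConfig.fast(seed=seed)
    screen, truth = simulate_viability_screen(
        n_c=n_c, n_d=n_d, k=k, interaction=interaction, seed=seed
    )
    grid = CommonGrid(k=k)
    fits, summaries = fit_screen_stage1(screen, grid, config=stage1_config)
    full = assemble_from_fits(summaries, grid)
    keys = sorted(summaries)
    train_keys, test_keys = train_test_split(keys, test_fraction, seed=seed)
    masked = full.with_mask(train_keys)
    b1, b2 = aggregate_transform_params([fits[key] for key in train_keys])

    # monotherapy-only Bliss surfaces for the held-out experiments
    p0_hat: dict[ExperimentKey, np.ndarray] = {}
    for key in test_keys:
        mono_fit = fit_single_experiment(
            screen, key, mode="monotherapy_only", config=stage1_config,
            scaler=fits[key].scaler,
        )
        p0_hat[key], _ = p0_star_on_grid(mono_fit, grid)

    f_obs = np.concatenate([summaries[key].f_mean for key in test_keys])
    f_var = np.concatenate([summaries[key].f_var for key in test_keys])
    z_obs = np.concatenate([summaries[key].z_mean for key in test_keys])
    z_var = np.concatenate([summaries[key].z_var for key in test_keys])

    latent_wrmse: dict[str, float] = {}
    dr_wrmse: dict[str, float] = {}
    dr_pearson: dict[str, float | None] = {}
    for variant in variants:
        cfg = TrainingConfig(
            r_c=r_c, r_d=r_d, variant=variant, seed=seed, max_steps=max_steps
        )
        state = train(masked, cfg)
        preds = predictive_posterior(state, masked, test_keys)
        zeta = np.concatenate([preds[key][0] for key in test_keys])
        latent_wrmse[variant] = evaluation_metrics(zeta, z_obs, z_var).wrmse
        f_pred = np.concatenate(
            [
                reconstruct_dose_response(
                    preds[key][0], p0_hat[key], b1, b2, key=key, grid=grid
                ).f_hat
                for key in test_keys
            ]
        )
        report = evaluation_metrics(f_pred, f_obs, f_var)
        dr_wrmse[variant] = report.wrmse
        dr_pearson[variant] = report.pearson_r

    base = np.concatenate([p0_hat[key] for key in test_keys])
    base_report = evaluation_metrics(base, f_obs, f_var)
    dr_wrmse["baseline"] = base_report.wrmse
    dr_pearson["baseline"] = base_report.pearson_r
    return EndToEndResult(
        seed=seed,
        latent_wrmse=latent_wrmse,
        dose_response_wrmse=dr_wrmse,
        dose_response_pearson=dr_pearson,
        held_out=test_keys,
    )
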