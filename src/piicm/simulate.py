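"""Synthetic data generators with ground truth retained.

Two levels: raw viability screens drawn from the full generative chain
(log-logistic monotherapies, Bliss product, bounded interaction transform,
heteroskedastic replicate noise), and stage-2 latent matrices drawn directly
from the permutation-invariant multi-output GP.  Everything is seeded, so
every other module is testable without external downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .kernels import (
    KernelHyperparams,
    build_permutations,
    assemble_full_covariance,
    inv_softplus,
    softplus,
)
from .screen_data import (
    CommonGrid,
    ExperimentKey,
    Screen,
    ScreenMatrices,
    ViabilityRecord,
    extended_pair_ordering,
)
from .stage1 import (
    InteractionTransformParams,
    MonotherapyParams,
    bliss_noninteraction,
    interaction_transform,
    matern32,
)

__all__ = [
    "GroundTruth",
    "Stage2Truth",
    "simulate_stage2_dataset",
    "simulate_viability_screen",
    "default_cell_lines",
    "default_pairs",
]

DENSE_CAP = 20000

InteractionSpec = Literal["none", "synergy_in_block", "independent"]


def default_cell_lines(n_c: int) -> list[str]:
    return [f"CL{i:02d}" for i in range(1, n_c + 1)]


def default_pairs(n_d: int) -> list[tuple[str, str]]:
    """First n_d lexicographic pairs over the smallest sufficient drug panel."""
    n_drugs = 2
    while n_drugs * (n_drugs - 1) // 2 < n_d:
        n_drugs += 1
    drugs = [f"D{i:02d}" for i in range(1, n_drugs + 1)]
    return sorted(itertools.combinations(drugs, 2))[:n_d]


@dataclass
class Stage2Truth:
    """Ground truth for a directly simulated latent dataset."""

    hyperparams: KernelHyperparams
    zeta: np.ndarray  # (N,) true symmetrized latent field, vec layout
    noise_sd: np.ndarray  # (N,) per-entry stage-1-style noise SD (observed scale)
    seed: int

    def zeta_column(self, screen: ScreenMatrices, key: ExperimentKey) -> np.ndarray:
        j = screen.column_index(key)
        n = screen.n
        return self.zeta[j * n : (j + 1) * n]


@dataclass
class GroundTruth:
    """Ground truth for a simulated raw viability screen."""

    monotherapy: dict[tuple[str, str], MonotherapyParams]
    transform: InteractionTransformParams
    latent: dict[ExperimentKey, np.ndarray]  # z on the grid, per experiment
    surfaces: dict[ExperimentKey, np.ndarray]  # f on the grid, per experiment
    grid: CommonGrid
    conc_range: tuple[float, float]
    noise: tuple[float, float]  # (sigma0, c0)
    seed: int


def simulate_stage2_dataset(
    n_c: int = 3,
    n_d: int = 4,
    k: int = 4,
    r_c: int = 2,
    r_d: int = 2,
    lengthscale: float = 0.4,
    output_scale: float = 0.7,
    noise_level: float = 0.1,
    global_noise: float = 0.05,
    mask_fraction: float = 0.0,
    seed: int = 0,
    hyperparams: KernelHyperparams | None = None,
) -> tuple[ScreenMatrices, Stage2Truth]:
    """Draw a masked stage-2 dataset from the invariant multi-output GP.

    A base field with covariance ``K_c (x) K_d (x) K_x`` is sampled densely
    and symmetrized by adding its image under the joint pair-block swap and
    grid reflection, which makes its covariance exactly the assembled
    invariant kernel.  Gaussian noise with per-entry variances (stored in S)
    plus a global component is added; all reversed-ordering columns and a
    random fraction of experiments are masked.
    """
    rng = np.random.default_rng(seed)
    cells = default_cell_lines(n_c)
    pairs = default_pairs(n_d)
    extended = extended_pair_ordering(pairs)
    grid = CommonGrid(k=k)
    n = grid.n
    N = n_c * 2 * n_d * n
    if N > DENSE_CAP:
        raise ValueError(f"dense simulation size {N} exceeds cap {DENSE_CAP}")

    if hyperparams is not None:
        h = hyperparams
        if h.n_cell_lines != n_c or h.n_extended_pairs != 2 * n_d:
            raise ValueError("supplied hyperparameters do not match n_c/n_d")
    else:
        h = KernelHyperparams(
            raw_ell=float(inv_softplus(lengthscale)),
            raw_sigma=float(inv_softplus(np.sqrt(global_noise))),
            L_d=output_scale * rng.standard_normal((2 * n_d, r_d)) / np.sqrt(r_d),
            raw_v_d=inv_softplus(rng.uniform(0.05, 0.2, 2 * n_d)),
            L_c=output_scale * rng.standard_normal((n_c, r_c)) / np.sqrt(r_c),
            raw_v_c=inv_softplus(rng.uniform(0.05, 0.2, n_c)),
        )
    perms = build_permutations(n_d, grid)
    base_op = assemble_full_covariance(h, perms, grid, variant="non_invariant")
    K_base = base_op.dense(cap=DENSE_CAP)
    L = np.linalg.cholesky(K_base + 1e-10 * np.eye(N))
    zeta_tilde = L @ rng.standard_normal(N)
    # symmetrize: add the value at the swapped (pair-block, reflected-grid) index
    T = zeta_tilde.reshape(n_c, 2 * n_d, n)
    zeta = (T + T[:, perms.p_index, :][:, :, perms.pt_index]).reshape(-1)

    noise_var = rng.uniform(0.5 * noise_level**2, 1.5 * noise_level**2, N)
    noise_sd = np.sqrt(noise_var + global_noise)
    z_obs = zeta + noise_sd * rng.standard_normal(N)

    n_cols = n_c * 2 * n_d
    Z = z_obs.reshape(n_cols, n).T.copy()  # vec layout back to n x cols
    S = noise_var.reshape(n_cols, n).T.copy()
    mask = np.zeros((n, n_cols), dtype=bool)
    observed_keys = [
        ExperimentKey(cell_line=c, drug_pair=p) for c in cells for p in pairs
    ]
    if mask_fraction > 0:
        n_drop = int(round(mask_fraction * len(observed_keys)))
        drop = set(
            rng.choice(len(observed_keys), size=n_drop, replace=False).tolist()
        )
        observed_keys = [key for i, key in enumerate(observed_keys) if i not in drop]
    screen = ScreenMatrices(
        Z=np.full_like(Z, -999.0),
        S=np.full_like(S, 1e12),
        mask=mask,
        cell_lines=cells,
        extended_pairs=extended,
        grid=grid,
    )
    for key in observed_keys:
        j = screen.column_index(key)
        screen.Z[:, j] = Z[:, j]
        screen.S[:, j] = S[:, j]
        screen.mask[:, j] = True
    truth = Stage2Truth(hyperparams=h, zeta=zeta, noise_sd=noise_sd, seed=seed)
    return screen, truth


def _draw_monotherapy(rng: np.random.Generator, lo: float, hi: float) -> MonotherapyParams:
    # ranges chosen to give realistic sigmoid coverage over the tested window
    return MonotherapyParams(
        l=float(rng.uniform(0.0, 0.6)),
        s=float(rng.uniform(0.5, 3.0)),
        m=float(rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo))),
    )


def _synergy_pattern(grid: CommonGrid) -> np.ndarray:
    """Smooth nonnegative bump peaking at high concentrations of both drugs."""
    pts = grid.points
    return (pts[:, 0] * pts[:, 1]) ** 1.5


def simulate_viability_screen(
    n_c: int = 3,
    n_d: int = 4,
    k: int = 4,
    combo_replicates: int = 4,
    mono_points: int = 8,
    mono_replicates: int = 4,
    interaction: InteractionSpec = "synergy_in_block",
    synergy_pairs: int | None = None,
    synergy_strength: float = 3.0,
    sigma0: float = 0.08,
    c0: float = 0.3,
    conc_range: tuple[float, float] = (-8.0, -5.0),
    b1: float = 1.0,
    b2: float = 1.0,
    seed: int = 0,
) -> tuple[Screen, GroundTruth]:
    """Generate a grid-designed combination screen with replicates.

    Each experiment combines its two drugs on a k x k grid of log10
    concentrations (``combo_replicates`` replicates per point) and measures
    each monotherapy at ``mono_points`` concentrations.  Replicate noise is
    heteroskedastic, growing with the underlying viability.  Interaction
    options: ``none`` (pure Bliss), ``synergy_in_block`` (a subset of pairs
    shares a common synergistic latent pattern across cell lines, exercising
    the low-rank pair covariance), ``independent`` (per-experiment GP draw).
    """
    rng = np.random.default_rng(seed)
    cells = default_cell_lines(n_c)
    pairs = default_pairs(n_d)
    drugs = sorted({d for p in pairs for d in p})
    lo, hi = conc_range
    grid = CommonGrid(k=k)
    transform = InteractionTransformParams(b1=b1, b2=b2)

    mono: dict[tuple[str, str], MonotherapyParams] = {}
    for cell in cells:
        for drug in drugs:
            mono[(cell, drug)] = _draw_monotherapy(rng, lo, hi)

    if synergy_pairs is None:
        synergy_pairs = max(1, n_d // 2)
    block = set(pairs[:synergy_pairs])
    pattern = _synergy_pattern(grid)

    screen = Screen()
    latent: dict[ExperimentKey, np.ndarray] = {}
    surfaces: dict[ExperimentKey, np.ndarray] = {}
    axis = np.linspace(lo, hi, k)
    mono_concs = np.linspace(lo, hi, mono_points)
    Kg = matern32(grid.points, grid.points, 0.4) + 1e-8 * np.eye(grid.n)
    Lg = np.linalg.cholesky(Kg)

    for cell in cells:
        for drug in drugs:
            p = mono[(cell, drug)]
            h = p.l + (1.0 - p.l) / (1.0 + 10.0 ** (p.s * (mono_concs - p.m)))
            for i, x in enumerate(mono_concs):
                for rep in range(1, mono_replicates + 1):
                    noise_sd = sigma0 * np.sqrt(c0 + h[i])
                    screen.add(
                        ViabilityRecord(
                            cell_line=cell, drug_a=drug, drug_b=None,
                            conc_a=float(x), conc_b=None, replicate=rep,
                            viability=float(h[i] + noise_sd * rng.standard_normal()),
                        )
                    )
        for pair in pairs:
            key = ExperimentKey(cell_line=cell, drug_pair=pair)
            orig = np.stack(
                np.meshgrid(axis, axis, indexing="ij"), axis=-1
            ).reshape(-1, 2)
            p0 = np.clip(
                bliss_noninteraction(orig, mono[(cell, pair[0])], mono[(cell, pair[1])]),
                1e-6, 1.0 - 1e-6,
            )
            if interaction == "none":
                z = np.zeros(grid.n)
            elif interaction == "synergy_in_block" and pair in block:
                z = -synergy_strength * pattern * rng.uniform(0.7, 1.3)
            elif interaction == "independent":
                z = Lg @ rng.standard_normal(grid.n)
            else:
                z = np.zeros(grid.n)
            delta = interaction_transform(z, p0, transform)
            f = p0 + delta
            latent[key] = z
            surfaces[key] = f
            for i in range(grid.n):
                for rep in range(1, combo_replicates + 1):
                    noise_sd = sigma0 * np.sqrt(c0 + f[i])
                    screen.add(
                        ViabilityRecord(
                            cell_line=cell, drug_a=pair[0], drug_b=pair[1],
                            conc_a=float(orig[i, 0]), conc_b=float(orig[i, 1]),
                            replicate=rep,
                            viability=float(f[i] + noise_sd * rng.standard_normal()),
                        )
                    )

    truth = GroundTruth(
        monotherapy=mono, transform=transform, latent=latent, surfaces=surfaces,
        grid=grid, conc_range=conc_range, noise=(sigma0, c0), seed=seed,
    )
    return screen, truth
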