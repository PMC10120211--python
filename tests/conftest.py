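import numpy as np
import pytest

from piicm.kernels import KernelHyperparams, build_permutations
from piicm.screen_data import (
    CommonGrid,
    ExperimentKey,
    ScreenMatrices,
    extended_pair_ordering,
)


def random_hyperparams(
    n_c: int, n_d: int, seed: int, r_c: int = 1, r_d: int = 2
) -> KernelHyperparams:
    rng = np.random.default_rng(seed)
    return KernelHyperparams(
        raw_ell=float(rng.normal(0.0, 0.5)),
        raw_sigma=float(rng.normal(-0.3, 0.3)),
        L_d=0.4 * rng.standard_normal((2 * n_d, r_d)),
        raw_v_d=rng.standard_normal(2 * n_d),
        L_c=0.4 * rng.standard_normal((n_c, r_c)),
        raw_v_c=rng.standard_normal(n_c),
    )


def make_screen_matrices(
    n_c: int = 2,
    n_d: int = 2,
    k: int = 2,
    masked_columns: frozenset[int] = frozenset(),
    homoskedastic: float | None = None,
    seed: int = 3,
    mask_reversed: bool = True,
) -> ScreenMatrices:
    """Random Z/S matrices with the reversed block plus given columns masked."""
    rng = np.random.default_rng(seed)
    grid = CommonGrid(k=k)
    pairs = [("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")][:n_d]
    extended = extended_pair_ordering(pairs)
    cells = [f"c{i}" for i in range(1, n_c + 1)]
    n = grid.n
    cols = n_c * 2 * n_d
    Z = np.full((n, cols), -999.0)
    S = np.full((n, cols), 1e12)
    mask = np.zeros((n, cols), dtype=bool)
    for j in range(cols):
        reversed_block = (j % (2 * n_d)) >= n_d
        if (mask_reversed and reversed_block) or j in masked_columns:
            continue
        Z[:, j] = rng.standard_normal(n)
        S[:, j] = (
            homoskedastic if homoskedastic is not None else rng.uniform(0.05, 0.3, n)
        )
        mask[:, j] = True
    return ScreenMatrices(
        Z=Z, S=S, mask=mask, cell_lines=cells, extended_pairs=extended, grid=grid
    )


@pytest.fixture
def grid2() -> CommonGrid:
    return CommonGrid(k=2)


@pytest.fixture
def grid4() -> CommonGrid:
    return CommonGrid(k=4)


@pytest.fixture
def small_screen_matrices() -> ScreenMatrices:
    return make_screen_matrices()


@pytest.fixture(scope="session")
def sim_screen():
    """One small simulated viability screen shared across stage-1 tests."""
    from piicm.simulate import simulate_viability_screen

    return simulate_viability_screen(n_c=1, n_d=1, k=4, seed=11)


@pytest.fixture(scope="session")
def sim_full_fit(sim_screen):
    """One full-mode stage-1 fit shared across tests (sampling is costly)."""
    from piicm.stage1 import SamplerConfig, fit_single_experiment

    screen, truth = sim_screen
    key = next(iter(screen.combinations))
    fit = fit_single_experiment(
        screen, key, mode="full", config=SamplerConfig.fast(seed=5), grid_k=4
    )
    return screen, truth, key, fit
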