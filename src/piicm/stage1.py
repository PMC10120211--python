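"""Per-experiment Bayesian dose-response model.

Each combination experiment is fit independently: log-logistic monotherapy
curves, a Bliss product non-interaction surface, and a latent Matern-3/2 GP
interaction field pushed through a double-logistic bounding transform so the
full surface stays in (0, 1).  Measurement noise is heteroskedastic,
growing with the mean viability.  Posterior sampling combines elliptical
slice updates of the whitened latent field with univariate slice sampling of
the scalar parameters; the latent GP posterior is then summarized on the
common unit-box grid as the mean/variance inputs of the joint model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import _stage1_core as _core
from .screen_data import (
    CommonGrid,
    ConcentrationScaler,
    ExperimentKey,
    Screen,
    ViabilityRecord,
    scale_to_common_grid,
)

__all__ = [
    "MonotherapyParams",
    "InteractionTransformParams",
    "PriorConfig",
    "SamplerConfig",
    "Stage1Fit",
    "LatentSummary",
    "log_logistic_response",
    "bliss_noninteraction",
    "interaction_transform",
    "fit_single_experiment",
    "latent_summary_on_grid",
    "p0_star_on_grid",
]

P0_CLIP = 1e-6
VAR_FLOOR = 1e-6
JITTER = 1e-8


@dataclass(frozen=True)
class MonotherapyParams:
    """Log-logistic curve parameters; the upper asymptote is fixed at 1."""

    l: float
    s: float
    m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.l <= 1.0:
            raise ValueError(f"lower asymptote must be in [0, 1], got {self.l}")
        if self.s <= 0:
            raise ValueError(f"slope must be positive, got {self.s}")


@dataclass(frozen=True)
class InteractionTransformParams:
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if self.b1 <= 0 or self.b2 <= 0:
            raise ValueError("transform parameters b1, b2 must be positive")


def log_logistic_response(x, p: MonotherapyParams):
    """l + (1 - l) / (1 + 10^(s (x - m))) at log10 concentration x."""
    x = np.asarray(x, dtype=float)
    return p.l + (1.0 - p.l) / (1.0 + 10.0 ** (p.s * (x - p.m)))


def bliss_noninteraction(x, pA: MonotherapyParams, pB: MonotherapyParams):
    """Product of the two monotherapy curves at concentration pair x."""
    x = np.asarray(x, dtype=float)
    return log_logistic_response(x[..., 0], pA) * log_logistic_response(x[..., 1], pB)


def _g_transform(z, p0, b1, b2):
    logit_p0 = np.log(p0) - np.log1p(-p0)
    neg = -p0 / (1.0 + np.exp(np.clip(b1 * z + logit_p0, -500, 500)))
    pos = (1.0 - p0) / (1.0 + np.exp(np.clip(-b2 * z - logit_p0, -500, 500)))
    return neg + pos


def interaction_transform(z, p0, b: InteractionTransformParams):
    """Bounding transform g: strictly increasing in z, with range (-p0, 1-p0)
    and g(0) = 0."""
    z = np.asarray(z, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 <= 0.0) or np.any(p0 >= 1.0):
        raise ValueError("p0 must lie strictly inside (0, 1)")
    return _g_transform(z, p0, b.b1, b.b2)


def matern32(a: np.ndarray, b: np.ndarray, lengthscale: float) -> np.ndarray:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    r = np.sqrt(np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1))
    u = np.sqrt(3.0) * r / lengthscale
    return (1.0 + u) * np.exp(-u)


@dataclass(frozen=True)
class PriorConfig:
    """Stand-in weakly-informative priors (isolated so they can be swapped).

    ``l ~ Beta(beta_a, beta_b)``, ``log s ~ N(0, s_sd)``,
    ``m ~ N(mid-range, observed range)``, ``log b ~ N(0, b_sd)``,
    GP amplitude ~ HalfNormal(amp_scale), ``log lengthscale ~ N(0, ls_sd)``,
    noise scales sigma0, c0 ~ HalfNormal(noise_scale).
    """

    l_beta_a: float = 1.0
    l_beta_b: float = 1.25
    s_log_sd: float = 1.0
    b_log_sd: float = 0.5
    amp_scale: float = 1.0
    ls_log_sd: float = 0.5
    noise_scale: float = 0.1


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05
    min_draws: int = 50

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerConfig":
        """Reduced draw budget for simulation studies and smoke tests."""
        return cls(chains=2, warmup=200, draws=250, seed=seed)

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


@dataclass
class LatentSummary:
    """Posterior mean/variance of z and f on the common grid for one experiment."""

    key: ExperimentKey
    z_mean: np.ndarray
    z_var: np.ndarray
    f_mean: np.ndarray
    f_var: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.z_var <= 0):
            raise ValueError("z_var must be strictly positive (flooring failed)")


@dataclass
class Stage1Fit:
    """Posterior draws and diagnostics from one experiment's fit."""

    key: ExperimentKey
    mode: Literal["full", "monotherapy_only"]
    scalar_draws: dict[str, np.ndarray]  # each (chains, draws)
    z_draws: np.ndarray | None  # (total_draws, n_locations), full mode only
    locations: np.ndarray | None  # unique scaled combo locations
    scaler: ConcentrationScaler
    diagnostics: dict[str, dict[str, float]]
    converged: bool
    prior: PriorConfig
    config: SamplerConfig

    def flat(self, name: str) -> np.ndarray:
        return self.scalar_draws[name].reshape(-1)

    @property
    def total_draws(self) -> int:
        first = next(iter(self.scalar_draws.values()))
        return first.shape[0] * first.shape[1]

    def monotherapy_posterior_mean(self, which: Literal["a", "b"]) -> MonotherapyParams:
        return MonotherapyParams(
            l=float(self.flat(f"l_{which}").mean()),
            s=float(self.flat(f"s_{which}").mean()),
            m=float(self.flat(f"m_{which}").mean()),
        )

    def transform_posterior_mean(self) -> InteractionTransformParams:
        return InteractionTransformParams(
            b1=float(self.flat("b1").mean()), b2=float(self.flat("b2").mean())
        )


# ---------------------------------------------------------------------------
# model internals


_FULL_PARAMS = (
    "l_a", "s_a", "m_a", "l_b", "s_b", "m_b",
    "b1", "b2", "amp", "ls", "sigma0", "c0",
)
_MONO_PARAMS = ("l_a", "s_a", "m_a", "l_b", "s_b", "m_b", "sigma0", "c0")


def _sigmoid(u):
    return 0.5 * (1.0 + np.tanh(0.5 * u))


class _Stage1Model:
    """Caches data arrays and evaluates the unnormalized log posterior.

    Scalar parameters live on an unconstrained vector; the latent field is
    whitened (z = amp * chol(Matern) @ u_z at the unique combination
    locations).  The likelihood is one vectorized pass over all mono +
    combination rows, since the samplers call it tens of thousands of times
    per fit.
    """

    def __init__(
        self,
        mono_a: tuple[np.ndarray, np.ndarray],
        mono_b: tuple[np.ndarray, np.ndarray],
        combo_xy,
        mode: str,
        prior: PriorConfig,
        m_center: float,
        m_sd: float,
    ):
        xa, self.ya = mono_a
        xb, self.yb = mono_b
        self.mode = mode
        self.prior = prior
        self.m_center = m_center
        self.m_sd = max(m_sd, 0.5)
        if combo_xy is not None:
            self.combo_orig, self.locations, self.row_of_loc, self.yc = combo_xy
            self.n_loc = self.locations.shape[0]
            self.x_a = np.concatenate([xa, self.combo_orig[:, 0]])
            self.x_b = np.concatenate([xb, self.combo_orig[:, 1]])
        else:
            self.locations = None
            self.n_loc = 0
            self.yc = np.empty(0)
            self.x_a = np.asarray(xa, dtype=float)
            self.x_b = np.asarray(xb, dtype=float)
        self.na = len(self.ya)
        self.nb = len(self.yb)
        self.y_all = np.concatenate([self.ya, self.yb, self.yc])
        self._const = -0.5 * self.y_all.size * np.log(2.0 * np.pi)
        self._chol_cache: tuple[float, np.ndarray] | None = None
        self.names = _FULL_PARAMS if mode == "full" else _MONO_PARAMS
        self.index = {name: i for i, name in enumerate(self.names)}
        self._ia = (self.index["l_a"], self.index["s_a"], self.index["m_a"])
        self._ib = (self.index["l_b"], self.index["s_b"], self.index["m_b"])
        self._is_l = np.array([nm.startswith("l_") for nm in self.names])
        self._is_m = np.array([nm.startswith("m_") for nm in self.names])
        self._is_exp = ~(self._is_l | self._is_m)
        # gaussian-in-u priors; half-normal-with-exp-transform priors
        mu, sd, gauss, hn_idx, hn_scale = [], [], [], [], []
        for i, nm in enumerate(self.names):
            if nm.startswith("s_"):
                gauss.append(i); mu.append(0.0); sd.append(prior.s_log_sd)
            elif nm.startswith("m_"):
                gauss.append(i); mu.append(self.m_center); sd.append(self.m_sd)
            elif nm in ("b1", "b2"):
                gauss.append(i); mu.append(0.0); sd.append(prior.b_log_sd)
            elif nm == "ls":
                gauss.append(i); mu.append(0.0); sd.append(prior.ls_log_sd)
            elif nm == "amp":
                hn_idx.append(i); hn_scale.append(prior.amp_scale)
            elif nm in ("sigma0", "c0"):
                hn_idx.append(i); hn_scale.append(prior.noise_scale)
        self._gauss = np.array(gauss, dtype=int)
        self._gauss_mu = np.array(mu)
        self._gauss_sd = np.array(sd)
        self._hn = np.array(hn_idx, dtype=int)
        self._hn_scale = np.array(hn_scale)
        self._l = np.flatnonzero(self._is_l)
        self._row64 = (
            self.row_of_loc.astype(np.int64) if mode == "full" else np.empty(0, np.int64)
        )
        self._z_dummy = np.empty(0)

    # -- transforms ---------------------------------------------------------

    def constrain(self, u: np.ndarray) -> np.ndarray:
        p = u.copy()
        p[self._is_l] = _sigmoid(u[self._is_l])
        p[self._is_exp] = np.exp(np.clip(u[self._is_exp], -30.0, 30.0))
        return p

    def as_dict(self, u: np.ndarray) -> dict[str, float]:
        p = self.constrain(u)
        return {name: float(p[i]) for i, name in enumerate(self.names)}

    def log_prior(self, u: np.ndarray) -> float:
        if _core.HAVE_NUMBA:
            return float(
                _core.logprior_core(
                    u, self._gauss, self._gauss_mu, self._gauss_sd,
                    self._hn, self._hn_scale, self._l,
                    self.prior.l_beta_a, self.prior.l_beta_b,
                )
            )
        pr = self.prior
        lp = -0.5 * float(
            np.sum(((u[self._gauss] - self._gauss_mu) / self._gauss_sd) ** 2)
        )
        v = np.exp(np.clip(u[self._hn], -30.0, 30.0))
        lp += float(np.sum(-0.5 * (v / self._hn_scale) ** 2 + u[self._hn]))
        # Beta(a, b) density on l plus the logit jacobian: a log l + b log(1-l)
        l = np.clip(_sigmoid(u[self._l]), 1e-12, 1.0 - 1e-12)
        lp += float(np.sum(pr.l_beta_a * np.log(l) + pr.l_beta_b * np.log1p(-l)))
        return lp

    # -- likelihood ---------------------------------------------------------

    def loglik(self, p: np.ndarray, z_loc: np.ndarray | None) -> float:
        if _core.HAVE_NUMBA:
            return float(
                _core.loglik_core(
                    p, self.x_a, self.x_b, self.y_all, self._row64,
                    z_loc if z_loc is not None else self._z_dummy,
                    self.na, self.nb, self.mode == "full",
                )
            )
        return self._loglik_numpy(p, z_loc)

    def _loglik_numpy(self, p: np.ndarray, z_loc: np.ndarray | None) -> float:
        la, sa, ma = p[self._ia[0]], p[self._ia[1]], p[self._ia[2]]
        lb, sb, mb = p[self._ib[0]], p[self._ib[1]], p[self._ib[2]]
        ha = la + (1.0 - la) / (1.0 + 10.0 ** np.clip(sa * (self.x_a - ma), -300, 300))
        hb = lb + (1.0 - lb) / (1.0 + 10.0 ** np.clip(sb * (self.x_b - mb), -300, 300))
        if self.mode == "full":
            p0 = np.clip(ha[self.na:] * hb[self.nb:], P0_CLIP, 1.0 - P0_CLIP)
            delta = _g_transform(
                z_loc[self.row_of_loc], p0, p[self.index["b1"]], p[self.index["b2"]]
            )
            mean = np.concatenate([ha[: self.na], hb[: self.nb], p0 + delta])
        else:
            mean = np.concatenate([ha, hb])
        var = p[self.index["sigma0"]] ** 2 * (p[self.index["c0"]] + mean) + VAR_FLOOR
        resid = self.y_all - mean
        return self._const - 0.5 * float(
            np.sum(np.log(var)) + np.sum(resid * resid / var)
        )

    def chol(self, ls: float) -> np.ndarray:
        if self._chol_cache is not None and self._chol_cache[0] == ls:
            return self._chol_cache[1]
        K = matern32(self.locations, self.locations, ls) + JITTER * np.eye(self.n_loc)
        L = np.linalg.cholesky(K)
        self._chol_cache = (ls, L)
        return L

    def z_from(self, u_z: np.ndarray, p: np.ndarray) -> np.ndarray:
        return p[self.index["amp"]] * (self.chol(p[self.index["ls"]]) @ u_z)

    def log_posterior(self, u: np.ndarray, u_z: np.ndarray | None) -> float:
        full = self.mode == "full"
        if _core.HAVE_NUMBA:
            if full:
                ls = float(np.exp(min(max(u[9], -30.0), 30.0)))
                Lu = self.chol(ls) @ u_z
            else:
                Lu = self._z_dummy
            return float(
                _core.logpost_core(
                    u, Lu, self.x_a, self.x_b, self.y_all, self._row64,
                    self.na, self.nb, full,
                    self._gauss, self._gauss_mu, self._gauss_sd,
                    self._hn, self._hn_scale, self._l,
                    self.prior.l_beta_a, self.prior.l_beta_b,
                )
            )
        p = self.constrain(u)
        z = self.z_from(u_z, p) if full else None
        return self.log_prior(u) + self.loglik(p, z)


def _slice_sample_coord(model, u, u_z, j, rng, cur_lp, width=1.0, max_out=8):
    """Univariate slice sampling with stepping out (Neal 2003).

    ``cur_lp`` is the log posterior at the current point; the value at the
    accepted point is returned so consecutive coordinate updates share
    evaluations.
    """
    x0 = u[j]
    log_y = cur_lp + np.log(rng.uniform())
    lo = x0 - width * rng.uniform()
    hi = lo + width

    def f(val):
        u[j] = val
        return model.log_posterior(u, u_z)

    steps = max_out
    while steps > 0 and f(lo) > log_y:
        lo -= width
        steps -= 1
    steps = max_out
    while steps > 0 and f(hi) > log_y:
        hi += width
        steps -= 1
    for _ in range(100):
        x1 = rng.uniform(lo, hi)
        lp1 = f(x1)
        if lp1 > log_y:
            return lp1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    u[j] = x0
    return cur_lp  # pathological shrinkage; keep the current point


def _elliptical_slice(model, u, u_z, rng):
    """Elliptical slice sampling of the whitened latent field."""
    p = model.constrain(u)
    amp = p[model.index["amp"]]
    L = model.chol(p[model.index["ls"]])

    def loglik(v):
        return model.loglik(p, amp * (L @ v))

    nu = rng.standard_normal(u_z.shape)
    log_y = loglik(u_z) + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    for _ in range(100):
        prop = u_z * np.cos(theta) + nu * np.sin(theta)
        if loglik(prop) > log_y:
            return prop
        if theta < 0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    return u_z


def experiment_seed(key: ExperimentKey, global_seed: int) -> int:
    """Stable per-experiment seed: CRC32 of the key XOR the global seed."""
    tag = f"{key.cell_line}|{key.drug_pair[0]}|{key.drug_pair[1]}".encode()
    return (zlib.crc32(tag) ^ (global_seed & 0xFFFFFFFF)) & 0x7FFFFFFF


def _prepare_combo(records: Sequence[ViabilityRecord], scaler: ConcentrationScaler):
    orig = np.array([[r.conc_a, r.conc_b] for r in records], dtype=float)
    y = np.array([r.viability for r in records], dtype=float)
    unit = scaler.forward(orig)
    rounded = np.round(unit, 9)
    locations, row_of_loc = np.unique(rounded, axis=0, return_inverse=True)
    return orig, locations, row_of_loc, y


def fit_single_experiment(
    screen: Screen,
    key: ExperimentKey,
    mode: Literal["full", "monotherapy_only"] = "full",
    prior: PriorConfig | None = None,
    config: SamplerConfig | None = None,
    scaler: ConcentrationScaler | None = None,
    grid_k: int = 10,
) -> Stage1Fit:
    """Posterior sampling for one experiment.

    ``full`` mode fits monotherapy curves, the bounding-transform parameters
    and the latent interaction GP jointly; ``monotherapy_only`` ignores
    combination rows and fits only the two curves plus noise, supporting the
    non-interaction surface of held-out experiments.  Convergence (split
    R-hat below the configured threshold on all scalar parameters) is
    reported in the diagnostics, never silently.
    """
    prior = prior or PriorConfig()
    config = config or SamplerConfig()
    combos = screen.combinations.get(key, [])
    mono_a_recs = screen.monotherapy_for(key.cell_line, key.drug_pair[0])
    mono_b_recs = screen.monotherapy_for(key.cell_line, key.drug_pair[1])
    if not mono_a_recs or not mono_b_recs:
        raise ValueError(f"monotherapy data missing for {key}")
    if mode == "full" and not combos:
        raise ValueError(f"no combination data for {key} in full mode")
    if scaler is None:
        if combos:
            scaler, _ = scale_to_common_grid(combos, k=grid_k)
        else:
            # monotherapy-only screens: unit box spans each drug's mono range
            a = [r.conc_a for r in mono_a_recs]
            b = [r.conc_a for r in mono_b_recs]
            scaler = ConcentrationScaler(
                lo=(min(a), min(b)), hi=(max(a), max(b))
            )

    xa = np.array([r.conc_a for r in mono_a_recs])
    ya = np.array([r.viability for r in mono_a_recs])
    xb = np.array([r.conc_a for r in mono_b_recs])
    yb = np.array([r.viability for r in mono_b_recs])
    combo_xy = _prepare_combo(combos, scaler) if mode == "full" else None

    all_x = np.concatenate([xa, xb])
    m_center = float(0.5 * (all_x.min() + all_x.max()))
    m_sd = float(all_x.max() - all_x.min())
    model = _Stage1Model((xa, ya), (xb, yb), combo_xy, mode, prior, m_center, m_sd)

    seed = experiment_seed(key, config.seed)
    n_par = len(model.names)
    chains_scalars = {name: np.empty((config.chains, config.draws)) for name in model.names}
    z_store = (
        np.empty((config.chains * config.draws, model.n_loc)) if mode == "full" else None
    )
    for chain in range(config.chains):
        rng = np.random.default_rng(seed + 1000 * chain)
        u = 0.1 * rng.standard_normal(n_par)
        u[model.index["m_a"]] = m_center + 0.1 * rng.standard_normal()
        u[model.index["m_b"]] = m_center + 0.1 * rng.standard_normal()
        u_z = rng.standard_normal(model.n_loc) if mode == "full" else None
        cur_lp = model.log_posterior(u, u_z)
        for it in range(config.warmup + config.draws):
            if mode == "full":
                u_z = _elliptical_slice(model, u, u_z, rng)
                cur_lp = model.log_posterior(u, u_z)
            for j in range(n_par):
                cur_lp = _slice_sample_coord(model, u, u_z, j, rng, cur_lp)
            if it >= config.warmup:
                idx = it - config.warmup
                p = model.constrain(u)
                for i, name in enumerate(model.names):
                    chains_scalars[name][chain, idx] = p[i]
                if mode == "full":
                    z_store[chain * config.draws + idx] = model.z_from(u_z, p)

    diagnostics = _diagnostics(chains_scalars)
    converged = all(
        d["rhat"] < config.rhat_threshold
        for d in diagnostics.values()
        if np.isfinite(d["rhat"])
    )
    return Stage1Fit(
        key=key,
        mode=mode,
        scalar_draws=chains_scalars,
        z_draws=z_store,
        locations=None if combo_xy is None else combo_xy[1],
        scaler=scaler,
        diagnostics=diagnostics,
        converged=converged,
        prior=prior,
        config=config,
    )


def _diagnostics(chains_scalars: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    import warnings

    import arviz as az

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, arr in chains_scalars.items():
            # single-chain runs are split in two for a split-Rhat analogue
            data = arr if arr.shape[0] > 1 else arr.reshape(2, -1)
            try:
                rhat = float(az.rhat(az.convert_to_dataset(data))["x"].values)
                ess = float(az.ess(az.convert_to_dataset(data))["x"].values)
            except Exception:
                rhat, ess = np.nan, np.nan
            out[name] = {"rhat": rhat, "ess": ess}
    return out


def _grid_p0(fit: Stage1Fit, grid: CommonGrid, draw_idx: np.ndarray) -> np.ndarray:
    """Per-draw Bliss surface on the grid, shape (len(draw_idx), n)."""
    orig = fit.scaler.inverse(grid.points)
    la, sa, ma = (fit.flat(k)[draw_idx] for k in ("l_a", "s_a", "m_a"))
    lb, sb, mb = (fit.flat(k)[draw_idx] for k in ("l_b", "s_b", "m_b"))
    ha = la[:, None] + (1.0 - la[:, None]) / (
        1.0 + 10.0 ** np.clip(sa[:, None] * (orig[None, :, 0] - ma[:, None]), -300, 300)
    )
    hb = lb[:, None] + (1.0 - lb[:, None]) / (
        1.0 + 10.0 ** np.clip(sb[:, None] * (orig[None, :, 1] - mb[:, None]), -300, 300)
    )
    return np.clip(ha * hb, P0_CLIP, 1.0 - P0_CLIP)


def latent_summary_on_grid(fit: Stage1Fit, grid: CommonGrid) -> LatentSummary:
    """Summarize the posterior predictive of z and f on the common grid.

    For every retained draw the latent field is extended from the observed
    combination locations to the grid through the GP conditional (with that
    draw's amplitude/lengthscale) and a conditional sample is drawn; means
    and variances are then empirical over draws, with a small variance floor
    so downstream noise matrices stay positive definite.
    """
    if fit.mode != "full":
        raise ValueError("grid summaries require a full-mode fit")
    total = fit.total_draws
    if total < fit.config.min_draws:
        raise ValueError(f"too few posterior draws ({total} < {fit.config.min_draws})")
    draw_idx = np.arange(total)
    rng = np.random.default_rng(experiment_seed(fit.key, fit.config.seed) + 7)
    amps = fit.flat("amp")
    lss = fit.flat("ls")
    n = grid.n
    z_grid = np.empty((total, n))
    eye_loc = JITTER * np.eye(fit.locations.shape[0])
    eye_g = JITTER * np.eye(n)
    for t in range(total):
        ls = lss[t]
        Kuu = matern32(fit.locations, fit.locations, ls) + eye_loc
        Kgu = matern32(grid.points, fit.locations, ls)
        Kgg = matern32(grid.points, grid.points, ls)
        sol = np.linalg.solve(Kuu, fit.z_draws[t])
        mean = Kgu @ sol
        cov = amps[t] ** 2 * (Kgg - Kgu @ np.linalg.solve(Kuu, Kgu.T)) + eye_g
        z_grid[t] = mean + np.linalg.cholesky(0.5 * (cov + cov.T)) @ rng.standard_normal(n)
    p0 = _grid_p0(fit, grid, draw_idx)
    b1 = fit.flat("b1")[:, None]
    b2 = fit.flat("b2")[:, None]
    f_grid = p0 + _g_transform(z_grid, p0, b1, b2)
    return LatentSummary(
        key=fit.key,
        z_mean=z_grid.mean(axis=0),
        z_var=np.maximum(z_grid.var(axis=0), VAR_FLOOR),
        f_mean=f_grid.mean(axis=0),
        f_var=np.maximum(f_grid.var(axis=0), VAR_FLOOR),
    )


def p0_star_on_grid(fit: Stage1Fit, grid: CommonGrid) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean/variance of the monotherapy-only Bliss surface."""
    total = fit.total_draws
    p0 = _grid_p0(fit, grid, np.arange(total))
    return p0.mean(axis=0), np.maximum(p0.var(axis=0), VAR_FLOOR)
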