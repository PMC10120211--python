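"""Marginal-likelihood training and prediction for the multi-output GP.

The masked screen is handled through dummy observations with huge noise: the
preconditioned conjugate-gradient solve on the padded Kronecker-structured
system reproduces the dense reduced system on observed entries exactly, and
the log-determinant of the reduced system is approximated from the exact
eigenvalue multiset of the structured prior covariance (scaled by the
observed fraction) combined with the observed noise entries through a
Weyl-type eigenvalue pairing.  Gradients of the marginal likelihood are
computed analytically, differentiating through the factor
eigendecompositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .kernels import (
    CovarianceOperator,
    KernelHyperparams,
    PermutationPair,
    assemble_full_covariance,
    build_permutations,
    proposition1_eigenvalues,
    softplus,
    softplus_grad,
    squared_exponential_gram,
)
from .screen_data import ExperimentKey, ScreenMatrices

__all__ = [
    "CGConvergenceError",
    "NoiseModel",
    "TrainingConfig",
    "TrainingState",
    "initialize_parameters",
    "preconditioned_cg_solve",
    "log_marginal_likelihood",
    "train",
    "predictive_posterior",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class CGConvergenceError(RuntimeError):
    def __init__(self, residual: float, tol: float, iterations: int):
        self.residual = residual
        self.tol = tol
        self.iterations = iterations
        super().__init__(
            f"CG did not converge in {iterations} iterations "
            f"(residual {residual:.3e}, tolerance {tol:.3e})"
        )


@dataclass
class NoiseModel:
    """Diagonal observation noise ``Sigma = diag(vec(S) + sigma^2)``."""

    sigma_diag: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sigma_diag <= 0):
            raise ValueError("noise diagonal must be strictly positive")
        if self.sigma_diag.shape != self.observed.shape:
            raise ValueError("noise diagonal and mask must have the same shape")

    @classmethod
    def from_screen(
        cls, screen: ScreenMatrices, sigma2: float, use_measurement_error: bool = True
    ) -> "NoiseModel":
        vec_s = screen.vec_S().copy()
        observed = screen.vec_mask()
        if not use_measurement_error:
            vec_s[observed] = 0.0
        return cls(sigma_diag=vec_s + sigma2, observed=observed)


@dataclass
class TrainingConfig:
    r_c: int = 2
    r_d: int = 2
    variant: Literal["invariant", "non_invariant"] = "invariant"
    use_measurement_error: bool = True
    learning_rate: float = 0.1
    cg_tolerance_factor: float = 0.1  # tolerance = factor * (M / N)
    cg_max_iterations: int = 1000
    max_steps: int = 500
    patience: int = 50
    min_rel_improvement: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.cg_tolerance_factor <= 0:
            raise ValueError("cg_tolerance_factor must be positive")
        if self.r_c < 1 or self.r_d < 1:
            raise ValueError("ranks must be >= 1")


@dataclass
class TrainingState:
    hyperparams: KernelHyperparams
    trace: list[float]
    converged: bool
    config: TrainingConfig


def initialize_parameters(
    n_cell_lines: int, n_pairs: int, r_c: int, r_d: int, seed: int = 0
) -> KernelHyperparams:
    """Softplus(0) lengthscale/noise, N(0, 0.1^2) low-rank factors, and
    softplus of standard-normal draws for the diagonal boosts, so both output
    covariances start near-diagonal."""
    if r_c < 1 or r_d < 1:
        raise ValueError("ranks must be >= 1")
    if r_c > n_cell_lines or r_d > 2 * n_pairs:
        raise ValueError("rank exceeds matrix dimension")
    rng = np.random.default_rng(seed)
    return KernelHyperparams(
        raw_ell=0.0,
        raw_sigma=0.0,
        L_d=0.1 * rng.standard_normal((2 * n_pairs, r_d)),
        raw_v_d=rng.standard_normal(2 * n_pairs),
        L_c=0.1 * rng.standard_normal((n_cell_lines, r_c)),
        raw_v_c=rng.standard_normal(n_cell_lines),
    )


def preconditioned_cg_solve(
    operator: CovarianceOperator,
    noise: NoiseModel,
    rhs: np.ndarray,
    tol: float = 1e-10,
    max_iterations: int = 1000,
) -> np.ndarray:
    """Solve ``(K + Sigma) q = rhs`` by CG preconditioned with ``Sigma^-1``.

    Equivalent to the symmetrically preconditioned system with
    ``C = Sigma^(-1/2)``; the huge dummy-noise entries make the masked
    components of the solution negligible, so the observed components match
    the dense reduced solve.
    """
    rhs = np.asarray(rhs, dtype=float)
    n_total = operator.shape[0]
    if rhs.shape != (n_total,):
        raise ValueError(f"rhs has shape {rhs.shape}, expected ({n_total},)")
    sigma = noise.sigma_diag
    if sigma.shape != (n_total,):
        raise ValueError("noise model size does not match the operator")
    b_norm = float(np.sqrt(rhs @ (rhs / sigma)))
    if b_norm == 0.0:
        return np.zeros(n_total)
    q = np.zeros(n_total)
    r = rhs.copy()
    y = r / sigma
    p = y.copy()
    rho = float(r @ y)
    for _ in range(max_iterations):
        res = float(np.sqrt(rho))
        if res <= tol * b_norm:
            return q
        Ap = operator.matvec(p) + sigma * p
        denom = float(p @ Ap)
        if denom <= 0:
            raise CGConvergenceError(res, tol * b_norm, max_iterations)
        alpha = rho / denom
        q += alpha * p
        r -= alpha * Ap
        y = r / sigma
        rho_new = float(r @ y)
        beta = rho_new / rho
        rho = rho_new
        p = y + beta * p
    res = float(np.sqrt(max(rho, 0.0)))
    if res <= tol * b_norm:
        return q
    raise CGConvergenceError(res, tol * b_norm, max_iterations)


def _logdet_terms(
    operator: CovarianceOperator, noise: NoiseModel, M: int, N: int
):
    """Approximate reduced log-determinant and its eigen-side ingredients.

    The k-th largest (M/N)-scaled prior eigenvalue is paired with the k-th
    smallest observed noise entry; in the fully observed homoskedastic case
    this reproduces the exact spectrum of ``K + sigma^2 I``.  The eigenvalue
    array is kept in factor cross-product order (index ``(i * n_d + j) * n_x
    + l``) so that gradients can be routed back to the factor matrices.
    """
    eigs, factors = proposition1_eigenvalues(
        operator, return_factors=True, keep_product_order=True
    )
    order = np.argsort(eigs)[::-1]
    top = order[:M]
    lam_scaled = (M / N) * eigs[top]
    s_sorted = np.sort(noise.sigma_diag[noise.observed])
    shifted = lam_scaled + s_sorted
    logdet = float(np.sum(np.log(shifted)))
    return logdet, top, lam_scaled, s_sorted, shifted, eigs, factors


def _quad_contractions(operator: CovarianceOperator, q_obs: np.ndarray):
    """All quadratic-form gradient contractions ``q^T (dK/dtheta) q``."""
    A = q_obs.reshape(
        operator.n_cell_lines, operator.n_extended_pairs, operator.n_grid
    )
    BA = operator._apply_inner(A)
    G_c = np.einsum("cax,Cax->cC", A, BA)
    T = np.einsum("cC,Cby->cby", operator.K_c, A)
    if operator.variant == "non_invariant":
        W1 = np.einsum("xy,cby->cbx", operator.K_x, T)
        G_d = np.einsum("cax,cbx->ab", A, W1)
        V1 = np.einsum("ab,cby->cay", operator.K_d, T)
        G_x = np.einsum("cax,cay->xy", A, V1)
        return G_c, G_d, G_x
    p = operator.perms.p_index
    pt = operator.perms.pt_index
    W1 = np.einsum("xy,cby->cbx", operator.K_x, T)
    H1 = np.einsum("cax,cbx->ab", A, W1)
    W2 = np.einsum("xy,cby->cbx", operator._PtKx, T)
    H2 = np.einsum("cax,cbx->ab", A, W2)
    G_d = H1 + H1[np.ix_(p, p)] + H2[p, :] + H2[:, p]
    V1 = np.einsum("ab,cby->cay", operator._Kd_sym, T)
    G_x1 = np.einsum("cax,cay->xy", A, V1)
    V2 = np.einsum("ab,cby->cay", operator._Kd_anti, T)
    G_x2 = np.einsum("cax,cay->xy", A, V2)
    G_x = G_x1 + G_x2[pt, :]
    return G_c, G_d, G_x


def _zero_grads(h: KernelHyperparams) -> dict[str, np.ndarray | float]:
    return {
        "raw_ell": 0.0,
        "raw_sigma": 0.0,
        "L_d": np.zeros_like(h.L_d),
        "raw_v_d": np.zeros_like(h.raw_v_d),
        "L_c": np.zeros_like(h.L_c),
        "raw_v_c": np.zeros_like(h.raw_v_c),
    }


def log_marginal_likelihood(
    h: KernelHyperparams,
    screen: ScreenMatrices,
    variant: Literal["invariant", "non_invariant"] = "invariant",
    use_measurement_error: bool = True,
    cg_tol: float = 1e-10,
    cg_max_iterations: int = 2000,
    perms: PermutationPair | None = None,
    with_grads: bool = False,
):
    """Gaussian log marginal likelihood of the observed entries.

    Returns ``-(quad + logdet + M log 2 pi) / 2`` with the quadratic form
    computed by the masked preconditioned CG solve and the log-determinant by
    the scaled-eigenvalue approximation (exact for fully observed
    homoskedastic noise).  With ``with_grads=True`` also returns the exact
    analytic gradient of this objective with respect to all raw parameters.
    """
    if perms is None:
        perms = build_permutations(screen.n_extended_pairs // 2, screen.grid)
    operator = assemble_full_covariance(h, perms, screen.grid, variant=variant)
    noise = NoiseModel.from_screen(screen, h.sigma2, use_measurement_error)
    M, N = screen.M, screen.N
    if M == 0:
        return (0.0, _zero_grads(h)) if with_grads else 0.0

    vec_z = screen.vec_Z()
    obs = noise.observed
    q = preconditioned_cg_solve(
        operator, noise, vec_z, tol=cg_tol, max_iterations=cg_max_iterations
    )
    q_obs = np.where(obs, q, 0.0)
    quad = float(vec_z[obs] @ q_obs[obs])
    logdet, top, lam_scaled, s_sorted, shifted, eigs, factors = _logdet_terms(
        operator, noise, M, N
    )
    ll = -0.5 * (quad + logdet + M * LOG_2PI)
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite marginal likelihood (quad={quad:.3e}, logdet={logdet:.3e}); "
            f"lengthscale={h.lengthscale:.3e}, sigma2={h.sigma2:.3e}"
        )
    if not with_grads:
        return ll

    wc, Uc, wd, Ud, wx, Ux = factors
    n_c, n_d, n_x = wc.size, wd.size, wx.size
    p = perms.p_index
    pt = perms.pt_index

    # --- log-det gradient through the factor eigendecompositions ---
    coeff = 1.0 / shifted  # d logdet / d shifted_k
    g_prod = np.zeros(N)
    scale = np.where(eigs[top] > 0, M / N, 0.0)
    if variant == "invariant":
        # selected eigenvalue = 2 * (wc_i wd_j wx_l) when positive, else 0
        np.add.at(g_prod, top, coeff * scale)
        deriv_factor = 2.0
    else:
        np.add.at(g_prod, top, coeff * scale)
        deriv_factor = 1.0
    G = (deriv_factor * g_prod).reshape(n_c, n_d, n_x)
    g_c = np.einsum("ijl,j,l->i", G, wd, wx)
    g_d = np.einsum("ijl,i,l->j", G, wc, wx)
    g_x = np.einsum("ijl,i,j->l", G, wc, wd)
    ld_Kc = (Uc * g_c) @ Uc.T
    Td = (Ud * g_d) @ Ud.T
    Tx = (Ux * g_x) @ Ux.T
    if variant == "invariant":
        ld_Kd = Td[p, :] + Td[:, p]  # P U g U^T + U g U^T P
        ld_Kx = Tx[pt, :]  # contraction weight for dK_x entries
    else:
        ld_Kd = Td
        ld_Kx = Tx
    ld_sigma2 = float(np.sum(coeff))

    # --- quadratic-form gradient: d quad / d theta = - q^T dK q (reduced) ---
    G_c, G_d, G_x = _quad_contractions(operator, q_obs)
    qd_sigma2 = -float(q_obs @ q_obs)

    # --- combine: ll = -(quad + logdet)/2 ---
    d_Kc = 0.5 * G_c - 0.5 * ld_Kc
    d_Kd = 0.5 * G_d - 0.5 * ld_Kd
    d_Kx = 0.5 * G_x - 0.5 * ld_Kx
    d_sigma2 = -0.5 * (qd_sigma2 + ld_sigma2)

    dist2 = np.sum(
        (screen.grid.points[:, None, :] - screen.grid.points[None, :, :]) ** 2, axis=-1
    )
    ell = h.lengthscale
    dKx_dell = operator.K_x * dist2 / ell ** 3
    d_ell = float(np.sum(d_Kx * dKx_dell))

    grads = {
        "raw_ell": d_ell * float(softplus_grad(h.raw_ell)),
        "raw_sigma": d_sigma2 * 2.0 * h.sigma * float(softplus_grad(h.raw_sigma)),
        "L_d": (d_Kd + d_Kd.T) @ h.L_d,
        "raw_v_d": np.diag(d_Kd) * softplus_grad(h.raw_v_d),
        "L_c": (d_Kc + d_Kc.T) @ h.L_c,
        "raw_v_c": np.diag(d_Kc) * softplus_grad(h.raw_v_c),
    }
    return ll, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray | float], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}
        self.v = {k: np.zeros_like(np.asarray(v, dtype=float)) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for k, val in params.items():
            g = np.asarray(grads[k], dtype=float)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g ** 2
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            update = self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            new = np.asarray(val, dtype=float) + update  # ascent
            out[k] = float(new) if np.ndim(val) == 0 else new
        return out


def _params_dict(h: KernelHyperparams) -> dict:
    return {
        "raw_ell": h.raw_ell, "raw_sigma": h.raw_sigma,
        "L_d": h.L_d, "raw_v_d": h.raw_v_d,
        "L_c": h.L_c, "raw_v_c": h.raw_v_c,
    }


def _params_to_hyper(params: dict) -> KernelHyperparams:
    return KernelHyperparams(
        raw_ell=float(params["raw_ell"]), raw_sigma=float(params["raw_sigma"]),
        L_d=np.asarray(params["L_d"]), raw_v_d=np.asarray(params["raw_v_d"]),
        L_c=np.asarray(params["L_c"]), raw_v_c=np.asarray(params["raw_v_c"]),
    )


def train(screen: ScreenMatrices, config: TrainingConfig) -> TrainingState:
    """Adam ascent on the marginal likelihood with early stopping.

    Stops once ``patience`` consecutive steps fail to improve the best-seen
    likelihood by a relative margin; returns the best-seen parameters.
    """
    n_pairs = screen.n_extended_pairs // 2
    h = initialize_parameters(
        screen.n_cell_lines, n_pairs, config.r_c, config.r_d, seed=config.seed
    )
    perms = build_permutations(n_pairs, screen.grid)
    alpha = screen.M / screen.N if screen.N else 0.0
    cg_tol = max(config.cg_tolerance_factor * alpha, 1e-12)

    params = _params_dict(h)
    opt = _Adam(params, config.learning_rate)
    trace: list[float] = []
    best_ll = -np.inf
    best_params = params
    since_improvement = 0
    bad_steps = 0
    converged = False
    for _ in range(config.max_steps):
        try:
            ll, grads = log_marginal_likelihood(
                _params_to_hyper(params), screen,
                variant=config.variant,
                use_measurement_error=config.use_measurement_error,
                cg_tol=cg_tol,
                cg_max_iterations=config.cg_max_iterations,
                perms=perms,
                with_grads=True,
            )
            bad_steps = 0
        except (FloatingPointError, CGConvergenceError):
            bad_steps += 1
            if bad_steps >= 5:
                raise RuntimeError(
                    f"training diverged: repeated non-finite likelihood; trace={trace[-5:]}"
                )
            params = opt.step(params, {k: np.zeros_like(np.asarray(v, dtype=float))
                                       for k, v in params.items()})
            continue
        trace.append(ll)
        threshold = abs(best_ll) * config.min_rel_improvement if np.isfinite(best_ll) else 0.0
        if ll > best_ll + threshold:
            best_ll = ll
            best_params = {k: (float(v) if np.ndim(v) == 0 else np.array(v))
                           for k, v in params.items()}
            since_improvement = 0
        else:
            if ll > best_ll:
                best_ll = ll
                best_params = {k: (float(v) if np.ndim(v) == 0 else np.array(v))
                               for k, v in params.items()}
            since_improvement += 1
            if since_improvement >= config.patience:
                converged = True
                break
        params = opt.step(params, grads)
    return TrainingState(
        hyperparams=_params_to_hyper(best_params),
        trace=trace,
        converged=converged,
        config=config,
    )


def predictive_posterior(
    state: TrainingState,
    screen: ScreenMatrices,
    targets: Sequence[ExperimentKey],
    want_variance: bool = False,
    cg_tol: float = 1e-8,
    cg_max_iterations: int = 2000,
) -> dict[ExperimentKey, tuple[np.ndarray, np.ndarray | None]]:
    """Predictive mean (and optional variance) of the latent GP on the grid.

    One masked CG solve is shared across all targets for the mean
    (``K (K+Sigma)^-1 vec(Z)`` restricted to observed entries); variances cost
    one extra CG solve per target grid point.  Unknown cell lines or pairs
    raise (cold start is impossible with free-form output kernels).
    """
    h = state.hyperparams
    n_pairs = screen.n_extended_pairs // 2
    perms = build_permutations(n_pairs, screen.grid)
    operator = assemble_full_covariance(h, perms, screen.grid, variant=state.config.variant)
    noise = NoiseModel.from_screen(screen, h.sigma2, state.config.use_measurement_error)
    obs = noise.observed

    q = preconditioned_cg_solve(
        operator, noise, screen.vec_Z(), tol=cg_tol, max_iterations=cg_max_iterations
    )
    q_obs = np.where(obs, q, 0.0)
    mean_all = operator.matvec(q_obs)
    n = screen.n
    diag = operator.diagonal()
    out: dict[ExperimentKey, tuple[np.ndarray, np.ndarray | None]] = {}
    for key in targets:
        j = screen.column_index(key)  # raises KeyError on cold start
        sl = slice(j * n, (j + 1) * n)
        mean = mean_all[sl].copy()
        var = None
        if want_variance:
            var = np.empty(n)
            for i in range(n):
                e = np.zeros(operator.shape[0])
                e[j * n + i] = 1.0
                k_star = operator.matvec(e)
                k_star_obs = np.where(obs, k_star, 0.0)
                sol = preconditioned_cg_solve(
                    operator, noise, k_star_obs, tol=cg_tol,
                    max_iterations=cg_max_iterations,
                )
                sol = np.where(obs, sol, 0.0)
                var[i] = diag[j * n + i] - float(k_star_obs @ sol)
        out[key] = (mean, var)
    return out
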