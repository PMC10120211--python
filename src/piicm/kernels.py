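"""Covariance construction for the permutation-invariant multi-output GP.

Builds the squared-exponential input Gram matrix, the low-rank free-form
output covariances, the block-swap and grid-reflection permutations, and the
full structured covariance

    K = K_c  (x)  [ (K_d + P K_d P) (x) K_x  +  (P K_d + K_d P) (x) Pt K_x ]

exposed as a matrix-free linear operator, together with its exact eigenvalue
multiset obtained from the Kronecker factorization of the swap-symmetrized
part (twice the positive eigenvalues of ``K_c (x) (P K_d + K_d P) (x) Pt K_x``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .screen_data import CommonGrid

__all__ = [
    "softplus",
    "softplus_grad",
    "inv_softplus",
    "KernelHyperparams",
    "PermutationPair",
    "squared_exponential_gram",
    "squared_exponential_cross",
    "lowrank_gram",
    "build_permutations",
    "CovarianceOperator",
    "assemble_full_covariance",
    "structured_matvec",
    "proposition1_eigenvalues",
    "kronecker_eigenvalues",
]

Variant = Literal["invariant", "non_invariant"]

#: relative cutoff below which eigenvalues are treated as zero
EIG_ZERO_RTOL = 1e-10


def softplus(x):
    """Numerically stable log(1 + exp(x))."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def softplus_grad(x):
    x = np.asarray(x, dtype=float)
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # logistic sigmoid


def inv_softplus(y):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("inv_softplus requires positive input")
    return y + np.log(-np.expm1(-y))


@dataclass
class KernelHyperparams:
    """Raw (unconstrained) kernel parameters with softplus positivity.

    Constrained values: ``lengthscale = softplus(raw_ell)``,
    ``sigma = softplus(raw_sigma)`` (global noise SD, ``sigma2 = sigma**2``),
    ``v_c = softplus(raw_v_c)``, ``v_d = softplus(raw_v_d)``.  ``L_c`` and
    ``L_d`` are unconstrained low-rank factors.
    """

    raw_ell: float
    raw_sigma: float
    L_d: np.ndarray
    raw_v_d: np.ndarray
    L_c: np.ndarray
    raw_v_c: np.ndarray

    @property
    def lengthscale(self) -> float:
        return float(softplus(self.raw_ell))

    @property
    def sigma(self) -> float:
        return float(softplus(self.raw_sigma))

    @property
    def sigma2(self) -> float:
        return self.sigma ** 2

    @property
    def v_d(self) -> np.ndarray:
        return softplus(self.raw_v_d)

    @property
    def v_c(self) -> np.ndarray:
        return softplus(self.raw_v_c)

    @property
    def K_d(self) -> np.ndarray:
        return lowrank_gram(self.L_d, self.v_d)

    @property
    def K_c(self) -> np.ndarray:
        return lowrank_gram(self.L_c, self.v_c)

    @property
    def n_extended_pairs(self) -> int:
        return self.L_d.shape[0]

    @property
    def n_cell_lines(self) -> int:
        return self.L_c.shape[0]

    def copy(self) -> "KernelHyperparams":
        return KernelHyperparams(
            raw_ell=self.raw_ell, raw_sigma=self.raw_sigma,
            L_d=self.L_d.copy(), raw_v_d=self.raw_v_d.copy(),
            L_c=self.L_c.copy(), raw_v_c=self.raw_v_c.copy(),
        )


@dataclass(frozen=True)
class PermutationPair:
    """Block-swap permutation P (pair space) and grid reflection Pt.

    Both are stored as index arrays: applying the permutation matrix to a
    vector ``w`` is ``w[index]``.  Both are involutions.
    """

    p_index: np.ndarray
    pt_index: np.ndarray

    @property
    def P(self) -> np.ndarray:
        return np.eye(len(self.p_index))[self.p_index]

    @property
    def P_tilde(self) -> np.ndarray:
        return np.eye(len(self.pt_index))[self.pt_index]


def squared_exponential_gram(points: np.ndarray, lengthscale: float) -> np.ndarray:
    """exp(-||x - x'||^2 / (2 l^2)) on all point pairs."""
    if lengthscale <= 0:
        raise ValueError(f"lengthscale must be positive, got {lengthscale}")
    points = np.asarray(points, dtype=float)
    sq = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return np.exp(-0.5 * sq / lengthscale ** 2)


def squared_exponential_cross(a: np.ndarray, b: np.ndarray, lengthscale: float) -> np.ndarray:
    if lengthscale <= 0:
        raise ValueError(f"lengthscale must be positive, got {lengthscale}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    sq = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return np.exp(-0.5 * sq / lengthscale ** 2)


def lowrank_gram(L: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Free-form low-rank covariance ``L L^T + diag(v)``."""
    L = np.asarray(L, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("diagonal boost v must be positive elementwise")
    return L @ L.T + np.diag(v)


def build_permutations(n_pairs: int, grid: CommonGrid) -> PermutationPair:
    """P swaps the canonical and reversed pair blocks; Pt reflects the grid."""
    if n_pairs < 1:
        raise ValueError("need at least one drug pair")
    p_index = np.concatenate([np.arange(n_pairs, 2 * n_pairs), np.arange(n_pairs)])
    pt_index = grid.reflection_index()
    if not np.array_equal(pt_index[pt_index], np.arange(grid.n)):
        raise ValueError("grid is not closed under coordinate reflection")
    return PermutationPair(p_index=p_index, pt_index=pt_index)


@dataclass
class CovarianceOperator:
    """Matrix-free linear operator for the full prior covariance.

    Holds only the three factor matrices (memory ``O(N_c^2 + (2 N_d)^2 + n^2)``);
    matvecs run as sums of triple-Kronecker contractions without ever
    materializing the N x N matrix.
    """

    K_c: np.ndarray
    K_d: np.ndarray
    K_x: np.ndarray
    perms: PermutationPair
    variant: Variant = "invariant"

    # symmetrized pair-space factors, precomputed once
    _Kd_sym: np.ndarray = field(init=False, repr=False)
    _Kd_anti: np.ndarray = field(init=False, repr=False)
    _PtKx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        q = self.K_d.shape[0]
        if self.K_d.shape != (q, q) or len(self.perms.p_index) != q:
            raise ValueError("K_d shape does not match the pair permutation")
        if self.K_x.shape[0] != len(self.perms.pt_index):
            raise ValueError("K_x shape does not match the grid reflection")
        if self.K_c.shape[0] != self.K_c.shape[1]:
            raise ValueError("K_c must be square")
        p = self.perms.p_index
        pt = self.perms.pt_index
        # K_d + P K_d P  and  P K_d + K_d P (both symmetric)
        self._Kd_sym = self.K_d + self.K_d[np.ix_(p, p)]
        self._Kd_anti = self.K_d[p, :] + self.K_d[:, p]
        self._PtKx = self.K_x[pt, :]

    @property
    def n_cell_lines(self) -> int:
        return self.K_c.shape[0]

    @property
    def n_extended_pairs(self) -> int:
        return self.K_d.shape[0]

    @property
    def n_grid(self) -> int:
        return self.K_x.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        n = self.n_cell_lines * self.n_extended_pairs * self.n_grid
        return (n, n)

    def _apply_inner(self, W: np.ndarray) -> np.ndarray:
        """Apply the pair/grid part B to a (N_c, 2N_d, n) tensor."""
        if self.variant == "non_invariant":
            U = np.einsum("ab,cbx->cax", self.K_d, W)
            return np.einsum("xy,cay->cax", self.K_x, U)
        U1 = np.einsum("ab,cbx->cax", self._Kd_sym, W)
        V1 = np.einsum("xy,cay->cax", self.K_x, U1)
        U2 = np.einsum("ab,cbx->cax", self._Kd_anti, W)
        V2 = np.einsum("xy,cay->cax", self._PtKx, U2)
        return V1 + V2

    def matvec(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        n_total = self.shape[0]
        if w.shape != (n_total,):
            raise ValueError(f"vector has shape {w.shape}, expected ({n_total},)")
        W = w.reshape(self.n_cell_lines, self.n_extended_pairs, self.n_grid)
        V = self._apply_inner(W)
        out = np.einsum("cC,Cax->cax", self.K_c, V)
        return out.reshape(-1)

    def matmat(self, W: np.ndarray) -> np.ndarray:
        return np.stack([self.matvec(W[:, j]) for j in range(W.shape[1])], axis=1)

    def diagonal(self) -> np.ndarray:
        dc = np.diag(self.K_c)
        if self.variant == "non_invariant":
            dinner = np.multiply.outer(np.diag(self.K_d), np.diag(self.K_x))
        else:
            dinner = (
                np.multiply.outer(np.diag(self._Kd_sym), np.diag(self.K_x))
                + np.multiply.outer(np.diag(self._Kd_anti), np.diag(self._PtKx))
            )
        return np.multiply.outer(dc, dinner).reshape(-1)

    def dense(self, cap: int = 5000) -> np.ndarray:
        n_total = self.shape[0]
        if n_total > cap:
            raise ValueError(f"refusing to materialize {n_total} x {n_total} matrix (cap {cap})")
        if self.variant == "non_invariant":
            inner = np.kron(self.K_d, self.K_x)
        else:
            inner = np.kron(self._Kd_sym, self.K_x) + np.kron(self._Kd_anti, self._PtKx)
        return np.kron(self.K_c, inner)


def assemble_full_covariance(
    h: KernelHyperparams,
    perms: PermutationPair,
    grid: CommonGrid,
    variant: Variant = "invariant",
) -> CovarianceOperator:
    """Build the covariance operator from hyperparameters on a common grid."""
    K_x = squared_exponential_gram(grid.points, h.lengthscale)
    return CovarianceOperator(
        K_c=h.K_c, K_d=h.K_d, K_x=K_x, perms=perms, variant=variant
    )


def structured_matvec(operator: CovarianceOperator, w: np.ndarray) -> np.ndarray:
    """K @ w through Kronecker contractions only."""
    return operator.matvec(w)


def kd_total(K_d: np.ndarray) -> np.ndarray:
    """Average the 2x2 block structure of the extended pair covariance into a
    single N_d x N_d summary across both orderings: 0.25 (A + C + B + B^T)."""
    q = K_d.shape[0]
    if q % 2:
        raise ValueError("extended pair covariance must have even dimension")
    nd = q // 2
    A = K_d[:nd, :nd]
    C = K_d[nd:, nd:]
    B = K_d[:nd, nd:]
    return 0.25 * (A + C + B + B.T)


def kronecker_eigenvalues(*eigenvalue_sets: np.ndarray) -> np.ndarray:
    """All cross-products of factor eigenvalues (the spectrum of A (x) B (x) ...)."""
    out = np.asarray(eigenvalue_sets[0], dtype=float)
    for eigs in eigenvalue_sets[1:]:
        out = np.multiply.outer(out, np.asarray(eigs, dtype=float)).reshape(-1)
    return out


def _check_psd(name: str, eigs: np.ndarray, tol_scale: float = 1e-8) -> None:
    if eigs.size == 0:
        return
    bound = -tol_scale * max(float(eigs.max()), 1.0)
    if float(eigs.min()) < bound:
        raise ValueError(f"{name} is not PSD (min eigenvalue {eigs.min():.3e})")


def proposition1_eigenvalues(
    operator: CovarianceOperator,
    return_factors: bool = False,
    keep_product_order: bool = False,
):
    """Exact eigenvalue multiset of the assembled covariance, length N.

    For the invariant variant the positive part of the spectrum equals twice
    the positive eigenvalues of ``K_c (x) (P K_d + K_d P) (x) Pt K_x``; the
    rest are zeros.  All three factor matrices are symmetric here (the grid
    is reflection-closed and the input kernel isotropic, so ``Pt K_x`` is
    symmetric), so plain symmetric eigendecompositions apply.  For the
    non-invariant variant the spectrum is the plain Kronecker cross-product.

    With ``keep_product_order`` the array is indexed by the factor
    cross-product ``(i * n_d + j) * n_x + l`` (zeros in place of dropped
    non-positive products) instead of packing positives first; the multiset
    is identical.
    """
    N = operator.shape[0]
    wc, Uc = np.linalg.eigh(operator.K_c)
    _check_psd("K_c", wc)
    if operator.variant == "non_invariant":
        wd, Ud = np.linalg.eigh(operator.K_d)
        _check_psd("K_d", wd)
        wx, Ux = np.linalg.eigh(0.5 * (operator.K_x + operator.K_x.T))
        _check_psd("K_x", wx)
        eigs = kronecker_eigenvalues(wc, wd, wx)
        if return_factors:
            return eigs, (wc, Uc, wd, Ud, wx, Ux)
        return eigs

    Kd_anti = operator._Kd_anti
    PtKx = operator._PtKx
    if not np.allclose(PtKx, PtKx.T, atol=1e-10):
        raise ValueError("Pt K_x is not symmetric; grid/kernel assumptions violated")
    wd, Ud = np.linalg.eigh(Kd_anti)
    wx, Ux = np.linalg.eigh(0.5 * (PtKx + PtKx.T))
    products = kronecker_eigenvalues(wc, wd, wx)
    cutoff = EIG_ZERO_RTOL * max(float(np.abs(products).max(initial=0.0)), 1.0)
    if keep_product_order:
        eigs = np.where(products > cutoff, 2.0 * products, 0.0)
    else:
        positive = products[products > cutoff]
        eigs = np.zeros(N)
        eigs[: positive.size] = 2.0 * positive
    if return_factors:
        return eigs, (wc, Uc, wd, Ud, wx, Ux)
    return eigs
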