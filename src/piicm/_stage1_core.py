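"""Jitted hot loops for the per-experiment sampler.

The slice samplers evaluate the log posterior tens of thousands of times per
fit on arrays of ~100 rows, where numpy call overhead dominates; these
scalar loops are compiled with numba when available and fall back to the
vectorized numpy implementation otherwise.

Parameter vector layout (unconstrained u / constrained p):
  full mode:  l_a, s_a, m_a, l_b, s_b, m_b, b1, b2, amp, ls, sigma0, c0
  mono mode:  l_a, s_a, m_a, l_b, s_b, m_b, sigma0, c0
with sigmoid transforms at indices 0 and 3, identity at 2 and 5, exp
elsewhere.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

_LN10 = 2.302585092994046
_LOG_2PI = 1.8378770664093453
_VAR_FLOOR = 1e-6
_P0_CLIP = 1e-6


@njit(cache=True)
def _curve(x, l, s, m):
    t = _LN10 * s * (x - m)
    if t > 600.0:
        return l
    if t < -600.0:
        return 1.0
    return l + (1.0 - l) / (1.0 + np.exp(t))


@njit(cache=True)
def constrain_core(u, full):
    p = u.copy()
    for i in range(u.size):
        v = u[i]
        if i == 0 or i == 3:
            p[i] = 1.0 / (1.0 + np.exp(-v))
        elif i == 2 or i == 5:
            p[i] = v
        else:
            if v > 30.0:
                v = 30.0
            elif v < -30.0:
                v = -30.0
            p[i] = np.exp(v)
    return p


@njit(cache=True)
def loglik_core(p, x_a, x_b, y_all, row, z, na, nb, full):
    if full:
        b1, b2, sig0, c0 = p[6], p[7], p[10], p[11]
    else:
        b1, b2, sig0, c0 = 1.0, 1.0, p[6], p[7]
    la, sa, ma, lb, sb, mb = p[0], p[1], p[2], p[3], p[4], p[5]
    total = 0.0
    s2 = sig0 * sig0
    for i in range(na):
        h = _curve(x_a[i], la, sa, ma)
        var = s2 * (c0 + h) + _VAR_FLOOR
        r = y_all[i] - h
        total += np.log(var) + r * r / var
    for i in range(nb):
        h = _curve(x_b[i], lb, sb, mb)
        var = s2 * (c0 + h) + _VAR_FLOOR
        r = y_all[na + i] - h
        total += np.log(var) + r * r / var
    if full:
        for i in range(row.size):
            ha = _curve(x_a[na + i], la, sa, ma)
            hb = _curve(x_b[nb + i], lb, sb, mb)
            p0 = ha * hb
            if p0 < _P0_CLIP:
                p0 = _P0_CLIP
            elif p0 > 1.0 - _P0_CLIP:
                p0 = 1.0 - _P0_CLIP
            lo = np.log(p0 / (1.0 - p0))
            zz = z[row[i]]
            e1 = b1 * zz + lo
            if e1 > 500.0:
                e1 = 500.0
            elif e1 < -500.0:
                e1 = -500.0
            e2 = -b2 * zz - lo
            if e2 > 500.0:
                e2 = 500.0
            elif e2 < -500.0:
                e2 = -500.0
            f = p0 - p0 / (1.0 + np.exp(e1)) + (1.0 - p0) / (1.0 + np.exp(e2))
            var = s2 * (c0 + f) + _VAR_FLOOR
            r = y_all[na + nb + i] - f
            total += np.log(var) + r * r / var
    return -0.5 * (total + y_all.size * _LOG_2PI)


@njit(cache=True)
def logprior_core(u, gauss_idx, gauss_mu, gauss_sd, hn_idx, hn_scale,
                  l_idx, beta_a, beta_b):
    lp = 0.0
    for i in range(gauss_idx.size):
        d = (u[gauss_idx[i]] - gauss_mu[i]) / gauss_sd[i]
        lp -= 0.5 * d * d
    for i in range(hn_idx.size):
        v = u[hn_idx[i]]
        if v > 30.0:
            v = 30.0
        ev = np.exp(v)
        d = ev / hn_scale[i]
        lp += -0.5 * d * d + v
    for i in range(l_idx.size):
        v = u[l_idx[i]]
        # sigmoid + Beta(a, b) log-density + logit jacobian
        l = 1.0 / (1.0 + np.exp(-v))
        if l < 1e-12:
            l = 1e-12
        elif l > 1.0 - 1e-12:
            l = 1.0 - 1e-12
        lp += beta_a * np.log(l) + beta_b * np.log(1.0 - l)
    return lp


@njit(cache=True)
def logpost_core(u, Lu, x_a, x_b, y_all, row, na, nb, full,
                 gauss_idx, gauss_mu, gauss_sd, hn_idx, hn_scale,
                 l_idx, beta_a, beta_b):
    """Full unnormalized log posterior; ``Lu = chol(Matern) @ u_z`` so the
    latent field is ``exp(u[8]) * Lu`` (amplitude times whitened draw)."""
    p = constrain_core(u, full)
    z = p[8] * Lu if full else Lu
    lp = logprior_core(u, gauss_idx, gauss_mu, gauss_sd, hn_idx, hn_scale,
                       l_idx, beta_a, beta_b)
    return lp + loglik_core(p, x_a, x_b, y_all, row, z, na, nb, full)
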