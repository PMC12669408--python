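"""Small numerical helpers shared across modules."""

from __future__ import annotations

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=8)
def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights on [-1, 1], cached."""
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def weibull_linear_cumhaz(
    t: np.ndarray | float,
    lam: float,
    rho: float,
    a: np.ndarray | float,
    n_nodes: int = 40,
) -> np.ndarray | float:
    """``∫_0^t λρ s^{ρ-1} exp(a s) ds`` by fixed Gauss-Legendre quadrature.

    Vectorized over ``t`` (and broadcast against ``a``).  ``a = 0`` reduces to
    the Weibull cumulative hazard λ t^ρ, which is returned exactly.  The
    integrand is smooth for ρ ≥ 1; for ρ < 1 the integrable endpoint
    singularity is removed by substituting q = s^ρ.
    """
    t_arr = np.asarray(t, dtype=float)
    a_arr = np.asarray(a, dtype=float)
    scalar = t_arr.ndim == 0 and a_arr.ndim == 0
    t_arr, a_arr = np.broadcast_arrays(np.atleast_1d(t_arr), np.atleast_1d(a_arr))
    if np.any(t_arr < 0):
        raise ValueError("cumulative hazard requires t >= 0")
    if np.allclose(a_arr, 0.0):
        out = lam * t_arr**rho
        return float(out[0]) if scalar else out

    x, w = gauss_legendre(n_nodes)
    if rho >= 1.0:
        # nodes s = t/2 (x+1) on [0, t]
        s = 0.5 * t_arr[..., None] * (x + 1.0)
        integrand = lam * rho * s ** (rho - 1.0) * np.exp(a_arr[..., None] * s)
        out = 0.5 * t_arr * (integrand @ w)
    else:
        # q = s^rho removes the s^{rho-1} singularity at 0
        q_hi = t_arr**rho
        q = 0.5 * q_hi[..., None] * (x + 1.0)
        integrand = lam * np.exp(a_arr[..., None] * q ** (1.0 / rho))
        out = 0.5 * q_hi * (integrand @ w)
    return float(out[0]) if scalar else out


def fd_hessian(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    f0 = f(x)

    def shifted(i, hi, j=None, hj=0.0):
        z = x.copy()
        z[i] += hi
        if j is not None:
            z[j] += hj
        return f(z)

    for i in range(p):
        h = step * max(1.0, abs(x[i]))
        H[i, i] = (shifted(i, h) - 2.0 * f0 + shifted(i, -h)) / h**2
        for j in range(i + 1, p):
            hj = step * max(1.0, abs(x[j]))
            H[i, j] = H[j, i] = (
                shifted(i, h, j, hj)
                - shifted(i, h, j, -hj)
                - shifted(i, -h, j, hj)
                + shifted(i, -h, j, -hj)
            ) / (4.0 * h * hj)
    return H


def se_from_hessian(neg_hess: np.ndarray) -> np.ndarray | None:
    """Standard errors from the negative-loglik Hessian; None when not PD."""
    try:
        L = np.linalg.cholesky(neg_hess)
    except np.linalg.LinAlgError:
        return None
    inv = np.linalg.inv(neg_hess)
    diag = np.diag(inv)
    if np.any(diag <= 0):
        return None
    del L
    return np.sqrt(diag)
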