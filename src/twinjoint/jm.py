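"""Two-stage joint model for the longitudinal marker and survival outcome.

Stage 1 fits the twin mixed model to all marker data and freezes the fixed
effects (β̂0, β̂1), the subject-level BLUPs b̂_ij, and Σ̂_b.  Stage 2
maximizes a joint likelihood in which each subject's marker trajectory is
Ĝ_ij(t) + u_i with Ĝ_ij(t) = β̂0 + β̂1 t + b̂_ij0 (+ b̂_ij1 t) — the pair
effect u_i is deliberately *not* plugged in.  Per pair, the frailty v is
integrated in closed form against its updated gamma distribution (the same
delayed-entry correction as the LOCF fit, with the entry marker value
Ĝ_ij(entry) + u), and the single remaining integral over u ~ N(0, σ_u²) is
evaluated by Gauss-Hermite quadrature.  The longitudinal observations enter
through their Gaussian residual density y − Ĝ_ij(t) − u with variance σ_e²,
so the fit does not require the measurement error to be small.

Stage-1 uncertainty is not propagated into the stage-2 standard errors; this
is a known limitation of the two-stage construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from ._numeric import fd_hessian, se_from_hessian, weibull_linear_cumhaz
from .dataset import TwinDataset
from .frailty import WeibullParams
from .lmm import LMMFit

__all__ = ["JMParams", "JMFit", "Stage1", "stage1_from_lmm", "jm_loglik", "fit_jm"]

_THETA_LIMIT = 1e-6
_SIGMA_U2_LIMIT = 1e-10


@dataclass(frozen=True)
class JMParams:
    """Stage-2 parameters: survival side plus σ_u² and σ_e²."""

    alpha: float
    theta: float
    weibull: WeibullParams
    sigma_u2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.theta < 0 or self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance parameters must be nonnegative")


@dataclass
class JMFit:
    estimates: JMParams
    se: dict[str, float] | None
    loglik: float
    converged: bool
    quadrature_nodes: int
    message: str = ""


@dataclass
class Stage1:
    """Frozen first-stage quantities: fixed line and subject BLUP offsets."""

    beta0: float
    beta1: float
    b0: dict[tuple[int, int], float]
    b1: dict[tuple[int, int], float]

    def g_coeffs(self, key: tuple[int, int]) -> tuple[float, float]:
        """(intercept, slope) of Ĝ_ij(t) for one subject."""
        return self.beta0 + self.b0.get(key, 0.0), self.beta1 + self.b1.get(key, 0.0)


def stage1_from_lmm(fit: LMMFit) -> Stage1:
    b0 = {k: float(v[0]) for k, v in fit.blups.b.items()} if fit.params.q >= 1 else {}
    b1 = (
        {k: float(v[1]) for k, v in fit.blups.b.items()} if fit.params.q == 2 else {}
    )
    return Stage1(beta0=fit.params.beta0, beta1=fit.params.beta1, b0=b0, b1=b1)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _JMArrays:
    """Per-subject and per-pair static arrays for the stage-2 likelihood."""

    def __init__(self, dataset: TwinDataset, stage1: Stage1):
        recs = dataset.records
        n = len(recs)
        self.g0 = np.empty(n)
        self.g1 = np.empty(n)
        self.entry = np.empty(n)
        self.exit = np.empty(n)
        self.event = np.empty(n, dtype=int)
        pair_ids = []
        for i, r in enumerate(recs):
            self.g0[i], self.g1[i] = stage1.g_coeffs(r.key)
            self.entry[i] = r.entry_age
            self.exit[i] = r.exit_age
            self.event[i] = r.event
            pair_ids.append(r.pair_id)
        codes, uniques = pd.factorize(pd.Series(pair_ids), sort=False)
        self.pair = codes
        self.n_pairs = len(uniques)
        self.d_pair = np.bincount(codes, weights=self.event, minlength=self.n_pairs).astype(int)
        # longitudinal residual sufficient statistics per pair
        self.n_obs = np.zeros(self.n_pairs)
        self.sum_r = np.zeros(self.n_pairs)
        self.sum_r2 = np.zeros(self.n_pairs)
        for i, r in enumerate(recs):
            resid = r.obs_values - (self.g0[i] + self.g1[i] * r.obs_times)
            p = codes[i]
            self.n_obs[p] += resid.size
            self.sum_r[p] += resid.sum()
            self.sum_r2[p] += float(resid @ resid)
        self.total_obs = int(self.n_obs.sum())


def _jm_loglik_arrays(arr: _JMArrays, params: JMParams, n_nodes: int) -> float:
    alpha, theta = params.alpha, params.theta
    lam, rho = params.weibull.scale, params.weibull.shape
    su2, se2 = params.sigma_u2, params.sigma_e2
    if se2 <= 0:
        return -np.inf

    # per-subject cumulative-hazard integrals at u = 0 (linear marker exponent)
    a = alpha * arr.g1
    scale = np.exp(alpha * arr.g0)
    K_exit = scale * weibull_linear_cumhaz(arr.exit, lam, rho, a)
    K_entry = scale * weibull_linear_cumhaz(arr.entry, lam, rho, a)
    A0 = np.bincount(arr.pair, weights=K_exit - K_entry, minlength=arr.n_pairs)
    B0 = np.bincount(arr.pair, weights=K_entry, minlength=arr.n_pairs)
    ev = arr.event == 1
    # event log-hazard terms excluding the alpha*u part
    e_terms = np.zeros(len(arr.event))
    e_terms[ev] = (
        np.log(lam * rho)
        + (rho - 1.0) * np.log(arr.exit[ev])
        + alpha * (arr.g0[ev] + arr.g1[ev] * arr.exit[ev])
    )
    E0 = np.bincount(arr.pair, weights=e_terms, minlength=arr.n_pairs)

    # The prior N(0, σ_u²) times the longitudinal residual likelihood is an
    # exact Gaussian in u: N(μ_i, τ_i²) up to the marginal constant C_i (the
    # pair's marginal Gaussian likelihood with covariance σ_e² I + σ_u² J).
    # Gauss-Hermite nodes centered at (μ_i, τ_i) then only have to resolve
    # the smooth survival factor, which keeps the quadrature accurate even
    # when the marker data concentrate the u-posterior far below σ_u.
    n_i = arr.n_obs
    if su2 < _SIGMA_U2_LIMIT:
        tau2 = np.zeros(arr.n_pairs)
        mu = np.zeros(arr.n_pairs)
        log_C = -0.5 * (n_i * np.log(2.0 * np.pi * se2) + arr.sum_r2 / se2)
        u = mu[:, None]
        log_w = np.zeros(1)
    else:
        tau2 = 1.0 / (1.0 / su2 + n_i / se2)
        mu = tau2 * arr.sum_r / se2
        quad_form = arr.sum_r2 / se2 - su2 * arr.sum_r**2 / (se2 * (se2 + n_i * su2))
        log_C = -0.5 * (
            n_i * np.log(2.0 * np.pi)
            + (n_i - 1.0) * np.log(se2)
            + np.log(se2 + n_i * su2)
            + quad_form
        )
        x, w = np.polynomial.hermite.hermgauss(n_nodes)
        u = mu[:, None] + np.sqrt(2.0 * tau2)[:, None] * x[None, :]
        log_w = np.log(w) - 0.5 * np.log(np.pi)

    eu = np.exp(alpha * u)  # (n_pairs, m)
    A = A0[:, None] * eu
    B = B0[:, None] * eu
    d = arr.d_pair[:, None]
    if theta < _THETA_LIMIT:
        frailty = -A
    else:
        inv = 1.0 / theta
        frailty = (
            gammaln(inv + d)
            - gammaln(inv)
            + inv * np.log(inv + B)
            - (inv + d) * np.log(inv + B + A)
        )
    surv = E0[:, None] + alpha * d * u + frailty
    return float(np.sum(log_C + logsumexp(log_w[None, :] + surv, axis=1)))


def jm_loglik(
    params: JMParams,
    dataset: TwinDataset,
    stage1: Stage1,
    n_nodes: int = 20,
) -> float:
    """Stage-2 joint log-likelihood (Gauss-Hermite over the pair effect)."""
    if n_nodes < 5:
        raise ValueError("Gauss-Hermite node count must be at least 5")
    arr = _JMArrays(dataset, stage1)
    return _jm_loglik_arrays(arr, params, n_nodes)


def fit_jm(
    dataset: TwinDataset,
    stage1: Stage1,
    init: JMParams | None = None,
    n_nodes: int = 20,
    compute_se: bool = True,
    options: dict | None = None,
) -> JMFit:
    """Maximize the stage-2 joint likelihood over (α, θ, λ, ρ, σ_u², σ_e²).

    Positive parameters are optimized on the log scale.  Convergence failures
    and non-positive-definite Hessians are reported through the fit flags,
    never raised: with heavy measurement error a noticeable fraction of
    replications fails to produce standard errors.
    """
    if n_nodes < 5:
        raise ValueError("Gauss-Hermite node count must be at least 5")
    arr = _JMArrays(dataset, stage1)
    if arr.d_pair.sum() == 0:
        return JMFit(
            estimates=init
            or JMParams(0.0, 0.5, WeibullParams(1e-3, 1.0), 0.01, 0.01),
            se=None,
            loglik=np.nan,
            converged=False,
            quadrature_nodes=n_nodes,
            message="no events: survival parameters not identifiable",
        )

    def unpack(x: np.ndarray) -> JMParams:
        return JMParams(
            alpha=x[0],
            weibull=WeibullParams(scale=np.exp(x[1]), shape=np.exp(x[2])),
            theta=np.exp(x[3]),
            sigma_u2=np.exp(x[4]),
            sigma_e2=np.exp(x[5]),
        )

    def negloglik(x: np.ndarray) -> float:
        ll = _jm_loglik_arrays(arr, unpack(x), n_nodes)
        return -ll if np.isfinite(ll) else 1e12

    if init is None:
        exposure = float(np.sum(arr.exit - arr.entry))
        mean_r2 = arr.sum_r2.sum() / max(arr.total_obs, 1)
        init = JMParams(
            alpha=0.0,
            weibull=WeibullParams(scale=max(arr.d_pair.sum() / exposure, 1e-8), shape=1.0),
            theta=0.5,
            sigma_u2=max(mean_r2 / 2.0, 1e-4),
            sigma_e2=max(mean_r2 / 2.0, 1e-4),
        )
    x0 = np.array(
        [
            init.alpha,
            np.log(init.weibull.scale),
            np.log(init.weibull.shape),
            np.log(max(init.theta, 1e-8)),
            np.log(max(init.sigma_u2, 1e-8)),
            np.log(max(init.sigma_e2, 1e-8)),
        ]
    )
    bounds = [
        (None, None),
        (np.log(1e-12), None),
        (np.log(1e-3), np.log(1e3)),
        (np.log(1e-8), np.log(1e3)),
        (np.log(1e-9), np.log(1e3)),
        (np.log(1e-9), np.log(1e3)),
    ]
    opts = {"maxiter": 1000}
    if options:
        opts.update(options)
    res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds, options=opts)
    est = unpack(res.x)
    se = None
    hess_ok = True
    if compute_se:
        H = fd_hessian(negloglik, res.x, step=1e-5)
        se_work = se_from_hessian(H)
        hess_ok = se_work is not None
        if hess_ok:
            se = {
                "alpha": float(se_work[0]),
                "lambda": float(est.weibull.scale * se_work[1]),
                "rho": float(est.weibull.shape * se_work[2]),
                "theta": float(est.theta * se_work[3]),
                "sigma_u2": float(est.sigma_u2 * se_work[4]),
                "sigma_e2": float(est.sigma_e2 * se_work[5]),
                "log_lambda": float(se_work[1]),
                "log_rho": float(se_work[2]),
                "log_theta": float(se_work[3]),
            }
    return JMFit(
        estimates=est,
        se=se,
        loglik=float(-res.fun),
        converged=bool(res.success and hess_ok),
        quadrature_nodes=n_nodes,
        message=str(res.message),
    )
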