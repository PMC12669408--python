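"""Twin-structured linear mixed model for the longitudinal marker.

Model: y_ijk = β0 + β1 t_k + b_ij0 (+ b_ij1 t_k) + u_i + ε_ijk, with
subject-level random effects b_ij ~ N(0, Σ_b), a pair-shared intercept
u_i ~ N(0, σ_u²) and residuals ε ~ N(0, σ_e²).  Pairs are independent, so
the exact Gaussian marginal likelihood factorizes over pair blocks; the
fixed effects are profiled out by generalized least squares and variance
parameters are maximized on an unconstrained working scale (ML, not REML:
the downstream estimators plug in point predictions, and ML keeps the
two-stage likelihood interpretation coherent).

Empirical-Bayes BLUPs follow the standard identity b̂ = D Zᵀ V⁻¹ (y − Xβ̂)
per pair, with D the joint random-effect covariance and V the pair's
marginal covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .dataset import TwinDataset

__all__ = [
    "LMMParams",
    "BLUPSet",
    "LMMFit",
    "pair_marginal_cov",
    "fit_lmm",
    "compute_blups",
    "predict_marker",
    "rrc_refit",
]

_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class LMMParams:
    """Fixed effects and variance components of the twin mixed model.

    ``Sigma_b`` is 1x1 (random intercept) or 2x2 (intercept + slope); a 0x0
    matrix drops the subject-level effect entirely (pair effect only).
    """

    beta0: float
    beta1: float
    Sigma_b: np.ndarray
    sigma_u2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.Sigma_b, dtype=float))
        if S.size == 0:
            S = S.reshape(0, 0)
        object.__setattr__(self, "Sigma_b", S)
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")
        if S.size and np.any(np.linalg.eigvalsh(S) < -1e-10):
            raise ValueError("Sigma_b must be positive semidefinite")

    @property
    def q(self) -> int:
        return self.Sigma_b.shape[0]


@dataclass
class BLUPSet:
    """Posterior-mean random effects: b per subject, u per pair."""

    b: dict[tuple[int, int], np.ndarray]
    u: dict[int, float]


@dataclass
class LMMFit:
    params: LMMParams
    blups: BLUPSet
    loglik: float
    converged: bool
    slope: bool
    fixed_slope_dropped: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# cluster structure
# ---------------------------------------------------------------------------

def _clusters_from_long(long: pd.DataFrame) -> list[tuple[int, list[tuple[int, np.ndarray, np.ndarray]]]]:
    out = []
    for pid, g in long.groupby("pair_id", sort=True):
        members = []
        for tid, gg in g.groupby("twin_id", sort=True):
            gg = gg.sort_values("time")
            members.append((int(tid), gg["time"].to_numpy(float), gg["y"].to_numpy(float)))
        out.append((int(pid), members))
    return out


def _as_long(data: TwinDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, TwinDataset):
        return data.longitudinal_frame()
    return data


def _z_subject(times: np.ndarray, q: int) -> np.ndarray:
    if q == 0:
        return np.zeros((times.size, 0))
    if q == 1:
        return np.ones((times.size, 1))
    return np.column_stack([np.ones_like(times), times])


def pair_marginal_cov(
    times: list[np.ndarray] | tuple[np.ndarray, ...], params: LMMParams
) -> np.ndarray:
    """Marginal covariance of one pair's stacked observation vector.

    Cov = blockdiag_subjects(Z Σ_b Zᵀ) + σ_u² J + σ_e² I with Z = [1, t]
    columns matching the random-effect structure.
    """
    times = [np.asarray(t, dtype=float) for t in times]
    sizes = [t.size for t in times]
    n = int(sum(sizes))
    V = np.full((n, n), params.sigma_u2)
    V[np.diag_indices(n)] += params.sigma_e2
    off = 0
    for t in times:
        Z = _z_subject(t, params.q)
        V[off : off + t.size, off : off + t.size] += Z @ params.Sigma_b @ Z.T
        off += t.size
    return V


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

def _pack_variance(params: LMMParams) -> np.ndarray:
    if params.q == 2:
        L = np.linalg.cholesky(params.Sigma_b + 1e-12 * np.eye(2))
        head = [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]
    elif params.q == 1:
        head = [0.5 * np.log(max(params.Sigma_b[0, 0], _VAR_FLOOR))]
    else:
        head = []
    return np.r_[
        head,
        np.log(max(params.sigma_u2, _VAR_FLOOR)),
        np.log(max(params.sigma_e2, _VAR_FLOOR)),
    ]


def _unpack_variance(x: np.ndarray, q: int) -> tuple[np.ndarray, float, float]:
    if q == 2:
        L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        Sigma_b = L @ L.T
        k = 3
    elif q == 1:
        Sigma_b = np.array([[np.exp(2.0 * x[0])]])
        k = 1
    else:
        Sigma_b = np.empty((0, 0))
        k = 0
    return Sigma_b, float(np.exp(x[k])), float(np.exp(x[k + 1]))


class _BatchedClusters:
    """Clusters stacked by observation-size pattern for vectorized likelihoods.

    All clusters sharing the same per-subject observation counts have
    identically shaped covariance blocks, so their V matrices can be built
    and factorized as one stacked array.
    """

    def __init__(self, clusters):
        groups: dict[tuple[int, ...], list] = {}
        for pid, members in clusters:
            key = tuple(m[1].size for m in members)
            groups.setdefault(key, []).append((pid, members))
        self.batches = []
        self.n_total = 0
        for key, items in groups.items():
            n = int(sum(key))
            T = np.empty((len(items), n))
            Y = np.empty((len(items), n))
            for c, (_, members) in enumerate(items):
                T[c] = np.concatenate([m[1] for m in members])
                Y[c] = np.concatenate([m[2] for m in members])
            mask = np.zeros((n, n), dtype=bool)  # same-subject indicator
            off = 0
            for sz in key:
                mask[off : off + sz, off : off + sz] = True
                off += sz
            self.batches.append({"T": T, "Y": Y, "mask": mask, "n": n})
            self.n_total += len(items) * n


def _batched_V(batch: dict, Sigma_b: np.ndarray, su2: float, se2: float) -> np.ndarray:
    T, mask, n = batch["T"], batch["mask"], batch["n"]
    nc = T.shape[0]
    V = np.full((nc, n, n), su2)
    V[:, np.arange(n), np.arange(n)] += se2
    q = Sigma_b.shape[0]
    if q == 1:
        V += Sigma_b[0, 0] * mask
    elif q == 2:
        Tr = T[:, :, None]
        Tc = T[:, None, :]
        V += (Sigma_b[0, 0] + Sigma_b[0, 1] * (Tr + Tc) + Sigma_b[1, 1] * Tr * Tc) * mask
    return V


def _profile_nll(
    x: np.ndarray,
    batched: _BatchedClusters,
    q: int,
    fix_beta1: bool,
) -> tuple[float, np.ndarray]:
    """Negative profile loglik over variance params; returns (nll, beta_gls)."""
    Sigma_b, su2, se2 = _unpack_variance(x, q)
    p = 1 if fix_beta1 else 2
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for batch in batched.batches:
        T, Y = batch["T"], batch["Y"]
        V = _batched_V(batch, Sigma_b, su2, se2)
        X = np.ones((T.shape[0], batch["n"], p))
        if p == 2:
            X[:, :, 1] = T
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(p)
        rhs = np.concatenate([X, Y[:, :, None]], axis=2)
        half = np.linalg.solve(L, rhs)  # L^{-1} [X | y], batched
        hX, hy = half[:, :, :p], half[:, :, p]
        XtVX += np.einsum("cnp,cnq->pq", hX, hX)
        XtVy += np.einsum("cnp,cn->p", hX, hy)
        ytVy += float(np.einsum("cn,cn->", hy, hy))
        logdet += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros(p)
    rss = ytVy - beta @ XtVy
    nll = 0.5 * (logdet + rss + batched.n_total * np.log(2.0 * np.pi))
    return float(nll), beta


def fit_lmm(
    data: TwinDataset | pd.DataFrame,
    slope: bool = False,
    subject_intercept: bool = True,
    fix_beta1: bool = False,
) -> LMMFit:
    """ML fit of the twin mixed model on long-format marker data.

    ``slope`` adds a subject-level random slope; ``subject_intercept=False``
    drops the subject random effect entirely (pair effect only, the fallback
    for risk sets without repeated measures); ``fix_beta1`` removes the fixed
    time slope (needed when all observations share one time point).
    """
    long = _as_long(data)
    clusters = _clusters_from_long(long)
    if len(clusters) < 2:
        raise ValueError("need at least 2 pairs to fit the mixed model")
    all_times = long["time"].to_numpy(float)
    if not fix_beta1 and np.unique(all_times).size < 2:
        raise ValueError("fixed slope not identifiable: all observation times identical")
    if slope and not subject_intercept:
        raise ValueError("random slope requires the subject intercept")
    if slope:
        max_per_subject = long.groupby(["pair_id", "twin_id"])["time"].nunique().max()
        if max_per_subject < 2:
            raise ValueError(
                "random slope not identifiable: no subject has repeated measurements"
            )
    q = 2 if slope else (1 if subject_intercept else 0)

    y_var = float(np.var(long["y"].to_numpy(float))) or 1.0
    init = LMMParams(
        beta0=0.0,
        beta1=0.0,
        Sigma_b=(y_var / 4.0) * np.eye(q) if q else np.empty((0, 0)),
        sigma_u2=y_var / 4.0,
        sigma_e2=y_var / 2.0,
    )
    x0 = _pack_variance(init)
    batched = _BatchedClusters(clusters)

    def obj(x: np.ndarray) -> float:
        return _profile_nll(x, batched, q, fix_beta1)[0]

    res = minimize(obj, x0, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    nll, beta = _profile_nll(res.x, batched, q, fix_beta1)
    Sigma_b, su2, se2 = _unpack_variance(res.x, q)
    params = LMMParams(
        beta0=float(beta[0]),
        beta1=0.0 if fix_beta1 else float(beta[1]),
        Sigma_b=Sigma_b,
        sigma_u2=su2,
        sigma_e2=se2,
    )
    fit = LMMFit(
        params=params,
        blups=BLUPSet(b={}, u={}),
        loglik=float(-nll),
        converged=bool(res.success),
        slope=slope,
        fixed_slope_dropped=fix_beta1,
        message=str(res.message),
    )
    fit.blups = compute_blups(fit, long)
    return fit


def compute_blups(fit: LMMFit, data: TwinDataset | pd.DataFrame) -> BLUPSet:
    """Empirical-Bayes random-effect predictions for every subject and pair."""
    long = _as_long(data)
    params = fit.params
    q = params.q
    b: dict[tuple[int, int], np.ndarray] = {}
    u: dict[int, float] = {}
    for pid, members in _clusters_from_long(long):
        tt = [m[1] for m in members]
        y = np.concatenate([m[2] for m in members])
        t_all = np.concatenate(tt)
        resid = y - params.beta0 - params.beta1 * t_all
        V = pair_marginal_cov(tt, params)
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular marginal covariance for pair {pid}") from exc
        Vi_r = cho_solve((c, low), resid)
        # stacked random-effect design: per-subject blocks then the pair column
        m = len(members)
        Z = np.zeros((y.size, q * m + 1))
        off = 0
        for s, t in enumerate(tt):
            Z[off : off + t.size, q * s : q * (s + 1)] = _z_subject(t, q)
            off += t.size
        Z[:, -1] = 1.0
        D = np.zeros((q * m + 1, q * m + 1))
        for s in range(m):
            D[q * s : q * (s + 1), q * s : q * (s + 1)] = params.Sigma_b
        D[-1, -1] = params.sigma_u2
        blup = D @ (Z.T @ Vi_r)
        for s, (tid, _, _) in enumerate(members):
            b[(pid, tid)] = blup[q * s : q * (s + 1)].copy()
        u[pid] = float(blup[-1])
    return BLUPSet(b=b, u=u)


def subject_in_fit(fit: LMMFit, pair_id: int, twin_id: int) -> bool:
    """Whether a subject contributed observations to a fit (has BLUPs)."""
    if fit.params.q == 0:
        return pair_id in fit.blups.u
    return (pair_id, twin_id) in fit.blups.b


def predict_marker(
    fit: LMMFit,
    pair_id: int,
    twin_id: int,
    times: np.ndarray,
    include_pair_effect: bool = True,
    strict: bool = True,
) -> np.ndarray:
    """Predicted marker trajectory M̂ (with û) or Ĝ (without) at given times.

    With ``strict=False`` a subject absent from the fitted data falls back to
    whatever effects are available (the pair's û, else the fixed line alone)
    instead of raising.
    """
    times = np.asarray(times, dtype=float)
    params = fit.params
    key = (pair_id, twin_id)
    if strict and params.q > 0 and key not in fit.blups.b:
        raise KeyError(f"subject {key} not present in the fitted data")
    pred = params.beta0 + params.beta1 * times
    if params.q >= 1 and key in fit.blups.b:
        bvec = fit.blups.b[key]
        pred = pred + bvec[0]
        if params.q == 2:
            pred = pred + bvec[1] * times
    if include_pair_effect:
        if pair_id in fit.blups.u:
            pred = pred + fit.blups.u[pair_id]
        elif strict:
            raise KeyError(f"pair {pair_id} not present in the fitted data")
    return pred


def rrc_refit(
    dataset: TwinDataset,
    risk_time: float,
    slope: bool = False,
    min_pairs: int = 10,
) -> LMMFit | None:
    """Mixed-model refit on the risk set at one age.

    Uses subjects who entered by ``risk_time`` and are still event-free and
    uncensored there, with only their marker observations taken at or before
    that age (no look-ahead).  Structure is reduced stepwise when the risk
    set cannot identify it: random slope → subject intercept → fixed slope.
    Returns None when fewer than ``min_pairs`` pairs remain (the caller
    reuses the nearest earlier refit).
    """
    at_risk = [
        r for r in dataset.records if r.entry_age <= risk_time <= r.exit_age
    ]
    if not at_risk:
        raise ValueError(f"empty risk set at age {risk_time}")
    rows = {"pair_id": [], "twin_id": [], "time": [], "y": []}
    for r in at_risk:
        keep = r.obs_times <= risk_time + 1e-12
        rows["pair_id"].extend([r.pair_id] * int(keep.sum()))
        rows["twin_id"].extend([r.twin_id] * int(keep.sum()))
        rows["time"].extend(r.obs_times[keep].tolist())
        rows["y"].extend(r.obs_values[keep].tolist())
    long = pd.DataFrame(rows)
    if long["pair_id"].nunique() < min_pairs:
        return None

    attempts = (
        [dict(slope=True)] if slope else []
    ) + [dict(slope=False), dict(slope=False, subject_intercept=False)]
    last_exc: Exception | None = None
    for kw in attempts:
        for fix in (False, True):
            try:
                return fit_lmm(long, fix_beta1=fix, **kw)
            except ValueError as exc:
                last_exc = exc
                continue
    raise ValueError(f"no identifiable mixed-model structure at age {risk_time}: {last_exc}")
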