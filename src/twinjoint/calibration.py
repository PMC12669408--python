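"""Start-stop table construction: LOCF and regression-calibrated covariates.

LOCF carries each observed marker value forward until the next observation
(or the exit age).  The calibration builders replace the marker by mixed-model
predictions on a dense age grid: ORC predicts from one model fitted to all
data; RRC predicts from risk-set refits, using for each interval the refit at
the latest event time not after the interval start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import TwinDataset
from .frailty import StartStopTable
from .lmm import LMMFit, fit_lmm, predict_marker, rrc_refit, subject_in_fit

__all__ = [
    "DenseGrid",
    "make_dense_grid",
    "build_locf_startstop",
    "build_calibrated_startstop",
    "RRCSchedule",
    "build_rrc_schedule",
]


@dataclass(frozen=True)
class DenseGrid:
    """Ascending age grid spanning the observed range of a dataset."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("grid must be strictly ascending with >= 2 points")
        object.__setattr__(self, "times", t)


def make_dense_grid(dataset: TwinDataset, n_points: int = 100) -> DenseGrid:
    """Equally spaced grid over [min entry, max exit]."""
    lo = min(r.entry_age for r in dataset.records)
    hi = max(r.exit_age for r in dataset.records)
    return DenseGrid(times=np.linspace(lo, hi, n_points))


def build_locf_startstop(dataset: TwinDataset) -> StartStopTable:
    """One row per inter-observation interval, last row ending at exit.

    The marker value in force on [t_k, t_{k+1}) is the observation y_k; the
    final row carries the last observed value to the exit age and holds the
    event flag.  Total exposure equals Σ (exit − entry) exactly.
    """
    rows = {"pair_id": [], "twin_id": [], "start": [], "stop": [], "status": [], "z": []}
    for r in dataset.records:
        bounds = np.r_[r.obs_times, r.exit_age]
        keep = bounds[1:] > bounds[:-1]  # drop zero-length final row if obs at exit
        n = int(keep.sum())
        rows["pair_id"].extend([r.pair_id] * n)
        rows["twin_id"].extend([r.twin_id] * n)
        rows["start"].extend(bounds[:-1][keep].tolist())
        rows["stop"].extend(bounds[1:][keep].tolist())
        status = np.zeros(n, dtype=int)
        status[-1] = r.event
        rows["status"].extend(status.tolist())
        rows["z"].extend(r.obs_values[keep].tolist())
    return StartStopTable(df=pd.DataFrame(rows))


@dataclass
class RRCSchedule:
    """Risk-set refits of the marker model, one per event time.

    ``times`` are the ascending event ages at which refits exist; ``fits``
    aligns with them.  ``log`` records fallbacks (structure reductions and
    reuse of earlier refits for thin risk sets).
    """

    times: np.ndarray
    fits: list[LMMFit]
    log: list[str] = field(default_factory=list)

    def fit_at(self, t: float) -> LMMFit:
        """The refit at the latest event time ≤ t (earliest refit before any)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.fits[max(idx, 0)]


def build_rrc_schedule(
    dataset: TwinDataset,
    slope: bool = False,
    min_pairs: int = 10,
    refit_times: np.ndarray | None = None,
) -> RRCSchedule:
    """Fit the marker mixed model on the risk set at each event time.

    Refit times default to the sorted unique event ages in the dataset.  At
    each time only subjects at risk (entered, event-free, uncensored) and
    their observations up to that time are used; risk sets with fewer than
    ``min_pairs`` complete pairs reuse the nearest earlier refit.
    """
    if refit_times is None:
        refit_times = np.unique(
            [r.exit_age for r in dataset.records if r.event == 1]
        )
    refit_times = np.asarray(refit_times, dtype=float)
    if refit_times.size == 0:
        raise ValueError("no event times to build an RRC schedule from")
    fits: list[LMMFit] = []
    log: list[str] = []
    for t in refit_times:
        try:
            fit = rrc_refit(dataset, t, slope=slope, min_pairs=min_pairs)
            if fit is None:
                raise ValueError("risk set below min_pairs")
            fits.append(fit)
        except ValueError as exc:
            if not fits:
                raise ValueError(f"no usable risk set at the first event time {t}: {exc}")
            log.append(f"t={t:.4g}: reusing earlier refit ({exc})")
            fits.append(fits[-1])
    return RRCSchedule(times=refit_times, fits=fits, log=log)


def build_calibrated_startstop(
    dataset: TwinDataset,
    fit: LMMFit | RRCSchedule,
    grid: DenseGrid,
    method: str = "orc",
) -> StartStopTable:
    """Start-stop table with mixed-model marker predictions on a dense grid.

    Each subject's at-risk window [entry, exit] is cut at the interior grid
    points; the marker value on each interval is the BLUP-based prediction
    M̂_ij (pair effect included) at the interval start.  ORC predicts from a
    single all-data fit; RRC from the schedule's refit at the latest event
    time not after the interval start.
    """
    if method not in ("orc", "rrc"):
        raise ValueError(f"unknown calibration method {method!r}")
    if method == "rrc" and not isinstance(fit, RRCSchedule):
        raise TypeError("rrc requires an RRCSchedule")
    rows = {"pair_id": [], "twin_id": [], "start": [], "stop": [], "status": [], "z": []}
    g = grid.times
    for r in dataset.records:
        interior = g[(g > r.entry_age) & (g < r.exit_age)]
        bounds = np.r_[r.entry_age, interior, r.exit_age]
        starts = bounds[:-1]
        if starts.size == 0:
            raise ValueError(f"subject ({r.pair_id}, {r.twin_id}) has an empty grid window")
        if method == "orc":
            z = predict_marker(fit, r.pair_id, r.twin_id, starts, include_pair_effect=True)
        else:
            # refits containing this subject (it may have entered after early
            # event times, or never been at risk at any event time)
            member_idx = [
                k for k, f in enumerate(fit.fits)
                if subject_in_fit(f, r.pair_id, r.twin_id)
            ]
            z = np.empty(starts.size)
            for m, s in enumerate(starts):
                idx = max(int(np.searchsorted(fit.times, s, side="right")) - 1, 0)
                if not subject_in_fit(fit.fits[idx], r.pair_id, r.twin_id) and member_idx:
                    idx = min(member_idx, key=lambda k: abs(fit.times[k] - s))
                z[m] = predict_marker(
                    fit.fits[idx], r.pair_id, r.twin_id, np.array([s]),
                    include_pair_effect=True, strict=False,
                )[0]
        n = starts.size
        rows["pair_id"].extend([r.pair_id] * n)
        rows["twin_id"].extend([r.twin_id] * n)
        rows["start"].extend(starts.tolist())
        rows["stop"].extend(bounds[1:].tolist())
        status = np.zeros(n, dtype=int)
        status[-1] = r.event
        rows["status"].extend(status.tolist())
        rows["z"].extend(np.asarray(z, dtype=float).tolist())
    return StartStopTable(df=pd.DataFrame(rows))
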