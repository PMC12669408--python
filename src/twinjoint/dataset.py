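"""Clustered study data: per-subject survival records plus longitudinal marker observations.

A :class:`TwinDataset` holds one :class:`SubjectRecord` per twin.  Survival
times are on the age scale; a subject enters observation at ``entry_age``
(delayed entry / left truncation) and leaves at ``exit_age`` with an event
indicator.  Marker observations are taken on a subject-specific grid whose
first point is the entry age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimulationConfig

__all__ = ["SubjectRecord", "TwinDataset"]


@dataclass
class SubjectRecord:
    """One twin: survival window plus the marker observations within it."""

    pair_id: int
    twin_id: int
    entry_age: float
    exit_age: float
    event: int
    obs_times: np.ndarray
    obs_values: np.ndarray

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.obs_values = np.asarray(self.obs_values, dtype=float)
        if self.twin_id not in (1, 2):
            raise ValueError(f"twin_id must be 1 or 2, got {self.twin_id}")
        if self.entry_age < 0:
            raise ValueError("entry_age must be nonnegative")
        if not self.exit_age > self.entry_age:
            raise ValueError(
                f"exit_age ({self.exit_age}) must exceed entry_age ({self.entry_age})"
            )
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")
        if self.obs_times.size != self.obs_values.size:
            raise ValueError("obs_times and obs_values must align")
        if self.obs_times.size == 0:
            raise ValueError("subject must have at least one marker observation")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError("obs_times must be strictly increasing")
        if not np.isclose(self.obs_times[0], self.entry_age):
            raise ValueError("first observation time must equal entry_age")
        if self.obs_times[-1] > self.exit_age + 1e-12:
            raise ValueError("observation times must not exceed exit_age")

    @property
    def key(self) -> tuple[int, int]:
        return (self.pair_id, self.twin_id)


@dataclass
class TwinDataset:
    """A collection of subject records, restricted to complete twin pairs by default."""

    records: list[SubjectRecord]
    complete_pairs_only: bool = True
    truth: "SimulationConfig | None" = None

    def __post_init__(self) -> None:
        if self.complete_pairs_only:
            counts: dict[int, int] = {}
            for r in self.records:
                counts[r.pair_id] = counts.get(r.pair_id, 0) + 1
            bad = [p for p, c in counts.items() if c != 2]
            if bad:
                raise ValueError(
                    f"complete_pairs_only set but pairs {bad[:5]} do not appear exactly twice"
                )

    # ---- basic summaries -------------------------------------------------
    @property
    def pair_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for r in self.records:
            seen.setdefault(r.pair_id, None)
        return list(seen)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_subjects(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.records)

    def pairs(self) -> Iterable[tuple[int, list[SubjectRecord]]]:
        by_pair: dict[int, list[SubjectRecord]] = {}
        for r in self.records:
            by_pair.setdefault(r.pair_id, []).append(r)
        for pid, recs in by_pair.items():
            yield pid, sorted(recs, key=lambda r: r.twin_id)

    def subject(self, pair_id: int, twin_id: int) -> SubjectRecord:
        for r in self.records:
            if r.pair_id == pair_id and r.twin_id == twin_id:
                return r
        raise KeyError(f"no subject ({pair_id}, {twin_id}) in dataset")

    # ---- frame conversion ------------------------------------------------
    def survival_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": [r.pair_id for r in self.records],
                "twin_id": [r.twin_id for r in self.records],
                "entry_age": [r.entry_age for r in self.records],
                "exit_age": [r.exit_age for r in self.records],
                "event": [r.event for r in self.records],
            }
        )

    def longitudinal_frame(self) -> pd.DataFrame:
        pid, tid, tt, yy = [], [], [], []
        for r in self.records:
            pid.extend([r.pair_id] * r.obs_times.size)
            tid.extend([r.twin_id] * r.obs_times.size)
            tt.extend(r.obs_times.tolist())
            yy.extend(r.obs_values.tolist())
        return pd.DataFrame({"pair_id": pid, "twin_id": tid, "time": tt, "y": yy})

    @classmethod
    def from_frames(
        cls,
        survival: pd.DataFrame,
        longitudinal: pd.DataFrame,
        complete_pairs_only: bool = True,
    ) -> "TwinDataset":
        long_groups = {
            key: g.sort_values("time") for key, g in longitudinal.groupby(["pair_id", "twin_id"])
        }
        records = []
        for row in survival.itertuples(index=False):
            g = long_groups.get((row.pair_id, row.twin_id))
            if g is None:
                raise ValueError(
                    f"subject ({row.pair_id}, {row.twin_id}) has no marker observations"
                )
            records.append(
                SubjectRecord(
                    pair_id=int(row.pair_id),
                    twin_id=int(row.twin_id),
                    entry_age=float(row.entry_age),
                    exit_age=float(row.exit_age),
                    event=int(row.event),
                    obs_times=g["time"].to_numpy(),
                    obs_values=g["y"].to_numpy(),
                )
            )
        return cls(records=records, complete_pairs_only=complete_pairs_only)
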