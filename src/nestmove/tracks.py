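"""Array container for one regularized track, as consumed by the sampler.

A :class:`TrackData` holds everything the likelihood needs about one
contiguous track segment on the 6-hour grid: fix positions with their
interval index and interpolation fraction j, and dive depths with their
interval index, all as flat numpy arrays grouped (sorted) by interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model import ArgosErrorTable
    from .preprocess import RegularTrack

INTERVAL_HOURS = 6.0


@dataclass
class TrackData:
    """One track segment, regularized onto the 6-h grid.

    ``fix_interval`` and ``dive_interval`` are 1-based interval indices in
    ``1..n_intervals``; a fix in interval t interpolates grid locations
    ``t-1`` and ``t``.  Arrays must be sorted by interval (fixes and dives
    each in time order).
    """

    animal: str
    track_id: int
    t0: np.datetime64
    n_intervals: int
    fix_interval: np.ndarray
    fix_j: np.ndarray
    fix_x: np.ndarray
    fix_y: np.ndarray
    fix_sd: np.ndarray
    dive_interval: np.ndarray
    dive_depth: np.ndarray
    dive_time: np.ndarray = field(default=None)  # type: ignore[assignment]
    interval_hours: float = INTERVAL_HOURS

    def __post_init__(self) -> None:
        self.fix_interval = np.asarray(self.fix_interval, dtype=np.int64)
        self.dive_interval = np.asarray(self.dive_interval, dtype=np.int64)
        for name in ("fix_j", "fix_x", "fix_y", "fix_sd", "dive_depth"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.dive_time is None:
            self.dive_time = np.full(self.dive_depth.shape, np.datetime64("NaT"),
                                     dtype="datetime64[s]")
        T = self.n_intervals
        if T < 1:
            raise ValueError("a track needs at least one interval")
        for arr, label in ((self.fix_interval, "fix"), (self.dive_interval, "dive")):
            if arr.size and (arr.min() < 1 or arr.max() > T):
                raise ValueError(f"{label} interval index outside 1..{T}")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{label}s must be sorted by interval")
        if self.fix_j.size and (self.fix_j.min() < 0 or self.fix_j.max() > 1):
            raise ValueError("interpolation fractions must lie in [0, 1]")

    @property
    def n_fixes(self) -> int:
        return int(self.fix_interval.size)

    @property
    def n_dives(self) -> int:
        return int(self.dive_interval.size)

    @property
    def fix_offsets(self) -> np.ndarray:
        """(T+1,) offsets such that interval t's fixes are offs[t-1]:offs[t]."""
        return np.searchsorted(self.fix_interval, np.arange(self.n_intervals + 1) + 1,
                               side="left").astype(np.int64)

    @property
    def dive_offsets(self) -> np.ndarray:
        return np.searchsorted(self.dive_interval, np.arange(self.n_intervals + 1) + 1,
                               side="left").astype(np.int64)

    @property
    def grid_times(self) -> np.ndarray:
        """(T+1,) timestamps of the grid points."""
        step = np.timedelta64(int(self.interval_hours * 3600), "s")
        return (np.datetime64(self.t0, "s")
                + np.arange(self.n_intervals + 1) * step)

    def initial_locations(self) -> np.ndarray:
        """Deterministic starting Y: fixes linearly interpolated to the grid.

        Fix times (as grid coordinates t-1+j) are interpolated per coordinate;
        grid points outside the observed fix span take the nearest fix value.
        """
        if self.n_fixes == 0:
            return np.zeros((self.n_intervals + 1, 2))
        ft = self.fix_interval - 1 + self.fix_j
        order = np.argsort(ft, kind="stable")
        ft = ft[order]
        grid = np.arange(self.n_intervals + 1, dtype=float)
        return np.column_stack([
            np.interp(grid, ft, self.fix_x[order]),
            np.interp(grid, ft, self.fix_y[order]),
        ])

    @classmethod
    def from_regular(cls, reg: "RegularTrack",
                     error_table: "ArgosErrorTable") -> "TrackData":
        """Attach per-class sds from the error table to a preprocessed track."""
        return cls(
            animal=reg.animal, track_id=reg.track_id, t0=reg.t0,
            n_intervals=reg.n_intervals,
            fix_interval=reg.fix_interval, fix_j=reg.fix_j,
            fix_x=reg.fix_x, fix_y=reg.fix_y,
            fix_sd=np.asarray(error_table.sd(list(reg.fix_class)), dtype=float),
            dive_interval=reg.dive_interval, dive_depth=reg.dive_depth,
            dive_time=reg.dive_time, interval_hours=reg.interval_hours,
        )
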