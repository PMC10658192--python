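"""Per-embryo developmental time series and cohort aggregation.

Embryos develop at different absolute rates, so all cross-individual and
cross-species comparison happens on *relative developmental time*: hours
are rescaled to [0, 1] between the 4-cell stage (0) and hatching (1).
Total energy is additionally min-max normalised within each individual
so that cohort means describe the shape, not the scale, of activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .ept_core import EPTSpectrum


@dataclass
class DevTimeSeries:
    """One embryo's developmental sequence of spectra and total energy.

    ``events`` holds relative event times in [0, 1]; ``timepoints_h`` are
    absolute hours since the 4-cell stage, strictly increasing.
    """

    embryo_id: str
    species: str
    timepoints_h: np.ndarray
    total_energy: np.ndarray
    events: Dict[str, float]
    spectra: Optional[List[EPTSpectrum]] = None
    t0_h: float = 0.0
    t_hatch_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.total_energy = np.asarray(self.total_energy, dtype=float)
        if len(self.timepoints_h) != len(self.total_energy):
            raise ValueError("timepoints and total_energy must align")
        if len(self.timepoints_h) > 1 and not np.all(np.diff(self.timepoints_h) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.spectra is not None and len(self.spectra) != len(self.timepoints_h):
            raise ValueError("spectra must align with timepoints")

    @property
    def rel_times(self) -> np.ndarray:
        if self.t_hatch_h is None:
            raise ValueError("t_hatch_h unset; cannot compute relative time")
        return np.array(
            [to_relative_time(t, self.t0_h, self.t_hatch_h) for t in self.timepoints_h]
        )


@dataclass
class CohortSeries:
    """Species-level mean ± sd of a gridded quantity over relative time."""

    species: str
    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    median_events: Dict[str, float]


def to_relative_time(time_h: float, t0_h: float, t_hatch_h: float) -> float:
    """Map absolute hours onto relative developmental time in [0, 1]."""
    if not t0_h < t_hatch_h:
        raise ValueError(f"need t0 < hatch, got {t0_h} >= {t_hatch_h}")
    if not (t0_h <= time_h <= t_hatch_h):
        raise ValueError(
            f"time {time_h} h outside developmental window [{t0_h}, {t_hatch_h}] h"
        )
    return (time_h - t0_h) / (t_hatch_h - t0_h)


def normalize_individual(values: Sequence[float]) -> np.ndarray:
    """Min-max normalise one individual's series to [0, 1]."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to normalise")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series cannot be min-max normalised")
    return (x - lo) / (hi - lo)


def resample_to_grid(
    rel_times: Sequence[float],
    values: np.ndarray,
    grid_size: int = 101,
) -> np.ndarray:
    """Linearly interpolate a series onto ``grid_size`` evenly spaced
    relative times in [0, 1].

    No extrapolation: grid points before the first (after the last)
    observation take the first (last) observed value.  ``values`` may be
    1-D (total energy) or 2-D with one row per timepoint (spectra/bands).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    t = np.asarray(rel_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 timepoints to resample")
    grid = np.linspace(0.0, 1.0, grid_size)
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(grid, t, values)
    return np.column_stack([np.interp(grid, t, values[:, j]) for j in range(values.shape[1])])


def grid_points(grid_size: int = 101) -> np.ndarray:
    return np.linspace(0.0, 1.0, grid_size)


def species_mean_series(
    series_list: Sequence[DevTimeSeries],
    gridded: Sequence[np.ndarray],
    grid: np.ndarray,
) -> CohortSeries:
    """Pointwise mean ± sd over a cohort of same-grid series.

    Event times are summarised by their cohort median (matching how they
    are drawn on time-series figures); sd uses the n−1 denominator and is
    reported as 0 with a warning for a single-member cohort.
    """
    if len(series_list) == 0:
        raise ValueError("empty cohort")
    if len(series_list) != len(gridded):
        raise ValueError("series_list and gridded must align")
    stack = np.vstack([np.asarray(g, dtype=float) for g in gridded])
    if stack.shape[1] != len(grid):
        raise ValueError("gridded series do not match the grid")
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        warnings.warn("single-member cohort: sd reported as 0", stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = stack.std(axis=0, ddof=1)
    species = series_list[0].species
    event_names = set()
    for s in series_list:
        event_names.update(s.events)
    median_events = {
        ev: float(np.median([s.events[ev] for s in series_list if ev in s.events]))
        for ev in sorted(event_names)
    }
    return CohortSeries(
        species=species,
        grid=np.asarray(grid, dtype=float),
        mean=mean,
        sd=sd,
        n=np.full(len(grid), stack.shape[0]),
        median_events=median_events,
    )
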