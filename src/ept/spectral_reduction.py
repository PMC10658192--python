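"""Frequency-band binning, normalisation and PCA trajectory embedding.

Native spectral grids differ between species recorded at different frame
rates, so spectra are compared only after averaging into a fixed scheme
of 0.1 Hz bands spanning 0.03–6.0 Hz (60 bands by default).  Band
energies are log transformed and min-max scaled per band across
developmental time, then a centred (unscaled) PCA embeds the time × band
matrix so that developmental trajectories can be traced in component
space and developmental events marked along them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .ept_core import EPTSpectrum


@dataclass(frozen=True)
class BandScheme:
    """Contiguous half-open frequency bands [edge_k, edge_{k+1})."""

    f_low_hz: float = 0.03
    f_high_hz: float = 6.0
    width_hz: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.f_low_hz < self.f_high_hz):
            raise ValueError("need 0 < f_low < f_high")
        if self.width_hz <= 0:
            raise ValueError("width_hz must be positive")

    @property
    def n_bands(self) -> int:
        # enough width_hz intervals to cover [f_low, f_high]; the top edge
        # may overshoot f_high so the upper limit itself is included
        span = self.f_high_hz - self.f_low_hz
        n = math.ceil(span / self.width_hz - 1e-9)
        if self.f_low_hz + n * self.width_hz <= self.f_high_hz - 1e-12:
            n += 1
        return n

    @property
    def edges(self) -> np.ndarray:
        return self.f_low_hz + self.width_hz * np.arange(self.n_bands + 1)

    @property
    def centres(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2


def bin_spectrum(spec: EPTSpectrum, scheme: BandScheme = BandScheme()) -> np.ndarray:
    """Mean native-grid energy within each band of ``scheme``.

    Band membership is half-open: a native frequency f belongs to band k
    iff edge_k <= f < edge_{k+1}.  An empty band is an error (it cannot
    occur with the full-record default grid, where every 0.1 Hz band
    holds three native k/30 Hz frequencies).
    """
    edges = scheme.edges
    f = spec.freqs_hz
    in_range = (f >= edges[0]) & (f < edges[-1])
    if not in_range.any():
        raise ValueError(
            f"spectrum ({f.min():.3g}-{f.max():.3g} Hz) lies entirely outside "
            f"the band scheme ({edges[0]:.3g}-{edges[-1]:.3g} Hz)"
        )
    idx = np.digitize(f[in_range], edges) - 1
    energy = spec.energy[in_range]
    out = np.empty(scheme.n_bands)
    for k in range(scheme.n_bands):
        sel = idx == k
        if not sel.any():
            raise ValueError(f"band {k} ({edges[k]:.3g}-{edges[k+1]:.3g} Hz) is empty")
        out[k] = energy[sel].mean()
    return out


def transform_and_normalize(
    matrix: np.ndarray, eps: float = 1e-12, log_first: bool = True
) -> np.ndarray:
    """Log transform then per-band min-max scale a time × band matrix.

    ``eps`` offsets the natural log so silent bands stay finite.  With
    ``log_first=False`` the scaling precedes the log (both orders are
    defensible readings of the source analyses; log-first is default).
    A band constant over all time carries no trajectory information and
    is set to 0 with a warning.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D time x band matrix")
    if (m < 0).any():
        raise ValueError("band energies must be non-negative")

    def _scale(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        for j in range(x.shape[1]):
            col = x[:, j]
            lo, hi = col.min(), col.max()
            if hi == lo:
                warnings.warn(f"band column {j} constant over time; set to 0", stacklevel=3)
                out[:, j] = 0.0
            else:
                out[:, j] = (col - lo) / (hi - lo)
        return out

    if log_first:
        return _scale(np.log(m + eps))
    return np.log(_scale(m) + eps)  # scaled values in [0,1]; eps keeps log finite


@dataclass
class PCAResult:
    scores: np.ndarray       # time point x component
    loadings: np.ndarray     # band x component, unit norm
    var_fraction: np.ndarray
    mean: np.ndarray


def pca_embed(matrix: np.ndarray, n_components: int = 2) -> PCAResult:
    """Centred (unscaled) PCA of a time × band matrix via SVD.

    Columns are centred but not variance-scaled — per-band 0–1 scaling
    upstream already equalises ranges.  Component sign is fixed by making
    the largest-magnitude loading entry positive, so output is
    deterministic across runs and platforms.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 rows and >= 1 column")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds max {max_comp}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total_var = var.sum()
    var_fraction = var / total_var if total_var > 0 else np.zeros_like(var)
    loadings = Vt[:n_components].T.copy()
    scores = Xc @ loadings
    for j in range(n_components):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        var_fraction=var_fraction[:n_components],
        mean=mean,
    )


def event_markers(
    pca: PCAResult, median_events: Dict[str, float], grid: Sequence[float]
) -> Dict[str, np.ndarray]:
    """Score coordinates at the grid point nearest each event (ties to
    the earlier grid point)."""
    grid = np.asarray(grid, dtype=float)
    out: Dict[str, np.ndarray] = {}
    for ev, t in median_events.items():
        if not (grid[0] <= t <= grid[-1]):
            raise ValueError(f"event {ev} at {t} outside grid range")
        dist = np.abs(grid - t)
        row = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
        out[ev] = pca.scores[row]
    return out
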