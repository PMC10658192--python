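"""Energy proxy trait (EPT) spectra.

An EPT reduces one short video recording to a power spectral density of
its mean-pixel time series: fluctuations in overall image brightness
driven by embryonic movement (ciliary rotation, muscular activity,
heartbeat) appear as energy at the corresponding temporal frequencies.

Spectra are estimated with Welch's method.  By default the segment
length equals the full record, so Welch degenerates to a single windowed
periodogram: a 30-s record then has a native frequency grid of k/30 Hz,
whose 1/30 Hz ≈ 0.033 Hz resolution is what makes the lowest analysis
band (starting at 0.03 Hz) resolvable at all.  Segment length, window,
overlap and detrending all remain configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .signal_io import FrameSeries, RecordingMeta


@dataclass(frozen=True)
class SpectralConfig:
    """Welch estimation settings.

    ``segment_duration_s=None`` means one segment spanning the whole
    record.  ``f_max_hz`` truncates the spectrum to the band where
    biologically meaningful signal is expected (6 Hz by default).
    """

    segment_duration_s: Optional[float] = None
    window: str = "hann"
    overlap_fraction: float = 0.5
    detrend: str = "constant"  # none | constant | linear
    f_max_hz: float = 6.0

    def __post_init__(self) -> None:
        if self.segment_duration_s is not None and self.segment_duration_s <= 0:
            raise ValueError("segment_duration_s must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.detrend not in ("none", "constant", "linear"):
            raise ValueError(f"unknown detrend {self.detrend!r}")
        if self.f_max_hz <= 0:
            raise ValueError("f_max_hz must be positive")


@dataclass
class EPTSpectrum:
    """Energy over temporal frequencies for one recording (PSD units,
    intensity²/Hz); the DC component is excluded."""

    freqs_hz: np.ndarray
    energy: np.ndarray
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.freqs_hz.shape != self.energy.shape:
            raise ValueError("freqs_hz and energy must have equal length")
        if len(self.freqs_hz) and self.freqs_hz[0] <= 0:
            raise ValueError("zero/negative frequencies must be excluded")
        if len(self.freqs_hz) > 1 and not np.all(np.diff(self.freqs_hz) > 0):
            raise ValueError("frequencies must be strictly increasing")


def welch_spectrum(series: FrameSeries, cfg: SpectralConfig = SpectralConfig()) -> EPTSpectrum:
    """Estimate the EPT spectrum of one recording.

    Averaged modified periodogram over (possibly one) overlapping
    segments; the DC bin and frequencies above ``cfg.f_max_hz`` are
    dropped.  Deterministic for fixed input and config.
    """
    x = np.asarray(series.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("frame series contains non-finite values")
    fps = series.fps
    if cfg.segment_duration_s is None:
        nperseg = len(x)
    else:
        nperseg = int(round(cfg.segment_duration_s * fps))
        if nperseg > len(x):
            raise ValueError(
                f"series of {len(x)} frames shorter than one segment ({nperseg} frames)"
            )
    if nperseg < 2:
        raise ValueError("segment must contain at least 2 frames")
    if fps < 2 * cfg.f_max_hz:
        raise ValueError(
            f"fps={fps} cannot resolve f_max_hz={cfg.f_max_hz} (need fps >= 2*f_max)"
        )
    detrend = False if cfg.detrend == "none" else cfg.detrend
    window = "boxcar" if cfg.window in ("rectangular", "boxcar") else cfg.window
    freqs, psd = sps.welch(
        x,
        fs=fps,
        window=window,
        nperseg=nperseg,
        noverlap=int(cfg.overlap_fraction * nperseg),
        detrend=detrend,
        scaling="density",
    )
    keep = (freqs > 0) & (freqs <= cfg.f_max_hz)
    return EPTSpectrum(freqs_hz=freqs[keep], energy=psd[keep], meta=series.meta)


def total_energy(spec: EPTSpectrum) -> float:
    """Sum of the spectrum's energy values across all analysed frequencies.

    A plain sum over PSD values (no Δf weighting): the quantity is a
    proxy trait, not a calibrated signal power, and the unweighted sum is
    what the downstream comparative analyses are defined on.  Multiply by
    the frequency step if an integral (variance-like) quantity is wanted.
    """
    if len(spec.energy) == 0:
        raise ValueError("cannot total an empty spectrum")
    return float(np.sum(spec.energy))
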