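"""Synthetic embryo cohorts with known developmental itineraries.

No public dataset of hourly embryo video exists for the three pulmonate
species this analysis targets, so cohorts are simulated with the
statistical structure the pipeline assumes: hourly 30-s recordings whose
mean-pixel signal is a baseline plus

* a broadband "rotation" component — band-limited Gaussian noise whose
  amplitude follows a piecewise-linear envelope over relative
  developmental time (zero before rotation onset, rising to a peak,
  declining into crawling, stepping down at crawling, tapering after
  radula onset) — ciliary rotation raises energy across the whole
  analysed band, not at a single tone;
* a narrowband cardiac sinusoid, zero before heart onset;
* Gaussian white observation noise.

Event times per embryo are the template's relative itinerary jittered
multiplicatively (lognormal, coefficient of variation ``timing_cv``),
which reproduces intraspecific timing variation.  The ``physid``
template carries the sequence heterochrony of interest: crawling onset
precedes cardiac onset, the reverse of the two lymnaeid-like templates.

All templates are synthetic: they are patterned on the qualitative
structure of pulmonate development, with no claim of matching any real
species quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .signal_io import FrameSeries, RecordingMeta


@dataclass(frozen=True)
class SpeciesTemplate:
    """Ground-truth developmental itinerary and signal parameters for one
    synthetic species."""

    name: str
    dev_duration_h: float
    event_rel_times: Dict[str, float]   # rotation/heart/crawling/radula in (0,1)
    heart_freq_hz: float
    rotation_band_hz: Tuple[float, float]
    #: (rel_time, amplitude) breakpoints of the movement envelope
    amplitude_schedule: Tuple[Tuple[float, float], ...]
    cardiac_amplitude: float = 1.0
    baseline: float = 100.0
    noise_sd: float = 0.5
    timing_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.dev_duration_h <= 0:
            raise ValueError("dev_duration_h must be positive")
        required = {"rotation", "heart", "crawling", "radula"}
        if set(self.event_rel_times) != required:
            raise ValueError(f"event_rel_times must cover {sorted(required)}")
        for ev, t in self.event_rel_times.items():
            if not (0 < t < 1):
                raise ValueError(f"event {ev} relative time {t} outside (0, 1)")

    @property
    def event_order(self) -> List[str]:
        return sorted(self.event_rel_times, key=self.event_rel_times.get)

    @property
    def heterochronic(self) -> bool:
        """True when crawling precedes cardiac onset (the physid order)."""
        return self.event_rel_times["crawling"] < self.event_rel_times["heart"]


@dataclass
class GroundTruth:
    """Realised per-embryo event times and injected signal parameters."""

    embryo_id: str
    species: str
    event_times_h: Dict[str, float]
    timepoints_h: np.ndarray
    rotation_amplitude: np.ndarray  # injected envelope value per timepoint
    cardiac_amplitude: np.ndarray
    heart_freq_hz: float


def _default_templates() -> Dict[str, SpeciesTemplate]:
    # Two lymnaeid-like itineraries (heart before crawl) and one
    # heterochronic physid-like itinerary (crawl before heart, everything
    # earlier and the pre-crawl decline compressed).  Cardiac fundamentals
    # sit in the 1.2-4 Hz range where heartbeat signal is expected.
    lymnaeid_a = SpeciesTemplate(
        name="lymnaeid_a",
        dev_duration_h=288.0,
        event_rel_times={"rotation": 0.18, "heart": 0.42, "crawling": 0.50, "radula": 0.65},
        heart_freq_hz=1.7,
        rotation_band_hz=(0.03, 6.0),
        amplitude_schedule=(
            (0.0, 0.0), (0.18, 0.0), (0.22, 2.0), (0.35, 6.0), (0.48, 3.5),
            (0.50, 1.2), (0.65, 1.0), (1.0, 0.45),
        ),
        cardiac_amplitude=1.2,
    )
    lymnaeid_b = SpeciesTemplate(
        name="lymnaeid_b",
        dev_duration_h=336.0,
        event_rel_times={"rotation": 0.20, "heart": 0.48, "crawling": 0.55, "radula": 0.68},
        heart_freq_hz=1.4,
        rotation_band_hz=(0.03, 6.0),
        amplitude_schedule=(
            (0.0, 0.0), (0.20, 0.0), (0.24, 2.0), (0.50, 6.0), (0.53, 3.5),
            (0.55, 1.2), (0.68, 1.0), (1.0, 0.4),
        ),
        cardiac_amplitude=1.2,
    )
    physid = SpeciesTemplate(
        name="physid",
        dev_duration_h=168.0,
        event_rel_times={"rotation": 0.15, "crawling": 0.37, "heart": 0.45, "radula": 0.62},
        heart_freq_hz=2.5,
        rotation_band_hz=(0.03, 6.0),
        amplitude_schedule=(
            (0.0, 0.0), (0.15, 0.0), (0.19, 2.0), (0.33, 6.0), (0.36, 3.5),
            (0.37, 1.2), (0.62, 1.0), (1.0, 0.4),
        ),
        cardiac_amplitude=1.2,
    )
    return {t.name: t for t in (lymnaeid_a, lymnaeid_b, physid)}


DEFAULT_TEMPLATES: Dict[str, SpeciesTemplate] = _default_templates()

#: Cohort sizes and frame rates per default template (hourly 30-s
#: recordings at 30-48 frames/s; cohort Ns in the tens).
DEFAULT_COHORTS: Dict[str, Dict[str, float]] = {
    "lymnaeid_a": {"n_embryos": 28, "fps": 48.0},
    "lymnaeid_b": {"n_embryos": 40, "fps": 30.0},
    "physid": {"n_embryos": 43, "fps": 48.0},
}


def envelope(template: SpeciesTemplate, rel_time: float) -> float:
    """Movement amplitude at one relative time (piecewise linear)."""
    pts = np.asarray(template.amplitude_schedule, dtype=float)
    return float(np.interp(rel_time, pts[:, 0], pts[:, 1]))


def _bandlimited_noise(
    n: int, fps: float, band: Tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to a frequency band."""
    x = rng.normal(size=n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, d=1.0 / fps)
    mask = (f >= band[0]) & (f <= band[1])
    spec[~mask] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _jittered_events(
    template: SpeciesTemplate, rng: np.random.Generator, max_tries: int = 100
) -> Tuple[Dict[str, float], float]:
    """Realised absolute event times (hours) and hatch time.

    Multiplicative lognormal jitter with cv = timing_cv keeps times
    positive; draws violating the template's event order are rejected
    and resampled (bounded retries).
    """
    cv = template.timing_cv
    sigma = np.sqrt(np.log(1.0 + cv**2))
    order = template.event_order
    for _ in range(max_tries):
        hatch = template.dev_duration_h * rng.lognormal(-sigma**2 / 2, sigma)
        times = {
            ev: template.event_rel_times[ev] * hatch * rng.lognormal(-sigma**2 / 2, sigma)
            for ev in template.event_rel_times
        }
        realised_order = sorted(times, key=times.get)
        if realised_order == order and max(times.values()) < hatch:
            return times, hatch
    raise RuntimeError(
        f"could not realise a valid event ordering for {template.name} "
        f"after {max_tries} tries; timing_cv={cv} may be too large"
    )


def simulate_embryo(
    template: SpeciesTemplate,
    fps: float,
    record_s: float = 30.0,
    seed: int = 0,
    embryo_id: str = "e0",
) -> Tuple[List[FrameSeries], GroundTruth]:
    """Simulate one embryo's hourly recordings from 4-cell to hatch."""
    if fps < 2 * (template.heart_freq_hz + 1.0):
        raise ValueError(
            f"fps={fps} too low to resolve cardiac {template.heart_freq_hz} Hz"
        )
    rng = np.random.default_rng(seed)
    times, hatch = _jittered_events(template, rng)
    n = int(round(fps * record_s))
    timepoints = np.arange(0.0, hatch, 1.0)
    t_sample = np.arange(n) / fps
    # anchor the amplitude schedule to this embryo's realised itinerary:
    # a monotone warp maps realised relative event times onto the
    # template's, so envelope steps coincide with the recorded onsets
    order = template.event_order
    realised_pts = np.array([0.0] + [times[e] / hatch for e in order] + [1.0])
    template_pts = np.array([0.0] + [template.event_rel_times[e] for e in order] + [1.0])
    series_list: List[FrameSeries] = []
    rot_amp = np.zeros(len(timepoints))
    card_amp = np.zeros(len(timepoints))
    for i, tp in enumerate(timepoints):
        rel = float(np.interp(tp / hatch, realised_pts, template_pts))
        sig = np.full(n, template.baseline)
        if tp >= times["rotation"]:
            rot_amp[i] = envelope(template, rel)
            if rot_amp[i] > 0:
                sig = sig + rot_amp[i] * _bandlimited_noise(
                    n, fps, template.rotation_band_hz, rng
                )
        if tp >= times["heart"]:
            card_amp[i] = template.cardiac_amplitude
            phase = rng.uniform(0, 2 * np.pi)
            sig = sig + card_amp[i] * np.sin(
                2 * np.pi * template.heart_freq_hz * t_sample + phase
            )
        sig = sig + rng.normal(scale=template.noise_sd, size=n)
        meta = RecordingMeta(
            embryo_id=embryo_id,
            species=template.name,
            timepoint_h=float(tp),
            fps=fps,
            n_frames=n,
        )
        series_list.append(FrameSeries(values=sig, fps=fps, meta=meta))
    truth = GroundTruth(
        embryo_id=embryo_id,
        species=template.name,
        event_times_h={"four_cell": 0.0, **times, "hatch": hatch},
        timepoints_h=timepoints,
        rotation_amplitude=rot_amp,
        cardiac_amplitude=card_amp,
        heart_freq_hz=template.heart_freq_hz,
    )
    return series_list, truth


def simulate_cohort(
    template: SpeciesTemplate,
    n_embryos: int,
    fps: float,
    record_s: float = 30.0,
    seed: int = 0,
) -> Tuple[List[List[FrameSeries]], pd.DataFrame, List[GroundTruth]]:
    """Simulate ``n_embryos`` independent embryos.

    Per-embryo seeds are spawned from the master seed, so cohorts are
    reproducible and embryos mutually independent.  Returns the per-embryo
    recording lists, a validated events table, and the ground truth.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_embryos)
    cohort, truths, rows = [], [], []
    for i, child in enumerate(children):
        embryo_id = f"{template.name}_{i:03d}"
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        series_list, truth = simulate_embryo(
            template, fps=fps, record_s=record_s, seed=sub_seed, embryo_id=embryo_id
        )
        cohort.append(series_list)
        truths.append(truth)
        for ev, t in truth.event_times_h.items():
            rows.append(
                {"embryo_id": embryo_id, "species": template.name, "event": ev, "time_h": t}
            )
    events = pd.DataFrame(rows)
    return cohort, events, truths


def render_frames(
    value: float,
    width: int,
    height: int,
    seed: int = 0,
    spatial_sd: float = 10.0,
    intensity_max: int = 255,
) -> np.ndarray:
    """Render one grayscale frame whose mean pixel equals ``value``
    within 0.5 intensity units (quantisation only)."""
    if not (0 <= value <= intensity_max):
        raise ValueError(f"value {value} outside [0, {intensity_max}]")
    rng = np.random.default_rng(seed)
    if width == height == 1:
        return np.array([[round(value)]], dtype=np.uint8)
    field_ = rng.normal(loc=value, scale=spatial_sd, size=(height, width))
    field_ = np.clip(field_, 0, intensity_max)
    field_ = field_ + (value - field_.mean())  # re-centre after clipping
    field_ = np.clip(np.round(field_), 0, intensity_max)
    return field_.astype(np.uint8)
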