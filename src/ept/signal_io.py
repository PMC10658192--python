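"""Input/output for recordings, events tables and configuration.

A *recording* is one short (typically 30 s) image sequence of a single
embryo acquired at one hourly timepoint.  The only quantity downstream
analysis needs from it is the per-frame mean pixel intensity, so a
recording can be supplied either as a directory of grayscale PNG/TIFF
frames or as a pre-extracted two-column CSV (``frame_idx,mean_pixel``).

Events tables record the absolute time (hours since the 4-cell stage)
at which each scored developmental event was first observed per embryo.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml

#: Scored developmental events, in the canonical (non-heterochronic)
#: order.  Only ``four_cell`` (first) and ``hatch`` (last) have a fixed
#: position; heart/crawling may swap between species.
EVENT_NAMES = ("four_cell", "rotation", "heart", "crawling", "radula", "hatch")

_FRAME_NAME_RE = re.compile(r"^(\d+)\.(png|tif|tiff)$", re.IGNORECASE)


@dataclass(frozen=True)
class RecordingMeta:
    """Acquisition metadata for one hourly recording of one embryo."""

    embryo_id: str
    species: str
    timepoint_h: float
    fps: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.timepoint_h < 0:
            raise ValueError(f"timepoint_h must be non-negative, got {self.timepoint_h}")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.n_frames <= 0:
            raise ValueError(f"n_frames must be positive, got {self.n_frames}")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass
class FrameSeries:
    """Per-frame mean pixel intensity of one recording."""

    values: np.ndarray
    fps: float
    meta: RecordingMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FrameSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FrameSeries values must all be finite")

    def __len__(self) -> int:
        return len(self.values)


def _to_grayscale(frame: np.ndarray) -> np.ndarray:
    # monochrome cameras in the target rigs; colour fixtures collapse by channel mean
    if frame.ndim == 3:
        return frame.astype(float).mean(axis=2)
    return frame.astype(float)


def _frame_paths(directory: Path) -> list:
    """Frames ordered by zero-padded numeric filename; anything else is an error."""
    entries = []
    for p in sorted(directory.iterdir()):
        if p.is_dir():
            continue
        m = _FRAME_NAME_RE.match(p.name)
        if m is None:
            raise ValueError(
                f"non-conforming frame filename {p.name!r} in {directory}: "
                "expected zero-padded numeric names like 000123.png"
            )
        entries.append((int(m.group(1)), p))
    entries.sort(key=lambda t: t[0])
    return [p for _, p in entries]


def load_frame_series(
    frame_source,
    meta: RecordingMeta,
    roi: Optional[Tuple[int, int, int, int]] = None,
) -> FrameSeries:
    """Load one recording into a :class:`FrameSeries`.

    Parameters
    ----------
    frame_source
        Directory containing numbered PNG/TIFF frames, or path to a
        ``frame_idx,mean_pixel`` CSV.
    meta
        Acquisition metadata; ``meta.n_frames`` must match the source.
    roi
        Optional 0-based half-open pixel rectangle ``(x0, x1, y0, y1)``;
        the mean is taken over ``[x0, x1) x [y0, y1)``.  Whole frame if
        absent.  Ignored for CSV sources (the extraction already happened).
    """
    source = Path(frame_source)
    if source.is_file() and source.suffix.lower() == ".csv":
        df = pd.read_csv(source)
        if list(df.columns) != ["frame_idx", "mean_pixel"]:
            raise ValueError(
                f"per-frame CSV {source} must have columns frame_idx,mean_pixel"
            )
        df = df.sort_values("frame_idx")
        if not np.array_equal(df["frame_idx"].to_numpy(), np.arange(len(df))):
            raise ValueError(f"frame_idx in {source} must be 0..n_frames-1 without gaps")
        values = df["mean_pixel"].to_numpy(dtype=float)
        if len(values) != meta.n_frames:
            raise ValueError(
                f"{source}: {len(values)} rows but meta.n_frames={meta.n_frames}"
            )
        return FrameSeries(values=values, fps=meta.fps, meta=meta)

    if not source.is_dir():
        raise FileNotFoundError(f"frame source {source} is neither a CSV nor a directory")

    import imageio.v3 as iio

    paths = _frame_paths(source)
    if len(paths) != meta.n_frames:
        raise ValueError(
            f"{source}: found {len(paths)} frames but meta.n_frames={meta.n_frames}"
        )
    values = np.empty(len(paths), dtype=float)
    shape = None
    for i, p in enumerate(paths):
        try:
            frame = _to_grayscale(iio.imread(p))
        except Exception as exc:  # corrupt frame: identify it
            raise ValueError(f"cannot read frame index {i} ({p.name}): {exc}") from exc
        if shape is None:
            shape = frame.shape
            if roi is not None:
                x0, x1, y0, y1 = roi
                h, w = shape
                if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                    raise ValueError(
                        f"roi {roi} outside frame of width {w}, height {h}"
                    )
        elif frame.shape != shape:
            raise ValueError(
                f"frame index {i} ({p.name}) has shape {frame.shape}, expected {shape}"
            )
        if roi is not None:
            x0, x1, y0, y1 = roi
            frame = frame[y0:y1, x0:x1]
        values[i] = frame.mean()
    return FrameSeries(values=values, fps=meta.fps, meta=meta)


def write_frame_series_csv(series: FrameSeries, path) -> None:
    pd.DataFrame(
        {"frame_idx": np.arange(len(series)), "mean_pixel": series.values}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# events tables


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    required = ["embryo_id", "species", "event", "time_h"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    bad = sorted(set(df["event"]) - set(EVENT_NAMES))
    if bad:
        raise ValueError(f"unknown event names {bad}; allowed: {list(EVENT_NAMES)}")
    if (df["time_h"] < 0).any():
        raise ValueError("event times must be non-negative hours")
    dup = df.duplicated(subset=["embryo_id", "event"])
    if dup.any():
        dupes = df.loc[dup, ["embryo_id", "event"]].drop_duplicates()
        raise ValueError(f"duplicate (embryo_id, event) rows: {dupes.to_dict('records')}")
    for embryo_id, grp in df.groupby("embryo_id"):
        times = dict(zip(grp["event"], grp["time_h"]))
        t0 = times.get("four_cell")
        th = times.get("hatch")
        for ev, t in times.items():
            if t0 is not None and t < t0:
                raise ValueError(
                    f"embryo {embryo_id}: event {ev} at {t} h precedes four_cell at {t0} h"
                )
            if th is not None and t > th:
                raise ValueError(
                    f"embryo {embryo_id}: event {ev} at {t} h follows hatch at {th} h"
                )
    return df.reset_index(drop=True)


def read_events(path) -> pd.DataFrame:
    """Read and validate an events CSV (embryo_id,species,event,time_h)."""
    return _validate_events(pd.read_csv(path))


def write_events(df: pd.DataFrame, path) -> None:
    _validate_events(df)[["embryo_id", "species", "event", "time_h"]].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# recordings manifest and config


def read_manifest(path) -> pd.DataFrame:
    """Read a recordings manifest CSV.

    Columns: embryo_id,species,timepoint_h,fps,n_frames,path — one row per
    hourly recording; ``path`` points at a frames directory or per-frame CSV,
    relative paths resolved against the manifest's own directory.
    """
    df = pd.read_csv(path)
    required = ["embryo_id", "species", "timepoint_h", "fps", "n_frames", "path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    base = Path(path).parent
    df["path"] = [str((base / p).resolve()) if not Path(p).is_absolute() else p
                  for p in df["path"]]
    return df


def meta_from_row(row) -> RecordingMeta:
    return RecordingMeta(
        embryo_id=str(row["embryo_id"]),
        species=str(row["species"]),
        timepoint_h=float(row["timepoint_h"]),
        fps=float(row["fps"]),
        n_frames=int(row["n_frames"]),
    )


def load_config(path) -> dict:
    """Load the single YAML config holding every cross-module tunable."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
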