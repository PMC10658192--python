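"""Frequency-band statistics around developmental event onsets.

Three questions, three procedures:

* does spectral composition change at an event? — Kruskal–Wallis on each
  frequency band, comparing the 5 hourly timepoints before onset with
  the 5 after, Bonferroni corrected;
* how does band energy shift between events? — percent change of mean
  band energy between consecutive inter-event intervals;
* do species differ in their total-energy trajectories? — mixed
  repeated-measures ANOVA with species between subjects and relative
  time within.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as st

from .timeline import DevTimeSeries

#: p-value display bins used for significance maps (upper edges); the
#: fourth edge is the Bonferroni-adjusted threshold 0.05/30.
P_VALUE_BINS = (1e-6, 1e-5, 1e-4, 0.05 / 30, 1.0)


@dataclass
class BandTestResult:
    event: str
    band_centre_hz: float
    H: float
    p_raw: float
    p_adjusted: float
    direction: int  # sign of (after - before) mean energy


def before_after_windows(
    series: DevTimeSeries, event: str, w: int = 5
) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of the ``w`` hourly timepoints immediately before (exclusive)
    and at/after (inclusive) the event onset.

    Raises if the embryo lacks ``w`` timepoints on either side; callers
    exclude such embryos with a warning and only fail if the whole cohort
    is excluded.
    """
    if event not in series.events:
        raise KeyError(f"embryo {series.embryo_id} has no event {event!r}")
    t_event = series.events[event]
    rel = series.rel_times
    before = np.flatnonzero(rel < t_event)
    after = np.flatnonzero(rel >= t_event)
    if len(before) < w or len(after) < w:
        raise ValueError(
            f"embryo {series.embryo_id}: fewer than {w} timepoints on one side "
            f"of event {event!r}"
        )
    return before[-w:], after[:w]


def kruskal_wallis(*groups: Sequence[float]) -> Tuple[float, float]:
    """Kruskal–Wallis H with tie correction and chi-square p-value.

    Degenerate input (all values identical across groups) is reported as
    no effect: H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("each group needs at least one observation")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = st.kruskal(*groups)
    return float(H), float(p)


def bonferroni(p_raw: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, m·p) elementwise."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def percent_change(before_mean: float, after_mean: float) -> float:
    """100 · (after − before) / before; undefined (NaN) for before = 0."""
    if before_mean == 0:
        return float("nan")
    return 100.0 * (after_mean - before_mean) / before_mean


def p_value_bin(p: float) -> int:
    """Display bin 1..5 for a (Bonferroni-raw) p-value; bin 5 is
    non-significant at the adjusted threshold."""
    for i, edge in enumerate(P_VALUE_BINS, start=1):
        if p <= edge:
            return i
    return len(P_VALUE_BINS)


def band_tests(
    cohort: Sequence[DevTimeSeries],
    band_matrices: Sequence[np.ndarray],
    band_centres: np.ndarray,
    event: str,
    w: int = 5,
    m: int = 30,
    pool: str = "pooled",
) -> List[BandTestResult]:
    """Kruskal–Wallis per band on before/after windows around one event.

    ``band_matrices[i]`` is embryo i's timepoint × band energy matrix on
    its own hourly grid.  Observations are either pooled per-embryo
    per-timepoint band energies (default: w · n_embryos per group) or
    per-embryo window means (``pool='embryo_mean'``).
    """
    if pool not in ("pooled", "embryo_mean"):
        raise ValueError(f"unknown pooling {pool!r}")
    before_rows, after_rows = [], []
    for series, bands in zip(cohort, band_matrices):
        try:
            bi, ai = before_after_windows(series, event, w)
        except ValueError as exc:
            warnings.warn(str(exc), stacklevel=2)
            continue
        b, a = bands[bi], bands[ai]
        if pool == "embryo_mean":
            b, a = b.mean(axis=0, keepdims=True), a.mean(axis=0, keepdims=True)
        before_rows.append(b)
        after_rows.append(a)
    if not before_rows:
        raise ValueError(f"no embryo has enough timepoints around event {event!r}")
    before = np.vstack(before_rows)
    after = np.vstack(after_rows)
    p_raws, Hs, directions = [], [], []
    for k in range(before.shape[1]):
        H, p = kruskal_wallis(before[:, k], after[:, k])
        Hs.append(H)
        p_raws.append(p)
        directions.append(int(np.sign(after[:, k].mean() - before[:, k].mean())))
    p_adj = bonferroni(p_raws, m)
    return [
        BandTestResult(event, float(band_centres[k]), Hs[k], p_raws[k], float(p_adj[k]), directions[k])
        for k in range(before.shape[1])
    ]


def percent_change_matrix(
    cohort: Sequence[DevTimeSeries],
    band_matrices: Sequence[np.ndarray],
    band_centres: np.ndarray,
    events_in_order: Sequence[str],
) -> pd.DataFrame:
    """Percent change of cohort-mean band energy between consecutive
    inter-event intervals.

    Intervals are [event_i, event_{i+1}) in relative time (the last ends
    at hatch, 1.0); row ``a->b`` compares interval b's mean against
    interval a's.
    """
    bounds = list(events_in_order) + ["hatch"]
    interval_means = []
    labels = []
    for i in range(len(bounds) - 1):
        lo_ev, hi_ev = bounds[i], bounds[i + 1]
        rows = []
        for series, bands in zip(cohort, band_matrices):
            lo = series.events[lo_ev] if lo_ev != "hatch" else 1.0
            hi = series.events[hi_ev] if hi_ev != "hatch" else 1.0 + 1e-12
            rel = series.rel_times
            sel = (rel >= lo) & (rel < hi)
            if sel.any():
                rows.append(bands[sel].mean(axis=0))
        if not rows:
            raise ValueError(f"no observations in interval {lo_ev}->{hi_ev}")
        interval_means.append(np.vstack(rows).mean(axis=0))
        labels.append(f"{lo_ev}->{hi_ev}")
    out = {}
    for i in range(1, len(interval_means)):
        out[f"{labels[i-1]} vs {labels[i]}"] = [
            percent_change(interval_means[i - 1][k], interval_means[i][k])
            for k in range(len(band_centres))
        ]
    return pd.DataFrame(out, index=np.round(band_centres, 3)).T


def rm_anova_total_energy(table: pd.DataFrame) -> Tuple[float, float, float, float]:
    """Species main effect from a mixed repeated-measures ANOVA.

    ``table`` is long-format with columns embryo_id, species, rel_time,
    total_energy; every embryo must be observed at every rel_time (the
    repeated factor).  Returns (F, df_between, df_within, p) for the
    between-subjects species effect.
    """
    required = {"embryo_id", "species", "rel_time", "total_energy"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table["species"].nunique() < 2:
        raise ValueError("need at least 2 species")
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=table,
            dv="total_energy",
            within="rel_time",
            between="species",
            subject="embryo_id",
        )
    row = aov.loc[aov["Source"] == "species"].iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return float(row["F"]), float(row["DF1"]), float(row["DF2"]), float(row[p_col])
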