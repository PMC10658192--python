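"""Staged analysis pipeline over the library modules.

Each stage reads the previous stage's CSV artifacts from the run
directory and writes its own, so stages can be re-run independently and
two runs with the same config and seed produce byte-identical artifacts
(floats are written at 9 significant digits).  The stages mirror the
analysis: simulate → spectra → timeline → reduce → events → impact.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal_impact import run_event_impacts
from .ept_core import SpectralConfig, total_energy, welch_spectrum
from .event_stats import band_tests, percent_change_matrix, rm_anova_total_energy
from .signal_io import load_frame_series, meta_from_row, read_events, read_manifest, write_events, write_frame_series_csv
from .spectral_reduction import BandScheme, bin_spectrum, event_markers, pca_embed, transform_and_normalize
from .timeline import DevTimeSeries, grid_points, normalize_individual, resample_to_grid, species_mean_series
from .synthetic_data import DEFAULT_COHORTS, DEFAULT_TEMPLATES, simulate_cohort

FLOAT_FMT = "%.9g"

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "output_dir": "results/run",
    "simulate": {
        "templates": ["lymnaeid_a", "lymnaeid_b", "physid"],
        "n_embryos": None,        # None -> per-template defaults
        "record_s": 30.0,
    },
    "spectral": {
        "segment_duration_s": None,
        "window": "hann",
        "overlap_fraction": 0.5,
        "detrend": "constant",
        "f_max_hz": 6.0,
    },
    "bands": {"f_low_hz": 0.03, "f_high_hz": 6.0, "width_hz": 0.1},
    "grid_size": 101,
    "log_eps": 1e-12,
    "log_first": True,
    "kw": {"window": 5, "bonferroni_m": 30, "pool": "pooled"},
    "bsts": {"draws": 1000, "burn_in": 200},
}


def _merge(base: Dict, override: Optional[Dict]) -> Dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def make_config(override: Optional[Dict] = None) -> Dict:
    return _merge(DEFAULT_CONFIG, override)


def _spectral_config(cfg: Dict) -> SpectralConfig:
    s = cfg["spectral"]
    return SpectralConfig(
        segment_duration_s=s["segment_duration_s"],
        window=s["window"],
        overlap_fraction=s["overlap_fraction"],
        detrend=s["detrend"],
        f_max_hz=s["f_max_hz"],
    )


def _band_scheme(cfg: Dict) -> BandScheme:
    b = cfg["bands"]
    return BandScheme(b["f_low_hz"], b["f_high_hz"], b["width_hz"])


def _band_cols(scheme: BandScheme) -> List[str]:
    return [f"band_{c:.2f}" for c in scheme.centres]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: Dict, outdir: Path) -> None:
    """Simulate cohorts for the configured templates; write per-recording
    mean-pixel CSVs, the recordings manifest, events table and ground truth."""
    outdir = Path(outdir)
    sim = cfg["simulate"]
    ss = np.random.SeedSequence(cfg["seed"])
    manifest_rows, event_frames, truth_rows = [], [], []
    sigdir = outdir / "signals"
    sigdir.mkdir(parents=True, exist_ok=True)
    for name, child in zip(sim["templates"], ss.spawn(len(sim["templates"]))):
        template = DEFAULT_TEMPLATES[name]
        defaults = DEFAULT_COHORTS[name]
        n = (sim["n_embryos"] or {}).get(name) if isinstance(sim["n_embryos"], dict) else sim["n_embryos"]
        n = int(n) if n else int(defaults["n_embryos"])
        fps = float(defaults["fps"])
        seed = int(child.generate_state(1)[0] % (2**31))
        cohort, events, truths = simulate_cohort(
            template, n_embryos=n, fps=fps, record_s=sim["record_s"], seed=seed
        )
        event_frames.append(events)
        for series_list, truth in zip(cohort, truths):
            edir = sigdir / truth.embryo_id
            edir.mkdir(exist_ok=True)
            for series in series_list:
                fname = f"tp_{series.meta.timepoint_h:07.1f}.csv"
                write_frame_series_csv(series, edir / fname)
                manifest_rows.append(
                    {
                        "embryo_id": truth.embryo_id,
                        "species": name,
                        "timepoint_h": series.meta.timepoint_h,
                        "fps": fps,
                        "n_frames": len(series),
                        "path": str(Path("signals") / truth.embryo_id / fname),
                    }
                )
            for i, tp in enumerate(truth.timepoints_h):
                truth_rows.append(
                    {
                        "embryo_id": truth.embryo_id,
                        "species": name,
                        "timepoint_h": tp,
                        "rotation_amplitude": truth.rotation_amplitude[i],
                        "cardiac_amplitude": truth.cardiac_amplitude[i],
                        "heart_freq_hz": truth.heart_freq_hz,
                    }
                )
    _write(pd.DataFrame(manifest_rows), outdir / "manifest.csv")
    write_events(pd.concat(event_frames, ignore_index=True), outdir / "events.csv")
    _write(pd.DataFrame(truth_rows), outdir / "ground_truth.csv")


def stage_spectra(cfg: Dict, outdir: Path, write_long_spectra: bool = False) -> None:
    """EPT extraction: Welch spectrum per recording, binned band energies
    and total energy per (embryo, timepoint)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"missing {manifest_path}: run the simulate stage (or point the "
            "config at an existing manifest) before extracting spectra"
        )
    manifest = read_manifest(manifest_path)
    scfg = _spectral_config(cfg)
    scheme = _band_scheme(cfg)
    cols = _band_cols(scheme)
    rows, long_rows = [], []
    for _, r in manifest.iterrows():
        meta = meta_from_row(r)
        series = load_frame_series(r["path"], meta)
        spec = welch_spectrum(series, scfg)
        bands = bin_spectrum(spec, scheme)
        row = {
            "embryo_id": meta.embryo_id,
            "species": meta.species,
            "timepoint_h": meta.timepoint_h,
            "total_energy": total_energy(spec),
        }
        row.update(dict(zip(cols, bands)))
        rows.append(row)
        if write_long_spectra:
            for f, e in zip(spec.freqs_hz, spec.energy):
                long_rows.append(
                    {"embryo_id": meta.embryo_id, "timepoint_h": meta.timepoint_h,
                     "freq_hz": f, "energy": e}
                )
    bands_df = pd.DataFrame(rows).sort_values(["embryo_id", "timepoint_h"])
    _write(bands_df, outdir / "bands.csv")
    if write_long_spectra:
        _write(pd.DataFrame(long_rows), outdir / "spectra.csv")


def _load_dev_series(
    cfg: Dict, outdir: Path
) -> Tuple[List[DevTimeSeries], List[np.ndarray], List[str]]:
    """Per-embryo DevTimeSeries and hourly band matrices from artifacts.

    Embryos lacking a recorded hatch (mortalities) are excluded here.
    """
    outdir = Path(outdir)
    bands_path = outdir / "bands.csv"
    if not bands_path.exists():
        raise FileNotFoundError(f"missing {bands_path}: run the spectra stage first")
    bands_df = pd.read_csv(bands_path)
    events_df = read_events(outdir / "events.csv")
    scheme = _band_scheme(cfg)
    cols = _band_cols(scheme)
    series_out, bands_out = [], []
    for embryo_id, grp in bands_df.groupby("embryo_id", sort=True):
        ev = events_df[events_df["embryo_id"] == embryo_id]
        times = dict(zip(ev["event"], ev["time_h"]))
        if "hatch" not in times or "four_cell" not in times:
            warnings.warn(f"embryo {embryo_id}: no hatch recorded (mortality?), excluded")
            continue
        t0, th = times["four_cell"], times["hatch"]
        grp = grp.sort_values("timepoint_h")
        keep = (grp["timepoint_h"] >= t0) & (grp["timepoint_h"] <= th)
        grp = grp[keep]
        rel_events = {
            e: (t - t0) / (th - t0) for e, t in times.items()
        }
        series_out.append(
            DevTimeSeries(
                embryo_id=embryo_id,
                species=str(grp["species"].iloc[0]),
                timepoints_h=grp["timepoint_h"].to_numpy(),
                total_energy=grp["total_energy"].to_numpy(),
                events=rel_events,
                t0_h=t0,
                t_hatch_h=th,
            )
        )
        bands_out.append(grp[cols].to_numpy())
    species = sorted({s.species for s in series_out})
    return series_out, bands_out, species


def stage_timeline(cfg: Dict, outdir: Path) -> None:
    """Per-embryo normalised gridded total energy and species cohort series."""
    outdir = Path(outdir)
    series_list, _, species = _load_dev_series(cfg, outdir)
    G = cfg["grid_size"]
    grid = grid_points(G)
    per_embryo_rows = []
    cohort_rows = []
    for sp in species:
        members = [s for s in series_list if s.species == sp]
        gridded = []
        for s in members:
            norm = normalize_individual(s.total_energy)
            g = resample_to_grid(s.rel_times, norm, G)
            gridded.append(g)
            for rt, v in zip(grid, g):
                per_embryo_rows.append(
                    {"embryo_id": s.embryo_id, "species": sp, "rel_time": rt,
                     "total_energy_norm": v}
                )
        cohort = species_mean_series(members, gridded, grid)
        for i, rt in enumerate(grid):
            cohort_rows.append(
                {"species": sp, "rel_time": rt, "mean": cohort.mean[i],
                 "sd": cohort.sd[i], "n": int(cohort.n[i])}
            )
        # raw (unnormalised) species mean, used by the impact stage
        raw = [resample_to_grid(s.rel_times, s.total_energy, G) for s in members]
        raw_cohort = species_mean_series(members, raw, grid)
        for i, rt in enumerate(grid):
            cohort_rows[-G + i]["mean_raw"] = raw_cohort.mean[i]
    _write(pd.DataFrame(per_embryo_rows), outdir / "gridded_total_energy.csv")
    _write(pd.DataFrame(cohort_rows), outdir / "cohort_series.csv")
    med_rows = []
    for sp in species:
        members = [s for s in series_list if s.species == sp]
        cohort = species_mean_series(members, [np.zeros(G)] * len(members), grid)
        for ev, t in cohort.median_events.items():
            med_rows.append({"species": sp, "event": ev, "median_rel_time": t})
    _write(pd.DataFrame(med_rows), outdir / "median_events.csv")


def stage_reduce(cfg: Dict, outdir: Path, n_components: int = 2) -> None:
    """Species-mean band matrices, log + per-band scaling, per-species PCA."""
    outdir = Path(outdir)
    series_list, band_mats, species = _load_dev_series(cfg, outdir)
    G = cfg["grid_size"]
    grid = grid_points(G)
    scheme = _band_scheme(cfg)
    cols = _band_cols(scheme)
    score_rows, load_rows, var_rows, binned_rows, marker_rows = [], [], [], [], []
    for sp in species:
        members = [(s, b) for s, b in zip(series_list, band_mats) if s.species == sp]
        gridded = [resample_to_grid(s.rel_times, b, G) for s, b in members]
        mean_matrix = np.mean(np.stack(gridded), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = transform_and_normalize(mean_matrix, eps=cfg["log_eps"], log_first=cfg["log_first"])
        pca = pca_embed(norm, n_components=n_components)
        cohort = species_mean_series(
            [s for s, _ in members], [np.zeros(G)] * len(members), grid
        )
        markers = event_markers(pca, cohort.median_events, grid)
        for i, rt in enumerate(grid):
            score_rows.append(
                {"species": sp, "rel_time": rt,
                 **{f"PC{j+1}": pca.scores[i, j] for j in range(n_components)}}
            )
            binned_rows.append(
                {"species": sp, "rel_time": rt, **dict(zip(cols, norm[i]))}
            )
        for k, c in enumerate(scheme.centres):
            load_rows.append(
                {"species": sp, "band_centre_hz": c,
                 **{f"PC{j+1}": pca.loadings[k, j] for j in range(n_components)}}
            )
        var_rows.append(
            {"species": sp,
             **{f"PC{j+1}": pca.var_fraction[j] for j in range(n_components)},
             "PC1_plus_PC2": float(pca.var_fraction[:2].sum())}
        )
        for ev, coords in markers.items():
            marker_rows.append(
                {"species": sp, "event": ev,
                 **{f"PC{j+1}": coords[j] for j in range(n_components)}}
            )
    _write(pd.DataFrame(score_rows), outdir / "pca_scores.csv")
    _write(pd.DataFrame(load_rows), outdir / "pca_loadings.csv")
    _write(pd.DataFrame(var_rows), outdir / "pca_variance.csv")
    _write(pd.DataFrame(binned_rows), outdir / "binned_matrix.csv")
    _write(pd.DataFrame(marker_rows), outdir / "pca_event_markers.csv")


def stage_events(cfg: Dict, outdir: Path) -> None:
    """Band-wise Kruskal–Wallis tests, percent-change matrices and the
    species repeated-measures ANOVA."""
    outdir = Path(outdir)
    series_list, band_mats, species = _load_dev_series(cfg, outdir)
    scheme = _band_scheme(cfg)
    kw = cfg["kw"]
    test_rows = []
    pc_frames = []
    for sp in species:
        members = [(s, b) for s, b in zip(series_list, band_mats) if s.species == sp]
        cohort = [s for s, _ in members]
        mats = [b for _, b in members]
        order = sorted(
            ("rotation", "heart", "crawling", "radula"),
            key=lambda e: float(np.median([s.events[e] for s in cohort])),
        )
        for event in order:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = band_tests(
                    cohort, mats, scheme.centres, event,
                    w=kw["window"], m=kw["bonferroni_m"], pool=kw["pool"],
                )
            for r in results:
                test_rows.append(
                    {"species": sp, "event": r.event, "band_centre_hz": r.band_centre_hz,
                     "H": r.H, "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
                     "direction": r.direction}
                )
        pc = percent_change_matrix(cohort, mats, scheme.centres, order)
        pc = pc.reset_index(names="interval_pair")
        pc.insert(0, "species", sp)
        pc_frames.append(pc)
    _write(pd.DataFrame(test_rows), outdir / "band_tests.csv")
    _write(pd.concat(pc_frames, ignore_index=True), outdir / "percent_change.csv")

    gridded = pd.read_csv(outdir / "gridded_total_energy.csv")
    gridded = gridded.rename(columns={"total_energy_norm": "total_energy"})
    F, df1, df2, p = rm_anova_total_energy(gridded)
    _write(
        pd.DataFrame(
            [{"effect": "species", "F": F, "df_between": df1, "df_within": df2, "p": p}]
        ),
        outdir / "anova.csv",
    )


def stage_impact(cfg: Dict, outdir: Path) -> None:
    """BSTS counterfactual impact of each event on the species-mean
    total-energy series (Table-2-shaped output)."""
    outdir = Path(outdir)
    cohort_path = outdir / "cohort_series.csv"
    if not cohort_path.exists():
        raise FileNotFoundError(f"missing {cohort_path}: run the timeline stage first")
    cohort = pd.read_csv(cohort_path)
    medians = pd.read_csv(outdir / "median_events.csv")
    bsts = cfg["bsts"]
    ss = np.random.SeedSequence(cfg["seed"] + 1)
    rows = []
    for sp, child in zip(sorted(cohort["species"].unique()),
                         ss.spawn(cohort["species"].nunique())):
        sub = cohort[cohort["species"] == sp].sort_values("rel_time")
        med = medians[medians["species"] == sp]
        ev_times = dict(zip(med["event"], med["median_rel_time"]))
        order = sorted(
            ("rotation", "heart", "crawling", "radula"), key=lambda e: ev_times[e]
        )
        events = [(e, ev_times[e]) for e in order]
        seed = int(child.generate_state(1)[0] % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries = run_event_impacts(
                sub["mean_raw"].to_numpy(), sub["rel_time"].to_numpy(), events,
                t_end=1.0 + 1e-9, draws=bsts["draws"], burn_in=bsts["burn_in"],
                seed=seed,
            )
        for s in summaries:
            rows.append(
                {"species": sp, "event": s.event, "actual": s.actual,
                 "predicted": s.predicted, "absolute_effect": s.absolute_effect,
                 "abs_lo": s.absolute_ci[0], "abs_hi": s.absolute_ci[1],
                 "relative_effect": s.relative_effect,
                 "rel_lo": s.relative_ci[0], "rel_hi": s.relative_ci[1],
                 "tail_p": s.tail_p, "posterior_prob_pct": s.posterior_prob_pct}
            )
    _write(pd.DataFrame(rows), outdir / "impacts.csv")


STAGES = {
    "simulate": stage_simulate,
    "spectra": stage_spectra,
    "timeline": stage_timeline,
    "reduce": stage_reduce,
    "events": stage_events,
    "impact": stage_impact,
}

STAGE_ORDER = ["simulate", "spectra", "timeline", "reduce", "events", "impact"]


def run_all(cfg: Dict, outdir: Optional[Path] = None) -> Path:
    """Run every stage in order and write the run manifest."""
    cfg = make_config(cfg)
    outdir = Path(outdir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    for name in STAGE_ORDER:
        STAGES[name](cfg, outdir)
    write_run_manifest(cfg, outdir)
    return outdir


def write_run_manifest(cfg: Dict, outdir: Path) -> None:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg["seed"],
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (Path(outdir) / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
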