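import numpy as np
import pytest

from ept.ept_core import SpectralConfig
from ept.signal_io import FrameSeries, RecordingMeta


def make_meta(fps=30.0, n_frames=900, embryo_id="e0", species="sp", timepoint_h=0.0):
    return RecordingMeta(
        embryo_id=embryo_id,
        species=species,
        timepoint_h=timepoint_h,
        fps=fps,
        n_frames=n_frames,
    )


def make_series(values, fps=30.0, **meta_kw):
    values = np.asarray(values, dtype=float)
    meta = make_meta(fps=fps, n_frames=len(values), **meta_kw)
    return FrameSeries(values=values, fps=fps, meta=meta)


@pytest.fixture(scope="session")
def rect_cfg():
    """Single-segment rectangular window, no truncation below Nyquist."""
    return SpectralConfig(window="boxcar", detrend="constant", f_max_hz=6.0)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One reduced-size full pipeline run shared across tests.

    Cohorts of 10 embryos per template keep the run inside a few minutes;
    the qualitative structure under test (effect signs, band-wise
    significance patterns, trajectory ordering) does not depend on
    cohort size.
    """
    from ept.pipeline import make_config, run_all

    outdir = tmp_path_factory.mktemp("run")
    cfg = make_config(
        {
            "seed": 20260930,
            "output_dir": str(outdir),
            "simulate": {"n_embryos": 10},
            "bsts": {"draws": 1000, "burn_in": 200},
        }
    )
    run_all(cfg, outdir)
    return outdir
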