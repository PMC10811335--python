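"""Shared fixtures.

The full phantom-to-validation pipeline is expensive (a few minutes), so it
runs once per session into a temp directory and every end-to-end assertion
reads from that one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vessel4d import phantom as ph
from vessel4d.pipeline import PipelineConfig, run_pipeline

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def quiet_spec():
    """Phantom family with the noise turned off (geometry-only oracles)."""
    return ph.PhantomSpec(seed=1, noise_sd_schedule={p: 0.0 for p in range(10, 101, 10)},
                          reference_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_spec():
    """Phantom with the default U-shaped noise schedule."""
    return ph.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def low_geo():
    return ph.low_res_geometry()


@pytest.fixture(scope="session")
def high_geo():
    return ph.high_res_geometry()


@pytest.fixture(scope="session")
def quiet_phase50(quiet_spec, low_geo):
    """(volume, truth mask) for the quiet 50% phase on the low-res grid."""
    return ph.generate_phase_volume(quiet_spec, 50, low_geo)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end run (phantom -> ... -> validation) per session."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(out_dir=str(out), seed=PIPELINE_SEED)
    manifest = run_pipeline(cfg)
    return {"config": cfg, "manifest": manifest, "out": out,
            "spec": ph.PhantomSpec(seed=PIPELINE_SEED)}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
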