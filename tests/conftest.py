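import numpy as np
import pytest

from corridorscope.landscape import LandscapeParams, gen_landscape
from corridorscope.pipeline import run_pipeline, validate_config
from corridorscope.raster import GridSpec
from corridorscope.telemetry import TelemetryParams, simulate_tracks

COMPACT_CONFIG = {
    "seed": 5,
    "landscape": {"nrows": 60, "ncols": 60, "cellsize": 1500.0, "n_wells": 15, "n_water_bodies": 12},
    "telemetry": {"n_individuals": 20, "n_spring_migrants": 8, "n_fall_migrants": 9},
    "hsm": {"background_size": 4000},
}


@pytest.fixture(scope="session")
def compact_run(tmp_path_factory):
    """One compact end-to-end pipeline run shared across the suite."""
    out = tmp_path_factory.mktemp("compact_run")
    config = validate_config(dict(COMPACT_CONFIG))
    manifest = run_pipeline(config, out)
    return config, manifest, out


@pytest.fixture(scope="session")
def default_landscape():
    """One default-sized synthetic landscape shared across the suite."""
    return gen_landscape(LandscapeParams(seed=1))


@pytest.fixture(scope="session")
def default_tracks(default_landscape):
    tracks, truth = simulate_tracks(default_landscape, TelemetryParams(seed=1))
    return tracks, truth


@pytest.fixture(scope="session")
def compact_landscape():
    """A smaller landscape for connectivity-heavy tests."""
    return gen_landscape(
        LandscapeParams(
            spec=GridSpec(60, 60, 1500.0, origin_y=90_000.0),
            n_wells=15,
            n_water_bodies=12,
            patch_radius_m=7000.0,
            seed=2,
        )
    )
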