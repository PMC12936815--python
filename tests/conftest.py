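import numpy as np
import pytest
from hypothesis import settings

from nanozyme2d.core import ScenarioConfig, calibrate_reference, preset_for
from nanozyme2d.grid import Grid2D, stretched_nodes

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def ref():
    return calibrate_reference()


@pytest.fixture(scope="session")
def preset(cfg):
    return preset_for(cfg)


@pytest.fixture(scope="session")
def coarse_grid(cfg):
    """Small grid for fast solves (still stretched toward the surface)."""
    tr = cfg.transport
    return Grid2D(x=np.linspace(0.0, tr.L, 17),
                  y=stretched_nodes(tr.H, 64, 1.08))


@pytest.fixture(scope="session")
def sweep_coarse(cfg, preset, coarse_grid):
    """Shared 1D + pseudo-2D steady sweep on the coarse grid."""
    from nanozyme2d.kinetics import run_sweep

    return run_sweep(cfg, preset, coarse_grid)
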