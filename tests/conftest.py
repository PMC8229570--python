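"""Shared fixtures: simulated acquisitions are expensive, so the FDTD
scenario runs are session-scoped and reused across tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.constants import c as C0

from imtr.arraypulse import PulseSpec, place_antennas
from imtr.forward import SignalSet, born_point_scatterer
from imtr.io import ScenarioConfig
from imtr.phantom import TissueSpec, build_phantom
from imtr.pipeline import reconstruct_all, score_images, simulate_scenario


#: record length used for the packaged test acquisitions: long enough
#: for the latest back-wall round trip (~2.1 ns) with margin, short
#: enough to keep a full scenario under half a minute.
FIXTURE_TIMESTEPS = 3072


@pytest.fixture(scope="session")
def nine_scenario():
    """nine_antennas acquisition pair (E1 empty, E2 total)."""
    cfg = ScenarioConfig.from_catalogue("nine_antennas")
    cfg.n_timesteps = FIXTURE_TIMESTEPS
    total, background = simulate_scenario(cfg, seed=0)
    return cfg, total, background


@pytest.fixture(scope="session")
def nine_images(nine_scenario):
    """All four reconstructions plus scores for the default scenario."""
    cfg, total, background = nine_scenario
    images = reconstruct_all(cfg, total, background)
    metrics = score_images(cfg, images)
    return cfg, images, metrics


@pytest.fixture(scope="session")
def two_tumor_run():
    """two_tumors acquisition and its IMTR reconstruction."""
    cfg = ScenarioConfig.from_catalogue("two_tumors")
    cfg.n_timesteps = FIXTURE_TIMESTEPS
    total, background = simulate_scenario(cfg, seed=0)
    images = reconstruct_all(cfg, total, background, algorithms=("imtr",))
    return cfg, images["imtr"]


@pytest.fixture(scope="session")
def ring9():
    return place_antennas(9, 60e-3)


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def born_single(ring9, pulse):
    """Analytic single-scatterer acquisition at the packaged tumor
    position, with a zero background set."""
    truth = (20e-3, 0.0)
    total = born_point_scatterer(ring9, [(truth, 1.0)], pulse, v=C0, dt=8e-12)
    background = SignalSet(
        np.zeros_like(total.data), total.t, "background", ring9, pulse
    )
    return truth, total, background


@pytest.fixture(scope="session")
def vacuum_phantom_50mm():
    """Breast-sized vacuum phantom (gate geometry for oracle data)."""
    vac = {k: TissueSpec(k, 1.0, 0.0) for k in ("background", "fat", "skin", "tumor")}
    return build_phantom(50e-3, 0.0, [], vac, 1e-3, check_resolution=False)
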