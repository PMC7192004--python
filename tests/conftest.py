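"""Shared fixtures: synthetic scenes are expensive enough to build once.

All scenes are deterministic functions of their configuration, so
session scope is safe; tests must not mutate fixture objects.
"""

import numpy as np
import pytest

from canopyflux.extraction import ExtractionConfig, run_extraction
from canopyflux.scene import SceneConfig, generate_scene, scene_variant

#: edge filter used for truth-recovery runs: removes triangles that
#: bridge between disjoint row strips inside one cell
RECOVERY_EDGE_FILTER = 0.5


@pytest.fixture(scope="session")
def flat_scene():
    """Default flat vineyard scene, 10x10 grid at 3.6 m."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def flat_cells_mode2(flat_scene):
    cfg = ExtractionConfig(mode="II", max_tin_edge=RECOVERY_EDGE_FILTER)
    return run_extraction(flat_scene.cloud, flat_scene.rasters,
                          flat_scene.grid, cfg, ground=flat_scene.ground)


@pytest.fixture(scope="session")
def quiet_ground_scene():
    """Flat scene with noise-free ground returns, for the geometric
    mode-I/mode-II equivalence (the min-of-noise bias of mode I is a
    separate, documented effect)."""
    return generate_scene(scene_variant(SceneConfig(seed=7),
                                        ground_z_noise_sd=1e-12))


@pytest.fixture(scope="session")
def sloped_scene():
    """Same vineyard on a 10 % plane."""
    return generate_scene(scene_variant(SceneConfig(seed=7),
                                        terrain_slope=0.1))


@pytest.fixture(scope="session")
def gapped_scene():
    """Scene with missing vine units and a full inter-row cover crop."""
    return generate_scene(scene_variant(SceneConfig(seed=7),
                                        gap_fraction=0.3,
                                        cover_fraction=1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
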