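"""Shared fixtures: small synthetic scenes and the session-scoped night runs."""

from __future__ import annotations

import numpy as np
import pytest

from radarvitals.pipeline import PipelineConfig, run_simulated
from radarvitals.synthetic import SceneConfig, noiseless_scene, noisy_scene


@pytest.fixture(scope="session")
def small_clean_scene():
    """A 5-minute clean scene; enough epochs for selection tests."""
    from radarvitals import simulate

    scene = SceneConfig(seed=7, duration_s=300.0)
    cube, truth = simulate(scene)
    return scene, cube, truth


@pytest.fixture(scope="session")
def small_displacement(small_clean_scene):
    from radarvitals import chirp_median_phase, phase_to_displacement

    _, cube, _ = small_clean_scene
    return phase_to_displacement(chirp_median_phase(cube))


@pytest.fixture(scope="session")
def night_runs():
    """Full 30-minute clean and noisy nights through the whole pipeline.

    Session-scoped: these are the most expensive fixtures in the suite and
    back several end-to-end assertions.
    """
    cfg = PipelineConfig(crop=False)
    clean_res, clean_truth = run_simulated(SceneConfig(seed=1), cfg)
    noisy_res, noisy_truth = run_simulated(noisy_scene(seed=1), cfg)
    return {
        "clean": (clean_res, clean_truth),
        "noisy": (noisy_res, noisy_truth),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
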