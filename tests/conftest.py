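import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from ccflow import EnFaceAngiogram, SyntheticSceneConfig, generate_scene


def make_angiogram(values, fov_mm: float = 6.0) -> EnFaceAngiogram:
    return EnFaceAngiogram(intensities=np.asarray(values, dtype=float), fov_mm=fov_mm)


@pytest.fixture(scope="session")
def default_scene():
    """One full-size scene at the default study conditions."""
    return generate_scene(SyntheticSceneConfig(seed=1))


@pytest.fixture(scope="session")
def quiet_scene():
    """A noise-free, artifact-free scene with a 10% implanted void fraction."""
    cfg = SyntheticSceneConfig(
        seed=3,
        speckle_cv=0.0,
        artifact_strength=0.0,
        vessel_density=0.0,
        void_depth=0.6,
        void_fraction_target=0.10,
        void_size_min_px=500,
        void_size_max_px=5000,
    )
    return generate_scene(cfg)
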