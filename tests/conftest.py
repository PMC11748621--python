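import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from chemimage.core_io import HyperspectralImage, WavenumberAxis
from chemimage.synthetic import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_axis() -> WavenumberAxis:
    return WavenumberAxis(np.linspace(1000.0, 1800.0, 40))


@pytest.fixture
def tiny_image(small_axis) -> HyperspectralImage:
    rng = np.random.default_rng(7)
    cube = rng.uniform(0.0, 1.0, size=(8, 8, 40))
    mask = np.ones((8, 8), dtype=bool)
    return HyperspectralImage(cube=cube, axis=small_axis, mask=mask,
                              image_id="img0", patient_id="p0")


@pytest.fixture(scope="session")
def desk_cohort():
    """Small noisy cohort with a strong class effect, shared across tests."""
    cfg = SynthConfig(
        n_patients=12, rows=24, cols=24, n_channels=24,
        effect_size=1.0, noise_sd=0.02, baseline_amplitude=0.05,
        recurrence_rate=0.34, seed=11,
    )
    cohort, images, manifest = generate_cohort(cfg)
    return cfg, cohort, images, manifest
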