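import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from canopytherm.cli_io import load_patch_table
from canopytherm.synthetic_scene import demo_scene_spec, generate_scene


@pytest.fixture(scope="session")
def patch_table():
    """Packaged 63-patch metric table of the Luoping built-up area."""
    return load_patch_table()


@pytest.fixture(scope="session")
def demo_scene():
    """Seeded five-class demo scene (sd 0.3 degC, >= 1e4 cells per class)."""
    return generate_scene(demo_scene_spec(seed=42))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Demo scene with zero within-class variance."""
    return generate_scene(demo_scene_spec(seed=7, lst_sd=0.0, ndvi_sd=0.0))
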