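import numpy as np
import pytest

from radarvitals import (
    RadarConfig,
    make_scene,
    simulate_recording,
    slow_time_cube,
)


@pytest.fixture(scope="session")
def small_config():
    """Cheap radar profile for tests.

    Fewer chirps and samples than the full device profile, but the ADC
    still spans the whole chirp so the range-bin spacing stays c/(2B).
    """
    return RadarConfig(n_samples=64, chirps_per_frame=4)


@pytest.fixture(scope="session")
def default_config():
    return RadarConfig()


@pytest.fixture(scope="session")
def slow_cube_factory(small_config):
    """Build a slow-time cube for a scene with the small profile, cached."""
    cache = {}

    def factory(distance=1.2, angle=20.0, duration=60.0, seed=0, **scene_kwargs):
        key = (distance, angle, duration, seed, tuple(sorted(scene_kwargs.items())))
        if key not in cache:
            scene = make_scene(distance, angle, seed=seed, **scene_kwargs)
            rec = simulate_recording(small_config, scene, duration, seed)
            cache[key] = (slow_time_cube(rec), scene)
        return cache[key]

    return factory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
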