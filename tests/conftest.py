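import numpy as np
import pytest

from evhotspot import MovieStack, SimulationConfig, simulate_movie


def single_event_config(event_class: str, **overrides) -> SimulationConfig:
    """One noiseless planted event of a given class in a quiet movie."""
    mix = {"stay": 0.0, "fade": 0.0, "flash": 0.0}
    mix[event_class] = 1.0
    defaults = dict(
        frames=60,
        n_events=1,
        class_mix=mix,
        amplitude_range=(100.0, 100.0),
        spot_sigma_range=(0.2, 0.2),
        noise_sigma=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def flash_movie():
    cfg = single_event_config("flash")
    movie, truth = simulate_movie(cfg)
    return cfg, movie, truth


def constant_movie(value: float = 50.0, frames: int = 10, side: int = 32) -> MovieStack:
    return MovieStack(np.full((frames, side, side), value))
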