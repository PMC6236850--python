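import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from expo4dct import (
    GridSpec,
    ScannerGeometry,
    acquire,
    assign_phases,
    generate_waveform,
    standard_phantom_suite,
)
from expo4dct.metrics import _auto_duration


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(64, 500.0)


@pytest.fixture(scope="session")
def small_geom():
    return ScannerGeometry(pitch=0.10, projections_per_rotation=180)


@pytest.fixture(scope="session")
def suite_objects():
    return standard_phantom_suite("si_sinusoid_grid").objects


@pytest.fixture(scope="session")
def static_objects(suite_objects):
    """The suite phantom with all motion frozen (zero excursion)."""
    from dataclasses import replace

    return tuple(replace(o, excursion=0.0) for o in suite_objects)


def make_tagged_sinogram(objects, geom, grid, bpm=10.0, amplitude=30.0, n_phases=10,
                         noise_sigma=0.0, seed=0, kind="sinusoidal"):
    """Acquire + phase-sort one run with an automatically sufficient duration."""
    bp = 60.0 / bpm
    duration = _auto_duration(geom, bp)
    wave = generate_waveform(kind, bpm, amplitude, duration, seed=seed)
    sino = acquire(objects, wave, geom, grid, noise_sigma=noise_sigma, seed=seed)
    return assign_phases(sino, n_phases)


@pytest.fixture(scope="session")
def moving_sino(suite_objects, small_geom, small_grid):
    """10 bpm sinusoid at pitch 0.10: breathing-period condition violated."""
    return make_tagged_sinogram(suite_objects, small_geom, small_grid)


@pytest.fixture(scope="session")
def frozen_sino(static_objects, small_geom, small_grid):
    """Same acquisition clock but a stationary phantom (oracle cases)."""
    return make_tagged_sinogram(static_objects, small_geom, small_grid)
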