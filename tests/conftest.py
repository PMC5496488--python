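import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from naadiff.protocol import default_protocol
from naadiff.tensor import FiberGeometry

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def straight_geometry():
    """Single-voxel geometry: fibers exactly parallel to the first gradient
    direction and perpendicular to the second."""
    return FiberGeometry(
        eigenvectors=np.array([[1.0, 0.0, 0.0]]),
        angles_deg=np.array([[0.0, 90.0]]),
        weights=np.array([1.0]),
    )


@pytest.fixture(scope="session")
def curved_geometry():
    """Nine-voxel geometry sweeping a 30-degree arc about the parallel
    direction (callosum-like macroscopic curvature)."""
    arc = np.linspace(-15.0, 15.0, 9)
    angles = np.column_stack([np.abs(arc), 90.0 - np.abs(arc) * 0.3])
    evecs = np.column_stack(
        [np.cos(np.deg2rad(arc)), np.sin(np.deg2rad(arc)), np.zeros(9)]
    )
    return FiberGeometry(eigenvectors=evecs, angles_deg=angles, weights=np.full(9, 1 / 9))


@pytest.fixture()
def noiseless_truth():
    from naadiff.synth import SpectralGroundTruth

    return SpectralGroundTruth(
        noise_sd=0.0,
        phase_jitter_sd_rad=0.0,
        freq_drift_hz_per_transient=0.0,
        eddy_amplitude_rad=0.0,
        amplitude_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_protocol(protocol):
    """Default conditions but few transients, for fast preprocessing tests."""
    from dataclasses import replace

    return replace(protocol, n_transients_per_condition=6, extra_transients_at_max_b=6)
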