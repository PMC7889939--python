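import matplotlib
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_channel_surface():
    """Two engineered channels (chains of Gaussian wells at y = +/-2)
    between end wells at (+/-3, 0), with a high ridge along y = 0."""
    from tetrafes.toy_systems import GaussianMixtureSurface

    centers = [[-3, 0], [3, 0]]
    for y in (2.0, -2.0):
        for x in (-1.5, 0.0, 1.5):
            centers.append([x, y])
    return GaussianMixtureSurface(centers, widths=0.7, log_weights=np.zeros(8),
                                  T0=300.0, name="two_channel")


@pytest.fixture(scope="session")
def quadratic_records():
    """Noiseless mean-force records on a 6-D quadratic bowl.

    Forces are the closed-form restrained-Gaussian mean forces, so the
    surface is exactly learnable and the records double as an oracle.
    """
    from tetrafes.meanforce import MeanForceRecord, closed_form_restrained_force
    from tetrafes.toy_systems import make_surface

    kappa, k = 0.5, 100.0
    surface = make_surface("quad_bowl_nd", n=6, kappa=kappa, center=np.full(6, 10.0))
    rng = np.random.default_rng(99)
    centers = rng.uniform(4.0, 16.0, (500, 6))
    records = [
        MeanForceRecord(
            c, closed_form_restrained_force(kappa, surface.center, k, c),
            np.zeros(6), spring=k, temperature=300.0, n_samples=1,
        )
        for c in centers
    ]
    return surface, records, kappa, k
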