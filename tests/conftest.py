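import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def dense_ellipse_pv(center, rx, ry, phi, shape, n=256):
    """Independent partial-volume oracle: per-voxel point counting.

    Written as an explicit per-voxel loop so it shares no code with the
    package's rasterizer.
    """
    px, py = center
    pv = np.zeros(shape)
    offs = (np.arange(n) + 0.5) / n - 0.5
    c, s = math.cos(phi), math.sin(phi)
    for i in range(shape[0]):
        for j in range(shape[1]):
            X, Y = np.meshgrid(i + offs, j + offs, indexing="ij")
            dx, dy = X - px, Y - py
            u = (c * dx + s * dy) / rx
            v = (-s * dx + c * dy) / ry
            pv[i, j] = float(((u * u + v * v) <= 1.0).mean())
    return pv


def mixture_slice(pv, chi_vein, chi_bg):
    """Exact two-compartment linear-mixture image."""
    return pv * chi_vein + (1.0 - pv) * chi_bg


def disk_section(center, radius, shape, chi_vein=0.30, chi_bg=0.0, n=256,
                 noise=0.0, rng=None):
    """CrossSection built from an exact mixture of a circular vein."""
    from scipy.ndimage import binary_dilation

    from veinicf.icf_core import CrossSection

    pv = dense_ellipse_pv(center, radius, radius, 0.0, shape, n)
    pixels = mixture_slice(pv, chi_vein, chi_bg)
    if noise > 0:
        rng = rng or np.random.default_rng(0)
        pixels = pixels + rng.normal(scale=noise, size=shape)
    init = binary_dilation(pv > 0, iterations=2)
    return CrossSection(pixels=pixels, init_mask=init, background_roi=~init), pv


@pytest.fixture(scope="session")
def full_study():
    """The scaled-down six-condition replication (25 phantoms/condition)."""
    from veinicf.experiments import run_all_conditions

    return run_all_conditions(base_seed=1, n_images=25, preset="desk")


@pytest.fixture(scope="session")
def systematic_study():
    """Noise-free systematic-error cases at the 256^3/radius-16 preset."""
    from veinicf.experiments import run_systematic

    return run_systematic(seed=1, preset="systematic")
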