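"""Shared fixtures and measurement helpers for the test suite.

Inference-heavy tests run on a reduced-sweep acquisition family
(sweep 237/2**m ppm, n_keep 4096/2**m complex points) that preserves the
30.6 ms fitted duration and the 0.0289 ppm/point resolution of the full
setup while shrinking the likelihood grid; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nmrdecon.spectra import Spectrum, preprocess
from nmrdecon.synthetic import AcquisitionParams, SimComponent, simulate_fid

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def scaled_acq(m: int, sigma_t: float = 0.0, center: float = -58.5) -> AcquisitionParams:
    """Sweep 237/2**m ppm, 4 * (4096/2**m) points, same dwell-resolution geometry."""
    return AcquisitionParams(
        sweep_width=237.0 / 2**m,
        n_points=4 * (4096 // 2**m),
        reference_shift=center,
        noise_sigma_t=sigma_t,
    )


def make_spec(components, m: int, sigma_t: float = 0.0, seed: int = 0) -> Spectrum:
    """Simulate and preprocess on the reduced family; N = 8192/2**m points."""
    acq = scaled_acq(m, sigma_t)
    fid = simulate_fid(list(components), acq, seed=seed)
    n_keep = 4096 // 2**m
    return preprocess(fid, n_keep=n_keep, n_total=2 * n_keep)


def measure_fwhm_ppm(ppm: np.ndarray, y: np.ndarray) -> float:
    """Half-height full width via linear interpolation around the maximum."""
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = i
    while left > 0 and y[left] > half:
        left -= 1
    right = i
    while right < y.size - 1 and y[right] > half:
        right += 1

    def crossing(i0: int, i1: int) -> float:
        return ppm[i0] + (half - y[i0]) * (ppm[i1] - ppm[i0]) / (y[i1] - y[i0])

    return abs(crossing(left, left + 1) - crossing(right - 1, right))


def integrate_area(spec: Spectrum) -> float:
    """Numerical area on the ppm axis (axis is descending, hence the sign)."""
    return float(-np.trapezoid(spec.intensity, spec.ppm_axis))


@pytest.fixture(scope="session")
def narrow_noise_free_spec() -> Spectrum:
    """Noise-free 50 Hz line, area 150, on the m=3 reduced grid (N=1024)."""
    return make_spec([SimComponent(150.0, -58.3, 50.0)], m=3)
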