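"""Lorentzian mixture model, uniform box priors, and the Gaussian likelihood.

Each signal k is an absorptive Lorentzian parameterised by
theta_k = {M_k, omega_k, beta_k}: M_k is the peak area (the macroscopic
magnetisation, arbitrary units), omega_k the chemical shift in ppm, and
beta_k the common logarithm of the full width at half maximum in Hz.
The spectrum model is the sum of the K component lineshapes, and spectral
noise is white Gaussian with a fixed, externally estimated sigma, so the
log likelihood is the usual sum of per-point Gaussian terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

from .spectra import Spectrum

__all__ = [
    "ComponentParams",
    "ParamSet",
    "PriorBox",
    "lorentzian_component",
    "mixture_spectrum",
    "mixture_batch",
    "log_likelihood",
    "log_likelihood_batch",
    "log_prior",
]


@dataclass(frozen=True)
class ComponentParams:
    """One signal's parameters: area ``M`` (a.u.), shift ``omega`` (ppm),
    ``beta`` = log10(FWHM in Hz)."""

    M: float
    omega: float
    beta: float

    @property
    def fwhm_hz(self) -> float:
        return float(10.0 ** self.beta)

    def as_array(self) -> np.ndarray:
        return np.array([self.M, self.omega, self.beta], dtype=float)


@dataclass(frozen=True)
class ParamSet:
    """An ordered set of K components; K = 0 is the pure-noise model."""

    components: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def K(self) -> int:
        return len(self.components)

    def as_array(self) -> np.ndarray:
        """(K, 3) array of [M, omega, beta] rows."""
        if self.K == 0:
            return np.empty((0, 3), dtype=float)
        return np.stack([c.as_array() for c in self.components])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParamSet":
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return cls(tuple(ComponentParams(*row) for row in arr))

    def to_json(self) -> str:
        return json.dumps(
            {
                "K": self.K,
                "components": [
                    {"M": c.M, "omega_ppm": c.omega, "beta_log10hz": c.beta}
                    for c in self.components
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ParamSet":
        obj = json.loads(text)
        return cls(
            tuple(
                ComponentParams(c["M"], c["omega_ppm"], c["beta_log10hz"])
                for c in obj["components"]
            )
        )


@dataclass(frozen=True)
class PriorBox:
    """Independent uniform priors on (M, omega, beta) for every component.

    Defaults: M in [0, 700] a.u., omega in [-62, -55] ppm, beta in [1, 4]
    log10(Hz) — i.e. FWHM between 10 Hz and 10,000 Hz.
    """

    m_range: tuple = (0.0, 700.0)
    omega_range: tuple = (-62.0, -55.0)
    beta_range: tuple = (1.0, 4.0)

    def __post_init__(self) -> None:
        for name in ("m_range", "omega_range", "beta_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy lower < upper, got {lo}, {hi}")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.m_range[0], self.omega_range[0], self.beta_range[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.m_range[1], self.omega_range[1], self.beta_range[1]])

    @property
    def log_volume(self) -> float:
        return float(np.sum(np.log(self.upper - self.lower)))

    def contains(self, arr: np.ndarray) -> np.ndarray:
        """Elementwise in-box test for trailing-axis (..., K, 3) parameters,
        reduced over the component and parameter axes."""
        arr = np.asarray(arr, dtype=float)
        ok = (arr >= self.lower) & (arr <= self.upper)
        return ok.all(axis=(-1, -2))

    def sample(self, rng: np.random.Generator, K: int, size: int) -> np.ndarray:
        """(size, K, 3) iid uniform draws from the box."""
        return rng.uniform(self.lower, self.upper, size=(size, K, 3))


def lorentzian_component(
    x: np.ndarray, theta: ComponentParams, spectrometer_freq: float
) -> np.ndarray:
    """Area-normalised absorptive Lorentzian on a ppm grid.

    f(x) = (M/pi) * (gamma/2) / ((x - omega)^2 + (gamma/2)^2) with
    gamma = 10**beta / spectrometer_freq, the FWHM converted from Hz to ppm.
    Integrating f over x (ppm) gives M.
    """
    if spectrometer_freq <= 0:
        raise ValueError("spectrometer_freq must be positive (MHz)")
    x = np.asarray(x, dtype=float)
    gamma = theta.fwhm_hz / spectrometer_freq  # FWHM in ppm
    hw = gamma / 2.0
    return (theta.M / np.pi) * hw / ((x - theta.omega) ** 2 + hw**2)


def mixture_spectrum(
    x: np.ndarray, params: ParamSet, spectrometer_freq: float
) -> np.ndarray:
    """Sum of the K component Lorentzians; K = 0 gives zeros."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for comp in params.components:
        out += lorentzian_component(x, comp, spectrometer_freq)
    return out


def mixture_batch(
    x: np.ndarray, thetas: np.ndarray, spectrometer_freq: float
) -> np.ndarray:
    """Vectorised mixtures for a batch of parameter sets.

    ``thetas`` has shape (W, K, 3); the result has shape (W, N).  This is the
    hot path of the samplers, so everything stays as one fused broadcast.
    """
    if spectrometer_freq <= 0:
        raise ValueError("spectrometer_freq must be positive (MHz)")
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 3:
        raise ValueError("thetas must have shape (W, K, 3)")
    W, K, _ = thetas.shape
    if K == 0:
        return np.zeros((W, np.asarray(x).size))
    M = thetas[:, :, 0][:, :, None]           # (W, K, 1)
    omega = thetas[:, :, 1][:, :, None]
    hw = (10.0 ** thetas[:, :, 2][:, :, None]) / (2.0 * spectrometer_freq)
    dx = x[None, None, :] - omega             # (W, K, N)
    comps = (M / np.pi) * hw / (dx * dx + hw * hw)
    return comps.sum(axis=1)


def log_likelihood(spec: Spectrum, params: ParamSet) -> float:
    """Gaussian log likelihood of the spectrum under the mixture model.

    sum_n [ -0.5*log(2*pi*sigma^2) - (y_n - F(x_n))^2 / (2*sigma^2) ]
    with sigma = ``spec.noise_sigma`` held fixed (plug-in estimate).
    """
    sigma = spec.noise_sigma
    if sigma <= 0:
        raise ValueError("spec.noise_sigma must be positive")
    f = mixture_spectrum(spec.ppm_axis, params, spec.meta["spectrometer_freq"])
    resid = spec.intensity - f
    n = spec.n_points
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma**2)
        - np.sum(resid**2) / (2.0 * sigma**2)
    )


def log_likelihood_batch(spec: Spectrum, thetas: np.ndarray) -> np.ndarray:
    """Vectorised :func:`log_likelihood` for (W, K, 3) parameter batches."""
    sigma = spec.noise_sigma
    if sigma <= 0:
        raise ValueError("spec.noise_sigma must be positive")
    F = mixture_batch(spec.ppm_axis, thetas, spec.meta["spectrometer_freq"])
    resid = spec.intensity[None, :] - F
    n = spec.n_points
    return -0.5 * n * np.log(2.0 * np.pi * sigma**2) - np.einsum(
        "wn,wn->w", resid, resid
    ) / (2.0 * sigma**2)


def log_prior(params: ParamSet | np.ndarray, box: PriorBox) -> float:
    """Log of the product of uniform densities; -inf outside the box.

    K = 0 has no parameters, hence log prior 0.
    """
    arr = params.as_array() if isinstance(params, ParamSet) else np.asarray(params)
    arr = np.atleast_2d(arr)
    K = arr.shape[0]
    if K == 0:
        return 0.0
    if not bool(box.contains(arr)):
        return -np.inf
    return -K * box.log_volume
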