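"""FID containers and the preprocessing chain that turns a raw FID into a spectrum.

The pipeline mirrors standard 1D NMR practice for low-SNR data: digital-filter
group-delay removal, truncation of the noisy FID tail, zero-filling, an
unapodized Fourier transform keeping the real (absorptive) part, robust
polynomial baseline correction, and a noise-level estimate taken from the FID
tail where the signal has fully decayed.

Conventions
-----------
* ``sweep_width`` is in ppm; the spectral width in Hz is
  ``sweep_width * spectrometer_freq`` (MHz), so the dwell time is
  ``1 / (sweep_width * spectrometer_freq)`` seconds.
* ``reference_shift`` is the ppm value at the centre of the spectral window
  (the carrier).  Placing the carrier on the TFA reference gives the
  conventional -76.55 ppm setting for 19F work.
* The ppm axis runs downfield-to-upfield (descending values left to right).
* No phase correction is applied anywhere: the contract covers purely
  absorptive (zero-phase) data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "RawFID",
    "Spectrum",
    "remove_digital_filter",
    "truncate_and_zero_fill",
    "transform_to_spectrum",
    "baseline_correct",
    "estimate_noise_sigma",
    "apodize_for_display",
    "read_fid_container",
    "write_fid_container",
    "write_spectrum",
    "preprocess",
    "TFA_REFERENCE_PPM",
]

#: Chemical-shift reference for 19F: trifluoroacetic acid.
TFA_REFERENCE_PPM = -76.55


@dataclass(frozen=True)
class RawFID:
    """A 1D complex free induction decay with its acquisition metadata.

    Parameters
    ----------
    points
        Ordered complex time-domain samples (arbitrary intensity units).
    spectrometer_freq
        Larmor frequency of the observed nucleus in MHz.
    sweep_width
        Spectral width in ppm.
    group_delay
        Digital-filter group delay in samples (fractional allowed, >= 0).
    reference_shift
        ppm value at the carrier (centre of the spectral window).
    scans
        Number of accumulated transients (metadata only).
    """

    points: np.ndarray
    spectrometer_freq: float = 565.0
    sweep_width: float = 237.0
    group_delay: float = 0.0
    reference_shift: float = TFA_REFERENCE_PPM
    scans: int = 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.complex128)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size == 0:
            raise ValueError("FID points must be a non-empty 1D array")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be positive (ppm)")
        if self.spectrometer_freq <= 0:
            raise ValueError("spectrometer_freq must be positive (MHz)")
        if self.group_delay < 0:
            raise ValueError(
                f"group_delay must be >= 0 samples, got {self.group_delay}"
            )
        if not math.isfinite(self.dwell_time) or self.dwell_time <= 0:
            raise ValueError("dwell time is not finite and positive")

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @property
    def sweep_width_hz(self) -> float:
        return self.sweep_width * self.spectrometer_freq

    @property
    def dwell_time(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / (self.sweep_width * self.spectrometer_freq)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at t = 0."""
        return np.arange(self.n_points) * self.dwell_time

    @property
    def duration(self) -> float:
        return self.n_points * self.dwell_time


@dataclass(frozen=True)
class Spectrum:
    """Real spectral intensities on a descending ppm axis.

    ``noise_sigma`` is the standard deviation of the spectral noise in the
    same arbitrary units as ``intensity``; it is the plug-in sigma of the
    Gaussian likelihood used downstream.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    noise_sigma: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_axis, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm_axis", ppm)
        object.__setattr__(self, "intensity", inten)
        if ppm.shape != inten.shape or ppm.ndim != 1:
            raise ValueError("ppm_axis and intensity must be 1D of equal length")
        d = np.diff(ppm)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ppm_axis must be strictly monotonic")

    @property
    def n_points(self) -> int:
        return int(self.ppm_axis.size)


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------

def remove_digital_filter(fid: RawFID) -> RawFID:
    """Remove the digital-filter group-delay artifact, restoring the time origin.

    The integer part of the delay is removed by a circular sample shift; the
    fractional remainder by a linear phase ramp in the frequency domain (an
    exact sub-sample time shift).  The length of the FID is preserved.

    Returns a FID with ``group_delay == 0``.
    """
    g = float(fid.group_delay)
    if g < 0:
        raise ValueError(f"group_delay must be >= 0, got {g}")
    if g == 0:
        return fid
    pts = fid.points
    g_int = int(np.floor(g))
    frac = g - g_int
    if g_int:
        pts = np.roll(pts, -g_int)
    if frac:
        f = np.fft.fftfreq(pts.size)  # cycles per sample
        pts = np.fft.ifft(np.fft.fft(pts) * np.exp(2j * np.pi * f * frac))
    return replace(fid, points=pts, group_delay=0.0)


def truncate_and_zero_fill(fid: RawFID, n_keep: int = 4096, n_total: int = 8192) -> RawFID:
    """Keep the first ``n_keep`` complex points and zero-fill to ``n_total``.

    Truncating before the noise-dominated tail and zero-filling interpolates
    the spectrum without adding information (or energy).
    """
    if n_keep <= 0:
        raise ValueError("n_keep must be positive")
    if n_keep > fid.n_points:
        raise ValueError(
            f"n_keep={n_keep} exceeds available points ({fid.n_points})"
        )
    if n_total < n_keep:
        raise ValueError(f"n_total={n_total} must be >= n_keep={n_keep}")
    out = np.zeros(n_total, dtype=np.complex128)
    out[:n_keep] = fid.points[:n_keep]
    return replace(fid, points=out)


def transform_to_spectrum(fid: RawFID, noise_sigma: float = 0.0) -> Spectrum:
    """Unnormalized DFT of the FID; real part on a descending ppm axis.

    No apodization is applied.  The axis is referenced so that the carrier
    sits at ``fid.reference_shift`` ppm in the centre of the window.
    """
    n = fid.n_points
    spec = np.fft.fftshift(np.fft.fft(fid.points))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_time))  # Hz
    ppm = fid.reference_shift + freqs / fid.spectrometer_freq
    # descending ppm (downfield on the left), NMR convention
    meta = {
        "spectrometer_freq": fid.spectrometer_freq,
        "sweep_width": fid.sweep_width,
        "reference_shift": fid.reference_shift,
        "n_points": n,
        "scans": fid.scans,
    }
    return Spectrum(
        ppm_axis=ppm[::-1].copy(),
        intensity=spec.real[::-1].copy(),
        noise_sigma=float(noise_sigma),
        meta=meta,
    )


def baseline_correct(spec: Spectrum, order: int = 4, max_iter: int = 10) -> Spectrum:
    """Subtract a robustly fitted polynomial baseline of the given order.

    The fit iteratively down-weights signal regions: points lying more than
    3 running scale units *above* the current fit (peaks are positive in
    absorptive spectra) are excluded and the polynomial refitted, up to
    ``max_iter`` passes or until the mask stabilises.  The running scale is
    the MAD-based robust sigma of the residuals, so tall peaks do not
    inflate the exclusion threshold.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    n = spec.n_points
    if order >= n:
        raise ValueError(f"order={order} must be < number of points ({n})")
    # fit in a scaled coordinate for conditioning
    x = np.linspace(-1.0, 1.0, n)
    y = spec.intensity
    keep = np.ones(n, dtype=bool)
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    for _ in range(max_iter):
        base = np.polynomial.polynomial.polyval(x, coeffs)
        resid = y - base
        kept = resid[keep]
        sigma = 1.4826 * np.median(np.abs(kept - np.median(kept)))
        if sigma == 0:
            break
        new_keep = resid <= 3.0 * sigma
        if new_keep.sum() <= order + 1:
            break
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep
        coeffs = np.polynomial.polynomial.polyfit(x[keep], y[keep], order)
    base = np.polynomial.polynomial.polyval(x, coeffs)
    return replace(spec, intensity=y - base)


def estimate_noise_sigma(
    fid: RawFID,
    tail_start: float = 0.0306,
    n_keep: int = 4096,
    min_tail_points: int = 64,
) -> float:
    """Spectral-domain noise sigma implied by the FID tail after ``tail_start`` s.

    The tail (where the signal has fully decayed) gives the per-quadrature
    time-domain noise standard deviation sigma_t.  With an unnormalized
    forward DFT and complex white noise confined to the first ``n_keep``
    points of the transform input, each spectral bin's real part has variance
    ``n_keep * sigma_t**2``; the returned value is ``sqrt(n_keep) * sigma_t``.
    """
    t = fid.times
    tail = fid.points[t >= tail_start]
    if tail.size < min_tail_points:
        raise ValueError(
            f"FID tail after {tail_start * 1e3:.1f} ms has only {tail.size} points "
            f"(need >= {min_tail_points}); acquire a longer FID"
        )
    var_q = 0.5 * (np.var(tail.real) + np.var(tail.imag))
    return float(np.sqrt(n_keep * var_q))


def apodize_for_display(fid: RawFID, lb: float = 200.0) -> RawFID:
    """Exponential line-broadening window exp(-pi * lb * t); display only.

    Convolving an absorptive Lorentzian of FWHM G with this window yields a
    Lorentzian of FWHM G + lb.  Never applied before fitting.
    """
    if lb < 0:
        raise ValueError("line broadening must be >= 0 Hz")
    if lb == 0:
        return fid
    w = np.exp(-np.pi * lb * fid.times)
    return replace(fid, points=fid.points * w)


def preprocess(
    fid: RawFID,
    n_keep: int = 4096,
    n_total: int = 8192,
    baseline_order: int = 4,
    tail_start: float = 0.0306,
) -> Spectrum:
    """Full preprocessing chain: filter removal, sigma estimate, truncate,
    zero-fill, transform, baseline correction.

    The noise sigma is estimated from the filter-corrected FID tail and
    attached to the returned :class:`Spectrum`.
    """
    fid = remove_digital_filter(fid)
    sigma = estimate_noise_sigma(fid, tail_start=tail_start, n_keep=n_keep)
    fid = truncate_and_zero_fill(fid, n_keep=n_keep, n_total=n_total)
    spec = transform_to_spectrum(fid, noise_sigma=sigma)
    return baseline_correct(spec, order=baseline_order)


# ---------------------------------------------------------------------------
# portable text container
# ---------------------------------------------------------------------------

_MANDATORY_KEYS = (
    "n_points",
    "spectrometer_freq_mhz",
    "sweep_width_ppm",
    "group_delay",
    "reference_shift_ppm",
    "scans",
)


def write_fid_container(fid: RawFID, path: Union[str, Path]) -> None:
    """Write the native text container: ``key = value`` header, blank line,
    then CSV rows ``real,imag`` at full double precision."""
    path = Path(path)
    lines = [
        f"n_points = {fid.n_points}",
        f"spectrometer_freq_mhz = {fid.spectrometer_freq!r}",
        f"sweep_width_ppm = {fid.sweep_width!r}",
        f"group_delay = {fid.group_delay!r}",
        f"reference_shift_ppm = {fid.reference_shift!r}",
        f"scans = {fid.scans}",
    ]
    body = "\n".join(
        f"{float(p.real)!r},{float(p.imag)!r}" for p in fid.points
    )
    path.write_text("\n".join(lines) + "\n\n" + body + "\n", encoding="utf-8")


def read_fid_container(path: Union[str, Path]) -> RawFID:
    """Read the native text container written by :func:`write_fid_container`."""
    text = Path(path).read_text(encoding="utf-8")
    header, _, body = text.partition("\n\n")
    meta: dict[str, str] = {}
    for line in header.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            meta[key.strip()] = val.strip()
    missing = [k for k in _MANDATORY_KEYS if k not in meta]
    if missing:
        raise ValueError(f"FID container missing mandatory keys: {missing}")
    rows = body.strip().splitlines()
    data = np.array(
        [[float(v) for v in row.split(",")] for row in rows], dtype=float
    )
    pts = data[:, 0] + 1j * data[:, 1]
    n = int(meta["n_points"])
    if n != pts.size:
        raise ValueError(f"header n_points={n} but {pts.size} rows present")
    return RawFID(
        points=pts,
        spectrometer_freq=float(meta["spectrometer_freq_mhz"]),
        sweep_width=float(meta["sweep_width_ppm"]),
        group_delay=float(meta["group_delay"]),
        reference_shift=float(meta["reference_shift_ppm"]),
        scans=int(meta["scans"]),
    )


def write_spectrum(spec: Spectrum, path: Union[str, Path]) -> None:
    """Export ``ppm,intensity`` CSV plus a JSON sidecar with noise_sigma/meta."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ppm,intensity\n")
        for p, i in zip(spec.ppm_axis, spec.intensity):
            fh.write(f"{float(p)!r},{float(i)!r}\n")
    sidecar = {"noise_sigma": spec.noise_sigma, "meta": spec.meta}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )
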