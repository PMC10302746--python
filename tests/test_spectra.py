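"""Preprocessing chain: filter removal, truncation, transform, baseline, noise."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import measure_fwhm_ppm, scaled_acq
from nmrdecon.spectra import (
    RawFID,
    Spectrum,
    apodize_for_display,
    baseline_correct,
    estimate_noise_sigma,
    preprocess,
    read_fid_container,
    remove_digital_filter,
    transform_to_spectrum,
    truncate_and_zero_fill,
    write_fid_container,
)
from nmrdecon.synthetic import SimComponent, paper_acquisition, simulate_fid
from dataclasses import replace


def _plain_fid(n=1024, seed=0, **kw):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2)) @ np.array([1, 1j])
    return RawFID(points=pts, **kw)


class TestRawFID:
    def test_metadata_validation(self):
        with pytest.raises(ValueError):
            _plain_fid(sweep_width=-1.0)
        with pytest.raises(ValueError):
            _plain_fid(spectrometer_freq=0.0)
        with pytest.raises(ValueError):
            _plain_fid(group_delay=-2.0)

    def test_acquisition_identity(self):
        """4096 complex points at 237 ppm / 565 MHz span 30.6 ms of signal."""
        fid = RawFID(points=np.zeros(4096, complex))
        assert 4096 * fid.dwell_time * 1e3 == pytest.approx(30.6, abs=0.05)


class TestDigitalFilter:
    def test_zero_delay_is_identity(self):
        fid = _plain_fid()
        assert remove_digital_filter(fid) is fid

    def test_integer_delay_round_trip(self):
        """A circularly shifted FID is restored exactly."""
        fid = _plain_fid(group_delay=0.0)
        shifted = replace(fid, points=np.roll(fid.points, 7), group_delay=7.0)
        fixed = remove_digital_filter(shifted)
        assert fixed.group_delay == 0.0
        np.testing.assert_allclose(fixed.points, fid.points, atol=1e-12)

    def test_fractional_delay_restores_peak_position(self):
        comp = [SimComponent(100.0, -57.8, 120.0)]
        acq = scaled_acq(3)
        clean = simulate_fid(comp, acq)
        delayed = simulate_fid(comp, replace(acq, group_delay=5.5))
        fixed = remove_digital_filter(delayed)
        ref = transform_to_spectrum(truncate_and_zero_fill(clean, 512, 1024))
        got = transform_to_spectrum(truncate_and_zero_fill(fixed, 512, 1024))
        i_ref, i_got = np.argmax(ref.intensity), np.argmax(got.intensity)
        assert abs(int(i_ref) - int(i_got)) <= 1


class TestTruncateZeroFill:
    def test_paper_shape(self):
        fid = _plain_fid(65_536)
        out = truncate_and_zero_fill(fid, 4096, 8192)
        assert out.n_points == 8192
        assert np.all(out.points[4096:] == 0)
        np.testing.assert_array_equal(out.points[:4096], fid.points[:4096])

    def test_identity_when_keeping_everything(self):
        fid = _plain_fid(256)
        out = truncate_and_zero_fill(fid, 256, 256)
        np.testing.assert_array_equal(out.points, fid.points)

    def test_errors_name_both_counts(self):
        fid = _plain_fid(128)
        with pytest.raises(ValueError, match="129.*128"):
            truncate_and_zero_fill(fid, 129, 256)
        with pytest.raises(ValueError):
            truncate_and_zero_fill(fid, 64, 32)

    @given(
        n=st.integers(16, 256),
        n_keep_frac=st.floats(0.1, 1.0),
        pad=st.integers(0, 64),
        seed=st.integers(0, 10),
    )
    def test_energy_never_increases(self, n, n_keep_frac, pad, seed):
        fid = _plain_fid(n, seed=seed)
        n_keep = max(1, int(n * n_keep_frac))
        out = truncate_and_zero_fill(fid, n_keep, n_keep + pad)
        e_in = np.sum(np.abs(fid.points) ** 2)
        e_out = np.sum(np.abs(out.points) ** 2)
        assert e_out <= e_in + 1e-9 * e_in
        assert e_out == pytest.approx(
            np.sum(np.abs(fid.points[:n_keep]) ** 2), rel=1e-12
        )


class TestTransform:
    def test_zero_in_zero_out(self):
        spec = transform_to_spectrum(RawFID(points=np.zeros(256, complex)))
        assert np.all(spec.intensity == 0)

    def test_linearity(self):
        a, b = _plain_fid(256, seed=1), _plain_fid(256, seed=2)
        both = replace(a, points=a.points + b.points)
        lhs = transform_to_spectrum(both).intensity
        rhs = transform_to_spectrum(a).intensity + transform_to_spectrum(b).intensity
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_axis_geometry(self):
        fid = _plain_fid(512, sweep_width=100.0, spectrometer_freq=565.0)
        spec = transform_to_spectrum(fid)
        d = np.diff(spec.ppm_axis)
        assert np.all(d < 0)  # descending, NMR convention
        np.testing.assert_allclose(-d, 100.0 / 512, rtol=1e-12)
        assert spec.ppm_axis[0] - spec.ppm_axis[-1] == pytest.approx(
            100.0 * (512 - 1) / 512
        )

    def test_lorentzian_fwhm_survives_transform(self):
        """exp(-pi*G*t) at an offset transforms to a line of FWHM G."""
        acq = scaled_acq(2)  # N = 2048, 0.0289 ppm/pt
        fid = simulate_fid([SimComponent(100.0, -57.5, 200.0)], acq)
        spec = transform_to_spectrum(truncate_and_zero_fill(fid, 1024, 2048))
        width_hz = measure_fwhm_ppm(spec.ppm_axis, spec.intensity) * 565.0
        assert width_hz == pytest.approx(200.0, abs=237.0 / 4 / 2048 * 565.0)


class TestBaseline:
    def _quartic_spec(self, n=1024):
        x = np.linspace(-1, 1, n)
        y = 5.0 + 3 * x - 2 * x**2 + x**3 + 4 * x**4
        ppm = np.linspace(-40, -70, n)
        return Spectrum(ppm_axis=ppm, intensity=y, noise_sigma=1.0)

    def test_exact_quartic_removed(self):
        spec = self._quartic_spec()
        out = baseline_correct(spec, order=4)
        rng_in = spec.intensity.max() - spec.intensity.min()
        assert np.max(np.abs(out.intensity)) < 1e-6 * rng_in

    def test_narrow_peak_area_preserved(self):
        # full 237 ppm sweep: the 80 Hz line and its tails occupy <5% of points
        acq = paper_acquisition()
        fid = simulate_fid([SimComponent(150.0, -58.3, 80.0)], acq)
        spec = transform_to_spectrum(truncate_and_zero_fill(fid, 4096, 8192))
        x = np.linspace(-1, 1, spec.n_points)
        baseline = 10.0 - 4 * x + 6 * x**2 - 2 * x**4
        dirty = replace(spec, intensity=spec.intensity + baseline)
        clean = baseline_correct(dirty, order=4)
        area = float(-np.trapezoid(clean.intensity, clean.ppm_axis))
        assert area == pytest.approx(150.0, rel=0.02)

    def test_near_idempotent(self):
        spec = self._quartic_spec()
        once = baseline_correct(spec, order=4)
        twice = baseline_correct(once, order=4)
        scale = np.max(np.abs(spec.intensity)) + 1.0
        assert np.max(np.abs(twice.intensity - once.intensity)) < 1e-8 * scale

    def test_order_bounds(self):
        spec = self._quartic_spec(16)
        with pytest.raises(ValueError):
            baseline_correct(spec, order=-1)
        with pytest.raises(ValueError):
            baseline_correct(spec, order=16)


class TestNoiseSigma:
    def test_zero_tail_gives_zero(self):
        fid = _plain_fid(8192)
        pts = fid.points.copy()
        pts[fid.times >= 0.0306] = 0.0
        assert estimate_noise_sigma(replace(fid, points=pts)) == 0.0

    def test_amplitude_linearity(self):
        fid = _plain_fid(8192, seed=3)
        s1 = estimate_noise_sigma(fid)
        s2 = estimate_noise_sigma(replace(fid, points=2.0 * fid.points))
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)

    def test_tail_too_short(self):
        fid = _plain_fid(256)  # 237 ppm sweep: 256 pts ~ 1.9 ms, no tail
        with pytest.raises(ValueError, match="acqui"):
            estimate_noise_sigma(fid)

    def test_monte_carlo_consistency(self):
        """sqrt(n_keep)*sigma_t predicts the spectral real-part SD (50 seeds)."""
        acq = paper_acquisition(noise_sigma_t=1.0)
        predicted, empirical = [], []
        for seed in range(50):
            fid = simulate_fid([], acq, seed=seed)
            predicted.append(estimate_noise_sigma(fid, n_keep=4096))
            spec = transform_to_spectrum(truncate_and_zero_fill(fid, 4096, 8192))
            empirical.append(np.std(spec.intensity))
        assert np.mean(predicted) == pytest.approx(np.mean(empirical), rel=0.05)
        # the estimator should sit at sqrt(4096) for unit sigma_t
        assert np.mean(predicted) == pytest.approx(64.0, rel=0.02)


class TestApodization:
    def test_zero_lb_identity_and_t0_weight(self):
        fid = _plain_fid(512)
        assert apodize_for_display(fid, 0.0) is fid
        out = apodize_for_display(fid, 150.0)
        assert out.points[0] == fid.points[0]  # t = 0 weight is 1

    def test_width_addition(self):
        """Exponential LB adds its decay constant to a Lorentzian's FWHM."""
        acq = scaled_acq(2)
        fid = simulate_fid([SimComponent(100.0, -57.5, 150.0)], acq)
        lb = 200.0
        spec = transform_to_spectrum(
            truncate_and_zero_fill(apodize_for_display(fid, lb), 1024, 2048)
        )
        width_hz = measure_fwhm_ppm(spec.ppm_axis, spec.intensity) * 565.0
        assert width_hz == pytest.approx(150.0 + lb, abs=237.0 / 4 / 2048 * 565.0)


class TestContainer:
    def test_round_trip_bit_exact(self, tmp_path):
        fid = _plain_fid(300, seed=9, group_delay=3.5, scans=1024)
        path = tmp_path / "fid.csv"
        write_fid_container(fid, path)
        back = read_fid_container(path)
        np.testing.assert_array_equal(back.points, fid.points)
        assert back.spectrometer_freq == fid.spectrometer_freq
        assert back.sweep_width == fid.sweep_width
        assert back.group_delay == fid.group_delay
        assert back.reference_shift == fid.reference_shift
        assert back.scans == fid.scans

    def test_missing_mandatory_key_rejected(self, tmp_path):
        fid = _plain_fid(16)
        path = tmp_path / "fid.csv"
        write_fid_container(fid, path)
        text = path.read_text().replace("spectrometer_freq_mhz", "zapped")
        path.write_text(text)
        with pytest.raises(ValueError, match="spectrometer_freq_mhz"):
            read_fid_container(path)

    def test_file_and_memory_paths_agree(self, tmp_path):
        acq = scaled_acq(3, sigma_t=0.5)
        fid = simulate_fid([SimComponent(120.0, -58.0, 100.0)], acq, seed=4)
        path = tmp_path / "sim.fid.csv"
        write_fid_container(fid, path)
        spec_mem = preprocess(fid, n_keep=512, n_total=1024)
        spec_file = preprocess(read_fid_container(path), n_keep=512, n_total=1024)
        np.testing.assert_array_equal(spec_mem.intensity, spec_file.intensity)
        assert spec_mem.noise_sigma == spec_file.noise_sigma
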