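import numpy as np
import pytest
from hypothesis import given, strategies as st

from nmrfinger.processing import (FID, BinnedMatrix, CalibrationError, Spectrum,
                                  apodize_transform, bin_edges, bin_spectra,
                                  bin_spectrum, calibrate, normalize_matrix,
                                  read_spectrum_txt, write_spectrum_txt)


def lorentzian(ppm, center, hw):
    return (hw / np.pi) / ((ppm - center) ** 2 + hw ** 2)


def measure_fwhm_hz(spec: Spectrum, carrier_mhz: float) -> float:
    asc_ppm, asc_int = spec.ppm[::-1], spec.intensity[::-1]
    i_max = np.argmax(asc_int)
    half = asc_int[i_max] / 2
    left = np.interp(half, asc_int[: i_max + 1], asc_ppm[: i_max + 1])
    right = np.interp(half, asc_int[i_max:][::-1], asc_ppm[i_max:][::-1])
    return (right - left) * carrier_mhz


class TestApodizeTransform:
    """An exponentially decaying FID transforms to a Lorentzian of width 1/(pi T2)."""

    T2 = 0.3          # s -> natural FWHM 1.0610 Hz
    SW = 6000.0       # Hz
    N = 65536         # grid step SW/N = 0.0916 Hz

    def _fid(self):
        t = np.arange(self.N) / self.SW
        pts = np.exp(2j * np.pi * 600.0 * t - t / self.T2)
        return FID(pts, dwell_time=1 / self.SW, carrier_mhz=600.13, reference_ppm=4.7)

    def test_natural_linewidth(self):
        spec = apodize_transform(self._fid(), line_broadening=0.0)
        expected = 1 / (np.pi * self.T2)
        assert measure_fwhm_hz(spec, 600.13) == pytest.approx(expected, abs=self.SW / self.N)

    def test_line_broadening_adds_to_width(self):
        lb = 0.3
        w0 = measure_fwhm_hz(apodize_transform(self._fid(), 0.0), 600.13)
        w1 = measure_fwhm_hz(apodize_transform(self._fid(), lb), 600.13)
        assert w1 - w0 == pytest.approx(lb, abs=self.SW / self.N)

    def test_peak_lands_at_offset_ppm(self):
        spec = apodize_transform(self._fid())
        assert spec.ppm[np.argmax(spec.intensity)] == pytest.approx(4.7 + 600 / 600.13, abs=1e-3)

    def test_zero_fid_gives_zero_spectrum(self):
        spec = apodize_transform(FID(np.zeros(1024, complex), 1 / 6000))
        assert not np.any(spec.intensity)

    def test_negative_lb_rejected(self):
        with pytest.raises(ValueError, match="line_broadening"):
            apodize_transform(self._fid(), -0.1)


class TestCalibrate:
    axis = np.linspace(10.5, -0.5, 2 ** 15)

    def _doublet(self, center, split=0.0063, hw=0.00125):
        inten = lorentzian(self.axis, center - split / 2, hw) + lorentzian(
            self.axis, center + split / 2, hw)
        return Spectrum(self.axis, inten)

    def test_shifts_offset_doublet_back(self):
        cal, shift = calibrate(self._doublet(5.30))
        assert shift == pytest.approx(-0.06, abs=2e-3)
        window = (cal.ppm > 5.15) & (cal.ppm < 5.35)
        top = cal.ppm[window][np.argmax(cal.intensity[window])]
        assert top == pytest.approx(5.24, abs=5e-3)

    def test_already_calibrated_is_identity(self):
        cal, shift = calibrate(self._doublet(5.24))
        assert shift == pytest.approx(0.0, abs=1e-3)

    def test_flat_spectrum_fails(self):
        with pytest.raises(CalibrationError):
            calibrate(Spectrum(self.axis, np.ones_like(self.axis)))

    def test_window_not_covered_fails(self):
        narrow = Spectrum(np.linspace(3.0, 0.2, 500), np.ones(500))
        with pytest.raises(CalibrationError):
            calibrate(narrow)


class TestBinning:
    def test_default_layout_has_490_bins(self):
        left, right = bin_edges()
        assert left.size == 490
        assert left[0] == pytest.approx(10.0)
        assert right[-1] == pytest.approx(0.2)
        np.testing.assert_allclose(left - right, 0.02, atol=1e-12)
        np.testing.assert_allclose(left[1:], right[:-1], atol=1e-12)  # contiguous

    def test_constant_intensity_gives_width_times_value(self):
        axis = np.linspace(10.5, -0.5, 8192)
        vals = bin_spectrum(Spectrum(axis, np.full(axis.size, 3.0)))
        np.testing.assert_allclose(vals, 3.0 * 0.02, rtol=1e-9)

    def test_unit_area_peak_confined_to_one_bin(self):
        axis = np.linspace(10.5, -0.5, 2 ** 16)
        # narrow unit-area Lorentzian wholly inside the bin [2.38, 2.36)
        inten = lorentzian(axis, 2.37, 2e-4)
        vals = bin_spectrum(Spectrum(axis, inten))
        left, right = bin_edges()
        hot = np.flatnonzero((left > 2.37) & (right < 2.37))
        assert vals[hot[0]] == pytest.approx(1.0, abs=0.02)
        cold = np.delete(vals, hot[0])
        assert np.abs(cold).max() < 0.05

    def test_region_not_covered_rejected(self):
        axis = np.linspace(8.0, 0.5, 1000)
        with pytest.raises(ValueError, match="cover"):
            bin_spectrum(Spectrum(axis, np.ones(1000)))

    def test_binning_matches_trapezoid_oracle(self, rng):
        from _oracles import trapezoid_window_integral

        axis = np.linspace(10.5, -0.5, 2 ** 14)
        inten = sum(lorentzian(axis, c, 0.002) for c in (1.33, 2.37, 5.24))
        vals = bin_spectrum(Spectrum(axis, inten))
        left, right = bin_edges()
        for k in rng.choice(490, size=12, replace=False):
            oracle = trapezoid_window_integral(axis, inten, right[k], left[k])
            assert vals[k] == pytest.approx(oracle, abs=1e-5)


class TestNormalize:
    def _matrix(self, n_subj=3, seed=0):
        g = np.random.default_rng(seed)
        axis = np.linspace(10.5, -0.5, 4096)
        spectra = [Spectrum(axis, 1.0 + g.random(axis.size), subject_id=f"S{i}")
                   for i in range(n_subj)]
        return bin_spectra(spectra)

    def test_water_exclusion_keeps_465_bins(self):
        out = normalize_matrix(self._matrix())
        assert out.n_bins == 465
        assert out.water_excluded and out.normalized
        # no retained bin interval overlaps (4.50, 5.00)
        assert not np.any((out.right_edges < 5.0 - 1e-9) & (out.left_edges > 4.5 + 1e-9))

    def test_rows_sum_to_one(self):
        out = normalize_matrix(self._matrix())
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_global_rescaling_invariance(self):
        m = self._matrix()
        m_scaled = BinnedMatrix(m.subject_ids, m.left_edges, m.right_edges,
                                m.values * np.array([[7.0], [1.0], [0.3]]))
        a = normalize_matrix(m)
        b = normalize_matrix(m_scaled)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_nonpositive_total_rejected_by_name(self):
        m = self._matrix()
        m.values[1] = 0.0
        with pytest.raises(ValueError, match="S1"):
            normalize_matrix(m)

    def test_double_normalization_rejected(self):
        out = normalize_matrix(self._matrix())
        with pytest.raises(ValueError, match="already"):
            normalize_matrix(out)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_property(self, factor):
        m = self._matrix(n_subj=2, seed=7)
        scaled = BinnedMatrix(m.subject_ids, m.left_edges, m.right_edges,
                              m.values * factor)
        np.testing.assert_allclose(normalize_matrix(m).values,
                                   normalize_matrix(scaled).values, atol=1e-11)


class TestIO:
    def test_matrix_csv_roundtrip_lossless(self, tmp_path, rng):
        left, right = bin_edges()
        vals = rng.random((4, 490))
        m = BinnedMatrix([f"P{i}" for i in range(4)], left, right, vals)
        m = normalize_matrix(m)
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        back = BinnedMatrix.from_csv(path)
        assert back.subject_ids == m.subject_ids
        assert back.normalized and back.water_excluded
        np.testing.assert_allclose(back.values, m.values, rtol=1e-12)
        np.testing.assert_allclose(back.left_edges, m.left_edges, atol=1e-12)

    def test_spectrum_txt_roundtrip(self, tmp_path):
        axis = np.linspace(10.5, -0.5, 512)
        sp = Spectrum(axis, np.sin(axis), subject_id="subj1")
        write_spectrum_txt(sp, tmp_path / "subj1.txt")
        back = read_spectrum_txt(tmp_path / "subj1.txt")
        assert back.subject_id == "subj1"
        np.testing.assert_allclose(back.intensity, sp.intensity, rtol=1e-6)

    def test_ascending_input_stored_descending(self):
        sp = Spectrum(np.linspace(0.0, 10.0, 11), np.arange(11.0))
        assert sp.ppm[0] > sp.ppm[-1]
        assert sp.intensity[0] == 10.0

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))
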