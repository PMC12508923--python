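import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sersdemux.exceptions import (
    DegenerateInputError,
    EmptyInputError,
    GridRangeError,
    ParameterError,
    SpectrumFormatError,
)
from sersdemux.simulate import PeakModel
from sersdemux.spectra import (
    GridSpec,
    RamanSpectrum,
    normalize_symmetric,
    peak_intensity,
    peak_ratio,
    read_spectrum,
    remove_baseline,
    resample,
    write_spectrum,
)


class TestRamanSpectrum:
    def test_validates_monotone_axis(self):
        with pytest.raises(SpectrumFormatError):
            RamanSpectrum([400.0, 400.0, 500.0], [1.0, 2.0, 3.0])

    def test_validates_equal_lengths_and_finiteness(self):
        with pytest.raises(SpectrumFormatError):
            RamanSpectrum([400.0, 500.0], [1.0, 2.0, 3.0])
        with pytest.raises(SpectrumFormatError):
            RamanSpectrum([400.0, 500.0], [1.0, np.nan])

    def test_minimum_two_points(self):
        with pytest.raises(SpectrumFormatError):
            RamanSpectrum([400.0], [1.0])


class TestReadWrite:
    def test_reads_csv_rows(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("400,1.0\n500,2.0\n600,1.5\n")
        s = read_spectrum(p)
        assert len(s) == 3
        assert s.intensities[1] == 2.0

    def test_sorts_descending_input(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("600,1.5\n400,1.0\n500,2.0\n")
        s = read_spectrum(p)
        np.testing.assert_array_equal(s.wavenumbers, [400.0, 500.0, 600.0])
        np.testing.assert_array_equal(s.intensities, [1.0, 2.0, 1.5])

    def test_header_skipped_and_round_trip(self, tmp_path, rng):
        w = np.sort(rng.uniform(400, 1800, 10))
        y = rng.normal(size=10)
        s = RamanSpectrum(np.unique(w), y[: np.unique(w).size])
        p = tmp_path / "rt.csv"
        write_spectrum(s, p)
        back = read_spectrum(p)
        assert back.wavenumbers.size == len(s)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=0, atol=0)

    def test_unparseable_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("400,1.0\nnot,a,number\n500,2.0\n")
        with pytest.raises(SpectrumFormatError, match="line 2"):
            read_spectrum(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("\n")
        with pytest.raises(EmptyInputError):
            read_spectrum(p)

    def test_duplicate_wavenumbers_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("400,1\n400,2\n500,3\n")
        with pytest.raises(SpectrumFormatError, match="duplicate"):
            read_spectrum(p)

    def test_tab_delimited_autodetected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("400\t1.0\n500\t2.0\n")
        assert len(read_spectrum(p)) == 2


class TestResample:
    def test_identity_on_target_grid(self):
        g = GridSpec(400, 600, 5)
        s = RamanSpectrum(g.wavenumbers, [0.0, 1.0, 4.0, 2.0, 1.0])
        out = resample(s, g)
        np.testing.assert_allclose(out.intensities, s.intensities)

    def test_linear_midpoint(self):
        s = RamanSpectrum([400.0, 600.0], [0.0, 2.0])
        out = resample(s, GridSpec(400, 600, 3))
        np.testing.assert_allclose(out.intensities, [0.0, 1.0, 2.0])

    def test_no_extrapolation(self):
        s = RamanSpectrum([450.0, 600.0], [0.0, 2.0])
        with pytest.raises(GridRangeError):
            resample(s, GridSpec(400, 600, 5))

    def test_matches_piecewise_linear_oracle(self, rng):
        w = np.unique(rng.uniform(400, 1800, 50))
        y = rng.normal(size=w.size)
        s = RamanSpectrum(w, y)
        g = GridSpec(float(w[0]), float(w[-1]), 896)
        out = resample(s, g)

        def oracle(q):
            j = np.searchsorted(w, q)
            j = np.clip(j, 1, w.size - 1)
            t = (q - w[j - 1]) / (w[j] - w[j - 1])
            return (1 - t) * y[j - 1] + t * y[j]

        expect = np.array([oracle(q) for q in g.wavenumbers])
        np.testing.assert_allclose(out.intensities, expect, atol=1e-9)


class TestNormalizeSymmetric:
    def test_affine_map(self):
        s = RamanSpectrum([1.0, 2.0, 3.0], [0.0, 5.0, 10.0])
        out, rec = normalize_symmetric(s)
        np.testing.assert_allclose(out.intensities, [-1.0, 0.0, 1.0])
        assert (rec.lo, rec.hi) == (0.0, 10.0)

    def test_constant_spectrum_rejected(self):
        s = RamanSpectrum([1.0, 2.0], [3.0, 3.0])
        with pytest.raises(DegenerateInputError):
            normalize_symmetric(s)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50).filter(
        lambda v: max(v) > min(v)))
    def test_range_exact_and_invertible(self, values):
        s = RamanSpectrum(np.arange(len(values), dtype=float), values)
        out, rec = normalize_symmetric(s)
        assert out.intensities.min() == -1.0
        assert out.intensities.max() == 1.0
        np.testing.assert_allclose(rec.invert(out.intensities), s.intensities,
                                   rtol=1e-9, atol=1e-9 * max(1.0, abs(rec.hi)))


class TestRemoveBaseline:
    def test_pure_baseline_goes_to_zero(self, grid):
        w = grid.wavenumbers
        base = 2.0 + 0.001 * (w - 400) + 1e-6 * (w - 1000) ** 2
        s = RamanSpectrum(w, base)
        out = remove_baseline(s)
        assert np.abs(out.intensities).max() < 0.05 * base.max()

    def test_peak_on_zero_baseline_preserved(self, grid):
        w = grid.wavenumbers
        peak = PeakModel(1044.0, 7.0, 10.0).profile(w)
        out = remove_baseline(RamanSpectrum(w, peak))
        assert abs(peak_intensity(out, 1044.0) - 7.0) < 0.35

    def test_peak_plus_ramp(self, grid):
        w = grid.wavenumbers
        peak = PeakModel(997.0, 5.0, 10.0).profile(w)
        ramp = 0.002 * (w - 400.0)
        out = remove_baseline(RamanSpectrum(w, peak + ramp))
        apex = w[np.argmax(out.intensities)]
        assert abs(apex - 997.0) < 10.0
        # residual trend: amplitude far from the peak < 5% of peak height
        far = np.abs(w - 997.0) > 150.0
        assert np.abs(out.intensities[far]).max() < 0.05 * 5.0

    def test_idempotent_within_tolerance(self, grid):
        w = grid.wavenumbers
        y = PeakModel(1044.0, 5.0, 9.0).profile(w) + 0.001 * (w - 400.0) + 1.0
        once = remove_baseline(RamanSpectrum(w, y))
        twice = remove_baseline(once)
        assert np.abs(twice.intensities - once.intensities).max() < 0.01 * 5.0

    def test_parameter_validation(self, small_grid):
        s = RamanSpectrum(small_grid.wavenumbers,
                          np.ones(small_grid.n_points) + small_grid.wavenumbers / 1e4)
        with pytest.raises(ParameterError):
            remove_baseline(s, lam=-1.0)
        with pytest.raises(ParameterError):
            remove_baseline(s, p=1.5)


class TestPeakUtilities:
    def test_apex_of_known_peak(self, grid):
        w = grid.wavenumbers
        s = RamanSpectrum(w, PeakModel(1044.0, 7.0, 10.0).profile(w))
        # grid sampling can miss the exact apex by half a step
        assert abs(peak_intensity(s, 1044.0, 10.0) - 7.0) < 0.2

    def test_flat_spectrum(self):
        s = RamanSpectrum([1000.0, 1044.0, 1100.0], [2.0, 2.0, 2.0])
        assert peak_intensity(s, 1044.0, 10.0) == 2.0

    def test_jittered_peak_found_by_window(self, small_grid):
        w = small_grid.wavenumbers
        s = RamanSpectrum(w, PeakModel(1040.0, 7.0, 8.0).profile(w))
        brute = s.intensities[(w >= 1034) & (w <= 1054)].max()
        assert peak_intensity(s, 1044.0, 10.0) == brute

    def test_out_of_range_window(self, small_grid):
        s = RamanSpectrum(small_grid.wavenumbers, np.ones(small_grid.n_points))
        with pytest.raises(GridRangeError):
            peak_intensity(s, 5000.0, 10.0)

    def test_ratio_equal_peaks(self, grid):
        w = grid.wavenumbers
        y = PeakModel(997.0, 3.0, 9.0).profile(w) + PeakModel(1044.0, 3.0, 9.0).profile(w)
        assert peak_ratio(RamanSpectrum(w, y), 997.0, 1044.0) == pytest.approx(1.0, abs=0.02)

    def test_ratio_direct(self, grid):
        w = grid.wavenumbers
        y = PeakModel(997.0, 3.0, 9.0).profile(w) + PeakModel(1044.0, 6.0, 9.0).profile(w)
        assert peak_ratio(RamanSpectrum(w, y), 997.0, 1044.0) == pytest.approx(0.5, abs=0.02)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.01, 1e4))
    def test_ratio_scale_invariant(self, scale):
        g = GridSpec(400.0, 1800.0, 256)
        w = g.wavenumbers
        y = PeakModel(997.0, 2.0, 9.0).profile(w) + PeakModel(1044.0, 5.0, 9.0).profile(w)
        s1 = RamanSpectrum(w, y)
        s2 = RamanSpectrum(w, scale * y)
        assert peak_ratio(s2, 997.0, 1044.0) == pytest.approx(
            peak_ratio(s1, 997.0, 1044.0), rel=1e-9)
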