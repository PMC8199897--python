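"""Peak metrics, foldover bookkeeping, calibration and scan extraction."""

import numpy as np
import pytest

from ft2dms.analysis import (
    Calibration,
    NoSplitError,
    Peak,
    UnresolvedPeakError,
    apply_zero_order,
    estimate_demod_from_split,
    extract_scan,
    fold_index,
    foldover_sign,
    freq_to_mz,
    fwhm,
    max_isotope_resolved_mass,
    mz_to_freq,
    peak_table,
    pick_peaks,
    resolving_power,
    snr,
)
from ft2dms.hypercomplex import FrequencyAxis, HypercomplexSpectrum


class TestPickPeaks:
    def test_flat_scan_yields_nothing(self):
        x = np.arange(100.0)
        assert pick_peaks(x, np.zeros(100), 0.5) == []

    def test_single_peak_with_parabolic_refinement(self):
        x = np.linspace(0.0, 99.0, 100)
        y = np.exp(-0.5 * ((x - 40.3) / 2.0) ** 2)
        peaks = pick_peaks(x, y, 0.5)
        assert len(peaks) == 1
        assert peaks[0].position == pytest.approx(40.3, abs=0.05)
        assert peaks[0].sign == 1

    def test_inverted_peak_detected_with_negative_sign(self):
        x = np.linspace(0.0, 99.0, 100)
        y = -np.exp(-0.5 * ((x - 40.0) / 2.0) ** 2)
        peaks = pick_peaks(x, y, 0.5)
        assert len(peaks) == 1 and peaks[0].sign == -1

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            pick_peaks(np.arange(3.0), np.zeros(3), 0.0)


class TestFwhm:
    def test_triangular_peak(self):
        # triangle of base 2w has FWHM exactly w
        w = 8.0
        x = np.arange(0.0, 41.0)
        y = np.clip(1.0 - np.abs(x - 20.0) / w, 0.0, None)
        pk = pick_peaks(x, y, 0.5)[0]
        assert fwhm(x, y, pk) == pytest.approx(w)

    def test_unresolved_shoulder_raises(self):
        x = np.arange(10.0)
        y = np.ones(10)
        y[5] = 2.0
        pk = Peak(position=5.0, height=2.0, index=5)
        with pytest.raises(UnresolvedPeakError):
            fwhm(x, y, pk)

    def test_sinc_absorption_width(self):
        # rectangular-window absorption mainlobe: FWHM = 1.2067 / T_record
        n, dwell = 4096, 1e-4
        T = n * dwell
        f0 = 600 / (n * dwell)
        sig = np.cos(2 * np.pi * f0 * dwell * np.arange(n))
        filled = np.concatenate([sig, np.zeros(15 * n)])  # fine interpolation
        cplx = np.fft.fft(filled)[: filled.size // 2]
        x = np.arange(cplx.size) / (filled.size * dwell)
        # remove the record-centroid linear phase e^{-i pi (f-f0)(N-1)dt}
        spec = np.real(cplx * np.exp(1j * np.pi * (x - f0) * (n - 1) * dwell))
        pk = pick_peaks(x, spec, 0.5 * spec.max())[0]
        assert fwhm(x, spec, pk) == pytest.approx(1.2067 / T, rel=0.01)

    def test_lorentzian_magnitude_absorption_ratio(self):
        # strong damping: magnitude/absorption FWHM ratio -> sqrt(3)
        n, dwell = 65536, 1e-4
        tau = n * dwell / 60.0  # decays to ~1e-26: pure Lorentzian limit
        f0 = 7000 / (n * dwell)
        t = dwell * np.arange(n)
        sig = np.cos(2 * np.pi * f0 * t) * np.exp(-t / tau)
        filled = np.concatenate([sig, np.zeros(3 * n)])
        spec = np.fft.fft(filled)[: filled.size // 2]
        x = np.arange(spec.size) / (filled.size * dwell)
        absorption = np.real(spec)
        magnitude = np.abs(spec)
        pk_a = pick_peaks(x, absorption, 0.5 * absorption.max())[0]
        pk_m = pick_peaks(x, magnitude, 0.5 * magnitude.max())[0]
        ratio = fwhm(x, magnitude, pk_m) / fwhm(x, absorption, pk_a)
        assert ratio == pytest.approx(np.sqrt(3.0), rel=0.02)


class TestResolvingPower:
    def test_worked_example(self):
        assert resolving_power(490.0, 0.035) == pytest.approx(14_000.0)

    def test_unity_and_proportionality(self):
        assert resolving_power(3.3, 3.3) == pytest.approx(1.0)
        assert resolving_power(980.0, 0.035) == pytest.approx(28_000.0)

    def test_domain(self):
        with pytest.raises(ValueError):
            resolving_power(-1.0, 0.035)


class TestSnr:
    def test_basic_value(self, rng):
        scan = np.zeros(1000)
        scan[200:] = rng.normal(0, 2.0, 800)
        scan[50] = 100.0
        pk = Peak(position=50.0, height=100.0, index=50)
        got = snr(scan, pk, slice(200, 1000))
        assert got == pytest.approx(100.0 / 2.0, rel=0.1)

    def test_zero_rms_raises(self):
        scan = np.zeros(100)
        scan[10] = 1.0
        pk = Peak(position=10.0, height=1.0, index=10)
        with pytest.raises(ValueError):
            snr(scan, pk, slice(50, 90))
        with pytest.raises(ValueError):
            snr(scan, pk, slice(50, 50))


class TestFoldover:
    @pytest.mark.parametrize("f,bw,n", [
        (146_340.0, 10_000.0, 14),
        (292_680.0, 10_000.0, 29),
        (5_000.0, 10_000.0, 0),
    ])
    def test_fold_counts(self, f, bw, n):
        assert fold_index(f, bw) == n

    @pytest.mark.parametrize("n,s", [(14, 1), (29, -1), (0, 1)])
    def test_fold_signs(self, n, s):
        assert foldover_sign(n) == s

    def test_domains(self):
        with pytest.raises(ValueError):
            fold_index(-1.0, 10.0)
        with pytest.raises(ValueError):
            fold_index(1.0, 0.0)
        with pytest.raises(ValueError):
            foldover_sign(-1)


class TestCalibration:
    def test_anchor_and_round_trip(self):
        cal = Calibration()  # anchored at (74,728.13 Hz, m/z 1450)
        assert freq_to_mz(cal.K / 1450.0, cal) == pytest.approx(1450.0)
        mz = 491.0
        assert freq_to_mz(mz_to_freq(mz, cal), cal) == pytest.approx(mz, rel=1e-12)

    def test_second_printed_anchor_deviates_slightly(self):
        # instrument anchor pairs are mutually inconsistent at the 0.03%
        # level; with K from the high-m/z anchor the low end lands at 202.27
        cal = Calibration()
        assert freq_to_mz(535_714.29, cal) == pytest.approx(202.27, abs=0.01)

    def test_domain(self):
        cal = Calibration()
        with pytest.raises(ValueError):
            freq_to_mz(0.0, cal)
        with pytest.raises(ValueError):
            Calibration(K=-1.0)


class TestIsotopeResolvedMass:
    @pytest.mark.parametrize("R,mass_da", [
        (14_000.0, 14_000.0),
        (27_000.0, 27_000.0),
        (1.0, 1.0),
    ])
    def test_values(self, R, mass_da):
        assert max_isotope_resolved_mass(R) == pytest.approx(mass_da)

    def test_domain(self):
        with pytest.raises(ValueError):
            max_isotope_resolved_mass(0.0)


class TestExtractScan:
    def _spectrum(self, rng):
        ax1 = FrequencyAxis(0.0, 10.0, 8)
        ax2 = FrequencyAxis(0.0, 100.0, 16)
        return HypercomplexSpectrum(*(rng.normal(size=(8, 16))
                                      for _ in range(4)), ax1, ax2)

    def test_round_trip_identity(self, rng):
        S = self._spectrum(rng)
        pos, vert = extract_scan(S, 1, 500.0)
        np.testing.assert_array_equal(np.real(vert), S.plane_rr[:, 5])
        np.testing.assert_array_equal(np.imag(vert), S.plane_ri[:, 5])
        pos2, horiz = extract_scan(S, 2, 30.0)
        np.testing.assert_array_equal(np.real(horiz), S.plane_rr[3, :])
        np.testing.assert_array_equal(np.imag(horiz), S.plane_ir[3, :])

    def test_zero_rotation_identity(self, rng):
        S = self._spectrum(rng)
        _, scan = extract_scan(S, 1, 500.0)
        np.testing.assert_array_equal(apply_zero_order(scan, 0.0), scan)

    def test_out_of_range_position(self, rng):
        S = self._spectrum(rng)
        with pytest.raises(ValueError):
            extract_scan(S, 1, 1e9)
        with pytest.raises(ValueError):
            extract_scan(S, 3, 0.0)


def test_no_split_detected_raises():
    x = np.linspace(0.0, 1000.0, 512)
    y = np.exp(-0.5 * ((x - 300.0) / 10.0) ** 2)
    with pytest.raises(NoSplitError):
        estimate_demod_from_split(x, y, 1000.0)


def test_peak_table_columns(rng):
    x = np.linspace(0.0, 999.0, 1000)
    y = np.exp(-0.5 * ((x - 300.0) / 5.0) ** 2) \
        - 0.5 * np.exp(-0.5 * ((x - 600.0) / 5.0) ** 2) \
        + rng.normal(0, 1e-4, 1000)
    table = peak_table(x, y, 0.2, noise_window=slice(800, 990))
    assert list(table.columns) == ["position", "height", "fwhm", "sign", "snr"]
    assert len(table) == 2
    assert table.sign.tolist() == [1, -1]
    assert (table.snr > 100).all()
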