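"""Quadratic/linear phase laws and tangent-based coefficient estimation."""

import numpy as np
import pytest

from ft2dms.phase_model import (
    PhaseEstimationError,
    PulseSequenceParams,
    QuadraticPhaseCoefficients,
    VerticalPhaseParams,
    chirp_c2_initializer,
    dispersion_objective,
    estimate_quadratic_from_tangents,
    estimate_zero_order,
    eval_quadratic,
    fragment_coefficients,
    fragment_horizontal_phase,
    precursor_horizontal_phase,
    region_tangent,
    theoretical_vertical_turns,
    vertical_phase,
)

TWO_PI = 2.0 * np.pi


class TestQuadraticLaws:
    def test_eval_quadratic_trivials(self):
        c = QuadraticPhaseCoefficients(c0=1.5, c1=0.0, c2=0.0)
        assert eval_quadratic(c, 0.0) == 1.5
        f = np.linspace(0, 1e5, 7)
        np.testing.assert_allclose(eval_quadratic(c, f), 1.5)

    def test_precursor_first_order_assembly(self, study_params):
        base = QuadraticPhaseCoefficients(c0=0.2, c1=1e-4, c2=3e-9)
        f1 = 2.0e5
        got = precursor_horizontal_phase(base, study_params, 0.0, f1)
        delays = (study_params.T1 + study_params.tau_m + study_params.T2
                  + study_params.T3)
        want = base.c2 * f1**2 + (base.c1 + TWO_PI * delays) * f1 + base.c0
        assert got == pytest.approx(want, rel=1e-12)

    def test_precursor_phase_linear_in_t1(self, study_params):
        base = QuadraticPhaseCoefficients()
        f1 = 1.5e5
        a, b = 3e-3, 7e-3
        diff = (precursor_horizontal_phase(base, study_params, a, f1)
                - precursor_horizontal_phase(base, study_params, b, f1))
        assert diff == pytest.approx(TWO_PI * f1 * (a - b), rel=1e-12)

    def test_fragment_generator_phase_step(self, study_params):
        base = QuadraticPhaseCoefficients()
        f2 = 3.0e5
        dt1 = 50e-6
        diff = (fragment_horizontal_phase(base, study_params, dt1, f2)
                - fragment_horizontal_phase(base, study_params, 0.0, f2))
        assert diff == pytest.approx(TWO_PI * study_params.f_min * dt1, rel=1e-12)

    def test_fragment_coefficients_absorb_constant(self, study_params):
        base = QuadraticPhaseCoefficients(c0=0.3, c1=2e-4, c2=1e-9)
        cc = fragment_coefficients(base, study_params, demodulated=True)
        const = TWO_PI * study_params.f_min * (2 * study_params.T1
                                               + study_params.tau_m)
        assert cc.c0 == pytest.approx(base.c0 + const)
        assert cc.c1 == base.c1 and cc.c2 == base.c2
        # demodulation removes the t1 dependence entirely
        assert fragment_coefficients(base, study_params, t1=1e-3,
                                     demodulated=True) == cc


class TestVerticalPhase:
    def test_at_f_min(self):
        vp_frag = VerticalPhaseParams(f_min=1000.0, T1=739e-6, pi_shift=True)
        vp_prec = VerticalPhaseParams(f_min=1000.0, T1=739e-6, pi_shift=False)
        assert vertical_phase(vp_frag, 1000.0) == pytest.approx(np.pi)
        assert vertical_phase(vp_prec, 1000.0) == pytest.approx(0.0)

    def test_fragment_precursor_differ_by_pi(self):
        f1 = np.linspace(0, 1e4, 11)
        frag = vertical_phase(VerticalPhaseParams(pi_shift=True), f1)
        prec = vertical_phase(VerticalPhaseParams(pi_shift=False), f1)
        np.testing.assert_allclose(frag - prec, np.pi)

    def test_slope_integrates_to_theoretical_turns(self):
        f_N, T1 = 10_000.0, 739e-6
        vp = VerticalPhaseParams(f_min=0.0, T1=T1, pi_shift=False)
        span_turns = (vertical_phase(vp, f_N) - vertical_phase(vp, 0.0)) / TWO_PI
        assert span_turns == pytest.approx(theoretical_vertical_turns(f_N, T1))

    def test_theoretical_turns_worked_values(self):
        assert theoretical_vertical_turns(10_000.0, 739e-6) == pytest.approx(7.39)
        assert theoretical_vertical_turns(12345.0, 0.0) == 0.0
        assert theoretical_vertical_turns(20_000.0, 739e-6) == pytest.approx(14.78)

    def test_study_bandwidth_convention(self, study_params):
        # 50 us increments <-> 10 kHz vertical bandwidth
        assert study_params.vertical_bandwidth == pytest.approx(10_000.0)


def test_chirp_initializer_value():
    p = PulseSequenceParams(sweep_step_hz=624.0, sweep_dwell_s=20e-6)
    assert chirp_c2_initializer(p) == pytest.approx(np.pi / (624.0 / 20e-6))


def _damped_cluster_spectrum(c, clusters, sep=150.0, n=16384, dwell=1e-5,
                             tau_frac=5.0, noise_sigma=0.0, seed=None):
    """1D complex spectrum of two-line clusters with imposed quadratic phase."""
    t = dwell * np.arange(n)
    sig = np.zeros(n)
    for fp in clusters:
        for f_line, a in ((fp, 1.0), (fp + sep, 0.7)):
            phi = eval_quadratic(c, f_line)
            sig += a * np.cos(TWO_PI * f_line * t + phi) * np.exp(
                -t / (n * dwell / tau_frac))
    if noise_sigma:
        sig = sig + np.random.default_rng(seed).normal(0, noise_sigma, n)
    filled = np.concatenate([sig, np.zeros_like(sig)])
    spec = np.fft.fft(filled)[: n]
    freqs = np.arange(n) / (2 * n * dwell)
    return freqs, spec


CLUSTERS = [12000.0, 19000.0, 27000.0, 35000.0, 44000.0]
SEP = 150.0
REGIONS = [(fp - 400.0, fp + SEP + 400.0) for fp in CLUSTERS]


class TestDispersionObjective:
    def _phased_peak(self, half_width=500.0):
        # sep=0 collapses the doublet into one line
        c = QuadraticPhaseCoefficients()
        freqs, spec = _damped_cluster_spectrum(c, [27000.0], sep=0.0)
        mask = np.abs(freqs - 27000.0) < half_width
        return freqs[mask], spec[mask]

    def test_well_phased_peak_scores_near_zero(self):
        freqs, region = self._phased_peak()
        assert dispersion_objective(region, 0.0, 0.0, freqs=freqs) < 0.05

    def test_pi_rotation_is_worst_among_rotations(self):
        # an on-grid undamped line is a single-bin absorption peak: the
        # negative-lobe area is |cos(p0)| for cos(p0) < 0, maximal at pi
        n, dwell = 1024, 1e-4
        f0 = 100 / (n * dwell)
        sig = np.cos(TWO_PI * f0 * dwell * np.arange(n))
        spec = np.fft.fft(sig)[: n // 2]
        freqs = np.arange(n // 2) / (n * dwell)
        mask = np.abs(freqs - f0) < 300.0
        grid = np.linspace(0, TWO_PI, 36, endpoint=False)
        scores = [dispersion_objective(spec[mask], p0, 0.0,
                                       freqs=freqs[mask], lam=0.0)
                  for p0 in grid]
        assert np.argmax(scores) == 18  # p0 = pi exactly

    def test_periodic_in_p0(self):
        freqs, region = self._phased_peak()
        a = dispersion_objective(region, 0.7, 0.0, freqs=freqs)
        b = dispersion_objective(region, 0.7 + TWO_PI, 0.0, freqs=freqs)
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            dispersion_objective(np.array([]), 0.0)


class TestTangentEstimation:
    def test_round_trip_recovery(self):
        c = QuadraticPhaseCoefficients(c0=0.7, c1=3e-4, c2=2e-8)
        freqs, spec = _damped_cluster_spectrum(c, CLUSTERS)
        fit = estimate_quadratic_from_tangents(freqs, spec, REGIONS,
                                               p1_half_range=4e-3)
        assert fit.coefficients.c2 == pytest.approx(c.c2, rel=0.01)
        assert fit.coefficients.c1 == pytest.approx(c.c1, rel=0.02)
        # zero order matters modulo one turn
        assert np.angle(np.exp(1j * (fit.coefficients.c0 - c.c0))) \
            == pytest.approx(0.0, abs=0.1)

    def test_zero_curvature_limit(self):
        c = QuadraticPhaseCoefficients(c0=-1.1, c1=5e-4, c2=0.0)
        freqs, spec = _damped_cluster_spectrum(c, CLUSTERS)
        fit = estimate_quadratic_from_tangents(freqs, spec, REGIONS,
                                               p1_half_range=4e-3)
        assert abs(fit.coefficients.c2) < 2e-10  # below measurement floor
        assert fit.coefficients.c1 == pytest.approx(c.c1, rel=0.02)

    def test_stable_under_noise(self):
        # peak S/N ~ 100 in the spectrum; coefficient drift < 5%
        c = QuadraticPhaseCoefficients(c0=0.7, c1=3e-4, c2=2e-8)
        drifts = []
        for seed in range(3):
            freqs, spec = _damped_cluster_spectrum(
                c, CLUSTERS, noise_sigma=0.01, seed=seed)
            fit = estimate_quadratic_from_tangents(freqs, spec, REGIONS,
                                                   p1_half_range=4e-3)
            drifts.append(abs(fit.coefficients.c2 - c.c2) / c.c2)
        assert max(drifts) < 0.05

    def test_needs_three_regions(self):
        c = QuadraticPhaseCoefficients()
        freqs, spec = _damped_cluster_spectrum(c, CLUSTERS)
        with pytest.raises(PhaseEstimationError):
            estimate_quadratic_from_tangents(freqs, spec, REGIONS[:2])

    def test_lone_lines_cannot_fix_slopes(self):
        c = QuadraticPhaseCoefficients(c1=3e-4)
        freqs, spec = _damped_cluster_spectrum(c, CLUSTERS, sep=0.0)
        # sep=0 collapses each cluster to a single line: no usable slopes
        with pytest.raises(PhaseEstimationError):
            estimate_quadratic_from_tangents(freqs, spec, REGIONS)

    def test_region_without_data_raises(self):
        c = QuadraticPhaseCoefficients()
        freqs, spec = _damped_cluster_spectrum(c, CLUSTERS)
        with pytest.raises(PhaseEstimationError):
            estimate_quadratic_from_tangents(
                freqs, spec, [(1e6, 2e6)] + list(REGIONS))


class TestRegionTangent:
    def test_single_line_reports_nan_slope(self):
        c = QuadraticPhaseCoefficients(c0=0.4)
        freqs, spec = _damped_cluster_spectrum(c, [27000.0], sep=0.0)
        mask = (freqs > 26000) & (freqs < 28500)
        fc, p0, p1, score = region_tangent(freqs[mask], spec[mask])
        assert np.isnan(p1)
        assert fc == pytest.approx(27000.0, abs=5.0)
        assert p0 == pytest.approx(0.4, abs=0.05)

    def test_doublet_slope(self):
        c = QuadraticPhaseCoefficients(c0=0.4, c1=3e-4, c2=2e-8)
        freqs, spec = _damped_cluster_spectrum(c, [27000.0])
        mask = (freqs > 26000) & (freqs < 28500)
        fc, p0, p1, _ = region_tangent(freqs[mask], spec[mask],
                                       p1_half_range=4e-3)
        assert p1 == pytest.approx(2 * c.c2 * fc + c.c1, rel=0.02)


def test_estimate_zero_order_recovers_rotation():
    c = QuadraticPhaseCoefficients()
    freqs, spec = _damped_cluster_spectrum(c, [27000.0], sep=0.0)
    mask = (freqs > 26500) & (freqs < 27500)
    rotated = spec[mask] * np.exp(1j * 1.234)
    phi0 = estimate_zero_order(rotated)
    assert np.angle(np.exp(1j * (phi0 - 1.234))) == pytest.approx(0.0, abs=0.1)
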