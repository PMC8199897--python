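"""Phase models for absorption-mode 2D FT-ICR MS.

Horizontal (fragment, f2) dimension: the chirped excitation pulses impose a
phase quadratic in frequency,

    phi(f) = c2*f^2 + c1*f + c0,

with additive corrections that depend on which pulse excited the ions:

* precursor ions (still excited at the end of the second pulse) accrue
  phi_p,h(f1) = c2*f1^2 + c1'*f1 + c0 + 2*pi*f1*t1 with
  c1' = c1 + 2*pi*(T1 + tau_m + T2 + T3) -- the extra linear term makes the
  precursor phase depend on the encoding delay t1, which is why precursor
  signals cannot be phased by the fragment correction function;
* fragment ions (and fully de-excited precursors re-excited by the third
  pulse) accrue phi_f,h(f2) = c2*f2^2 + c1*f2 + c0'' with
  c0'' = c0 + 2*pi*f_min*(2*T1 + t1 + tau_m), the pulse-generator phase.
  Digital demodulation removes the 2*pi*f_min*t1 part; the remaining
  constant 2*pi*f_min*(2*T1 + tau_m) folds into the zero-order term, leaving
  one t1-independent quadratic for the whole stack.

Vertical (precursor, f1) dimension: the radius modulation
cos(2*pi*(f1 - f_min)*(t1 - T1)) makes the line phase linear in f1 with
slope set by the first-pulse duration T1; the correction spans f_N * T1
turns across the vertical bandwidth.  Fragment modulation is inverted
(fragmentation is maximal when precursors sit at the cell centre), adding a
pi shift, so fragment and precursor peaks emerge with opposite signs under
one correction.

The quadratic coefficients can be estimated from the spectrum itself: small
regions are phased with local *linear* functions (p0, p1), and since each
local function is a tangent of the overall quadratic, a least-squares fit of
the tangency constraints phi(fc) = p0, phi'(fc) = p1 recovers (c0, c1, c2)
without any phase unwrapping across the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PulseSequenceParams",
    "QuadraticPhaseCoefficients",
    "VerticalPhaseParams",
    "eval_quadratic",
    "precursor_horizontal_phase",
    "fragment_horizontal_phase",
    "fragment_coefficients",
    "vertical_phase",
    "theoretical_vertical_turns",
    "chirp_c2_initializer",
    "dispersion_objective",
    "local_linear_phase",
    "region_tangent",
    "estimate_quadratic_from_tangents",
    "estimate_zero_order",
    "TangentFit",
    "PhaseEstimationError",
]

TWO_PI = 2.0 * np.pi


class PhaseEstimationError(RuntimeError):
    """Raised when phase coefficients cannot be estimated from the data."""


@dataclass(frozen=True)
class PulseSequenceParams:
    """Timing and frequency parameters of the 2D MS pulse sequence.

    All durations in seconds, frequencies in Hz.  T1 is the duration of the
    first and second (encoding) pulses, T2 of the third (excite-to-detect)
    pulse, T3 the delay between excitation and detection, tau_m the
    fragmentation period.  The encoding-delay grid is
    t1 = t1_start + t1_step * arange(n1).
    """

    T1: float = 739e-6
    T2: float = 14.78e-3
    T3: float = 3e-3
    tau_m: float = 0.06
    f_min: float = 74_728.13
    f_max: float = 535_714.29
    sweep_step_hz: float = 624.0
    sweep_dwell_s: float = 1e-6
    t1_start: float = 0.0
    t1_step: float = 50e-6
    n1: int = 1024

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "T3", "tau_m", "t1_start"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")
        if self.t1_step <= 0:
            raise ValueError("t1_step must be positive")

    @property
    def vertical_bandwidth(self) -> float:
        """Half-spectrum bandwidth f_N = 1/(2*t1_step) of the real vertical FT.

        A 50 us increment gives the 10 kHz vertical bandwidth convention.
        """
        return 1.0 / (2.0 * self.t1_step)


@dataclass(frozen=True)
class QuadraticPhaseCoefficients:
    """Coefficients of phi(f) = c2*f^2 + c1*f + c0.

    Units: c0 in rad, c1 in rad/Hz, c2 in rad/Hz^2.  ``role`` tags whether
    these are the base chirp coefficients or the assembled fragment
    (double-primed) / precursor (primed) variants.
    """

    c0: float = 0.0
    c1: float = 0.0
    c2: float = 0.0
    role: str = "base"  # "base" | "fragment" | "precursor"

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.c0, self.c1, self.c2])):
            raise ValueError("phase coefficients must be finite")


@dataclass(frozen=True)
class VerticalPhaseParams:
    """Parameters of the linear vertical correction.

    phi(f1) = 2*pi*(f1 - f_min)*T1 + pi*pi_shift + extra_zero_order.

    ``pi_shift`` is set for fragment signals (centre-of-cell fragmentation
    inverts the modulation); ``extra_zero_order`` holds operator tweaks such
    as the per-scan correction used for extracted harmonic scans.
    """

    f_min: float = 0.0
    T1: float = 739e-6
    pi_shift: bool = True
    extra_zero_order: float = 0.0


def eval_quadratic(coeffs: QuadraticPhaseCoefficients, f) -> np.ndarray:
    """phi(f) = c2*f^2 + c1*f + c0 in radians."""
    f = np.asarray(f, dtype=float)
    return coeffs.c2 * f**2 + coeffs.c1 * f + coeffs.c0


def precursor_horizontal_phase(
    coeffs_base: QuadraticPhaseCoefficients,
    params: PulseSequenceParams,
    t1: float,
    f1,
    delays_2pi: bool = True,
) -> np.ndarray:
    """Horizontal phase of a precursor signal at encoding delay t1.

    phi_p,h(f1) = c2*f1^2 + c1'*f1 + c0 + 2*pi*f1*t1 with
    c1' = c1 + 2*pi*(T1 + tau_m + T2 + T3).  The post-excitation delays add
    to the first-order coefficient; ``delays_2pi=False`` adds the bare
    seconds instead (literal reading, for comparison only).
    """
    if t1 < 0:
        raise ValueError("t1 must be >= 0")
    f1 = np.asarray(f1, dtype=float)
    delays = params.T1 + params.tau_m + params.T2 + params.T3
    c1p = coeffs_base.c1 + (TWO_PI * delays if delays_2pi else delays)
    return coeffs_base.c2 * f1**2 + c1p * f1 + coeffs_base.c0 + TWO_PI * f1 * t1


def fragment_horizontal_phase(
    coeffs_base: QuadraticPhaseCoefficients,
    params: PulseSequenceParams,
    t1: float,
    f2,
) -> np.ndarray:
    """Horizontal phase of a fragment signal at encoding delay t1.

    phi_f,h(f2) = c2*f2^2 + c1*f2 + c0'' with
    c0'' = c0 + 2*pi*f_min*(2*T1 + t1 + tau_m).
    """
    f2 = np.asarray(f2, dtype=float)
    c0pp = coeffs_base.c0 + TWO_PI * params.f_min * (2 * params.T1 + t1 + params.tau_m)
    return coeffs_base.c2 * f2**2 + coeffs_base.c1 * f2 + c0pp


def fragment_coefficients(
    coeffs_base: QuadraticPhaseCoefficients,
    params: PulseSequenceParams,
    t1: float = 0.0,
    demodulated: bool = True,
) -> QuadraticPhaseCoefficients:
    """Assembled fragment coefficients (c0'', c1, c2).

    With ``demodulated`` the 2*pi*f_min*t1 contribution is absent (removed
    by digital demodulation) and the returned coefficients are valid for
    every row of the stack; otherwise they hold for the given t1 only.
    """
    extra = TWO_PI * params.f_min * (2 * params.T1 + params.tau_m)
    if not demodulated:
        extra += TWO_PI * params.f_min * t1
    return QuadraticPhaseCoefficients(
        c0=coeffs_base.c0 + extra, c1=coeffs_base.c1, c2=coeffs_base.c2,
        role="fragment",
    )


def vertical_phase(params: VerticalPhaseParams, f1) -> np.ndarray:
    """Linear vertical correction phi(f1) = 2*pi*(f1 - f_min)*T1 (+ pi).

    Applied to the vertical spectrum after the column FT; the slope
    integrates to f_N * T1 turns over the vertical bandwidth.  With
    ``pi_shift`` (fragment signals) the correction differs by exactly pi
    from the precursor one, so the two signal classes take opposite signs.
    """
    f1 = np.asarray(f1, dtype=float)
    phi = TWO_PI * (f1 - params.f_min) * params.T1 + params.extra_zero_order
    if params.pi_shift:
        phi = phi + np.pi
    return phi


def theoretical_vertical_turns(f_N: float, T1: float) -> float:
    """Total span, in turns, of the vertical linear correction: f_N * T1."""
    if f_N < 0 or T1 < 0:
        raise ValueError("f_N and T1 must be >= 0")
    return f_N * T1


def chirp_c2_initializer(params: PulseSequenceParams) -> float:
    """Convenience c2 seed for a linear frequency sweep: pi / (sweep rate).

    The sweep rate is sweep_step_hz / sweep_dwell_s (Hz per second).  Only an
    optimizer starting value; real instruments deviate from the ideal chirp.
    """
    rate = params.sweep_step_hz / params.sweep_dwell_s
    return np.pi / rate


# ---------------------------------------------------------------------------
# Local phasing and tangent-based estimation
# ---------------------------------------------------------------------------

def dispersion_objective(
    region: np.ndarray,
    p0: float,
    p1: float = 0.0,
    freqs: Optional[np.ndarray] = None,
    lam: float = 1.0,
) -> float:
    """Badness of a local linear phase (p0, p1) applied to a spectrum slice.

    The slice is rotated by exp(-i*(p0 + p1*(f - fc))) with fc at the peak
    maximum, and the score is

        (negative-lobe area of the real part
         + lam * asymmetry about the peak maximum) / total |region| area.

    The real part is referenced to the median of the region's outer-edge
    bins before the negative-lobe sum, which makes the score insensitive to
    the flat baseline a one-sided DFT places under damped lines (the edges
    of a sensible region are signal-free); the asymmetry window is confined to the
    peak's own flanks (out to where the magnitude falls below 20% of the
    maximum) so that neighbouring lines in a cluster do not register as
    asymmetry.  Zero for a perfectly phased symmetric absorption peak;
    2*pi-periodic in p0; deterministic.
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    ipk = int(np.argmax(np.abs(region)))
    if freqs is None:
        offsets = np.arange(region.size, dtype=float) - ipk
    else:
        freqs = np.asarray(freqs, dtype=float)
        offsets = freqs - freqs[ipk]
    phased = np.real(region * np.exp(-1j * (p0 + p1 * offsets)))
    total = float(np.sum(np.abs(region)))
    if total == 0.0:
        return 0.0
    edge = max(1, phased.size // 8)
    baseline = float(np.median(np.concatenate([phased[:edge], phased[-edge:]])))
    centered = phased - baseline
    neg = float(np.sum(np.clip(-centered, 0.0, None)))
    mag = np.abs(region)
    imax = int(np.argmax(phased))
    floor = 0.2 * mag[ipk]
    k = min(imax, phased.size - 1 - imax)
    below = np.flatnonzero(mag < floor)
    if below.size:
        dist = np.abs(below - imax)
        k = min(k, int(dist.min()))
    if k > 0:
        right = centered[imax + 1: imax + 1 + k]
        left = centered[imax - k: imax][::-1]
        asym = float(np.sum(np.abs(right - left)))
    else:
        asym = 0.0
    return (neg + lam * asym) / total


def _region_line_phases(
    freqs: np.ndarray,
    region: np.ndarray,
    max_lines: int = 6,
    rel_threshold: float = 0.2,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequencies, phases and amplitudes of the resolved lines in a region.

    The region is modelled as a sum of complex Lorentzians with one shared
    decay rate,

        v(f) = sum_l  z_l / (a + i*2*pi*(f - f_l)),

    the frequency-domain shape of exponentially damped sinusoids, and fit
    by deterministic least squares seeded from the picked maxima.  The
    phase of each line is arg(z_l) -- free of the dispersion-lineshape bias
    that corrupts a peak-bin phase readout for off-grid lines.
    """
    from scipy.optimize import least_squares

    mags = np.abs(region)
    top = float(mags.max())
    # local maxima above threshold, strongest first
    cand = [i for i in range(1, region.size - 1)
            if mags[i] > rel_threshold * top
            and mags[i] > mags[i - 1] and mags[i] >= mags[i + 1]]
    cand.sort(key=lambda i: -mags[i])
    picked: List[int] = []
    df = freqs[1] - freqs[0]
    for i in cand:
        if all(abs(i - j) > 3 for j in picked):
            picked.append(i)
        if len(picked) >= max_lines:
            break
    if not picked:
        raise PhaseEstimationError("no lines found in region")
    picked.sort()
    f_seeds = []
    for i in picked:
        y0, y1, y2 = mags[i - 1], mags[i], mags[i + 1]
        den = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / den if den else 0.0
        f_seeds.append(freqs[i] + np.clip(delta, -0.5, 0.5) * df)
    f_seeds = np.asarray(f_seeds)
    # decay-rate seed from the tallest line's half-height width
    a_seed = np.pi * max(3.0 * df, _rough_fwhm(freqs, mags, picked[0]))

    L = len(picked)

    def model_matrix(a: float, f_l: np.ndarray) -> np.ndarray:
        return 1.0 / (a + 1j * TWO_PI * (freqs[:, None] - f_l[None, :]))

    def residual(theta: np.ndarray) -> np.ndarray:
        a = np.exp(theta[0])
        f_l = theta[1: 1 + L]
        M = model_matrix(a, f_l)
        z, *_ = np.linalg.lstsq(
            np.vstack([np.column_stack([M.real, -M.imag]),
                       np.column_stack([M.imag, M.real])]),
            np.concatenate([region.real, region.imag]),
            rcond=None,
        )
        zc = z[:L] + 1j * z[L:]
        fit = M @ zc
        return np.concatenate([(fit - region).real, (fit - region).imag])

    theta0 = np.concatenate([[np.log(a_seed)], f_seeds])
    sol = least_squares(residual, theta0, method="lm", max_nfev=400)
    a = np.exp(sol.x[0])
    f_l = sol.x[1: 1 + L]
    M = model_matrix(a, f_l)
    z, *_ = np.linalg.lstsq(
        np.vstack([np.column_stack([M.real, -M.imag]),
                   np.column_stack([M.imag, M.real])]),
        np.concatenate([region.real, region.imag]),
        rcond=None,
    )
    zc = z[:L] + 1j * z[L:]
    order = np.argsort(f_l)
    return f_l[order], np.angle(zc[order]), np.abs(zc[order])


def _rough_fwhm(freqs: np.ndarray, mags: np.ndarray, i: int) -> float:
    half = 0.5 * mags[i]
    lo = i
    while lo > 0 and mags[lo] > half:
        lo -= 1
    hi = i
    while hi < mags.size - 1 and mags[hi] > half:
        hi += 1
    return float(freqs[hi] - freqs[lo])


def region_tangent(
    freqs: np.ndarray,
    region: np.ndarray,
    p1_half_range: Optional[float] = None,
    lam: float = 1.0,
) -> Tuple[float, float, float, float]:
    """Tangency data (fc, p0, p1, score) of one spectral region.

    The line phases are read from a complex Lorentzian fit of the region
    (see _region_line_phases) and the local slope p1 from a weighted
    least-squares line through the unwrapped phases.  For a quadratic
    overall phase the weighted slope equals the derivative at
    fc = f_bar + m3/(2*m2) (f_bar the amplitude-weighted mean line
    frequency, m2/m3 the second/third weighted central moments), so the
    returned (fc, p0, p1) is an exact tangency triple up to line-fit error.

    A lone line cannot fix the local slope -- one resonance carries one
    constant phase times its lineshape -- so a single-line region returns
    p1 = 0.  ``p1_half_range`` (default 2 turns across the region) bounds
    the accepted slope; the score is the dispersion objective at the
    solution.
    """
    freqs = np.asarray(freqs, dtype=float)
    region = np.asarray(region)
    if region.size < 3:
        raise PhaseEstimationError("region too small for local phasing")
    width = float(freqs[-1] - freqs[0])
    if width <= 0:
        raise PhaseEstimationError("degenerate region frequency span")
    if p1_half_range is None:
        p1_half_range = 2.0 * TWO_PI / width  # +/- 2 turns across the region

    f_l, phi_l, amp_l = _region_line_phases(freqs, region)
    if f_l.size == 1:
        fc = float(f_l[0])
        p0 = float(phi_l[0])
        p1 = float("nan")  # a lone line carries no slope information
    else:
        # unwrap sequentially: adjacent lines are assumed within half a turn
        phi_u = np.copy(phi_l)
        for k in range(1, phi_u.size):
            step = phi_u[k] - phi_u[k - 1]
            phi_u[k] -= TWO_PI * np.round(step / TWO_PI)
        w = amp_l / amp_l.sum()
        fb = float(np.sum(w * f_l))
        pb = float(np.sum(w * phi_u))
        m2 = float(np.sum(w * (f_l - fb) ** 2))
        m3 = float(np.sum(w * (f_l - fb) ** 3))
        p1 = float(np.sum(w * (f_l - fb) * (phi_u - pb)) / m2)
        p1 = float(np.clip(p1, -p1_half_range, p1_half_range))
        fc = fb + m3 / (2.0 * m2)
        p0 = float(np.angle(np.exp(1j * (pb + p1 * (fc - fb)))))
    i_top = int(np.argmax(amp_l))
    off = freqs[int(np.argmin(np.abs(freqs - f_l[i_top])))] - fc
    p1_sc = 0.0 if np.isnan(p1) else p1
    sc = dispersion_objective(region, p0 + p1_sc * off, p1_sc, freqs=freqs,
                              lam=lam)
    return fc, p0, p1, sc


def local_linear_phase(
    freqs: np.ndarray,
    region: np.ndarray,
    p1_half_range: Optional[float] = None,
    lam: float = 1.0,
) -> Tuple[float, float, float]:
    """Best local linear phase (p0, p1, score) for one spectral region.

    p0 is referenced at the region's tangency centre (see region_tangent):
    rotating the region by exp(-i*(p0 + p1*(f - fc))) phases every line in
    it to positive absorption.
    """
    _, p0, p1, sc = region_tangent(freqs, region, p1_half_range, lam)
    return p0, (0.0 if np.isnan(p1) else p1), sc


@dataclass
class TangentFit:
    """Result of the tangent-based quadratic phase estimation."""

    coefficients: QuadraticPhaseCoefficients
    centers_hz: np.ndarray
    p0: np.ndarray
    p1: np.ndarray
    slope_residuals: np.ndarray
    value_residuals: np.ndarray
    scores: np.ndarray


def estimate_quadratic_from_tangents(
    freqs: np.ndarray,
    spectrum: np.ndarray,
    regions: Sequence[Tuple[float, float]],
    p1_half_range: Optional[float] = None,
    lam: float = 1.0,
) -> TangentFit:
    """Estimate (c0, c1, c2) from locally phased regions of a complex spectrum.

    Each region is phased with a local linear function (p0, p1); because
    those lines are tangents of the overall quadratic, phi'(fc) = p1 gives a
    wrap-free linear system for (c2, c1), and c0 follows from the circular
    mean of p0 - c2*fc^2 - c1*fc.  Needs at least 3 regions, each containing
    a peak *cluster* (two or more lines -- a lone line cannot fix the local
    slope; see local_linear_phase).

    The tangency centre fc is the magnitude-weighted centroid of the
    region: for a quadratic, the secant slope between two lines equals the
    derivative at their midpoint, so anchoring at the centroid removes the
    secant bias.
    """
    if len(regions) < 3:
        raise PhaseEstimationError("need at least 3 regions for a quadratic fit")
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum)
    centers, p0s, p1s, scores = [], [], [], []
    for (flo, fhi) in regions:
        mask = (freqs >= flo) & (freqs <= fhi)
        if np.count_nonzero(mask) < 3:
            raise PhaseEstimationError(f"region ({flo}, {fhi}) contains no data")
        sub_f = freqs[mask]
        sub = spectrum[mask]
        if np.max(np.abs(sub)) == 0:
            raise PhaseEstimationError(f"region ({flo}, {fhi}) contains no peak")
        fc, p0, p1, sc = region_tangent(sub_f, sub, p1_half_range, lam)
        centers.append(fc)
        p0s.append(p0)
        p1s.append(p1)
        scores.append(sc)
    centers = np.asarray(centers)
    p0s = np.asarray(p0s)
    p1s = np.asarray(p1s)
    usable = ~np.isnan(p1s)
    if np.count_nonzero(usable) < 3:
        raise PhaseEstimationError(
            "need at least 3 regions with a measurable local slope "
            "(two or more lines each); lone lines carry no slope")
    # phi'(fc) = 2*c2*fc + c1  (no 2*pi wrap in derivatives)
    A = np.column_stack([2.0 * centers[usable], np.ones(usable.sum())])
    if np.linalg.matrix_rank(A) < 2:
        raise PhaseEstimationError("region centers are degenerate (collinear fit)")
    (c2, c1), *_ = np.linalg.lstsq(A, p1s[usable], rcond=None)
    slope_res = p1s[usable] - A @ np.array([c2, c1])
    # zero-order: circular mean of the wrapped residual phases
    resid = p0s - (c2 * centers**2 + c1 * centers)
    c0 = float(np.angle(np.mean(np.exp(1j * resid))))
    value_res = np.angle(np.exp(1j * (resid - c0)))
    coeffs = QuadraticPhaseCoefficients(c0=c0, c1=float(c1), c2=float(c2),
                                        role="fragment")
    return TangentFit(
        coefficients=coeffs,
        centers_hz=centers,
        p0=p0s,
        p1=p1s,
        slope_residuals=slope_res,
        value_residuals=value_res,
        scores=np.asarray(scores),
    )


def estimate_zero_order(region: np.ndarray, lam: float = 1.0) -> float:
    """Zero-order phase that best phases one peak to positive absorption.

    Seeded at the peak-bin phase (exact for a symmetric line) and refined
    by a bounded search of the dispersion objective plus a peak-positivity
    anchor 1 - cos(seed - p0); the anchor removes the degenerate optimum at
    which the whole peak rotates into the quadrature plane.  This is the
    operator step used when a single scan needs a constant rotation (e.g.
    extracted harmonic scans).
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    ipk = int(np.argmax(np.abs(region)))
    seed = float(np.angle(region[ipk]))

    def score(p0: float) -> float:
        return (dispersion_objective(region, p0, 0.0, lam=lam)
                + (1.0 - np.cos(seed - p0)))

    res = minimize_scalar(score, bounds=(seed - np.pi / 2, seed + np.pi / 2),
                          method="bounded", options={"xatol": 1e-10})
    best = float(res.x) if res.fun <= score(seed) else seed
    return float(np.mod(best, TWO_PI))
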