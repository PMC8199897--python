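"""Spectral quality metrics and bookkeeping for 2D FT-ICR MS.

Peak picking with parabolic interpolation, FWHM and resolving power,
signal-to-noise estimation, Nyquist foldover and harmonic-sign rules,
demodulation-frequency determination from split peaks, scan extraction and
frequency <-> m/z conversion.

S/N is defined as |peak height| / RMS-about-zero of a signal-free window.
Taking the RMS about zero (not about the Rayleigh mean of a magnitude
baseline) makes the theoretical absorption-vs-magnitude gains exact in
expectation: a complex FT bin of white noise has Rayleigh-distributed
magnitude with power 2*sigma_plane^2, and the 4-quadrant hypercomplex
magnitude has power 4*sigma_plane^2, giving the sqrt(2) (1D) and 2 (2D)
signal-to-noise factors of absorption mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .hypercomplex import FrequencyAxis, HypercomplexSpectrum

__all__ = [
    "Peak",
    "Calibration",
    "UnresolvedPeakError",
    "NoSplitError",
    "pick_peaks",
    "fwhm",
    "resolving_power",
    "snr",
    "fold_index",
    "foldover_sign",
    "estimate_demod_from_split",
    "freq_to_mz",
    "mz_to_freq",
    "max_isotope_resolved_mass",
    "extract_scan",
    "apply_zero_order",
    "peak_table",
    "write_scan",
]


class UnresolvedPeakError(RuntimeError):
    """The peak's flanks never fall below half height."""


class NoSplitError(RuntimeError):
    """No split pair detected: demodulation already correct."""


@dataclass(frozen=True)
class Peak:
    """One picked line: interpolated position, signed height, optional FWHM."""

    position: float
    height: float
    index: int
    fwhm: Optional[float] = None

    @property
    def sign(self) -> int:
        return 1 if self.height >= 0 else -1


@dataclass(frozen=True)
class Calibration:
    """Single-anchor cyclotron calibration f = K / (m/z), K in Hz*Th."""

    K: float = 74_728.13 * 1450.0  # anchored at (74,728.13 Hz, m/z 1450)

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("calibration constant K must be positive")


def pick_peaks(
    positions: np.ndarray,
    scan: np.ndarray,
    threshold: float,
) -> List[Peak]:
    """Local extrema of |scan| above ``threshold``, parabolically refined.

    Sign is the sign of the scan value at the extremum; position ties break
    toward lower frequency (peaks are returned in ascending position).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    positions = np.asarray(positions, dtype=float)
    scan = np.asarray(scan, dtype=float)
    mag = np.abs(scan)
    peaks: List[Peak] = []
    for i in range(1, scan.size - 1):
        if mag[i] < threshold:
            continue
        # strict rise on the left, non-strict fall on the right: a flat-top
        # plateau yields its leftmost (lower-frequency) sample
        if mag[i] > mag[i - 1] and mag[i] >= mag[i + 1]:
            pos = _parabolic_vertex(positions, mag, i)
            peaks.append(Peak(position=pos, height=float(scan[i]), index=i))
    return peaks


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> float:
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[i] - x[i - 1]))


def fwhm(positions: np.ndarray, scan: np.ndarray, peak: Peak) -> float:
    """Full width at half maximum by linear interpolation of the crossings.

    Works on the signed scan oriented so the peak is positive.  Raises
    UnresolvedPeakError if either flank never falls below half height.
    """
    positions = np.asarray(positions, dtype=float)
    y = np.asarray(scan, dtype=float) * peak.sign
    i = peak.index
    half = 0.5 * abs(peak.height)

    def cross(direction: int) -> float:
        j = i
        while 0 <= j + direction < y.size:
            if y[j + direction] < half:
                a, b = y[j], y[j + direction]
                frac = (a - half) / (a - b)
                return float(positions[j] + frac * (positions[j + direction] - positions[j]))
            j += direction
        raise UnresolvedPeakError(
            f"flank at direction {direction} of peak at {peak.position} "
            "never falls below half height"
        )

    return abs(cross(+1) - cross(-1))


def resolving_power(mz: float, fwhm_mz: float) -> float:
    """R = (m/z) / FWHM, both in Th."""
    if mz <= 0 or fwhm_mz <= 0:
        raise ValueError("m/z and FWHM must be positive")
    return mz / fwhm_mz


def snr(scan: np.ndarray, peak: Peak, noise_window: slice) -> float:
    """|peak height| / RMS-about-zero of the samples in ``noise_window``.

    The noise window must be signal-free and disjoint from any peak; for
    magnitude scans the RMS is still taken about zero, not about the
    Rayleigh mean.
    """
    noise = np.asarray(scan)[noise_window]
    if noise.size == 0:
        raise ValueError("empty noise window")
    rms = float(np.sqrt(np.mean(np.square(np.abs(noise)))))
    if rms == 0.0:
        raise ValueError("zero noise RMS: noise window contains no noise")
    return abs(peak.height) / rms


def fold_index(f_true: float, bandwidth: float) -> int:
    """Number of times a signal at f_true folds into [0, bandwidth)."""
    if f_true < 0:
        raise ValueError("f_true must be >= 0")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return int(np.floor(f_true / bandwidth))


def foldover_sign(n_folds: int) -> int:
    """Peak sign after n foldovers: +1 for even n, -1 for odd n.

    Amplitude-modulated data under the real vertical FT shifts phase by
    180 degrees per fold, so an even fold count leaves the sign unchanged
    (phase shifted by a multiple of 360 degrees) and an odd count inverts it.
    """
    if n_folds < 0:
        raise ValueError("fold count must be >= 0")
    return 1 if n_folds % 2 == 0 else -1


def estimate_demod_from_split(
    positions: np.ndarray,
    scan: np.ndarray,
    nominal_f_demod: float,
    reprocess: Optional[Callable[[float], np.ndarray]] = None,
    threshold_frac: float = 0.2,
) -> Tuple[float, float]:
    """Demodulation-frequency correction from a split vertical peak pair.

    ``scan`` is a vertical scan (magnitude or absolute) processed at the
    nominal demodulation frequency; a demodulation offset delta splits the
    peak into two components 2*delta apart.  Returns (delta, corrected
    f_demod).  The sign of the correction is resolved by ``reprocess``,
    a callable mapping a candidate f_demod to a new scan: the candidate
    minimizing the residual splitting wins.  Without ``reprocess`` the
    positive sign is returned.  Raises NoSplitError when no pair resolves.
    """
    positions = np.asarray(positions, dtype=float)
    mags = np.abs(np.asarray(scan, dtype=float))
    top = float(mags.max())
    if top == 0.0:
        raise NoSplitError("scan is empty")
    peaks = pick_peaks(positions, mags, threshold_frac * top)
    if len(peaks) < 2:
        raise NoSplitError("no split pair detected; demodulation already correct")
    # two strongest components
    peaks = sorted(peaks, key=lambda p: abs(p.height), reverse=True)[:2]
    delta = abs(peaks[0].position - peaks[1].position) / 2.0
    if delta == 0.0:
        raise NoSplitError("coincident components; no split")
    if reprocess is None:
        return delta, nominal_f_demod + delta

    def residual_split(candidate: float) -> float:
        new = np.abs(np.asarray(reprocess(candidate), dtype=float))
        new_top = float(new.max())
        if new_top == 0.0:
            return np.inf
        cand = pick_peaks(positions, new, threshold_frac * new_top)
        if len(cand) < 2:
            return 0.0
        cand = sorted(cand, key=lambda p: abs(p.height), reverse=True)[:2]
        return abs(cand[0].position - cand[1].position)

    plus = residual_split(nominal_f_demod + delta)
    minus = residual_split(nominal_f_demod - delta)
    if plus <= minus:
        return delta, nominal_f_demod + delta
    return -delta, nominal_f_demod - delta


def freq_to_mz(f: float, cal: Calibration) -> float:
    """m/z = K / f (single-anchor cyclotron law)."""
    if np.any(np.asarray(f) <= 0):
        raise ValueError("frequency must be positive")
    return cal.K / f


def mz_to_freq(mz: float, cal: Calibration) -> float:
    """f = K / (m/z); strict inverse of freq_to_mz."""
    if np.any(np.asarray(mz) <= 0):
        raise ValueError("m/z must be positive")
    return cal.K / mz


def max_isotope_resolved_mass(R: float) -> float:
    """Largest neutral mass (Da) whose ~1 Da isotope spacing stays resolved.

    FWHM in m/z is (m/z)/R and the isotope spacing is ~1 Da per charge, so
    spacing >= FWHM exactly when m <= R * 1 Da.
    """
    if R <= 0:
        raise ValueError("resolving power must be positive")
    return R * 1.0


def extract_scan(
    S: HypercomplexSpectrum,
    axis: int,
    position: float,
    plane: str = "rr",
) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-bin 1D scan through a 2D spectrum.

    ``axis=1`` extracts a vertical (precursor) scan at fragment frequency
    ``position``; ``axis=2`` a horizontal (fragment) scan at precursor
    frequency ``position``.  Returns (axis values, complex scan): the real
    part is the requested plane and the imaginary part the quadrature
    partner along the scan direction (RI for vertical, IR for horizontal;
    zero if dropped), so a zero-order rotation can still be applied.
    """
    partners = {1: {"rr": "ri", "ir": "ii"}, 2: {"rr": "ir", "ri": "ii"}}
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    if plane not in partners[axis]:
        raise ValueError(f"cannot extract axis-{axis} scan from plane {plane!r}")
    imag_plane = partners[axis][plane]
    if axis == 1:
        idx = S.axis2.index_of(position)
        values = S.plane(plane)[:, idx] + 1j * S.plane(imag_plane)[:, idx]
        return S.axis1.values, values
    idx = S.axis1.index_of(position)
    values = S.plane(plane)[idx, :] + 1j * S.plane(imag_plane)[idx, :]
    return S.axis2.values, values


def apply_zero_order(scan: np.ndarray, phi0: float) -> np.ndarray:
    """Rotate a complex scan by exp(-i*phi0) (correction convention)."""
    return np.asarray(scan) * np.exp(-1j * phi0)


def peak_table(
    positions: np.ndarray,
    scan: np.ndarray,
    threshold: float,
    noise_window: Optional[slice] = None,
) -> pd.DataFrame:
    """Peak list with position, height, FWHM, sign and (optional) S/N.

    FWHM is NaN for peaks whose flanks never resolve below half height.
    """
    rows = []
    for pk in pick_peaks(positions, scan, threshold):
        try:
            width = fwhm(positions, scan, pk)
        except UnresolvedPeakError:
            width = np.nan
        row = {
            "position": pk.position,
            "height": pk.height,
            "fwhm": width,
            "sign": pk.sign,
        }
        if noise_window is not None:
            row["snr"] = snr(scan, pk, noise_window)
        rows.append(row)
    return pd.DataFrame(rows)


def write_scan(path: str, positions: np.ndarray, values: np.ndarray) -> None:
    """Two-column delimited text export (position, intensity)."""
    np.savetxt(path, np.column_stack([positions, np.real(values)]),
               delimiter="\t", header="position\tintensity")
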