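"""Apodization, zero-filling, row/column Fourier transforms and demodulation.

The time-domain object is a real stack of transients s(t1, t2): each row is
one detection transient recorded after an encoding delay t1, sampled at the
detection dwell along t2.  Processing runs row-wise first (fragment axis,
f2), then column-wise (precursor axis, f1).

Sign convention: the forward transform is exp(-i 2*pi*f*t) (numpy default),
fixed globally.  A component cos(2*pi*f*t + theta) therefore lands on the
positive-frequency half with complex amplitude (N/2) * exp(+i*theta), and a
phase correction multiplies by exp(-i*theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .hypercomplex import FrequencyAxis, HypercomplexSpectrum

__all__ = [
    "TransientStack",
    "RowSpectrumStack",
    "sine_bell",
    "zero_fill",
    "ft_rows",
    "demodulate",
    "ft_columns",
]


@dataclass
class TransientStack:
    """Real 2D time-domain data: n1 encoding increments x n2 detection points.

    ``t1_start``/``t1_step`` give the encoding-delay grid in seconds;
    ``t2_dwell`` the detection sampling period.  ``metadata`` carries the
    pulse-sequence parameters (durations, frequency range) when known.
    """

    data: np.ndarray
    t1_start: float
    t1_step: float
    t2_dwell: float
    metadata: Optional[object] = None  # PulseSequenceParams, kept untyped to avoid cycles

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("transient stack must be 2D (n1 x n2)")
        n1, n2 = self.data.shape
        if n1 < 1 or n2 < 2:
            raise ValueError("need n1 >= 1 rows and n2 >= 2 detection points")
        if self.t1_step <= 0 or self.t2_dwell <= 0:
            raise ValueError("t1_step and t2_dwell must be positive")

    @property
    def n1(self) -> int:
        return self.data.shape[0]

    @property
    def n2(self) -> int:
        return self.data.shape[1]

    @property
    def t1_values(self) -> np.ndarray:
        return self.t1_start + self.t1_step * np.arange(self.n1)

    @property
    def t2_values(self) -> np.ndarray:
        return self.t2_dwell * np.arange(self.n2)


@dataclass
class RowSpectrumStack:
    """Intermediate after the row FT: complex rows over the fragment axis.

    ``data`` is (n1 rows x m2 frequency bins); ``axis2`` the fragment
    frequency grid with bin spacing 1 / (filled record length * dwell).
    """

    data: np.ndarray
    axis2: FrequencyAxis
    t1_start: float
    t1_step: float
    metadata: Optional[object] = None

    @property
    def n1(self) -> int:
        return self.data.shape[0]

    @property
    def t1_values(self) -> np.ndarray:
        return self.t1_start + self.t1_step * np.arange(self.n1)

    def copy(self) -> "RowSpectrumStack":
        return replace(self, data=self.data.copy())


def sine_bell(n: int, max_pos: float = 0.15) -> np.ndarray:
    """Shifted sine-bell apodization window.

    w(u) = sin(pi * (phi0 + (1 - phi0) * u)),  u = index / (n - 1),
    phi0 = (0.5 - max_pos) / (1 - max_pos)

    so the bell peaks (w = 1) at u = max_pos and falls to exactly 0 at the
    last point.  ``max_pos`` must lie in (0, 0.5]; max_pos = 0.5 is the plain
    unshifted sine bell.
    """
    if n < 2:
        raise ValueError("window needs n >= 2")
    if not (0.0 < max_pos <= 0.5):
        raise ValueError("max_pos must lie in (0, 0.5]")
    u = np.arange(n) / (n - 1)
    phi0 = (0.5 - max_pos) / (1.0 - max_pos)
    return np.sin(np.pi * (phi0 + (1.0 - phi0) * u))


def zero_fill(vector: np.ndarray, doublings: int) -> np.ndarray:
    """Append zeros until the last-axis length is multiplied by 2**doublings."""
    if doublings < 0:
        raise ValueError("doublings must be >= 0")
    vector = np.asarray(vector)
    if doublings == 0:
        return vector.copy()
    n = vector.shape[-1]
    pad = [(0, 0)] * (vector.ndim - 1) + [(0, n * (2**doublings - 1))]
    return np.pad(vector, pad)


def ft_rows(
    stack: TransientStack,
    window: Optional[np.ndarray] = None,
    doublings: int = 2,
) -> RowSpectrumStack:
    """Apodize, zero-fill and Fourier transform each detection transient.

    Returns the positive-frequency half-spectrum of each (real) row: bin b
    maps to b / (M * dwell) where M is the filled record length.
    """
    data = stack.data
    if window is not None:
        window = np.asarray(window, dtype=float)
        if window.shape != (stack.n2,):
            raise ValueError(
                f"window length {window.shape} does not match n2 = {stack.n2}"
            )
        data = data * window[None, :]
    data = zero_fill(data, doublings)
    m = data.shape[1]
    spec = np.fft.fft(data, axis=1)[:, : m // 2]
    axis2 = FrequencyAxis(start_hz=0.0, step_hz=1.0 / (m * stack.t2_dwell),
                          n_points=m // 2)
    return RowSpectrumStack(
        data=spec,
        axis2=axis2,
        t1_start=stack.t1_start,
        t1_step=stack.t1_step,
        metadata=stack.metadata,
    )


def demodulate(rows: RowSpectrumStack, f_demod: float) -> RowSpectrumStack:
    """Remove the generator phase roll 2*pi*f_demod*t1 along the t1 axis.

    Each row at encoding delay t1 is multiplied by exp(-i 2*pi*f_demod*t1),
    the complex rotation opposite to the frequency-generator advance that is
    locked to the lowest pulse frequency f_min.  Demodulating at the wrong
    frequency (offset delta) leaves a residual rotation that splits every
    vertical peak into a pair 2*delta apart.
    """
    rot = np.exp(-2j * np.pi * f_demod * rows.t1_values)
    return replace(rows, data=rows.data * rot[:, None])


def ft_columns(
    rows: RowSpectrumStack,
    window: Optional[np.ndarray] = None,
    doublings: int = 2,
    use_row_imaginary: bool = True,
) -> HypercomplexSpectrum:
    """Fourier transform each column and assemble the hypercomplex quadrants.

    Each retained row plane (real part A, and imaginary part B unless it was
    dropped) is apodized and zero-filled along t1 and transformed with a
    complex FT of the real column, keeping the positive half -- the "real
    Fourier transform" appropriate for amplitude (cosine) modulated data.
    The quadrants are RR = Re FT(A), RI = Im FT(A), IR = Re FT(B),
    II = Im FT(B).
    """
    if rows.n1 < 2:
        raise ValueError("need at least 2 rows for the column transform")
    planes = [np.real(rows.data)]
    if use_row_imaginary:
        planes.append(np.imag(rows.data))
    if window is not None:
        window = np.asarray(window, dtype=float)
        if window.shape != (rows.n1,):
            raise ValueError(
                f"window length {window.shape} does not match n1 = {rows.n1}"
            )
        planes = [p * window[:, None] for p in planes]
    planes = [zero_fill(p.T, doublings).T for p in planes]
    m1 = planes[0].shape[0]
    ft = [np.fft.fft(p, axis=0)[: m1 // 2, :] for p in planes]
    axis1 = FrequencyAxis(start_hz=0.0, step_hz=1.0 / (m1 * rows.t1_step),
                          n_points=m1 // 2)
    rr, ri = np.real(ft[0]), np.imag(ft[0])
    if use_row_imaginary:
        ir, ii = np.real(ft[1]), np.imag(ft[1])
    else:
        ir, ii = None, None
    return HypercomplexSpectrum(
        plane_rr=rr, plane_ri=ri, plane_ir=ir, plane_ii=ii,
        axis1=axis1, axis2=rows.axis2,
    )
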