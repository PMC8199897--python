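"""Bicomplex (hypercomplex) values and spectra for 2D FT-ICR MS.

A two-dimensional amplitude-modulated FT-ICR data set transforms into a
four-quadrant spectrum

    S(f1, f2) = RR + i*RI + j*IR + k*II

where the four planes are real grids over the (precursor f1, fragment f2)
frequency mesh and the units obey the *commutative* bicomplex rules

    i^2 = j^2 = -1,   k^2 = +1,
    i*j = j*i = k,    i*k = k*i = -j,    j*k = k*j = -i.

This is the bicomplex ring C(i) (x) C(j), not the quaternions (note k^2 = +1
and ij = ji).  The two imaginary units act on different frequency axes, so a
phase correction ``exp(i*phi1(f1))`` rotates the vertical (precursor)
dimension and ``exp(j*phi2(f2))`` the horizontal (fragment) dimension, and
the two rotations commute.

Conventions
-----------
* ``i`` belongs to axis 1 (vertical / precursor): RI is the i-component,
  i.e. the axis-1 imaginary part of the axis-2 real part.
* ``j`` belongs to axis 2 (horizontal / fragment): IR is the j-component.
* Plane arrays are indexed ``[axis1, axis2]``; the four planes are stored as
  separate real grids so that axis-wise FFTs and imaginary-part drops
  operate on whole planes.
* Angles are radians everywhere inside the library.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional, Union

import numpy as np

__all__ = [
    "HypercomplexValue",
    "FrequencyAxis",
    "HypercomplexSpectrum",
    "hc_multiply",
    "apply_phase_axis1",
    "apply_phase_axis2",
    "magnitude2d",
    "drop_imaginary",
    "ONE",
    "I",
    "J",
    "K",
]


@dataclass(frozen=True)
class HypercomplexValue:
    """A single bicomplex number ``rr + i*ri + j*ir + k*ii``."""

    rr: float = 0.0
    ri: float = 0.0
    ir: float = 0.0
    ii: float = 0.0

    def __add__(self, other: "HypercomplexValue") -> "HypercomplexValue":
        return HypercomplexValue(
            self.rr + other.rr, self.ri + other.ri,
            self.ir + other.ir, self.ii + other.ii,
        )

    def __sub__(self, other: "HypercomplexValue") -> "HypercomplexValue":
        return HypercomplexValue(
            self.rr - other.rr, self.ri - other.ri,
            self.ir - other.ir, self.ii - other.ii,
        )

    def __neg__(self) -> "HypercomplexValue":
        return HypercomplexValue(-self.rr, -self.ri, -self.ir, -self.ii)

    def __mul__(self, other: Union["HypercomplexValue", float, int]) -> "HypercomplexValue":
        if isinstance(other, (int, float)):
            return HypercomplexValue(
                self.rr * other, self.ri * other, self.ir * other, self.ii * other
            )
        return hc_multiply(self, other)

    __rmul__ = __mul__

    def isclose(self, other: "HypercomplexValue", atol: float = 1e-12) -> bool:
        return bool(
            np.isclose(self.rr, other.rr, atol=atol)
            and np.isclose(self.ri, other.ri, atol=atol)
            and np.isclose(self.ir, other.ir, atol=atol)
            and np.isclose(self.ii, other.ii, atol=atol)
        )

    def magnitude(self) -> float:
        return float(np.sqrt(self.rr**2 + self.ri**2 + self.ir**2 + self.ii**2))


#: Basis elements of the bicomplex ring.
ONE = HypercomplexValue(rr=1.0)
I = HypercomplexValue(ri=1.0)
J = HypercomplexValue(ir=1.0)
K = HypercomplexValue(ii=1.0)


def hc_multiply(a: HypercomplexValue, b: HypercomplexValue) -> HypercomplexValue:
    """Product of two bicomplex numbers.

    Distributes over the 16 basis products with i^2 = j^2 = -1, k^2 = +1,
    ij = ji = k, ik = ki = -j, jk = kj = -i.  The product is commutative and
    associative.
    """
    return HypercomplexValue(
        rr=a.rr * b.rr - a.ri * b.ri - a.ir * b.ir + a.ii * b.ii,
        ri=a.rr * b.ri + a.ri * b.rr - a.ir * b.ii - a.ii * b.ir,
        ir=a.rr * b.ir + a.ir * b.rr - a.ri * b.ii - a.ii * b.ri,
        ii=a.rr * b.ii + a.ii * b.rr + a.ri * b.ir + a.ir * b.ri,
    )


@dataclass(frozen=True)
class FrequencyAxis:
    """A uniform frequency grid ``start + step * arange(n)``.

    ``unit`` is a tag ("Hz" by default, "m/z" after conversion) carried for
    labelling only; all spectral arithmetic happens in Hz.
    """

    start_hz: float
    step_hz: float
    n_points: int
    unit: str = "Hz"

    def __post_init__(self) -> None:
        if self.step_hz <= 0:
            raise ValueError("frequency step must be positive")
        if self.n_points < 2:
            raise ValueError("a frequency axis needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return self.start_hz + self.step_hz * np.arange(self.n_points)

    @property
    def stop_hz(self) -> float:
        return self.start_hz + self.step_hz * (self.n_points - 1)

    def index_of(self, freq: float) -> int:
        """Nearest-bin index of ``freq``; raises if outside the axis."""
        idx = int(round((freq - self.start_hz) / self.step_hz))
        if idx < 0 or idx >= self.n_points:
            raise ValueError(f"{freq} {self.unit} outside axis "
                             f"[{self.start_hz}, {self.stop_hz}]")
        return idx


@dataclass
class HypercomplexSpectrum:
    """Four co-registered real planes over a (f1, f2) frequency mesh.

    A plane set to ``None`` has been dropped (it is exactly zero and is not
    stored, halving the memory footprint per drop).
    """

    plane_rr: np.ndarray
    plane_ri: Optional[np.ndarray]
    plane_ir: Optional[np.ndarray]
    plane_ii: Optional[np.ndarray]
    axis1: FrequencyAxis
    axis2: FrequencyAxis

    def __post_init__(self) -> None:
        shape = self.plane_rr.shape
        for name in ("plane_ri", "plane_ir", "plane_ii"):
            p = getattr(self, name)
            if p is not None and p.shape != shape:
                raise ValueError(f"{name} shape {p.shape} != RR shape {shape}")
        if shape != (self.axis1.n_points, self.axis2.n_points):
            raise ValueError(
                f"plane shape {shape} does not match axes "
                f"({self.axis1.n_points}, {self.axis2.n_points})"
            )

    @property
    def shape(self) -> tuple:
        return self.plane_rr.shape

    def plane(self, name: str) -> np.ndarray:
        """Plane by name ('rr', 'ri', 'ir', 'ii'); zeros if dropped."""
        p = getattr(self, f"plane_{name}")
        if p is None:
            return np.zeros_like(self.plane_rr)
        return p

    def copy(self) -> "HypercomplexSpectrum":
        return HypercomplexSpectrum(
            self.plane_rr.copy(),
            None if self.plane_ri is None else self.plane_ri.copy(),
            None if self.plane_ir is None else self.plane_ir.copy(),
            None if self.plane_ii is None else self.plane_ii.copy(),
            self.axis1,
            self.axis2,
        )


PhaseFunction = Union[Callable[[np.ndarray], np.ndarray], np.ndarray, float]


def _phase_values(phi: PhaseFunction, axis: FrequencyAxis) -> np.ndarray:
    if callable(phi):
        out = np.asarray(phi(axis.values), dtype=float)
    else:
        out = np.broadcast_to(np.asarray(phi, dtype=float), (axis.n_points,)).copy()
    if out.shape != (axis.n_points,):
        raise ValueError(
            f"phase evaluations have shape {out.shape}, expected ({axis.n_points},)"
        )
    return out


def apply_phase_axis1(S: HypercomplexSpectrum, phi: PhaseFunction) -> HypercomplexSpectrum:
    """Rotate ``S`` by ``exp(i*phi(f1))`` along the vertical (precursor) axis.

    Per row, ``S * (cos phi1 + i sin phi1)`` mixes the plane pairs
    (RR, RI) and (IR, II):

        RR' = RR cos - RI sin      RI' = RR sin + RI cos
        IR' = IR cos - II sin      II' = IR sin + II cos
    """
    phi1 = _phase_values(phi, S.axis1)
    c = np.cos(phi1)[:, None]
    s = np.sin(phi1)[:, None]
    rr, ri = S.plane("rr"), S.plane("ri")
    ir, ii = S.plane("ir"), S.plane("ii")
    new_ir: Optional[np.ndarray]
    new_ii: Optional[np.ndarray]
    if S.plane_ir is None and S.plane_ii is None:
        new_ir, new_ii = None, None  # i-rotation never populates j/k planes
    else:
        new_ir = ir * c - ii * s
        new_ii = ir * s + ii * c
    return HypercomplexSpectrum(
        plane_rr=rr * c - ri * s,
        plane_ri=rr * s + ri * c,
        plane_ir=new_ir,
        plane_ii=new_ii,
        axis1=S.axis1,
        axis2=S.axis2,
    )


def apply_phase_axis2(S: HypercomplexSpectrum, phi: PhaseFunction) -> HypercomplexSpectrum:
    """Rotate ``S`` by ``exp(j*phi(f2))`` along the horizontal (fragment) axis.

    Mixes the plane pairs (RR, IR) and (RI, II).
    """
    phi2 = _phase_values(phi, S.axis2)
    c = np.cos(phi2)[None, :]
    s = np.sin(phi2)[None, :]
    rr, ri = S.plane("rr"), S.plane("ri")
    ir, ii = S.plane("ir"), S.plane("ii")
    new_ri: Optional[np.ndarray]
    new_ii: Optional[np.ndarray]
    if S.plane_ri is None and S.plane_ii is None:
        new_ri, new_ii = None, None
    else:
        new_ri = ri * c - ii * s
        new_ii = ri * s + ii * c
    return HypercomplexSpectrum(
        plane_rr=rr * c - ir * s,
        plane_ri=new_ri,
        plane_ir=rr * s + ir * c,
        plane_ii=new_ii,
        axis1=S.axis1,
        axis2=S.axis2,
    )


def magnitude2d(S: HypercomplexSpectrum) -> np.ndarray:
    """Element-wise 4-quadrant magnitude sqrt(RR^2 + RI^2 + IR^2 + II^2).

    Invariant under both axis rotations (they preserve the quadratic form).
    """
    out = np.square(S.plane_rr)
    for name in ("plane_ri", "plane_ir", "plane_ii"):
        p = getattr(S, name)
        if p is not None:
            out = out + np.square(p)
    return np.sqrt(out)


def drop_imaginary(S: HypercomplexSpectrum, axis: int) -> HypercomplexSpectrum:
    """Discard the planes imaginary along ``axis`` (1 or 2).

    axis=1 removes the i-components (RI, II); axis=2 removes the
    j-components (IR, II).  Dropping along both axes leaves only RR.
    """
    if axis == 1:
        return replace(S, plane_ri=None, plane_ii=None)
    if axis == 2:
        return replace(S, plane_ir=None, plane_ii=None)
    raise ValueError("axis must be 1 or 2")
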