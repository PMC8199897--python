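"""Pulse-sequence-faithful synthetic 2D FT-ICR transient generator.

Generates real time-domain stacks s(t1, t2) with the exact phase structure
of the narrowband 2D MS experiment, so that every processing stage has a
ground-truth oracle:

* precursor radius modulation r(t1) = r0/2 * (1 + cos 2*pi*(f_ICR - f_min)
  * (t1 - T1)) imprinted by the first two pulses;
* fragment abundance proportional to the de-excited fraction 1 - r/r0
  (centre-of-cell fragmentation), i.e. inverted modulation -- the origin of
  the pi shift between fragment and precursor vertical phases;
* the continuous-phase generator term 2*pi*f_min*(2*T1 + t1 + tau_m) on
  every fragment transient (removed later by digital demodulation);
* the chirp quadratic phase c2*f^2 + c1*f + c0 on each detected frequency;
* optional 2*omega harmonic components of the vertical modulation;
* optional detected (not fully de-excited) precursor terms carrying the
  precursor phase law, including its 2*pi*f1*t1 term.

Foldover is produced physically: species may modulate far above the t1
Nyquist band, and aliasing arises from the t1 sampling itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .phase_model import (
    PulseSequenceParams,
    QuadraticPhaseCoefficients,
    fragment_horizontal_phase,
    precursor_horizontal_phase,
)
from .transforms import TransientStack

__all__ = [
    "FragmentSpec",
    "IonSpecies",
    "NoiseModel",
    "AcquisitionGrid",
    "radius_modulation",
    "fragment_amplitude",
    "synthesize",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FragmentSpec:
    """One fragment line: detection frequency, abundance, harmonic content.

    ``harmonic2w_fraction`` injects a vertical amplitude-modulation
    component at twice the precursor modulation frequency, emulating the
    2-omega harmonic of the ion signal.
    """

    f2: float
    relative_abundance: float = 1.0
    harmonic2w_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.relative_abundance) or self.relative_abundance < 0:
            raise ValueError("relative_abundance must be finite and >= 0")
        if not (0.0 <= self.harmonic2w_fraction <= 1.0):
            raise ValueError("harmonic2w_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class IonSpecies:
    """A precursor ion and its fragments.

    ``f_icr`` is the precursor cyclotron frequency in Hz (convert m/z with
    analysis.mz_to_freq if needed).  ``r0`` scales all signal amplitudes.
    ``detect_precursor`` adds the surviving-precursor signal (radius
    modulation, precursor phase law) to the stack.
    ``deexcited_abundance`` adds unfragmented but fully de-excited
    precursors re-excited by the third pulse: same frequency as the
    precursor but carrying the *fragment* phase law.
    """

    f_icr: float
    r0: float = 1.0
    fragments: Sequence[FragmentSpec] = field(default_factory=tuple)
    detect_precursor: bool = False
    deexcited_abundance: float = 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian detection noise."""

    gaussian_sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class AcquisitionGrid:
    """Detection grid: n2 samples at dwell t2_dwell per transient.

    The t1 grid (t1_start, t1_step, n1) lives in PulseSequenceParams.
    """

    n2: int
    t2_dwell: float

    def __post_init__(self) -> None:
        if self.n2 < 2:
            raise ValueError("n2 must be >= 2")
        if self.t2_dwell <= 0:
            raise ValueError("t2_dwell must be positive")


def radius_modulation(params: PulseSequenceParams, f_icr: float, t1) -> np.ndarray:
    """Precursor radius after the second pulse, as a fraction of r0.

    r(t1)/r0 = (1 + cos 2*pi*(f_ICR - f_min)*(t1 - T1)) / 2, bounded in
    [0, 1]; the modulation frequency over t1 is f_ICR - f_min.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 < 0):
        raise ValueError("t1 must be >= 0")
    f_mod = f_icr - params.f_min
    return 0.5 * (1.0 + np.cos(TWO_PI * f_mod * (t1 - params.T1)))


def fragment_amplitude(params: PulseSequenceParams, f_icr: float, t1) -> np.ndarray:
    """Fragment abundance fraction at encoding delay t1.

    Proportional to the de-excited precursor fraction 1 - r(t1)/r0 =
    (1 - cos 2*pi*(f_ICR - f_min)*(t1 - T1)) / 2: fragmentation efficiency
    is maximal when precursors are returned to the cell centre.  The sign
    inversion relative to the radius modulation encodes the pi shift of the
    fragment vertical phase.  Complementary: precursor and fragment
    modulations sum to 1 at every t1.
    """
    t1 = np.asarray(t1, dtype=float)
    f_mod = f_icr - params.f_min
    return 0.5 * (1.0 - np.cos(TWO_PI * f_mod * (t1 - params.T1)))


def synthesize(
    grid: AcquisitionGrid,
    species: Sequence[IonSpecies],
    coeffs_base: Optional[QuadraticPhaseCoefficients] = None,
    params: Optional[PulseSequenceParams] = None,
    noise: Optional[NoiseModel] = None,
    tau_damp: Optional[float] = None,
) -> TransientStack:
    """Generate a real transient stack for the given ion species.

    s(t1, t2) = sum over species and fragments of

        A * fragment_amplitude(t1)
          * (1 + h * cos(2 * 2*pi*(f_ICR - f_min)*(t1 - T1)))
          * cos(2*pi*f2*t2 + phi_f,h(f2; t1)) * exp(-t2 / tau_damp)

    plus detected-precursor terms A * r(t1)/r0 * cos(2*pi*f_ICR*t2 +
    phi_p,h(f_ICR; t1)) * exp(-t2/tau_damp), plus Gaussian noise.
    Deterministic for a fixed NoiseModel seed.

    ``tau_damp`` defaults to one third of the detection record length; pass
    ``np.inf`` for undamped transients.
    """
    params = params or PulseSequenceParams()
    coeffs = coeffs_base or QuadraticPhaseCoefficients()
    t1 = params.t1_start + params.t1_step * np.arange(params.n1)
    t2 = grid.t2_dwell * np.arange(grid.n2)
    record = grid.n2 * grid.t2_dwell
    if tau_damp is None:
        tau_damp = record / 3.0
    if tau_damp <= 0:
        raise ValueError("tau_damp must be positive (np.inf for undamped)")
    damp = np.exp(-t2 / tau_damp) if np.isfinite(tau_damp) else np.ones_like(t2)

    data = np.zeros((params.n1, grid.n2))
    for sp in species:
        f_mod = sp.f_icr - params.f_min
        frag_mod = fragment_amplitude(params, sp.f_icr, t1)
        for frag in sp.fragments:
            amp = sp.r0 * frag.relative_abundance * frag_mod
            if frag.harmonic2w_fraction > 0.0:
                amp = amp * (
                    1.0
                    + frag.harmonic2w_fraction
                    * np.cos(2.0 * TWO_PI * f_mod * (t1 - params.T1))
                )
            phi = fragment_horizontal_phase(coeffs, params, 0.0, frag.f2)
            phi_t1 = phi + TWO_PI * params.f_min * t1  # generator roll per row
            data += (
                amp[:, None]
                * np.cos(TWO_PI * frag.f2 * t2[None, :] + phi_t1[:, None])
                * damp[None, :]
            )
        if sp.deexcited_abundance > 0.0:
            amp = sp.r0 * sp.deexcited_abundance * frag_mod
            phi = fragment_horizontal_phase(coeffs, params, 0.0, sp.f_icr)
            phi_t1 = phi + TWO_PI * params.f_min * t1
            data += (
                amp[:, None]
                * np.cos(TWO_PI * sp.f_icr * t2[None, :] + phi_t1[:, None])
                * damp[None, :]
            )
        if sp.detect_precursor:
            amp = sp.r0 * radius_modulation(params, sp.f_icr, t1)
            # phase depends on t1 through the 2*pi*f1*t1 term of the
            # precursor law, evaluated row by row
            phi_rows = np.array([
                precursor_horizontal_phase(coeffs, params, float(tt), sp.f_icr)
                for tt in t1
            ])
            data += (
                amp[:, None]
                * np.cos(TWO_PI * sp.f_icr * t2[None, :] + phi_rows[:, None])
                * damp[None, :]
            )

    if noise is not None and noise.gaussian_sigma > 0.0:
        rng = np.random.default_rng(noise.seed)
        data += rng.normal(0.0, noise.gaussian_sigma, size=data.shape)

    return TransientStack(
        data=data,
        t1_start=params.t1_start,
        t1_step=params.t1_step,
        t2_dwell=grid.t2_dwell,
        metadata=params,
    )
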