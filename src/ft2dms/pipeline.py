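"""End-to-end processing chains, configuration and HDF5 persistence.

The absorption-mode 2D chain runs in this fixed order:

    row apodize -> row zero-fill -> row complex FT -> digital demodulation
    -> quadratic phase per row -> drop row imaginaries -> column apodize
    -> column zero-fill -> column real FT -> linear vertical phase
    -> drop column imaginaries

Magnitude mode skips both phase steps, zero-fills once per axis by default
(memory parity with typical magnitude workflows) and returns the 4-quadrant
magnitude.

HDF5 layout (version 1):

    /transient   data, t1_start, t1_step, t2_dwell, pulse_params (attrs)
    /spectrum    rr [, ri, ir, ii] or magnitude; axis1/axis2 attrs; mode
    /processing  config (JSON), phase coefficients, software version, log
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import h5py
import numpy as np

from . import __version__
from .hypercomplex import (
    FrequencyAxis,
    HypercomplexSpectrum,
    apply_phase_axis1,
    drop_imaginary,
    magnitude2d,
)
from .phase_model import (
    PhaseEstimationError,
    PulseSequenceParams,
    QuadraticPhaseCoefficients,
    VerticalPhaseParams,
    estimate_quadratic_from_tangents,
    eval_quadratic,
    fragment_coefficients,
    vertical_phase,
)
from .transforms import (
    RowSpectrumStack,
    TransientStack,
    demodulate,
    ft_columns,
    ft_rows,
    sine_bell,
    zero_fill,
)
from .analysis import estimate_demod_from_split, NoSplitError

__all__ = [
    "ProcessingConfig",
    "MagnitudeSpectrum",
    "Spectrum1D",
    "process_2d",
    "process_1d",
    "auto_regions",
    "save_transient",
    "load_transient",
    "save_spectrum",
    "load_spectrum",
    "SpectrumFormatError",
    "SpectrumModeError",
]

logger = logging.getLogger("ft2dms")

LAYOUT_VERSION = "1"


class SpectrumFormatError(RuntimeError):
    """The HDF5 file does not follow the expected layout/version."""


class SpectrumModeError(RuntimeError):
    """A magnitude file was loaded into an absorption workflow or vice versa."""


@dataclass
class ProcessingConfig:
    """Knobs of the 2D (and 1D) processing chains.

    ``row_zero_fill``/``col_zero_fill`` count length doublings ("zero-filled
    twice" = 2 doublings, x4); ``None`` resolves per mode (2 for absorption,
    1 for magnitude).  ``f_demod`` is a frequency in Hz, None (use the
    pulse-sequence f_min) or "auto" (estimate from the split-peak
    workflow).  ``quadratic`` is a QuadraticPhaseCoefficients (base chirp
    coefficients), "estimate" or None (no horizontal phasing).
    ``vertical_slope_turns`` overrides the theoretical f_N*T1 slope.
    """

    row_window_max_pos: Optional[float] = 0.15
    row_zero_fill: Optional[int] = None
    f_demod: Union[float, str, None] = None
    quadratic: Union[QuadraticPhaseCoefficients, str, None] = None
    col_window_max_pos: Optional[float] = 0.15
    col_zero_fill: Optional[int] = None
    vertical_slope_turns: Optional[float] = None
    pi_shift: bool = True
    vertical_zero_order: float = 0.0
    mode: str = "absorption"
    drop_imaginaries: bool = True
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("absorption", "magnitude"):
            raise ValueError("mode must be 'absorption' or 'magnitude'")
        for zf in (self.row_zero_fill, self.col_zero_fill):
            if zf is not None and zf < 0:
                raise ValueError("zero-fill doublings must be >= 0")

    def resolved_zero_fills(self) -> Tuple[int, int]:
        default = 2 if self.mode == "absorption" else 1
        row = default if self.row_zero_fill is None else self.row_zero_fill
        col = default if self.col_zero_fill is None else self.col_zero_fill
        return row, col

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.quadratic, QuadraticPhaseCoefficients):
            d["quadratic"] = dataclasses.asdict(self.quadratic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingConfig":
        d = dict(d)
        q = d.get("quadratic")
        if isinstance(q, dict):
            d["quadratic"] = QuadraticPhaseCoefficients(**q)
        return cls(**d)


@dataclass
class MagnitudeSpectrum:
    """2D magnitude-mode spectrum (phase-insensitive display)."""

    data: np.ndarray
    axis1: FrequencyAxis
    axis2: FrequencyAxis


@dataclass
class Spectrum1D:
    """1D complex spectrum; ``absorption`` is the phased real part."""

    axis: FrequencyAxis
    values: np.ndarray

    @property
    def absorption(self) -> np.ndarray:
        return np.real(self.values)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def _checksum(arr: np.ndarray) -> int:
    return zlib.adler32(np.ascontiguousarray(arr).tobytes())


def _resolve_params(stack: TransientStack) -> PulseSequenceParams:
    if isinstance(stack.metadata, PulseSequenceParams):
        return stack.metadata
    return PulseSequenceParams(t1_start=stack.t1_start, t1_step=stack.t1_step,
                               n1=stack.n1)


def auto_regions(
    freqs: np.ndarray,
    spectrum: np.ndarray,
    n_regions: int = 5,
    width_hz: Optional[float] = None,
    min_separation_hz: Optional[float] = None,
) -> List[Tuple[float, float]]:
    """Frequency windows around the strongest well-separated peaks.

    Used to seed the tangent-based quadratic phase estimation when no
    regions are supplied.
    """
    freqs = np.asarray(freqs, dtype=float)
    mags = np.abs(np.asarray(spectrum))
    span = freqs[-1] - freqs[0]
    width = width_hz if width_hz is not None else span / 50.0
    min_sep = min_separation_hz if min_separation_hz is not None else 2.0 * width
    order = np.argsort(mags)[::-1]
    centers: List[float] = []
    for idx in order:
        f = freqs[idx]
        if all(abs(f - c) >= min_sep for c in centers):
            centers.append(float(f))
        if len(centers) >= n_regions:
            break
    centers.sort()
    return [(c - width / 2.0, c + width / 2.0) for c in centers]


def _estimate_quadratic(rows: RowSpectrumStack) -> QuadraticPhaseCoefficients:
    """Tangent-fit coefficients from the t1-averaged row spectrum."""
    avg = rows.data.mean(axis=0)
    freqs = rows.axis2.values
    regions = auto_regions(freqs, avg)
    fit = estimate_quadratic_from_tangents(freqs, avg, regions)
    logger.info("quadratic estimate c0=%g c1=%g c2=%g, slope residuals %s",
                fit.coefficients.c0, fit.coefficients.c1, fit.coefficients.c2,
                fit.slope_residuals)
    return fit.coefficients


def _resolve_f_demod(
    stack: TransientStack,
    cfg: ProcessingConfig,
    params: PulseSequenceParams,
) -> float:
    if cfg.f_demod is None:
        return params.f_min
    if cfg.f_demod == "auto":
        return _auto_demod(stack, cfg, params)
    return float(cfg.f_demod)


def _auto_demod(
    stack: TransientStack,
    cfg: ProcessingConfig,
    params: PulseSequenceParams,
) -> float:
    """Split-peak demodulation workflow: process at the nominal frequency,
    measure the split, keep the candidate that removes it."""
    nominal = params.f_min

    def vertical_scan(f_demod: float) -> Tuple[np.ndarray, np.ndarray]:
        rows = ft_rows(stack, None, 0)
        rows = demodulate(rows, f_demod)
        spec = ft_columns(rows, None, 1, use_row_imaginary=True)
        mag = magnitude2d(spec)
        col = int(np.argmax(mag.max(axis=0)))
        return spec.axis1.values, mag[:, col]

    pos, scan = vertical_scan(nominal)
    try:
        delta, corrected = estimate_demod_from_split(
            pos, scan, nominal,
            reprocess=lambda f: vertical_scan(f)[1],
        )
    except NoSplitError:
        return nominal
    logger.info("auto demodulation: delta=%g Hz, corrected f_demod=%g Hz",
                delta, corrected)
    return corrected


def process_2d(
    stack: TransientStack,
    cfg: Optional[ProcessingConfig] = None,
    coeffs: Optional[QuadraticPhaseCoefficients] = None,
) -> Union[HypercomplexSpectrum, MagnitudeSpectrum]:
    """Run the full 2D chain; absorption returns a HypercomplexSpectrum
    (planes dropped per config), magnitude mode a MagnitudeSpectrum.

    ``coeffs`` overrides cfg.quadratic; they are *base* chirp coefficients,
    assembled into the fragment function (generator constant folded into the
    zero order) before application.
    """
    cfg = cfg or ProcessingConfig()
    params = _resolve_params(stack)
    row_zf, col_zf = cfg.resolved_zero_fills()
    row_win = (sine_bell(stack.n2, cfg.row_window_max_pos)
               if cfg.row_window_max_pos else None)
    rows = ft_rows(stack, row_win, row_zf)
    logger.info("row FT: shape=%s checksum=%d", rows.data.shape,
                _checksum(rows.data))

    f_demod = _resolve_f_demod(stack, cfg, params)
    rows = demodulate(rows, f_demod)
    logger.info("demodulated at %g Hz", f_demod)

    absorption = cfg.mode == "absorption"
    if absorption:
        base = coeffs if coeffs is not None else cfg.quadratic
        if base == "estimate":
            base = _estimate_quadratic(rows)
        if base is not None:
            applied = fragment_coefficients(base, params, demodulated=True)
            phi2 = eval_quadratic(applied, rows.axis2.values)
            rows.data = rows.data * np.exp(-1j * phi2)[None, :]
            logger.info("quadratic phase applied: c0=%g c1=%g c2=%g",
                        applied.c0, applied.c1, applied.c2)

    use_imag = not (absorption and cfg.drop_imaginaries)
    col_win = (sine_bell(stack.n1, cfg.col_window_max_pos)
               if cfg.col_window_max_pos and stack.n1 >= 2 else None)
    spec = ft_columns(rows, col_win, col_zf, use_row_imaginary=use_imag)
    logger.info("column FT: shape=%s", spec.shape)

    if not absorption:
        return MagnitudeSpectrum(data=magnitude2d(spec), axis1=spec.axis1,
                                 axis2=spec.axis2)

    T1_eff = params.T1
    if cfg.vertical_slope_turns is not None:
        T1_eff = cfg.vertical_slope_turns / params.vertical_bandwidth
    vp = VerticalPhaseParams(f_min=0.0, T1=T1_eff, pi_shift=cfg.pi_shift,
                             extra_zero_order=cfg.vertical_zero_order)
    spec = apply_phase_axis1(spec, lambda f1: vertical_phase(vp, f1))
    logger.info("vertical phase applied: slope %g turns over %g Hz",
                T1_eff * params.vertical_bandwidth, params.vertical_bandwidth)
    if cfg.drop_imaginaries:
        spec = drop_imaginary(spec, 1)
    return spec


def process_1d(
    transient: np.ndarray,
    dwell: float,
    cfg: Optional[ProcessingConfig] = None,
    coeffs: Optional[QuadraticPhaseCoefficients] = None,
) -> Spectrum1D:
    """1D chain: apodize -> zero-fill -> FT -> quadratic phase.

    ``coeffs`` here are the *effective* 1D coefficients (chirp plus delay
    terms as estimated from the 1D tandem spectrum); "estimate" in the
    config triggers the tangent workflow on the spectrum itself.
    """
    cfg = cfg or ProcessingConfig()
    transient = np.asarray(transient, dtype=float)
    if transient.ndim != 1 or transient.size < 2:
        raise ValueError("transient must be a 1D array with >= 2 samples")
    data = transient
    if cfg.row_window_max_pos:
        data = data * sine_bell(data.size, cfg.row_window_max_pos)
    row_zf, _ = cfg.resolved_zero_fills()
    data = zero_fill(data, row_zf)
    m = data.size
    values = np.fft.fft(data)[: m // 2]
    axis = FrequencyAxis(start_hz=0.0, step_hz=1.0 / (m * dwell), n_points=m // 2)
    base = coeffs if coeffs is not None else cfg.quadratic
    if base == "estimate":
        regions = auto_regions(axis.values, values)
        base = estimate_quadratic_from_tangents(axis.values, values, regions).coefficients
    if base is not None:
        values = values * np.exp(-1j * eval_quadratic(base, axis.values))
    return Spectrum1D(axis=axis, values=values)


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def _write_axis(group: h5py.Group, name: str, axis: FrequencyAxis) -> None:
    g = group.create_group(name)
    g.attrs["start_hz"] = axis.start_hz
    g.attrs["step_hz"] = axis.step_hz
    g.attrs["n_points"] = axis.n_points
    g.attrs["unit"] = axis.unit


def _read_axis(group: h5py.Group, name: str) -> FrequencyAxis:
    g = group[name]
    return FrequencyAxis(
        start_hz=float(g.attrs["start_hz"]),
        step_hz=float(g.attrs["step_hz"]),
        n_points=int(g.attrs["n_points"]),
        unit=str(g.attrs["unit"]),
    )


def save_transient(path: str, stack: TransientStack) -> None:
    """Lossless HDF5 round-trip of a transient stack (64-bit floats)."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["software_version"] = __version__
        g = f.create_group("transient")
        g.create_dataset("data", data=stack.data, dtype="f8")
        g.attrs["t1_start"] = stack.t1_start
        g.attrs["t1_step"] = stack.t1_step
        g.attrs["t2_dwell"] = stack.t2_dwell
        if isinstance(stack.metadata, PulseSequenceParams):
            g.attrs["pulse_params"] = json.dumps(
                dataclasses.asdict(stack.metadata))


def load_transient(path: str) -> TransientStack:
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "transient" not in f:
            raise SpectrumFormatError("no /transient group in file")
        g = f["transient"]
        metadata = None
        if "pulse_params" in g.attrs:
            metadata = PulseSequenceParams(**json.loads(g.attrs["pulse_params"]))
        return TransientStack(
            data=g["data"][...],
            t1_start=float(g.attrs["t1_start"]),
            t1_step=float(g.attrs["t1_step"]),
            t2_dwell=float(g.attrs["t2_dwell"]),
            metadata=metadata,
        )


def _check_version(f: h5py.File) -> None:
    version = f.attrs.get("layout_version")
    if version != LAYOUT_VERSION:
        raise SpectrumFormatError(
            f"unsupported or missing layout version {version!r}")


def save_spectrum(
    path: str,
    spec: Union[HypercomplexSpectrum, MagnitudeSpectrum],
    cfg: Optional[ProcessingConfig] = None,
    coeffs: Optional[QuadraticPhaseCoefficients] = None,
    log: str = "",
) -> None:
    """Persist a processed spectrum with its config and provenance."""
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["software_version"] = __version__
        g = f.create_group("spectrum")
        if isinstance(spec, MagnitudeSpectrum):
            g.attrs["mode"] = "magnitude"
            g.create_dataset("magnitude", data=spec.data, dtype="f8")
        else:
            g.attrs["mode"] = "absorption"
            g.create_dataset("rr", data=spec.plane_rr, dtype="f8")
            for name in ("ri", "ir", "ii"):
                plane = getattr(spec, f"plane_{name}")
                if plane is not None:
                    g.create_dataset(name, data=plane, dtype="f8")
        _write_axis(g, "axis1", spec.axis1)
        _write_axis(g, "axis2", spec.axis2)
        p = f.create_group("processing")
        if cfg is not None:
            p.attrs["config"] = json.dumps(cfg.to_dict())
        if coeffs is not None:
            p.attrs["phase_coefficients"] = json.dumps(dataclasses.asdict(coeffs))
        p.attrs["log"] = log


def load_spectrum(
    path: str,
    expect_mode: Optional[str] = None,
) -> Union[HypercomplexSpectrum, MagnitudeSpectrum]:
    """Load a spectrum; raises SpectrumModeError on a mode mismatch."""
    with h5py.File(path, "r") as f:
        _check_version(f)
        if "spectrum" not in f:
            raise SpectrumFormatError("no /spectrum group in file")
        g = f["spectrum"]
        mode = str(g.attrs.get("mode"))
        if expect_mode is not None and mode != expect_mode:
            raise SpectrumModeError(
                f"file holds a {mode} spectrum, workflow expects {expect_mode}")
        axis1 = _read_axis(g, "axis1")
        axis2 = _read_axis(g, "axis2")
        if mode == "magnitude":
            return MagnitudeSpectrum(data=g["magnitude"][...], axis1=axis1,
                                     axis2=axis2)
        planes = {
            name: (g[name][...] if name in g else None)
            for name in ("rr", "ri", "ir", "ii")
        }
        if planes["rr"] is None:
            raise SpectrumFormatError("absorption spectrum lacks an RR plane")
        return HypercomplexSpectrum(
            plane_rr=planes["rr"], plane_ri=planes["ri"],
            plane_ir=planes["ir"], plane_ii=planes["ii"],
            axis1=axis1, axis2=axis2,
        )
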