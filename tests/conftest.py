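import numpy as np
import pytest

from ft2dms import (
    AcquisitionGrid,
    FragmentSpec,
    IonSpecies,
    ProcessingConfig,
    PulseSequenceParams,
)


@pytest.fixture
def study_params() -> PulseSequenceParams:
    """Narrowband 2D acquisition parameters of the histone-peptide study."""
    return PulseSequenceParams()  # defaults are the study values


@pytest.fixture
def plain_params() -> PulseSequenceParams:
    """Stripped-down sequence: no delays, no generator offset.

    With T1 = T2 = T3 = tau_m = 0 and f_min = 0 every phase term vanishes,
    so processed peaks are pure positive absorption -- the cleanest oracle
    for transform-level tests.
    """
    return PulseSequenceParams(T1=0.0, T2=0.0, T3=0.0, tau_m=0.0,
                               f_min=0.0, f_max=500_000.0,
                               t1_step=50e-6, n1=128)


@pytest.fixture
def small_grid() -> AcquisitionGrid:
    return AcquisitionGrid(n2=1024, t2_dwell=1e-5)


@pytest.fixture
def raw_config() -> ProcessingConfig:
    """No apodization, no zero-fill: on-grid lines stay single-bin."""
    return ProcessingConfig(row_window_max_pos=None, col_window_max_pos=None,
                            row_zero_fill=0, col_zero_fill=0)


def on_grid_fragment(plain_params, grid, k1=26, k2=200, **frag_kw):
    """One species whose modulation and detection frequencies sit on-grid."""
    f_mod = k1 / (plain_params.n1 * plain_params.t1_step)
    f2 = k2 / (grid.n2 * grid.t2_dwell)
    return IonSpecies(
        f_icr=plain_params.f_min + f_mod,
        fragments=(FragmentSpec(f2=f2, **frag_kw),),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
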