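import numpy as np
import pytest

from epidose import (
    CalibrationConfig,
    CommissioningProtocol,
    FTMRTable,
    TMRTable,
    TruthModel,
)
from epidose.simulate import commission_from_truth


@pytest.fixture(scope="session")
def truth():
    """Zero-noise virtual-linac truth model (exact fixtures)."""
    return TruthModel()


@pytest.fixture(scope="session")
def calib(truth):
    return truth.calibration


@pytest.fixture(scope="session")
def protocol():
    return CommissioningProtocol()


@pytest.fixture(scope="session")
def tables(truth, protocol):
    """Tables commissioned from the zero-noise virtual linac (6 fields x 4
    thicknesses), TPS-corrected."""
    tset, _ = commission_from_truth(truth, protocol)
    return tset


@pytest.fixture
def small_ftmr():
    """Hand-sized fTMR table with known node values."""
    return FTMRTable(
        fields=np.array([4.0, 10.0]),
        thicknesses=np.array([0.0, 10.0, 20.0]),
        air_gaps=np.array([50.0]),
        values=np.array([[[1.0], [0.55], [0.32]],
                         [[1.0], [0.58], [0.35]]]),
    )


@pytest.fixture
def small_tmr():
    return TMRTable(
        fields=np.array([10.0]),
        depths=np.array([1.5, 10.0, 20.0]),
        values=np.array([[1.0, 0.80, 0.55]]),
        d_max=1.5,
    )
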