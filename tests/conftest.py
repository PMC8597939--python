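import numpy as np
import pytest

from bekit.calibration import CalibrationStandard, fit_calibration
from bekit.pampa import PampaGeometry


@pytest.fixture
def default_geometry() -> PampaGeometry:
    """96-well sandwich geometry: 0.18 cm³ per compartment, 0.266 cm² filter."""
    return PampaGeometry()


@pytest.fixture
def uv_curve():
    """UV calibration curve fitted to points on the exact published-style line
    A = 0.045 c + 0.009 over the 0.375–6 µg/ml standards."""
    standards = [
        CalibrationStandard(c, 0.045 * c + 0.009) for c in (0.375, 0.75, 1.5, 3.0, 6.0)
    ]
    return fit_calibration(standards)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
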