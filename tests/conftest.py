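import numpy as np
import pytest

from eisdep.circuit_models import RandlesParameters
from eisdep.dielectric import CellGeometry
from eisdep.synthetic_data import log_frequency_grid

# parameter ranges of the published six-sample concentration series
SERIES_RANGES = {
    "r_u": (313.0, 2700.0),
    "y0": (1e-6, 14e-6),
    "alpha": (0.65, 1.0),
    "w_d": (2e-5, 3.5e-5),
    "r_p": (24.0, 24000.0),
}


def draw_series_params(rng) -> RandlesParameters:
    """One random parameter set, log-uniform in the series ranges."""
    lo, hi = SERIES_RANGES["alpha"]
    return RandlesParameters(
        r_u=np.exp(rng.uniform(*np.log(SERIES_RANGES["r_u"]))),
        y0=np.exp(rng.uniform(*np.log(SERIES_RANGES["y0"]))),
        alpha=rng.uniform(lo, hi),
        w_d=np.exp(rng.uniform(*np.log(SERIES_RANGES["w_d"]))),
        r_p=np.exp(rng.uniform(*np.log(SERIES_RANGES["r_p"]))),
    )


@pytest.fixture
def cell_geometry() -> CellGeometry:
    """The parallel-plate measurement cell: 4.75 mm gap, 1.97 cm^2 plates."""
    return CellGeometry(thickness=4.75e-3, area=1.97e-4)


@pytest.fixture
def default_grid() -> np.ndarray:
    return log_frequency_grid(0.1, 1e6, 10)
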