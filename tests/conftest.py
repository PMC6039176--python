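import numpy as np
import pytest

from fusi.core import AcquisitionConfig, GroundTruthMap, HemodynamicModel, TrialProtocol


@pytest.fixture
def config():
    return AcquisitionConfig()


@pytest.fixture
def protocol():
    return TrialProtocol()


@pytest.fixture
def hrf():
    return HemodynamicModel.gamma()


@pytest.fixture
def small_truth():
    """4x5 grid: one column per best frequency, uniform 20 %CBV amplitude."""
    nz, nx = 4, 5
    bf = np.tile(np.arange(nx), (nz, 1))
    return GroundTruthMap(
        bf_index=bf,
        tuning_width=np.ones((nz, nx)),
        amplitude=np.full((nz, nx), 20.0),
        responsive=np.ones((nz, nx), dtype=bool),
    )
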