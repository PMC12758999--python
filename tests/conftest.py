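import numpy as np
import pytest

from csidose import (
    DVH,
    DoseValue,
    Prescription,
    reference_imaging_doses,
)


@pytest.fixture(scope="session")
def two_bin_dvh() -> DVH:
    """Half the organ at 10 Gy, half at 30 Gy."""
    return DVH.from_bins("organ", [(10.0, 0.5), (30.0, 0.5)])


@pytest.fixture(scope="session")
def imaging_table():
    """Bundled phantom-measured organ dose table (planning CT + one CBCT)."""
    return reference_imaging_doses()


@pytest.fixture(scope="session")
def prescription() -> Prescription:
    """36 Gy craniospinal course in 20 fractions, 18 Gy boost in 10."""
    return Prescription()


@pytest.fixture(scope="session")
def heart_pair():
    """Published mean-dose/NTCP pair for the heart across techniques."""
    return [(DoseValue(16.0, "Gy"), 0.30), (DoseValue(6.6, "Gy"), 0.004)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260102)
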