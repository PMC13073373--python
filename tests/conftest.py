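import numpy as np
import pytest

from tchur.fitness import ThermoTable, load_default_thermo


@pytest.fixture(scope="session")
def thermo() -> ThermoTable:
    return load_default_thermo()


@pytest.fixture(scope="session")
def uniform_thermo() -> ThermoTable:
    """Every dinucleotide step exactly at the target energy."""
    steps = [a + b for a in "ACGT" for b in "ACGT"]
    return ThermoTable(dg={s: -1.45 for s in steps}, dg_target=-1.45)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
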