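import numpy as np
import pytest

import methylamp as m
from methylamp.cli import RunConfig


@pytest.fixture(scope="session")
def assay() -> m.AssayDefinition:
    return m.default_assay()


@pytest.fixture(scope="session")
def conv_ref(assay) -> m.ConvertedReference:
    return m.build_converted_reference(assay)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def noiseless_chem() -> m.ChemistryModel:
    """Perfect chemistry: complete conversion, no errors."""
    return m.ChemistryModel(conversion_efficiency=1.0, inappropriate_conversion=0.0,
                            seq_error_rate=0.0)
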