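import pytest
from hypothesis import settings

from molconduct import parse_smiles
from molconduct.fitmodels import paper_parameters

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: 2,2,3,3-tetramethylbutane: two quaternary carbons, six methyls.
FIG1_SMILES = "CC(C)(C)C(C)(C)C"


@pytest.fixture
def fig1():
    return parse_smiles(FIG1_SMILES, label="2,2,3,3-Tetramethylbutane")


@pytest.fixture(scope="session")
def paper_params():
    return paper_parameters()
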