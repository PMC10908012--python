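import pytest

from tcscea.parameters import load_paper_params
from tcscea.synthetic_data import LifeTableSpec, make_life_table


@pytest.fixture(scope="session")
def paper_params():
    """The bundled canonical parameter set (no life table)."""
    return load_paper_params()


@pytest.fixture(scope="session")
def default_life_table():
    return make_life_table(LifeTableSpec())


@pytest.fixture(scope="session")
def params(paper_params, default_life_table):
    """Paper parameters with the default synthetic life table attached."""
    return paper_params.with_life_table(default_life_table)
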