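import numpy as np
import pytest

from atsf.molecule import (
    ANOMERS,
    SUGARS,
    assign_atom_types,
    build_furanoside_fixture,
    load_typing_template,
)


@pytest.fixture(scope="session")
def template():
    return load_typing_template()


@pytest.fixture(scope="session")
def rib_beta(template):
    """A typed methyl beta-D-ribofuranoside fixture."""
    return assign_atom_types(build_furanoside_fixture("rib", "beta"), template)


@pytest.fixture(scope="session")
def all_fixtures(template):
    return [
        assign_atom_types(build_furanoside_fixture(s, a), template)
        for s in SUGARS
        for a in ANOMERS
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
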