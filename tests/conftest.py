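import pytest

from hspscreen import HSPVector
from hspscreen.components import load_reference_group_summaries, load_reference_polymers
from hspscreen.estimation import SolventTable, load_reference_swelling

#: Five-solvent swelling-estimated polymer HSP used throughout screening tests.
CUTIN = HSPVector(19.7, 5.4, 2.5)

FIVE_SOLVENTS = ("hexane", "diethyl ether", "chloroform", "acetone", "ethyl acetate")


@pytest.fixture(scope="session")
def solvent_table() -> SolventTable:
    return SolventTable.default()


@pytest.fixture(scope="session")
def cutin() -> HSPVector:
    return CUTIN


@pytest.fixture(scope="session")
def reference_swelling():
    """Shipped two-repetition cutin swelling experiment (water pre-excluded)."""
    return load_reference_swelling()


@pytest.fixture(scope="session")
def group_summaries():
    return load_reference_group_summaries()


@pytest.fixture(scope="session")
def reference_polymers():
    return load_reference_polymers()
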