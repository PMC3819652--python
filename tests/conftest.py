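from fractions import Fraction

import pytest

from umcheck.fixtures import fig1a_network, fig1b_network, fig2_network
from umcheck.gpr import parse_gpr
from umcheck.model import Metabolite, Model, Reaction


@pytest.fixture(scope="session")
def fig1a():
    return fig1a_network()


@pytest.fixture(scope="session")
def fig1b():
    return fig1b_network()


@pytest.fixture(scope="session")
def fig2():
    return fig2_network()


@pytest.fixture()
def toy_gpr_model():
    """Growth on A through two parallel A->B conversions gated by g1/g2,
    plus a dead branch gated by g3."""
    mets = [Metabolite(x) for x in ("A", "B", "DEAD")]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -1000, 1000),
        Reaction("R1", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000,
                 gpr=parse_gpr("g1")),
        Reaction("R2", {"A": Fraction(-1), "B": Fraction(1)}, 0, 1000,
                 gpr=parse_gpr("g2")),
        Reaction("RDEAD", {"DEAD": Fraction(-1), "B": Fraction(1)}, 0, 1000,
                 gpr=parse_gpr("g3")),
        Reaction("BM", {"A": Fraction(-1), "B": Fraction(-1)}, 0, 1000),
    ]
    return Model("toy", mets, rxns, exchange_ids={"EX_A"}, biomass_id="BM")
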