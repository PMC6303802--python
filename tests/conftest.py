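"""Shared fixtures: toy displacement system, sequenced duplex, catalyst file."""

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from dsdkin import (
    Domain,
    Strand,
    SystemSpec,
    ToyEnergyModel,
    ToyKineticModel,
    build_first_step_model,
    build_reaction_subnetwork,
    condense_reactions,
    derive_stop_states,
    enumerate_detailed_reactions,
    find_resting_macrostates,
    parse_structure,
)


@pytest.fixture(scope="session")
def displacement_system():
    """Toehold-mediated strand displacement: invader (t,d) vs substrate (d*,t*)/incumbent (d)."""
    t = Domain("t", 3)
    d = Domain("d", 8)
    inv = Strand("inv", (t, d))
    sub = Strand("sub", (d.complement(), t.complement()))
    inc = Strand("inc", (d,))
    invader = parse_structure("..", [inv])
    substrate = parse_structure("(.+)", [sub, inc])
    spec = SystemSpec(
        domains={x.name: x for x in (t, d, t.complement(), d.complement())},
        strands={s.name: s for s in (inv, sub, inc)},
        complexes={"invader": invader, "substrate": substrate},
    )
    return {
        "domains": {"t": t, "d": d},
        "strands": {"inv": inv, "sub": sub, "inc": inc},
        "invader": invader,
        "substrate": substrate,
        "spec": spec,
    }


@pytest.fixture(scope="session")
def displacement_network(displacement_system):
    net = enumerate_detailed_reactions(displacement_system["spec"])
    find_resting_macrostates(net)
    condense_reactions(net)
    return net


@pytest.fixture(scope="session")
def displacement_first_step(displacement_system, displacement_network):
    net = displacement_network
    A = [
        net.macrostate_of(displacement_system["invader"]),
        net.macrostate_of(displacement_system["substrate"]),
    ]
    model = build_first_step_model(A, net.condensed_reactions)
    subnetwork = build_reaction_subnetwork(A, net)
    stops = derive_stop_states(A, subnetwork, model)
    return {"A": A, "model": model, "subnetwork": subnetwork, "stops": stops}


@pytest.fixture(scope="session")
def kinetic_model():
    return ToyKineticModel()


@pytest.fixture(scope="session")
def energy_model():
    return ToyEnergyModel()


@pytest.fixture(scope="session")
def duplex_strands():
    """A sequenced 4-nt duplex pair with a small enumerable ensemble."""
    a = Domain("a", 4, "ACGT")
    s1 = Strand("s1", (a,))
    s2 = Strand("s2", (a.complement(),))
    return s1, s2


CATALYST_PIL = """
# entropy-driven catalyst, six domains / seven complexes
length d1 = 10
length d2 = 24
length d3 = 4
length d4 = 16
length d5 = 6
length d6 = 16
strand F  = d2 d3 d4
strand C  = d4 d5
strand OB = d1 d2
strand SB = d6 d3 d4
strand LB = d5* d4* d3* d2*
complex Fuel      = F : ...
complex Catalyst  = C : ..
complex Output    = OB : ..
complex Signal    = SB : ...
complex Substrate = OB SB LB : .(+.((+.)))
complex Intermediate = OB C LB : .(+((+)).)
complex Waste     = F LB : (((+.)))
conc Catalyst = 1e-9
conc Fuel = 1.3e-8
conc Substrate = 1e-8
"""


@pytest.fixture(scope="session")
def catalyst_pil_text():
    return CATALYST_PIL
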