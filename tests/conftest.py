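import logging

import numpy as np
import pytest

from bipfold import ModelSpec, ParameterSet, build_network
from bipfold.dynamics import CompiledSystem
from bipfold.network import (
    FOLDED,
    Form,
    Reaction,
    ReactionNetwork,
    SpeciesState,
    Tag,
    _normalise,
)

logging.getLogger("bipfold").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_params():
    return ParameterSet()


@pytest.fixture(scope="session", params=[1, 2, 3, 4])
def k(request):
    return request.param


@pytest.fixture(scope="session")
def networks():
    """All four sub-models at C=1, built once."""
    return {k: build_network(ModelSpec(k=k)) for k in (1, 2, 3, 4)}


@pytest.fixture(scope="session")
def network_k1(networks):
    return networks[1]


@pytest.fixture(scope="session")
def network_k4(networks):
    return networks[4]


def toy_network(reactions, k=1, params=None):
    """Assemble a hand-written network (for isolated-kinetics tests)."""
    spec = ModelSpec(k=k, params=params or ParameterSet())
    species = set()
    for rxn in reactions:
        for sp, _ in rxn.reactants:
            species.add(sp)
        for sp, _ in rxn.products:
            species.add(sp)
    ordered = tuple(sorted(species, key=SpeciesState.sort_key))
    return ReactionNetwork(
        species=ordered, reactions=tuple(reactions), k=spec.k, C=spec.C,
        spec=spec,
    )


def reaction(reactants, products, rate, tag=Tag.TRIAGE):
    return Reaction(_normalise(reactants), _normalise(products), rate, tag)


@pytest.fixture(scope="session")
def binding_network():
    """Isolated reversible binding U + BiP <-> U.BiP."""
    from bipfold.network import BIP, unfolded

    k_on, k_off = 1e6, 0.5
    rxns = [
        reaction([unfolded(0), BIP], [unfolded(1)], k_on),
        reaction([unfolded(1)], [unfolded(0), BIP], k_off),
    ]
    return toy_network(rxns), k_on, k_off
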