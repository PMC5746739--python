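"""Shared fixtures: the bundled networks plus a small cycle network that
exercises condensation, decarboxylation, carbon scrambling and exchange flux
within the brute-force oracle's size limit."""

import numpy as np
import pytest

from hetflux import synth
from hetflux.network import complete_fluxes, free_flux_basis, parse_network

# closed carbon cycle: a 2-carbon unit condenses onto a 3-carbon acceptor,
# two carbons leave as CO2 per turn, and the decarboxylation scrambles the
# acceptor orientation (two alternative maps); the condensation is
# reversible.  11 carbons total over the iterated pools.
MINICYCLE_TEXT = """\
NETWORK minicycle
METABOLITES
S 2 substrate
AC 2 internal
OA 3 internal
CIT 5 internal
CO2 1 internal
CO2out 1 sink
REACTIONS
u: S (ab) -> AC (ab)
cs: OA (cde) + AC (ab) -> CIT (cdeab) rev
dc: CIT (abcde) -> OA (ead) + CO2 (b) + CO2 (c) | OA (dae) + CO2 (b) + CO2 (c)
co2x: CO2 (a) -> CO2out (a)
FREE
u.net in [0.1, 10]
cs.xch in [0, 0.99]
"""


@pytest.fixture(scope="session")
def fig1():
    net = synth.build_fig1_network()
    return net, free_flux_basis(net)


@pytest.fixture(scope="session")
def fig2():
    net = synth.build_fig2_network()
    return net, free_flux_basis(net)


@pytest.fixture(scope="session")
def minicycle():
    net = parse_network(MINICYCLE_TEXT)
    return net, free_flux_basis(net)


@pytest.fixture(scope="session")
def canonical():
    net = synth.build_canonical_network()
    return net, free_flux_basis(net)


@pytest.fixture(scope="session")
def table1_state(canonical):
    net, param = canonical
    values = np.array([synth.TABLE1_FREE_FLUXES[k] for k in param.free_names])
    return complete_fluxes(param, values), values


@pytest.fixture(scope="session")
def panel_targets():
    return synth.panel_targets()


@pytest.fixture(scope="session")
def toy_tracer():
    return synth.toy_tracer()
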