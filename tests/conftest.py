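import numpy as np
import pytest

from mabflux.inference import infer_rate_constants
from mabflux.io import load_table1, load_table3
from mabflux.network import Topology, steady_state


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def by_name(table1):
    return {d.name: d for d in table1}


@pytest.fixture(scope="session")
def fits(table1):
    """Inference results per topology per line (cached: fits are reused
    throughout the suite)."""
    return {
        topo: [infer_rate_constants(d, topo) for d in table1]
        for topo in (Topology.HL, Topology.HH, Topology.COMBINED)
    }


@pytest.fixture(scope="session")
def fit_2n2_hl(fits):
    return fits[Topology.HL][0]


@pytest.fixture(scope="session")
def steady_states(fits):
    """Solved steady states per (topology, line)."""
    out = {}
    for topo, results in fits.items():
        for res in results:
            out[(topo, res.line)] = steady_state(
                res.rates, topo, x0=res.operating_point())
    return out
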