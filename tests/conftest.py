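import pytest

from qualmc.dynamics import Scenario, TransitionSystem
from qualmc.explicit import build_graph
from qualmc.logic_model import parse_network

NFKB_TOY = """
name: nfkb-toy
nodes:
  - {name: NFkB, kind: internal, levels: 3, basal: 2, init: [0]}
  - {name: IkB, kind: internal, levels: 3, init: [0]}
edges:
  - {from: IkB, to: NFkB, sign: "-"}
  - {from: NFkB, to: IkB, sign: "+"}
"""

CHAIN = """
name: chain
nodes:
  - {name: A, kind: input, levels: 3}
  - {name: B, kind: internal, levels: 3}
  - {name: C, kind: internal, levels: 3}
edges:
  - {from: A, to: B, sign: "+"}
  - {from: B, to: C, sign: "+"}
"""


@pytest.fixture(scope="session")
def nfkb_toy():
    return parse_network(NFKB_TOY)


@pytest.fixture(scope="session")
def chain_net():
    return parse_network(CHAIN)


@pytest.fixture(scope="session")
def er_net():
    from qualmc.casestudy import er_golgi_network
    return er_golgi_network()


def sat_sets_agree(ts: TransitionSystem, graph, sym_sat, exp_sat) -> bool:
    """Symbolic and explicit satisfying sets agree on every reachable state."""
    return all(ts.contains(sym_sat, s) == (i in exp_sat)
               for i, s in enumerate(graph.states))


def compare_on(net, scenario, semantics, formula, fair=False):
    """Run both engines; return (symbolic verdict, explicit verdict, agree)."""
    from qualmc.ctl import check
    from qualmc.explicit import explicit_check
    ts = TransitionSystem(net, scenario, semantics)
    g = build_graph(net, scenario, semantics)
    vs = check(ts, formula, fair)
    ve = explicit_check(g, formula, fair)
    return vs, ve, (vs.holds == ve.holds and sat_sets_agree(ts, g, vs.sat, ve.sat))
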