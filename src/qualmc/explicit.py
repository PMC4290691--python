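"""Brute-force explicit-state CTL checking and a random network generator.

This is the ground-truth oracle for the symbolic engine on systems small
enough to enumerate.  Fairness is handled by the textbook construction:
a state satisfies fair-EG f iff, inside the f-subgraph, it can reach a
nontrivial strongly connected component intersecting every fairness
constraint.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import networkx as nx

from .ctl import CtlFormula, Verdict
from .dynamics import (Scenario, State, async_successors, initial_states,
                       sync_successor)
from .logic_model import (EdgeSpec, ModelError, Network, NodeSpec,
                          check_valid)

DEFAULT_CAP = 2_000_000


class SizeError(ModelError):
    """State space exceeds the enumeration cap."""


@dataclass
class ExplicitGraph:
    net: Network
    scenario: Scenario
    semantics: str
    states: List[State]                      # reachable states only
    index: Dict[State, int]
    succ: List[List[Tuple[int, int]]]        # per state: (process id, target)
    initial: List[int]
    fairness: List[FrozenSet[int]]           # per process: states with that tag

    @property
    def processes(self) -> List[str]:
        return [n.name for n in self.net.non_input_nodes()]


def _bound(net: Network, semantics: str) -> int:
    n = net.configuration_count()
    if semantics == "async":
        n *= len(net.non_input_nodes()) + 1
    return n


def build_graph(net: Network, scenario: Scenario, semantics: str = "sync",
                cap: int = DEFAULT_CAP) -> ExplicitGraph:
    """Reachable-state enumeration from the scenario's initial states."""
    bound = _bound(net, semantics)
    if bound > cap:
        raise SizeError(
            f"state space bound {bound} exceeds the enumeration cap {cap}")
    states: List[State] = []
    index: Dict[State, int] = {}
    succ: List[List[Tuple[int, int]]] = []

    def intern(s: State) -> int:
        i = index.get(s)
        if i is None:
            i = len(states)
            index[s] = i
            states.append(s)
            succ.append([])
        return i

    initial = [intern(s) for s in initial_states(net, scenario, semantics)]
    frontier = list(range(len(states)))
    while frontier:
        nxt = []
        for i in frontier:
            s = states[i]
            if semantics == "sync":
                outs = [(0, sync_successor(net, s))]
            else:
                procs = async_successors(net, s)
                outs = [(k, t) for k, (_, t) in enumerate(procs)]
            for pid, t in outs:
                before = len(states)
                j = intern(t)
                succ[i].append((pid, j))
                if j == before:
                    nxt.append(j)
        frontier = nxt
    fairness: List[FrozenSet[int]] = []
    if semantics == "async":
        procs = [n.name for n in net.non_input_nodes()]
        for p in procs:
            fairness.append(frozenset(
                i for i, s in enumerate(states) if s.sched == p))
    return ExplicitGraph(net, scenario, semantics, states, index, succ,
                         initial, fairness)


def to_dot(g: ExplicitGraph) -> str:
    lines = [f'digraph "{g.net.name}-{g.semantics}" {{']
    for i, s in enumerate(g.states):
        label = ",".join(map(str, s.assignment))
        if s.sched is not None:
            label += f"|{s.sched}"
        shape = "doublecircle" if i in set(g.initial) else "circle"
        lines.append(f'  n{i} [label="{label}", shape={shape}];')
    for i, outs in enumerate(g.succ):
        for _, j in outs:
            lines.append(f"  n{i} -> n{j};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# -- explicit CTL -----------------------------------------------------

def _pred(g: ExplicitGraph) -> List[List[int]]:
    pred: List[List[int]] = [[] for _ in g.states]
    for i, outs in enumerate(g.succ):
        for _, j in outs:
            pred[j].append(i)
    return pred


def _ex(g: ExplicitGraph, target: Set[int]) -> Set[int]:
    return {i for i, outs in enumerate(g.succ)
            if any(j in target for _, j in outs)}


def _eu(g: ExplicitGraph, f: Set[int], t: Set[int],
        pred: List[List[int]]) -> Set[int]:
    sat = set(t)
    work = list(t)
    while work:
        j = work.pop()
        for i in pred[j]:
            if i in f and i not in sat:
                sat.add(i)
                work.append(i)
    return sat


def _eg_plain(g: ExplicitGraph, f: Set[int]) -> Set[int]:
    z = set(f)
    while True:
        nz = {i for i in z if any(j in z for _, j in g.succ[i])}
        if nz == z:
            return z
        z = nz


def _eg_fair(g: ExplicitGraph, f: Set[int], pred: List[List[int]]) -> Set[int]:
    """States reaching, within f, a nontrivial SCC of the f-subgraph
    that intersects every fairness constraint."""
    sub = nx.DiGraph()
    sub.add_nodes_from(f)
    for i in f:
        for _, j in g.succ[i]:
            if j in f:
                sub.add_edge(i, j)
    good: Set[int] = set()
    for comp in nx.strongly_connected_components(sub):
        if len(comp) == 1:
            i = next(iter(comp))
            if not sub.has_edge(i, i):
                continue
        if not comp <= f:
            continue
        if all(comp & c for c in g.fairness):
            good |= comp
    return _eu(g, f, good, pred)


def _fair_states(g: ExplicitGraph, pred: List[List[int]]) -> Optional[Set[int]]:
    if not g.fairness:
        return None
    return _eg_fair(g, set(range(len(g.states))), pred)


def label_atom(g: ExplicitGraph, f: CtlFormula) -> Set[int]:
    node = g.net.node(f.name)
    k = [n.name for n in g.net.nodes].index(f.name)
    if f.cmp == "=":
        ok = lambda v: v == f.value
    elif f.cmp == ">=":
        ok = lambda v: v >= f.value
    else:
        ok = lambda v: v <= f.value
    return {i for i, s in enumerate(g.states) if ok(s.assignment[k])}


def explicit_check(g: ExplicitGraph, f: CtlFormula, fair: bool = False,
                   property_id: str = "") -> Verdict:
    if fair and not g.fairness:
        raise ModelError("fair checking requested on a system without fairness constraints")
    pred = _pred(g)
    fs = _fair_states(g, pred) if fair else None
    all_states = set(range(len(g.states)))

    def sat(phi: CtlFormula) -> Set[int]:
        if phi.op == "atom":
            return label_atom(g, phi)
        if phi.op == "const":
            return set(all_states) if phi.value else set()
        if phi.op == "not":
            return all_states - sat(phi.args[0])
        if phi.op == "and":
            return sat(phi.args[0]) & sat(phi.args[1])
        if phi.op == "or":
            return sat(phi.args[0]) | sat(phi.args[1])
        if phi.op == "imp":
            return (all_states - sat(phi.args[0])) | sat(phi.args[1])
        if phi.op == "EX":
            t = sat(phi.args[0])
            return _ex(g, t & fs if fair else t)
        if phi.op == "AX":
            t = all_states - sat(phi.args[0])
            return all_states - _ex(g, t & fs if fair else t)
        if phi.op == "EF":
            t = sat(phi.args[0])
            return _eu(g, all_states, t & fs if fair else t, pred)
        if phi.op == "AG":
            t = all_states - sat(phi.args[0])
            return all_states - _eu(g, all_states, t & fs if fair else t, pred)
        if phi.op == "EG":
            body = sat(phi.args[0])
            return _eg_fair(g, body, pred) if fair else _eg_plain(g, body)
        if phi.op == "AF":
            body = all_states - sat(phi.args[0])
            bad = _eg_fair(g, body, pred) if fair else _eg_plain(g, body)
            return all_states - bad
        if phi.op == "EU":
            a, b = sat(phi.args[0]), sat(phi.args[1])
            return _eu(g, a, b & fs if fair else b, pred)
        if phi.op == "AU":
            a, b = sat(phi.args[0]), sat(phi.args[1])
            nb = all_states - b
            left = _eu(g, nb, ((all_states - a) & nb) & fs if fair else (all_states - a) & nb, pred)
            right = _eg_fair(g, nb, pred) if fair else _eg_plain(g, nb)
            return all_states - (left | right)
        raise ValueError(f"unknown operator {phi.op!r}")

    result = sat(f)
    holds = set(g.initial) <= result
    return Verdict(property_id or str(f), g.semantics, fair, holds,
                   frozenset(result), f)


# -- random generator -------------------------------------------------

def random_network(seed: int, n_nodes: int, edge_density: float = 0.4,
                   basal_prob: float = 0.2) -> Network:
    """Seeded, always-valid random network for fuzzing.

    Guarantees at least one input and (for ``n_nodes >= 2``) one
    non-input node; edge signs uniform; occasional joint_min rules.
    """
    if n_nodes < 1:
        raise ModelError("n_nodes must be >= 1")
    rng = random.Random(seed)
    nodes: List[NodeSpec] = []
    kinds = ["input"]
    if n_nodes >= 2:
        kinds.append(rng.choice(["internal", "output"]))
    while len(kinds) < n_nodes:
        kinds.append(rng.choice(["input", "internal", "internal", "output"]))
    rng.shuffle(kinds)
    if "input" not in kinds:
        kinds[0] = "input"
    for i, kind in enumerate(kinds):
        levels = 2 if kind == "output" else rng.choice([2, 3, 3])
        basal = 0
        if kind == "internal" and rng.random() < basal_prob:
            basal = rng.randint(1, levels - 1)
        rule = "joint_min" if kind != "input" and rng.random() < 0.15 else "additive"
        nodes.append(NodeSpec(name=f"n{i}", kind=kind, levels=levels,
                              basal=basal, rule=rule))
    edges: List[EdgeSpec] = []
    for tgt in nodes:
        if tgt.kind == "input":
            continue
        for src in nodes:
            if src.name == tgt.name and src.kind == "input":
                continue
            if rng.random() < edge_density:
                sign = rng.choice(["activate", "inhibit"])
                edges.append(EdgeSpec(src.name, tgt.name, sign))
    net = Network(tuple(nodes), tuple(edges), name=f"random-{seed}")
    return check_valid(net)


def random_formula(seed: int, net: Network, depth: int = 3) -> CtlFormula:
    """Seeded random CTL formula over the network's nodes (depth-bounded)."""
    rng = random.Random(seed)
    names = [n.name for n in net.nodes]

    def gen(d: int) -> CtlFormula:
        if d <= 0 or rng.random() < 0.3:
            name = rng.choice(names)
            node = net.node(name)
            cmp = rng.choice(["=", ">=", "<="])
            return CtlFormula("atom", name=name, cmp=cmp,
                              value=rng.randrange(node.levels))
        op = rng.choice(["not", "and", "or", "imp",
                         "EX", "AX", "EF", "AF", "EG", "AG", "EU", "AU"])
        if op == "not":
            return CtlFormula("not", (gen(d - 1),))
        if op in ("and", "or", "imp", "EU", "AU"):
            return CtlFormula(op, (gen(d - 1), gen(d - 1)))
        return CtlFormula(op, (gen(d - 1),))

    return gen(depth)
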