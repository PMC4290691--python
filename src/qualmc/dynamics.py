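"""Synchronous and asynchronous transition systems over a network.

A :class:`TransitionSystem` packages a network plus a scenario into a
Kripke structure.  Synchronous semantics updates every non-input node
simultaneously and is deterministic; asynchronous semantics runs one
update process per step (one process per non-input node, chosen
nondeterministically), records the chosen process in the explicit
state's scheduler tag, and carries one fairness constraint per process
("process i runs infinitely often"), the standard reading of a model
checker's *running* predicate.

Input nodes are chosen nondeterministically at time 0 and frozen along
every path under both semantics.

The symbolic side never builds a transition relation: each node's
update function is encoded as per-bit BDDs, and preimages are computed
by substituting those functions into the target set (for asynchronous
systems, per process and unioned).
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

from .bdd import BDD, FALSE, TRUE
from .logic_model import ModelError, Network, NodeSpec, transfer_level

INIT_TAG = "-"  # scheduler tag before any process has run


@dataclass(frozen=True)
class State:
    assignment: Tuple[int, ...]          # levels in network node order
    sched: Optional[str] = None          # last executed process (async only)

    def level(self, net: Network, name: str) -> int:
        return self.assignment[[n.name for n in net.nodes].index(name)]


@dataclass(frozen=True)
class Scenario:
    """Initial-value constraints: fixed inputs and init-set overrides."""
    name: str = "default"
    input_fix: Mapping[str, Union[int, Tuple[int, ...]]] = field(default_factory=dict)
    init_overrides: Mapping[str, Tuple[int, ...]] = field(default_factory=dict)

    def validate(self, net: Network) -> None:
        nm = net.node_map
        for src, col in (("input_fix", self.input_fix),
                         ("init_overrides", self.init_overrides)):
            for name, levels in col.items():
                if name not in nm:
                    raise ModelError(f"scenario {self.name!r}: unknown node {name!r}")
                if src == "input_fix" and nm[name].kind != "input":
                    raise ModelError(f"scenario {self.name!r}: {name!r} is not an input")
                for v in _as_tuple(levels):
                    if not 0 <= v < nm[name].levels:
                        raise ModelError(
                            f"scenario {self.name!r}: level {v} out of domain for {name!r}")


def _as_tuple(v) -> Tuple[int, ...]:
    if isinstance(v, int):
        return (v,)
    return tuple(v)


def initial_level_sets(net: Network, scenario: Scenario) -> Dict[str, Tuple[int, ...]]:
    """Per-node initial level sets: scenario fixes/overrides applied on
    top of the conventions (inputs free, internals {0,1}, outputs {0})."""
    scenario.validate(net)
    sets: Dict[str, Tuple[int, ...]] = {}
    for n in net.nodes:
        levels = tuple(n.init_set)
        if n.name in scenario.init_overrides:
            levels = _as_tuple(scenario.init_overrides[n.name])
        if n.name in scenario.input_fix:
            levels = _as_tuple(scenario.input_fix[n.name])
        if not levels:
            raise ModelError(f"empty initial set for node {n.name!r}")
        sets[n.name] = tuple(sorted(set(levels)))
    return sets


def initial_states(net: Network, scenario: Scenario,
                   semantics: str = "sync") -> Iterator[State]:
    """Explicit enumeration of the initial-state set (Cartesian product)."""
    sets = initial_level_sets(net, scenario)
    sched = INIT_TAG if semantics == "async" else None
    for combo in itertools.product(*(sets[n.name] for n in net.nodes)):
        yield State(combo, sched)


# -- explicit successors ---------------------------------------------

def _next_level(net: Network, node: NodeSpec, assignment: Sequence[int],
                index: Mapping[str, int]) -> int:
    signs = net.parent_signs(node.name)
    parent_levels = {p: assignment[index[p]] for p in signs}
    return transfer_level(node, parent_levels, signs)


def sync_successor(net: Network, state: State) -> State:
    """The unique synchronous successor (inputs frozen)."""
    index = {n.name: i for i, n in enumerate(net.nodes)}
    nxt = list(state.assignment)
    for i, n in enumerate(net.nodes):
        if n.kind != "input":
            nxt[i] = _next_level(net, n, state.assignment, index)
    return State(tuple(nxt), state.sched)


def async_successors(net: Network, state: State) -> List[Tuple[str, State]]:
    """One successor per update process (per non-input node).

    Stuttering successors are retained so the relation stays total.
    """
    index = {n.name: i for i, n in enumerate(net.nodes)}
    out = []
    for i, n in enumerate(net.nodes):
        if n.kind == "input":
            continue
        nxt = list(state.assignment)
        nxt[i] = _next_level(net, n, state.assignment, index)
        out.append((n.name, State(tuple(nxt), n.name)))
    return out


def simulate(net: Network, start: State, steps: int, semantics: str = "sync",
             choice_seed: int = 0) -> List[State]:
    """Length ``steps + 1`` trace; async draws processes from a seeded RNG."""
    rng = random.Random(choice_seed)
    trace = [start]
    for _ in range(steps):
        if semantics == "sync":
            trace.append(sync_successor(net, trace[-1]))
        else:
            succs = async_successors(net, trace[-1])
            trace.append(rng.choice(succs)[1])
    return trace


def trace_tsv(net: Network, trace: Sequence[State]) -> str:
    lines = ["step\tnode\tlevel"]
    for t, st in enumerate(trace):
        for n, v in zip(net.nodes, st.assignment):
            lines.append(f"{t}\t{n.name}\t{v}")
    return "\n".join(lines) + "\n"


# -- symbolic transition system ---------------------------------------

def _nbits(n: int) -> int:
    return max(1, (n - 1).bit_length())


def _variable_order(net: Network) -> List[NodeSpec]:
    """Depth-first order from the inputs: regulatory chains become
    contiguous variable blocks, which keeps the diagrams small."""
    children: Dict[str, List[str]] = {}
    for e in net.edges:
        children.setdefault(e.source, []).append(e.target)
    out: List[str] = []
    seen: set = set()

    def visit(name: str) -> None:
        if name in seen:
            return
        seen.add(name)
        out.append(name)
        for c in children.get(name, []):
            visit(c)

    for n in net.nodes:
        if n.kind == "input":
            visit(n.name)
    for n in net.nodes:
        visit(n.name)
    nm = net.node_map
    return [nm[x] for x in out]


class TransitionSystem:
    """Kripke structure M = (S, S0, R, L) with a BDD state encoding.

    Each node gets ceil(log2(levels)) bits, blocks laid out depth-first
    from the inputs.  The asynchronous scheduler tag is kept only on
    explicit states: atoms cannot mention it and successors do not depend
    on it, so symbolic sets live on the assignment space and fairness
    constraints are handled per process (see :func:`qualmc.ctl.fair_eg`).
    """

    def __init__(self, net: Network, scenario: Scenario, semantics: str = "sync"):
        if semantics not in ("sync", "async"):
            raise ModelError(f"unknown semantics {semantics!r}")
        scenario.validate(net)
        self.net = net
        self.scenario = scenario
        self.semantics = semantics
        self.processes: List[str] = [n.name for n in net.non_input_nodes()]

        order = _variable_order(net)
        nv = 0
        self.node_bits: Dict[str, List[int]] = {}
        for n in order:
            k = _nbits(n.levels)
            self.node_bits[n.name] = list(range(nv, nv + k))
            nv += k
        # scratch variables (below everything) for per-process images
        maxbits = max(_nbits(n.levels) for n in net.nodes)
        self.aux_bits = list(range(nv, nv + maxbits))
        self.bdd = BDD(nv + maxbits)

        self.care = self._build_care()
        self.update_bits = {n.name: self._encode_update(n)
                            for n in net.non_input_nodes()}
        self.initial = self._build_initial()
        # fairness constraints are per-process ("process i runs infinitely
        # often"); the scheduler tag is observable only on explicit states,
        # so symbolically they are handled as process indices
        self.fairness: List[int] = []
        if semantics == "async":
            self.fairness = list(range(len(self.processes)))
        self._fair_states: Optional[int] = None
        self._reachable: Optional[int] = None
        # all checking happens within this set (care, or care & reachable)
        self.universe = self.care
        # persistent satisfying-set caches, one per fairness mode
        self.sat_cache: Dict[bool, dict] = {False: {}, True: {}}

    # -- encoding helpers ---------------------------------------------

    def _value_bdd(self, bits: List[int], value: int) -> int:
        """bits == value (bits[0] is the least significant)."""
        b = self.bdd
        r = TRUE
        for k, v in enumerate(bits):
            lit = b.var(v) if (value >> k) & 1 else b.apply_not(b.var(v))
            r = b.apply_and(r, lit)
        return r

    def node_equals(self, name: str, value: int) -> int:
        return self._value_bdd(self.node_bits[name], value)

    def node_in(self, name: str, values: Sequence[int]) -> int:
        return self.bdd.disj(self.node_equals(name, v) for v in values)

    def _build_care(self) -> int:
        b = self.bdd
        r = TRUE
        for n in self.net.nodes:
            r = b.apply_and(r, self.node_in(n.name, range(n.levels)))
        return r

    def _encode_update(self, node: NodeSpec) -> List[int]:
        """Per-bit BDDs of the node's update function (over parent bits)."""
        b = self.bdd
        signs = self.net.parent_signs(node.name)
        parents = sorted(signs, key=lambda p: self.node_bits[p][0])
        nbits = len(self.node_bits[node.name])
        bits = [FALSE] * nbits
        domains = [self.net.node(p).domain for p in parents]
        for combo in itertools.product(*domains):
            value = transfer_level(node, dict(zip(parents, combo)), signs)
            if value == 0:
                continue
            minterm = b.conj(self.node_equals(p, v) for p, v in zip(parents, combo))
            for k in range(nbits):
                if (value >> k) & 1:
                    bits[k] = b.apply_or(bits[k], minterm)
        return bits

    def _build_initial(self) -> int:
        b = self.bdd
        sets = initial_level_sets(self.net, self.scenario)
        r = TRUE
        for n in self.net.nodes:
            r = b.apply_and(r, self.node_in(n.name, sets[n.name]))
        return r

    # -- image computation --------------------------------------------

    def preimage(self, target: int) -> int:
        """{s | some successor of s is in target}, within the universe."""
        b = self.bdd
        if self.semantics == "sync":
            sub = {}
            for name, fbits in self.update_bits.items():
                for v, f in zip(self.node_bits[name], fbits):
                    sub[v] = f
            return b.apply_and(b.compose(target, sub), self.universe)
        acc = FALSE
        for i in range(len(self.processes)):
            acc = b.apply_or(acc, self._pre_raw(i, target))
        return b.apply_and(acc, self.universe)

    def _pre_raw(self, i: int, target: int) -> int:
        name = self.processes[i]
        sub = dict(zip(self.node_bits[name], self.update_bits[name]))
        return self.bdd.compose(target, sub)

    def pre_process(self, i: int, target: int) -> int:
        """{s | firing process i from s lands in target}, within universe."""
        return self.bdd.apply_and(self._pre_raw(i, target), self.universe)

    def image_process(self, i: int, source: int) -> int:
        """Successors of ``source`` under update process i (async)."""
        b = self.bdd
        name = self.processes[i]
        bits = self.node_bits[name]
        t = source
        for k, v in enumerate(bits):
            f = self.update_bits[name][k]
            aux = b.var(self.aux_bits[k])
            t = b.apply_and(t, b.ite(aux, f, b.apply_not(f)))
        t = b.exist(bits, t)
        t = b.compose(t, {self.aux_bits[k]: b.var(v) for k, v in enumerate(bits)})
        return b.apply_and(t, self.care)

    def reachable(self) -> int:
        """States reachable from the initial set (async only)."""
        if self.semantics != "async":
            raise ModelError("symbolic reachability is only built for async systems")
        if self._reachable is None:
            b = self.bdd
            reach = self.initial
            frontier = self.initial
            while frontier != FALSE:
                new = FALSE
                for i in range(len(self.processes)):
                    new = b.apply_or(new, self.image_process(i, frontier))
                frontier = b.apply_diff(new, reach)
                reach = b.apply_or(reach, frontier)
            self._reachable = b.apply_and(reach, self.care)
        return self._reachable

    def restrict_to_scenario_inputs(self) -> None:
        """Confine checking to the scenario's fixed input values.

        Input nodes are frozen, so the set is closed under successors and
        verdicts at initial states are unchanged; every intermediate set
        is effectively cofactored by the input constants.
        """
        b = self.bdd
        universe = self.care
        for name, levels in self.scenario.input_fix.items():
            universe = b.apply_and(universe, self.node_in(name, _as_tuple(levels)))
        if universe != self.universe:
            self.universe = universe
            self.sat_cache = {False: {}, True: {}}
            self._fair_states = None

    def restrict_to_reachable(self) -> None:
        """Confine all subsequent checking to the reachable space.

        Verdicts at initial states are unaffected (the reachable set is
        closed under successors); intermediate sets get much smaller.
        Satisfying sets are then only meaningful on reachable states.
        """
        universe = self.bdd.apply_and(self.care, self.reachable())
        if universe != self.universe:
            self.universe = universe
            self.sat_cache = {False: {}, True: {}}
            self._fair_states = None

    # -- explicit/symbolic bridging -----------------------------------

    def state_bits(self, state: State) -> List[bool]:
        bits = [False] * self.bdd.nvars
        for n, v in zip(self.net.nodes, state.assignment):
            for k, var in enumerate(self.node_bits[n.name]):
                bits[var] = bool((v >> k) & 1)
        return bits

    def contains(self, bdd_set: int, state: State) -> bool:
        return self.bdd.eval(bdd_set, self.state_bits(state))

    def pick_state(self, bdd_set: int) -> Optional[State]:
        """Some state in the set (set must lie within the care space)."""
        asg = self.bdd.pick(self.bdd.apply_and(bdd_set, self.care))
        if asg is None:
            return None
        levels = []
        for n in self.net.nodes:
            v = sum((1 << k) for k, var in enumerate(self.node_bits[n.name])
                    if asg.get(var, False))
            levels.append(v)
        sched = INIT_TAG if self.semantics == "async" else None
        return State(tuple(levels), sched)

    def successors(self, state: State) -> List[State]:
        if self.semantics == "sync":
            return [sync_successor(self.net, state)]
        return [s for _, s in async_successors(self.net, state)]

    # -- housekeeping -------------------------------------------------

    def compact(self, keep_sat_cache: bool = True) -> None:
        """Copy-collect the BDD store, keeping only live sets."""
        roots: List[int] = [self.care, self.initial, self.universe]
        if self._fair_states is not None:
            roots.append(self._fair_states)
        if self._reachable is not None:
            roots.append(self._reachable)
        for bits in self.update_bits.values():
            roots.extend(bits)
        if keep_sat_cache:
            for cache in self.sat_cache.values():
                roots.extend(cache.values())
        else:
            self.sat_cache = {False: {}, True: {}}
        new, remap = self.bdd.copy_roots(roots)
        self.bdd = new
        self.care = remap[self.care]
        self.initial = remap[self.initial]
        self.universe = remap[self.universe]
        if self._fair_states is not None:
            self._fair_states = remap[self._fair_states]
        if self._reachable is not None:
            self._reachable = remap[self._reachable]
        self.update_bits = {k: [remap[b] for b in bits]
                            for k, bits in self.update_bits.items()}
        if keep_sat_cache:
            self.sat_cache = {fair: {f: remap[s] for f, s in cache.items()}
                              for fair, cache in self.sat_cache.items()}

    # -- fairness -----------------------------------------------------

    def fair_states(self) -> int:
        """States from which some fair path starts.

        Every update process is defined at every state (stutters kept),
        so a round-robin schedule from any state is fair: the set is the
        whole universe.  The explicit oracle computes it independently
        via its fair-SCC construction; the equivalence suite compares.
        """
        return self.universe
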