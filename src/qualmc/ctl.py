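"""CTL parsing and symbolic fixpoint checking.

Formulas are decided bottom-up over a :class:`~qualmc.dynamics.TransitionSystem`:
``EX`` is a preimage, ``EF``/``EU`` least fixpoints, ``EG`` a greatest
fixpoint, and the universal operators reduce by duality.  With fairness
enabled the existential operators are relativized to fair states and
``EG`` uses the Emerson-Lei iteration over the fairness constraint
family.

Grammar (precedence low to high: ``->``, ``|``, ``&``, ``!``/temporal)::

    formula  := or ('->' formula)?
    or       := and ('|' and)*
    and      := unary ('&' unary)*
    unary    := '!' unary | ('EX'|'AX'|'EF'|'AF'|'EG'|'AG') unary
              | ('E'|'A') '[' formula 'U' formula ']'
              | '(' formula ')' | 'True' | 'False' | atom
    atom     := NAME ('='|'>='|'<=') (INT|'True'|'False')
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .bdd import FALSE, TRUE
from .dynamics import State, TransitionSystem, async_successors
from .logic_model import ModelError, Network


# -- abstract syntax --------------------------------------------------

@dataclass(frozen=True)
class CtlFormula:
    op: str                                  # atom/const/not/and/or/imp/EX/EF/EG/EU/AX/AF/AG/AU
    args: Tuple["CtlFormula", ...] = ()
    name: Optional[str] = None               # atom: node name
    cmp: Optional[str] = None                # atom: '=', '>=', '<='
    value: Optional[int] = None              # atom: constant / const: 0|1

    def __str__(self) -> str:
        if self.op == "atom":
            return f"{self.name} {self.cmp} {self.value}"
        if self.op == "const":
            return "True" if self.value else "False"
        if self.op == "not":
            return f"!({self.args[0]})"
        if self.op in ("and", "or", "imp"):
            sym = {"and": "&", "or": "|", "imp": "->"}[self.op]
            return f"({self.args[0]} {sym} {self.args[1]})"
        if self.op in ("EU", "AU"):
            return f"{self.op[0]}[{self.args[0]} U {self.args[1]}]"
        return f"{self.op} ({self.args[0]})"


def atom(name: str, cmp: str, value: int) -> CtlFormula:
    return CtlFormula("atom", name=name, cmp=cmp, value=value)


class CtlSyntaxError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\s*(->|>=|<=|=|!|&|\||\(|\)|\[|\]|[A-Za-z_][A-Za-z0-9_']*|\d+)")

_TEMPORAL1 = {"EX", "AX", "EF", "AF", "EG", "AG"}


class _Parser:
    def __init__(self, text: str, net: Optional[Network]):
        self.text = text
        self.net = net
        self.tokens: List[Tuple[str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                if text[pos:].strip():
                    raise CtlSyntaxError(f"unexpected character at position {pos}: {text[pos]!r}")
                break
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def next(self) -> str:
        if self.i >= len(self.tokens):
            raise CtlSyntaxError("unexpected end of formula")
        tok = self.tokens[self.i][0]
        self.i += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.next()
        if got != tok:
            raise CtlSyntaxError(f"expected {tok!r}, got {got!r} at position "
                                 f"{self.tokens[self.i - 1][1]}")

    def parse(self) -> CtlFormula:
        f = self.formula()
        if self.i < len(self.tokens):
            raise CtlSyntaxError(f"trailing input at position {self.tokens[self.i][1]}")
        return f

    def formula(self) -> CtlFormula:
        left = self.or_()
        if self.peek() == "->":
            self.next()
            return CtlFormula("imp", (left, self.formula()))
        return left

    def or_(self) -> CtlFormula:
        f = self.and_()
        while self.peek() == "|":
            self.next()
            f = CtlFormula("or", (f, self.and_()))
        return f

    def and_(self) -> CtlFormula:
        f = self.unary()
        while self.peek() == "&":
            self.next()
            f = CtlFormula("and", (f, self.unary()))
        return f

    def unary(self) -> CtlFormula:
        tok = self.peek()
        if tok is None:
            raise CtlSyntaxError("unexpected end of formula")
        if tok == "!":
            self.next()
            return CtlFormula("not", (self.unary(),))
        if tok in _TEMPORAL1:
            self.next()
            return CtlFormula(tok, (self.unary(),))
        if tok in ("E", "A") and self.i + 1 < len(self.tokens) \
                and self.tokens[self.i + 1][0] == "[":
            self.next()
            self.expect("[")
            f = self.formula()
            self.expect("U")
            g = self.formula()
            self.expect("]")
            return CtlFormula(tok + "U", (f, g))
        if tok == "(":
            self.next()
            f = self.formula()
            self.expect(")")
            return f
        if tok in ("True", "TRUE"):
            self.next()
            return CtlFormula("const", value=1)
        if tok in ("False", "FALSE"):
            self.next()
            return CtlFormula("const", value=0)
        return self.atom_()

    def atom_(self) -> CtlFormula:
        name = self.next()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_']*", name):
            raise CtlSyntaxError(f"expected a node name, got {name!r}")
        cmp = self.next()
        if cmp not in ("=", ">=", "<="):
            raise CtlSyntaxError(f"expected comparator after {name!r}, got {cmp!r}")
        val_tok = self.next()
        if val_tok in ("True", "TRUE"):
            value = 1
        elif val_tok in ("False", "FALSE"):
            value = 0
        elif val_tok.isdigit():
            value = int(val_tok)
        else:
            raise CtlSyntaxError(f"expected a constant, got {val_tok!r}")
        if self.net is not None:
            node = self.net.node(name)   # raises on unknown node
            if not 0 <= value < node.levels:
                raise ModelError(
                    f"constant {value} out of domain [0, {node.levels - 1}] for {name!r}")
        return atom(name, cmp, value)


def parse_ctl(text: str, net: Optional[Network] = None) -> CtlFormula:
    """Parse a CTL formula, binding and range-checking atoms against ``net``."""
    return _Parser(text, net).parse()


# -- verdicts ---------------------------------------------------------

@dataclass
class Verdict:
    property_id: str
    semantics: str
    fair: bool
    holds: bool
    sat: int                       # BDD id (symbolic) or frozenset (explicit)
    formula: CtlFormula
    trace: Optional["Trace"] = None


@dataclass
class Trace:
    """Lasso or finite path.  ``cycle_start`` is None for finite paths."""
    states: List[State]
    cycle_start: Optional[int] = None
    kind: str = "counterexample"


NO_TRACE = None


# -- symbolic checking ------------------------------------------------

def label_atom(ts: TransitionSystem, f: CtlFormula) -> int:
    node = ts.net.node(f.name)
    if f.cmp == "=":
        values = [f.value]
    elif f.cmp == ">=":
        values = range(f.value, node.levels)
    else:
        values = range(0, f.value + 1)
    return ts.bdd.apply_and(ts.node_in(f.name, list(values)), ts.universe)


def ex(ts: TransitionSystem, target: int, fair_set: Optional[int] = None) -> int:
    if fair_set is not None:
        target = ts.bdd.apply_and(target, fair_set)
    return ts.preimage(target)


def eu(ts: TransitionSystem, f: int, g: int, fair_set: Optional[int] = None) -> int:
    """Least fixpoint Z = g | (f & EX Z), with the frontier optimization."""
    b = ts.bdd
    if fair_set is not None:
        g = b.apply_and(g, fair_set)
    z = g
    frontier = g
    while frontier != FALSE:
        new = b.apply_diff(b.apply_and(f, ts.preimage(frontier)), z)
        z = b.apply_or(z, new)
        frontier = new
    return z


def eg(ts: TransitionSystem, f: int) -> int:
    """Greatest fixpoint Z = f & EX Z (unfair semantics)."""
    b = ts.bdd
    z = b.apply_and(f, ts.universe)
    while True:
        nz = b.apply_and(z, ts.preimage(z))
        if nz == z:
            return z
        z = nz


def fair_eg(ts: TransitionSystem, f: int, interest: Optional[int] = None) -> int:
    """Emerson-Lei: states with a fair path staying in f forever.

    With ``interest`` given, iteration stops as soon as the current
    (shrinking, over-approximating) iterate no longer meets it; the
    returned set is then only valid for "disjoint from interest" tests.

    Fairness constraints are processes that must run infinitely often.
    Per process j the inner least fixpoint W = pre_j(Z) | pre(f & W)
    collects states that can reach, within f, a j-step back into Z.
    """
    b = ts.bdd
    if not ts.fairness:
        return eg(ts, f)
    z = b.apply_and(f, ts.universe)
    # downstream-first constraint order converges faster on cascades
    order = list(reversed(ts.fairness))
    while True:
        old = z
        for j in order:
            w = ts.pre_process(j, z)
            frontier = w
            while frontier != FALSE:
                new = b.apply_diff(ts.preimage(b.apply_and(f, frontier)), w)
                w = b.apply_or(w, new)
                frontier = new
            z = b.apply_and(z, w)
        if interest is not None and b.apply_and(z, interest) == FALSE:
            return z          # sound for emptiness tests: z over-approximates
        if z == old:
            return z




# -- interval certificates --------------------------------------------

def _is_state_formula(f: CtlFormula) -> bool:
    if f.op in ("atom", "const"):
        return True
    if f.op in ("not", "and", "or", "imp"):
        return all(_is_state_formula(a) for a in f.args)
    return False


def interval_truth(net: Network, iv, f: CtlFormula) -> Optional[bool]:
    """Three-valued truth of a state formula on an interval envelope."""
    if f.op == "atom":
        lo, hi = iv[f.name]
        if f.cmp == "=":
            if lo == hi == f.value:
                return True
            if not lo <= f.value <= hi:
                return False
            return None
        if f.cmp == ">=":
            return True if lo >= f.value else (False if hi < f.value else None)
        return True if hi <= f.value else (False if lo > f.value else None)
    if f.op == "const":
        return bool(f.value)
    if f.op == "not":
        t = interval_truth(net, iv, f.args[0])
        return None if t is None else not t
    if f.op in ("and", "or"):
        ts = [interval_truth(net, iv, a) for a in f.args]
        if f.op == "and":
            if all(t is True for t in ts):
                return True
            if any(t is False for t in ts):
                return False
            return None
        if any(t is True for t in ts):
            return True
        if all(t is False for t in ts):
            return False
        return None
    if f.op == "imp":
        a = interval_truth(net, iv, f.args[0])
        b = interval_truth(net, iv, f.args[1])
        if a is False or b is True:
            return True
        if a is True and b is False:
            return False
        return None
    raise ValueError(f.op)


def _eventually_certified(ts: TransitionSystem, f: CtlFormula) -> bool:
    """True when the interval envelope proves every (fair) path ends up
    satisfying f forever — a sufficient condition for AF f / EF f
    everywhere.  Requires all inputs scenario-fixed to single values."""
    if not _is_state_formula(f):
        return False
    fix = {}
    for n in ts.net.input_nodes():
        v = ts.scenario.input_fix.get(n.name)
        if isinstance(v, (tuple, list)):
            if len(v) != 1:
                return False
            v = v[0]
        if v is None:
            return False
        fix[n.name] = v
    from .logic_model import eternal_intervals
    iv = eternal_intervals(ts.net, fix)
    return interval_truth(ts.net, iv, f) is True


def stutter_fixpoints(ts: TransitionSystem) -> int:
    """States where every update process leaves the state unchanged."""
    b = ts.bdd
    r = ts.universe
    for name, fbits in ts.update_bits.items():
        for v, fb in zip(ts.node_bits[name], fbits):
            r = b.apply_and(r, b.ite(b.var(v), fb, b.apply_not(fb)))
    return r


def _sat(ts: TransitionSystem, f: CtlFormula, fair: bool,
         cache: Dict[CtlFormula, int]) -> int:
    hit = cache.get(f)
    if hit is not None:
        return hit
    b = ts.bdd
    det = ts.semantics == "sync"   # one successor: A and E coincide
    fs = ts.fair_states() if fair else None
    neg = lambda s: b.apply_diff(ts.universe, s)

    def ef(target: int) -> int:
        return eu(ts, ts.universe, target, fs)

    if f.op == "atom":
        r = label_atom(ts, f)
    elif f.op == "const":
        r = ts.universe if f.value else FALSE
    elif f.op == "not":
        r = neg(_sat(ts, f.args[0], fair, cache))
    elif f.op == "and":
        r = b.apply_and(_sat(ts, f.args[0], fair, cache), _sat(ts, f.args[1], fair, cache))
    elif f.op == "or":
        r = b.apply_or(_sat(ts, f.args[0], fair, cache), _sat(ts, f.args[1], fair, cache))
    elif f.op == "imp":
        r = b.apply_or(neg(_sat(ts, f.args[0], fair, cache)),
                       _sat(ts, f.args[1], fair, cache))
    elif f.op == "EX":
        r = ex(ts, _sat(ts, f.args[0], fair, cache), fs)
    elif f.op == "AX":
        r = neg(ex(ts, neg(_sat(ts, f.args[0], fair, cache)), fs))
    elif f.op == "EF":
        if fair and _eventually_certified(ts, f.args[0]):
            r = ts.universe
        else:
            r = ef(_sat(ts, f.args[0], fair, cache))
    elif f.op == "AF":
        if fair and _eventually_certified(ts, f.args[0]):
            r = ts.universe
        else:
            body = _sat(ts, f.args[0], fair, cache)
            if det:
                r = ef(body)
            else:
                r = neg(fair_eg(ts, neg(body)) if fair else eg(ts, neg(body)))
    elif f.op == "EG":
        body = _sat(ts, f.args[0], fair, cache)
        if det:
            r = neg(ef(neg(body)))
        else:
            r = fair_eg(ts, body) if fair else eg(ts, body)
    elif f.op == "AG":
        r = neg(ef(neg(_sat(ts, f.args[0], fair, cache))))
    elif f.op == "EU":
        r = eu(ts, _sat(ts, f.args[0], fair, cache), _sat(ts, f.args[1], fair, cache), fs)
    elif f.op == "AU":
        sf = _sat(ts, f.args[0], fair, cache)
        sg = _sat(ts, f.args[1], fair, cache)
        if det:
            r = eu(ts, sf, sg, fs)
        else:
            # A[f U g] = !(E[!g U (!f & !g)] | EG !g)
            ng = neg(sg)
            left = eu(ts, ng, b.apply_and(neg(sf), ng), fs)
            right = fair_eg(ts, ng) if fair else eg(ts, ng)
            r = neg(b.apply_or(left, right))
    else:  # pragma: no cover
        raise ValueError(f"unknown operator {f.op!r}")
    cache[f] = r
    return r


def check(ts: TransitionSystem, f: CtlFormula, fair: bool = False,
          property_id: str = "") -> Verdict:
    """Decide f over ts; ``holds`` iff every initial state satisfies f."""
    if fair and not ts.fairness:
        raise ModelError("fair checking requested on a system without fairness constraints")
    sat = _sat(ts, f, fair, getattr(ts, "sat_cache", {False: {}, True: {}})[fair])
    holds = ts.bdd.apply_diff(ts.initial, sat) == FALSE
    return Verdict(property_id or str(f), ts.semantics, fair, holds, sat, f)


# -- witness / counterexample extraction ------------------------------

def _eu_layers(ts: TransitionSystem, f: int, g: int,
               fair_set: Optional[int]) -> List[int]:
    """Onion rings of E[f U g]: layer k needs exactly k steps to reach g."""
    b = ts.bdd
    if fair_set is not None:
        g = b.apply_and(g, fair_set)
    layers = [g]
    z = g
    while True:
        new = b.apply_diff(b.apply_and(f, ts.preimage(layers[-1])), z)
        if new == FALSE:
            return layers
        layers.append(new)
        z = b.apply_or(z, new)


def _walk_to(ts: TransitionSystem, start: State, layers: List[int]) -> List[State]:
    """Explicit walk from ``start`` (in some layer) down to layer 0."""
    k = next(i for i, l in enumerate(layers) if ts.contains(l, start))
    path = [start]
    st = start
    while k > 0:
        st = next(s for s in ts.successors(st) if ts.contains(layers[k - 1], s))
        path.append(st)
        k -= 1
    return path


def _lasso_in(ts: TransitionSystem, start: State, body: int, region: int,
              fair: bool) -> Trace:
    """Lasso from ``start``: all states satisfy ``body``; ``region`` is
    the (fair-)EG set of ``body``.

    For fair systems the path is steered through every fairness
    constraint in round-robin order; rounds repeat until a round
    boundary state recurs, so the cycle intersects each constraint.
    """
    b = ts.bdd
    path = [start]
    st = start
    if not fair:
        seen = {start: 0}
        while True:
            st = next(s for s in ts.successors(st) if ts.contains(region, s))
            if st in seen:
                return Trace(path + [st], cycle_start=seen[st])
            seen[st] = len(path)
            path.append(st)
    # round-robin over processes: walk within body to a state from which
    # firing process j lands back in the region, fire it, repeat; stop
    # when a round-boundary state recurs (every round fires every
    # process, so the cycle is fair)
    boundaries = {start: 0}
    layer_cache = []
    for j in ts.fairness:
        l0 = ts.pre_process(j, region)
        layers = [l0]
        w = l0
        while True:
            new = b.apply_diff(ts.preimage(b.apply_and(body, layers[-1])), w)
            if new == FALSE:
                break
            layers.append(new)
            w = b.apply_or(w, new)
        layer_cache.append(layers)
    proc_names = [ts.processes[j] for j in ts.fairness]
    while True:
        for j, layers in zip(ts.fairness, layer_cache):
            k = next(i for i, l in enumerate(layers) if ts.contains(l, st))
            while k > 0:
                st = next(s for s in ts.successors(st)
                          if ts.contains(body, s) and ts.contains(layers[k - 1], s))
                path.append(st)
                k -= 1
            st = dict(async_successors(ts.net, st))[ts.processes[j]]
            path.append(st)
        if st in boundaries:
            return Trace(path, cycle_start=boundaries[st])
        boundaries[st] = len(path) - 1


def _state_bdd(ts: TransitionSystem, state: State) -> int:
    b = ts.bdd
    bits = ts.state_bits(state)
    return b.conj(b.var(i) if bits[i] else b.apply_not(b.var(i))
                  for i in range(b.nvars))


def witness(ts: TransitionSystem, f: CtlFormula, verdict: Verdict) -> Optional[Trace]:
    """A replayable trace explaining the verdict, or None when the
    formula shape admits none (e.g., a passing AG)."""
    b = ts.bdd
    fair = verdict.fair
    fs = ts.fair_states() if fair else None
    cache = getattr(ts, "sat_cache", {False: {}, True: {}})[fair]

    def initial_in(region: int) -> Optional[State]:
        return ts.pick_state(b.apply_and(ts.initial, region))

    g = f
    init_region = ts.initial
    # peel a top-level implication: counterexamples live where the
    # antecedent holds
    if g.op == "imp" and not verdict.holds:
        pre = _sat(ts, g.args[0], fair, cache)
        init_region = b.apply_and(init_region, pre)
        init_region = b.apply_diff(init_region, _sat(ts, g, fair, cache))
        g = g.args[1]

    if not verdict.holds:
        if g.op == "AF":
            body = b.apply_diff(ts.universe, _sat(ts, g.args[0], fair, cache))
            region = fair_eg(ts, body) if fair else eg(ts, body)
            start = ts.pick_state(b.apply_and(init_region, region))
            if start is None:
                return NO_TRACE
            return _lasso_in(ts, start, body, region, fair)
        if g.op == "AG":
            bad = b.apply_diff(ts.universe, _sat(ts, g.args[0], fair, cache))
            layers = _eu_layers(ts, ts.universe, bad, fs)
            reach = b.disj(layers)
            start = ts.pick_state(b.apply_and(init_region, reach))
            if start is None:
                return NO_TRACE
            return Trace(_walk_to(ts, start, layers), kind="counterexample")
        if g.op == "AX":
            bad = b.apply_diff(ts.universe, _sat(ts, g.args[0], fair, cache))
            start = ts.pick_state(b.apply_and(init_region, ex(ts, bad, fs)))
            if start is None:
                return NO_TRACE
            nxt = next(s for s in ts.successors(start) if ts.contains(bad, s))
            return Trace([start, nxt], kind="counterexample")
        return NO_TRACE

    # witnesses for held existential shapes
    if g.op == "EF":
        target = _sat(ts, g.args[0], fair, cache)
        layers = _eu_layers(ts, ts.universe, target, fs)
        start = initial_in(b.disj(layers))
        if start is None:
            return NO_TRACE
        return Trace(_walk_to(ts, start, layers), kind="witness")
    if g.op == "EU":
        sf = _sat(ts, g.args[0], fair, cache)
        sg = _sat(ts, g.args[1], fair, cache)
        layers = _eu_layers(ts, sf, sg, fs)
        start = initial_in(b.disj(layers))
        if start is None:
            return NO_TRACE
        return Trace(_walk_to(ts, start, layers), kind="witness")
    if g.op == "EX":
        target = _sat(ts, g.args[0], fair, cache)
        if fair:
            target = b.apply_and(target, fs)
        start = initial_in(ex(ts, target))
        if start is None:
            return NO_TRACE
        nxt = next(s for s in ts.successors(start) if ts.contains(target, s))
        return Trace([start, nxt], kind="witness")
    return NO_TRACE


def replay_ok(ts: TransitionSystem, trace: Trace) -> bool:
    """Every consecutive pair is a transition; lassos close correctly."""
    states = trace.states
    for a, b_ in zip(states, states[1:]):
        if b_ not in ts.successors(a):
            return False
    if trace.cycle_start is not None:
        if states[-1] != states[trace.cycle_start]:
            return False
    return True


# -- cone-of-influence decomposition ----------------------------------

def formula_atoms(f: CtlFormula) -> List[CtlFormula]:
    if f.op == "atom":
        return [f]
    out: List[CtlFormula] = []
    for a in f.args:
        out.extend(formula_atoms(a))
    return out


def cone_of_influence(net: Network, f: CtlFormula) -> set:
    """Nodes that can influence the formula's atoms (transitive parents)."""
    keep = {a.name for a in formula_atoms(f)}
    changed = True
    while changed:
        changed = False
        for e in net.edges:
            if e.target in keep and e.source not in keep:
                keep.add(e.source)
                changed = True
    return keep


def reduce_to_cone(net: Network, f: CtlFormula):
    """Sub-network over the cone of influence of f.

    Sound for the X-free fragment of CTL (all properties here): dropped
    nodes never feed the cone, and removing their update processes only
    removes or inserts stuttering steps of the reduced system.
    """
    from .logic_model import Network as Net, NodeSpec
    keep = cone_of_influence(net, f)
    nodes = tuple(n for n in net.nodes if n.name in keep)
    edges = tuple(e for e in net.edges if e.source in keep and e.target in keep)
    if not any(n.kind != "input" for n in nodes):
        # keep the relation total (and fairness well-defined) with one
        # inert process; it has no parents and cannot affect any atom
        nodes += (NodeSpec("_tick", "internal", levels=2, init_set=(0,)),)
    return Net(nodes, edges, name=net.name + "-cone")


def _has_x_operator(f: CtlFormula) -> bool:
    if f.op in ("EX", "AX"):
        return True
    return any(_has_x_operator(a) for a in f.args)


def _input_only(net: Network, f: CtlFormula) -> bool:
    return all(net.node(a.name).kind == "input" for a in formula_atoms(f))


def _eval_input_formula(net: Network, f: CtlFormula, combo: Dict[str, int]) -> bool:
    """Truth of a Boolean combination of input atoms under fixed inputs."""
    if f.op == "atom":
        v = combo[f.name]
        return {"=": v == f.value, ">=": v >= f.value, "<=": v <= f.value}[f.cmp]
    if f.op == "const":
        return bool(f.value)
    if f.op == "not":
        return not _eval_input_formula(net, f.args[0], combo)
    if f.op == "and":
        return all(_eval_input_formula(net, a, combo) for a in f.args)
    if f.op == "or":
        return any(_eval_input_formula(net, a, combo) for a in f.args)
    if f.op == "imp":
        return (not _eval_input_formula(net, f.args[0], combo)
                or _eval_input_formula(net, f.args[1], combo))
    raise ValueError(f.op)


def check_decomposed(net: Network, scenario, f: CtlFormula, semantics: str,
                     fair: bool = False, property_id: str = "") -> Verdict:
    """Verdict-equivalent to :func:`check` on the full system, computed
    on the cone of influence and split over frozen-input combinations.

    Only valid for X-free formulas (falls back to a full check
    otherwise).  The satisfying set is not retained (``sat`` is None).
    """
    import itertools as _it

    from .dynamics import Scenario, TransitionSystem

    if _has_x_operator(f):
        ts = TransitionSystem(net, scenario, semantics)
        v = check(ts, f, fair, property_id)
        return Verdict(v.property_id, v.semantics, v.fair, v.holds, None, f)

    rnet = reduce_to_cone(net, f)
    rnames = {n.name for n in rnet.nodes}
    rfix = {k: v for k, v in scenario.input_fix.items() if k in rnames}
    rscenario = Scenario(name=scenario.name, input_fix=rfix,
                         init_overrides={k: v for k, v in scenario.init_overrides.items()
                                         if k in rnames})
    if semantics == "sync":
        ts = TransitionSystem(rnet, rscenario, "sync")
        ts.restrict_to_scenario_inputs()
        v = check(ts, f, fair, property_id)
        return Verdict(v.property_id, v.semantics, v.fair, v.holds, None, f)
    inputs = [n for n in rnet.nodes if n.kind == "input"]

    # peel an input-only antecedent: combos falsifying it are vacuous
    ante = None
    if f.op == "imp" and _input_only(rnet, f.args[0]):
        ante = f.args[0]

    domains = []
    for n in inputs:
        if n.name in rfix:
            v = rfix[n.name]
            domains.append(list(v) if isinstance(v, (tuple, list)) else [v])
        else:
            domains.append(list(n.domain))
    combos = list(_it.product(*domains))
    # extremes first: falsifying schedules usually live at the corners
    combos.sort(key=lambda c: (c != tuple(d[0] for d in domains),
                               c != tuple(d[-1] for d in domains)))

    holds = True
    for combo in combos:
        fix = dict(zip((n.name for n in inputs), combo))
        if ante is not None and not _eval_input_formula(rnet, ante, fix):
            continue
        sub = Scenario(name=f"{scenario.name}|{fix}", input_fix=fix,
                       init_overrides=scenario.init_overrides)
        ts = TransitionSystem(rnet, sub, semantics)
        ts.restrict_to_scenario_inputs()
        if not _check_combo(ts, f, fair).holds:
            holds = False
            break
    return Verdict(property_id or str(f), semantics, fair, holds, None, f)


def _check_combo(ts: TransitionSystem, f: CtlFormula, fair: bool) -> Verdict:
    """Per-combination check with a bounded fair-EG shortcut for
    top-level AF obligations."""
    b = ts.bdd
    g = f
    interest = ts.initial
    cache = ts.sat_cache[fair]
    if fair and g.op == "imp":
        interest = b.apply_and(interest, _sat(ts, g.args[0], fair, cache))
        if interest == FALSE:
            return Verdict(str(f), ts.semantics, fair, True, None, f)
        g = g.args[1]
    if fair and g.op == "AF":
        if _eventually_certified(ts, g.args[0]):
            return Verdict(str(f), ts.semantics, fair, True, None, f)
        body = b.apply_diff(ts.universe, _sat(ts, g.args[0], fair, cache))
        # cheap falsifier: reach, within the body, a state where every
        # process stutters — from there the fair path avoids the target
        trap = b.apply_and(stutter_fixpoints(ts), body)
        if trap != FALSE:
            z = trap
            frontier = trap
            while frontier != FALSE:
                if b.apply_and(z, interest) != FALSE:
                    return Verdict(str(f), ts.semantics, fair, False, None, f)
                frontier = b.apply_diff(b.apply_and(body, ts.preimage(frontier)), z)
                z = b.apply_or(z, frontier)
        bad = fair_eg(ts, body, interest=interest)
        holds = b.apply_and(bad, interest) == FALSE
        return Verdict(str(f), ts.semantics, fair, holds, None, f)
    v = check(ts, f, fair)
    return Verdict(str(f), ts.semantics, fair, v.holds, None, f)
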