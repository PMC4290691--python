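"""Multi-valued logical networks and their update rule.

A network is a set of named nodes carrying a small discrete level domain
``{0, ..., levels-1}`` connected by signed edges.  A node's next level is
computed by :func:`transfer_level`: the clamped difference between the
summed activator levels (plus an optional basal production constant) and
the summed inhibitor levels.  Nodes tagged ``joint_min`` instead require
*all* of their activators (minimum instead of sum), which expresses
obligatory co-regulation such as a protein needing both a substrate and
a processing enzyme.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Tuple

import yaml

KINDS = ("input", "internal", "output")
RULES = ("additive", "joint_min")
SIGNS = ("activate", "inhibit")

_SIGN_TOKEN = {"+": "activate", "-": "inhibit",
               "activate": "activate", "inhibit": "inhibit"}
_TOKEN_SIGN = {"activate": "+", "inhibit": "-"}


class ModelError(ValueError):
    """Schema or invariant violation in a model file."""


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: str = "internal"
    levels: int = 3
    init_set: Tuple[int, ...] = ()
    basal: int = 0
    rule: str = "additive"

    def __post_init__(self):
        if not self.init_set:
            object.__setattr__(self, "init_set", tuple(self.default_init()))

    def default_init(self) -> Tuple[int, ...]:
        if self.kind == "input":
            return tuple(range(self.levels))
        if self.kind == "output":
            return (0,)
        return (0, 1)

    @property
    def domain(self) -> range:
        return range(self.levels)


@dataclass(frozen=True)
class EdgeSpec:
    source: str
    target: str
    sign: str  # "activate" | "inhibit"


@dataclass(frozen=True)
class Network:
    nodes: Tuple[NodeSpec, ...]
    edges: Tuple[EdgeSpec, ...]
    name: str = "network"

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))

    # -- lookups ------------------------------------------------------

    @property
    def node_map(self) -> Dict[str, NodeSpec]:
        return {n.name: n for n in self.nodes}

    def node(self, name: str) -> NodeSpec:
        try:
            return self.node_map[name]
        except KeyError:
            raise ModelError(f"unknown node {name!r}") from None

    def parents(self, target: str) -> List[EdgeSpec]:
        return [e for e in self.edges if e.target == target]

    def parent_signs(self, target: str) -> Dict[str, str]:
        return {e.source: e.sign for e in self.parents(target)}

    def non_input_nodes(self) -> List[NodeSpec]:
        return [n for n in self.nodes if n.kind != "input"]

    def input_nodes(self) -> List[NodeSpec]:
        return [n for n in self.nodes if n.kind == "input"]

    def configuration_count(self) -> int:
        c = 1
        for n in self.nodes:
            c *= n.levels
        return c


def transfer_level(node: NodeSpec,
                   parent_levels: Mapping[str, int],
                   edge_signs: Mapping[str, str]) -> int:
    """Next level of ``node`` given its parents' current levels.

    ``additive``: clamp(basal + sum(activators) - sum(inhibitors)).
    ``joint_min``: min over activators replaces the activator sum.
    A node with neither parents nor basal production decays to 0.
    """
    acts: List[int] = []
    inhs: List[int] = []
    for name, level in parent_levels.items():
        sign = edge_signs.get(name)
        if sign is None:
            raise ModelError(f"unknown parent {name!r} for node {node.name!r}")
        if not 0 <= level:
            raise ModelError(f"parent {name!r} level {level} out of domain")
        if sign == "activate":
            acts.append(level)
        else:
            inhs.append(level)
    if node.rule == "joint_min":
        drive = min(acts) if acts else 0
    else:
        drive = sum(acts)
    raw = node.basal + drive - sum(inhs)
    return max(0, min(node.levels - 1, raw))


# -- validation -------------------------------------------------------

def validate_network(net: Network) -> List[str]:
    """Diagnostics for every violated invariant; empty when valid."""
    diags: List[str] = []
    seen = set()
    for n in net.nodes:
        if n.name in seen:
            diags.append(f"duplicate node name {n.name!r}")
        seen.add(n.name)
        if n.kind not in KINDS:
            diags.append(f"node {n.name!r}: unknown kind {n.kind!r}")
        if n.rule not in RULES:
            diags.append(f"node {n.name!r}: unknown rule {n.rule!r}")
        if n.levels < 2:
            diags.append(f"node {n.name!r}: levels must be >= 2")
        if n.kind == "output" and n.levels != 2:
            diags.append(f"output node {n.name!r} must be Boolean (levels=2)")
        if not 0 <= n.basal <= n.levels - 1:
            diags.append(f"node {n.name!r}: basal {n.basal} outside [0, {n.levels - 1}]")
        bad = [v for v in n.init_set if not 0 <= v < n.levels]
        if bad or not n.init_set:
            diags.append(f"node {n.name!r}: init set {tuple(n.init_set)} invalid")
    names = {n.name for n in net.nodes}
    seen_pairs = set()
    for e in net.edges:
        tag = f"edge {e.source}->{e.target}"
        if e.source not in names:
            diags.append(f"{tag}: unknown source")
        if e.target not in names:
            diags.append(f"{tag}: unknown target")
        if e.sign not in SIGNS:
            diags.append(f"{tag}: unknown sign {e.sign!r}")
        if (e.source, e.target) in seen_pairs:
            diags.append(f"{tag}: duplicate edge")
        seen_pairs.add((e.source, e.target))
        if e.target in names and net.node(e.target).kind == "input":
            diags.append(f"{tag}: input nodes cannot be regulated")
    return diags


def check_valid(net: Network) -> Network:
    diags = validate_network(net)
    if diags:
        raise ModelError("; ".join(diags))
    return net


# -- serialization ----------------------------------------------------

def network_to_dict(net: Network) -> dict:
    nodes = []
    for n in net.nodes:
        d: dict = {"name": n.name, "kind": n.kind, "levels": n.levels}
        if tuple(n.init_set) != n.default_init():
            d["init"] = list(n.init_set)
        if n.basal:
            d["basal"] = n.basal
        if n.rule != "additive":
            d["rule"] = n.rule
        nodes.append(d)
    edges = [{"from": e.source, "to": e.target, "sign": _TOKEN_SIGN[e.sign]}
             for e in net.edges]
    return {"name": net.name, "nodes": nodes, "edges": edges}


def serialize_network(net: Network) -> str:
    return yaml.safe_dump(network_to_dict(net), sort_keys=False)


def network_from_dict(data: dict) -> Network:
    if not isinstance(data, dict):
        raise ModelError("model file must contain a mapping")
    for key in ("nodes", "edges"):
        if key not in data:
            raise ModelError(f"missing top-level key {key!r}")
    nodes = []
    for i, nd in enumerate(data["nodes"]):
        if not isinstance(nd, dict) or "name" not in nd:
            raise ModelError(f"nodes[{i}]: expected a mapping with a 'name'")
        extra = set(nd) - {"name", "kind", "levels", "init", "basal", "rule"}
        if extra:
            raise ModelError(f"nodes[{i}] ({nd['name']}): unknown keys {sorted(extra)}")
        kind = nd.get("kind", "internal")
        levels = nd.get("levels", 2 if kind == "output" else 3)
        spec = NodeSpec(name=str(nd["name"]), kind=kind, levels=int(levels),
                        basal=int(nd.get("basal", 0)),
                        rule=nd.get("rule", "additive"))
        if "init" in nd:
            init = nd["init"]
            init = tuple(sorted({int(v) for v in (init if isinstance(init, list) else [init])}))
            spec = replace(spec, init_set=init)
        nodes.append(spec)
    edges = []
    for i, ed in enumerate(data["edges"]):
        if not isinstance(ed, dict) or not {"from", "to", "sign"} <= set(ed):
            raise ModelError(f"edges[{i}]: expected keys from/to/sign")
        sign = _SIGN_TOKEN.get(str(ed["sign"]))
        if sign is None:
            raise ModelError(f"edges[{i}]: sign must be '+' or '-'")
        edges.append(EdgeSpec(str(ed["from"]), str(ed["to"]), sign))
    net = Network(tuple(nodes), tuple(edges), name=str(data.get("name", "network")))
    return check_valid(net)


def parse_network(text: str) -> Network:
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ModelError(f"not valid YAML/JSON: {exc}") from exc
    return network_from_dict(data)


def to_dot(net: Network) -> str:
    """GraphViz rendering of the signed interaction graph."""
    lines = [f'digraph "{net.name}" {{', "  rankdir=LR;"]
    shape = {"input": "invhouse", "internal": "ellipse", "output": "doubleoctagon"}
    for n in net.nodes:
        label = n.name if not n.basal else f"{n.name}\\nbasal={n.basal}"
        lines.append(f'  "{n.name}" [shape={shape[n.kind]}, label="{label}"];')
    for e in net.edges:
        style = ("arrowhead=normal" if e.sign == "activate" else
                 "arrowhead=tee, color=red")
        lines.append(f'  "{e.source}" -> "{e.target}" [{style}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def eternal_intervals(net: Network,
                      input_fix: Mapping[str, int]) -> Dict[str, Tuple[int, int]]:
    """Per-node envelope of eventually-attainable levels under frozen inputs.

    Iterates the interval abstraction of the update functions downward
    from full domains.  Sound for synchronous paths and for asynchronous
    paths on which every node is updated infinitely often: once every
    node has re-fired against stage-k parents, its value lies in stage
    k+1, so every such path eventually stays inside the fixpoint
    envelope forever.
    """
    iv: Dict[str, Tuple[int, int]] = {}
    for n in net.nodes:
        if n.kind == "input":
            v = int(input_fix[n.name])
            iv[n.name] = (v, v)
        else:
            iv[n.name] = (0, n.levels - 1)
    changed = True
    while changed:
        changed = False
        for n in net.nodes:
            if n.kind == "input":
                continue
            signs = net.parent_signs(n.name)
            acts = [iv[p] for p, s in signs.items() if s == "activate"]
            inhs = [iv[p] for p, s in signs.items() if s == "inhibit"]
            if n.rule == "joint_min":
                lo_d = min((a[0] for a in acts), default=0)
                hi_d = min((a[1] for a in acts), default=0)
            else:
                lo_d = sum(a[0] for a in acts)
                hi_d = sum(a[1] for a in acts)
            top = n.levels - 1
            lo = max(0, min(top, n.basal + lo_d - sum(i[1] for i in inhs)))
            hi = max(0, min(top, n.basal + hi_d - sum(i[0] for i in inhs)))
            new = (lo, hi)
            if new != iv[n.name]:
                iv[n.name] = new
                changed = True
    return iv
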