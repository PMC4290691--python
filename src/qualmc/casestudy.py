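"""The bundled 30-node ER-Golgi stress network and its property suite.

The network couples the three unfolded-protein-response sensor arms
(ATF6/S1-2P processing, PERK translation attenuation, IRE1 stress
kinase signaling) with an NFkB negative-feedback oscillator and three
Boolean cell-fate outputs.  The property suite pairs each CTL formula
with the expected synchronous and asynchronous (fairness-constrained)
verdicts; ``reproduce`` re-checks the whole table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from importlib import resources
from typing import List, Optional, Sequence

import yaml

from .ctl import CtlFormula, parse_ctl
from .dynamics import Scenario
from .logic_model import Network, parse_network


def _data(name: str) -> str:
    return resources.files("qualmc.data").joinpath(name).read_text()


def er_golgi_network() -> Network:
    """The shipped, validated 30-node case-study model."""
    return parse_network(_data("er_golgi.model.yaml"))


@dataclass(frozen=True)
class PropertyRecord:
    id: str
    formula: str
    scenario: Scenario
    expect_sync: Optional[bool]
    expect_async: Optional[bool]
    tier: str = "core"

    def parsed(self, net: Network) -> CtlFormula:
        return parse_ctl(self.formula, net)


def property_suite() -> List[PropertyRecord]:
    records = []
    for item in yaml.safe_load(_data("er_golgi.props.yaml")):
        fix = (item.get("scenario") or {}).get("fix") or {}
        scenario = Scenario(name=item["id"],
                           input_fix={k: tuple(v) if isinstance(v, list) else v
                                      for k, v in fix.items()})
        records.append(PropertyRecord(
            id=item["id"],
            formula=item["formula"],
            scenario=scenario,
            expect_sync=item.get("expect_sync"),
            expect_async=item.get("expect_async"),
            tier=item.get("tier", "core"),
        ))
    return records


@dataclass
class ReportRow:
    id: str
    semantics: str
    fair: bool
    expected: Optional[bool]
    observed: bool
    runtime_s: float
    tier: str

    @property
    def match(self) -> bool:
        return self.expected is None or self.expected == self.observed


def _check_record(net, rec: PropertyRecord, semantics: str,
                  backend: str = "dd") -> ReportRow:
    fair = semantics == "async"
    t0 = time.perf_counter()
    if backend == "explicit":
        from .explicit import build_graph, explicit_check
        g = build_graph(net, rec.scenario, semantics)
        verdict = explicit_check(g, rec.parsed(net), fair, rec.id)
    else:
        from .ctl import check_decomposed
        verdict = check_decomposed(net, rec.scenario, rec.parsed(net),
                                   semantics, fair, rec.id)
    dt = time.perf_counter() - t0
    expected = rec.expect_sync if semantics == "sync" else rec.expect_async
    return ReportRow(rec.id, semantics, fair, expected, verdict.holds, dt, rec.tier)


def reproduce(backend: str = "dd",
              records: Optional[Sequence[PropertyRecord]] = None,
              semantics: Sequence[str] = ("sync", "async")) -> List[ReportRow]:
    """Check every property under each semantics with an expectation.

    Asynchronous checks run with fairness enabled (every update process
    executes infinitely often).
    """
    if backend not in ("dd", "explicit"):
        raise ValueError(f"unknown backend {backend!r}")
    net = er_golgi_network()
    if records is None:
        records = property_suite()
    rows = []
    for rec in records:
        for sem in semantics:
            expected = rec.expect_sync if sem == "sync" else rec.expect_async
            if expected is None:
                continue
            rows.append(_check_record(net, rec, sem, backend))
    return rows


def report_tsv(rows: Sequence[ReportRow]) -> str:
    out = ["id\tsemantics\tfair\texpected\tobserved\tmatch\truntime_s"]
    for r in rows:
        out.append("\t".join([
            r.id, r.semantics, str(r.fair).lower(),
            "" if r.expected is None else str(r.expected).lower(),
            str(r.observed).lower(), str(r.match).lower(), f"{r.runtime_s:.3f}",
        ]))
    mism = sum(not r.match for r in rows)
    out.append(f"# rows={len(rows)} mismatches={mism}")
    return "\n".join(out) + "\n"
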