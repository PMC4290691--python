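import random

import pytest

from qualmc.bdd import FALSE
from qualmc.ctl import (CtlFormula, CtlSyntaxError, atom, check,
                        check_decomposed, eu, label_atom, parse_ctl)
from qualmc.dynamics import Scenario, State, TransitionSystem
from qualmc.explicit import build_graph, random_formula, random_network
from qualmc.logic_model import ModelError, parse_network

from conftest import compare_on


class TestParser:
    def test_headline_formula_shape(self, er_net):
        f = parse_ctl("AG (ASK1 = 2 -> AF (Abeta >= 1 & Alzheimer = True))", er_net)
        assert f.op == "AG"
        imp = f.args[0]
        assert imp.op == "imp"
        assert imp.args[0] == atom("ASK1", "=", 2)
        af = imp.args[1]
        assert af.op == "AF" and af.args[0].op == "and"

    def test_constants(self):
        assert parse_ctl("True").value == 1
        assert parse_ctl("False").value == 0

    def test_boolean_sugar_maps_to_levels(self, er_net):
        f = parse_ctl("Alzheimer = True", er_net)
        assert f.value == 1

    def test_out_of_domain_constant(self, er_net):
        with pytest.raises(ModelError, match="out of domain"):
            parse_ctl("EF (P53 >= 3)", er_net)

    def test_unknown_node(self, er_net):
        with pytest.raises(ModelError, match="unknown node"):
            parse_ctl("EF (P54 >= 1)", er_net)

    def test_precedence(self):
        f = parse_ctl("!a = 1 & b = 1 | c = 1 -> d = 1")
        assert f.op == "imp"
        assert f.args[0].op == "or"
        assert f.args[0].args[0].op == "and"
        assert f.args[0].args[0].args[0].op == "not"

    def test_until_brackets(self):
        f = parse_ctl("E [ a = 1 U b = 0 ]")
        assert f.op == "EU"
        g = parse_ctl("A [ a = 1 U b = 0 ]")
        assert g.op == "AU"

    def test_syntax_error_has_position(self):
        with pytest.raises(CtlSyntaxError, match="position"):
            parse_ctl("AG (a = 1 ))")

    def test_round_trip_via_str(self, er_net):
        text = "AG ((NFkB >= 1 -> AF (NFkB = 0)) & (NFkB = 0 -> AF (NFkB >= 1)))"
        f = parse_ctl(text, er_net)
        assert parse_ctl(str(f), er_net) == f


class TestLabelAtom:
    def test_threshold_atom(self):
        net = parse_network("""
nodes: [{name: NFkB, kind: internal, levels: 3}]
edges: []
""")
        ts = TransitionSystem(net, Scenario(), "sync")
        sat = label_atom(ts, atom("NFkB", ">=", 1))
        got = {v for v in range(3) if ts.contains(sat, State((v,)))}
        assert got == {1, 2}

    def test_boolean_atom(self, er_net):
        ts = TransitionSystem(er_net, Scenario(), "sync")
        sat = label_atom(ts, atom("Alzheimer", "=", 1))
        st = next(iter([s for s in [State(tuple(
            2 if n.name == "Alzheimer" else 0 for n in er_net.nodes))]]))
        # level 2 is outside the Boolean domain: not in care space
        assert not ts.contains(sat, st)

    @pytest.mark.parametrize("seed", range(10))
    def test_conjunction_is_intersection(self, seed):
        net = random_network(seed, 4)
        ts = TransitionSystem(net, Scenario(), "sync")
        rng = random.Random(seed)
        n1, n2 = rng.sample([n.name for n in net.nodes], 2)
        a1 = atom(n1, ">=", 1)
        a2 = atom(n2, "<=", 0)
        both = check(ts, CtlFormula("and", (a1, a2))).sat
        assert both == ts.bdd.apply_and(label_atom(ts, a1), label_atom(ts, a2))


class TestPreimage:
    def test_whole_space_and_empty(self, nfkb_toy):
        for sem in ("sync", "async"):
            ts = TransitionSystem(nfkb_toy, Scenario(), sem)
            assert ts.preimage(ts.care) == ts.care   # R total
            assert ts.preimage(FALSE) == FALSE

    @pytest.mark.parametrize("seed", range(200))
    def test_matches_explicit_predecessors(self, seed):
        net = random_network(seed, 4)
        sem = "async" if seed % 2 else "sync"
        ts = TransitionSystem(net, Scenario(), sem)
        g = build_graph(net, Scenario(), sem)
        rng = random.Random(seed)
        targets = set(rng.sample(range(len(g.states)),
                                 max(1, len(g.states) // 3)))
        tgt = FALSE
        for i in targets:
            s = g.states[i]
            tgt = ts.bdd.apply_or(tgt, ts.bdd.conj(
                ts.node_equals(n.name, v)
                for n, v in zip(net.nodes, s.assignment)))
        pre = ts.preimage(tgt)
        target_assignments = {g.states[i].assignment for i in targets}
        for i, s in enumerate(g.states):
            expected = any(g.states[j].assignment in target_assignments
                           for _, j in g.succ[i])
            assert ts.contains(pre, s) == expected


def _mk_ts(net, sem):
    return TransitionSystem(net, Scenario(), sem)


class TestCheck:
    def test_ag_true_everywhere(self, nfkb_toy, chain_net):
        for net in (nfkb_toy, chain_net):
            for sem in ("sync", "async"):
                ts = _mk_ts(net, sem)
                assert check(ts, parse_ctl("AG True")).holds

    @pytest.mark.parametrize("seed", range(30))
    def test_dualities(self, seed):
        net = random_network(seed, 4)
        sem = "async" if seed % 2 else "sync"
        ts = _mk_ts(net, sem)
        inner = random_formula(seed * 7 + 1, net, 2)
        pairs = [
            (CtlFormula("AG", (inner,)),
             CtlFormula("not", (CtlFormula("EF", (CtlFormula("not", (inner,)),)),))),
            (CtlFormula("AX", (inner,)),
             CtlFormula("not", (CtlFormula("EX", (CtlFormula("not", (inner,)),)),))),
            (CtlFormula("AF", (inner,)),
             CtlFormula("not", (CtlFormula("EG", (CtlFormula("not", (inner,)),)),))),
        ]
        for lhs, rhs in pairs:
            assert check(ts, lhs).sat == check(ts, rhs).sat

    @pytest.mark.parametrize("seed", range(20))
    def test_af_implies_ef(self, seed):
        net = random_network(seed, 4)
        sem = "async" if seed % 2 else "sync"
        fair = bool(seed % 4 == 1) and sem == "async"
        ts = _mk_ts(net, sem)
        inner = random_formula(seed * 13 + 5, net, 2)
        af = check(ts, CtlFormula("AF", (inner,)), fair).sat
        ef = check(ts, CtlFormula("EF", (inner,)), fair).sat
        assert ts.bdd.apply_diff(af, ef) == FALSE

    @pytest.mark.parametrize("seed", range(15))
    def test_sync_collapse(self, seed):
        net = random_network(seed, 4)
        ts = _mk_ts(net, "sync")
        inner = random_formula(seed * 3 + 2, net, 2)
        assert check(ts, CtlFormula("AF", (inner,))).sat == \
            check(ts, CtlFormula("EF", (inner,))).sat
        assert check(ts, CtlFormula("AG", (inner,))).sat == \
            check(ts, CtlFormula("EG", (inner,))).sat

    @pytest.mark.parametrize("seed", range(10))
    def test_single_process_fairness_is_trivial(self, seed):
        # one update process: every path runs it infinitely often, so
        # fair and unfair semantics coincide
        net = parse_network("""
nodes:
  - {name: In, kind: input, levels: 3}
  - {name: Out, kind: internal, levels: 3}
edges:
  - {from: In, to: Out, sign: "%s"}
""" % ("+" if seed % 2 else "-"))
        ts = _mk_ts(net, "async")
        f = random_formula(seed, net, 3)
        assert check(ts, f, fair=True).sat == check(ts, f, fair=False).sat

    def test_ef_fixpoint_is_least(self, nfkb_toy):
        # one more preimage iteration adds nothing
        ts = _mk_ts(nfkb_toy, "async")
        target = label_atom(ts, atom("NFkB", "=", 0))
        sat = eu(ts, ts.universe, target)
        extra = ts.bdd.apply_and(ts.universe, ts.preimage(sat))
        assert ts.bdd.apply_or(sat, extra) == sat

    def test_fair_requires_constraints(self, chain_net):
        ts = _mk_ts(chain_net, "sync")
        with pytest.raises(ModelError):
            check(ts, parse_ctl("AG True"), fair=True)


class TestOracleAgreementSmoke:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_systems(self, seed):
        net = random_network(seed, 4)
        sem = "async" if seed % 2 else "sync"
        fair = sem == "async" and seed % 4 < 2
        f = random_formula(seed * 31 + 7, net, 3)
        _, _, agree = compare_on(net, Scenario(), sem, f, fair)
        assert agree

    @pytest.mark.parametrize("seed", range(10))
    def test_fixed_input_scenarios(self, seed):
        # exercises the interval-certificate fast path for fair AF/EF
        net = random_network(seed, 5)
        rng = random.Random(seed + 99)
        fix = {n.name: rng.randrange(n.levels) for n in net.input_nodes()}
        scen = Scenario(input_fix=fix)
        f = CtlFormula("AF", (random_formula(seed * 5 + 3, net, 1),))
        _, _, agree = compare_on(net, scen, "async", f, fair=True)
        assert agree


class TestCheckDecomposed:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_plain_check(self, seed):
        net = random_network(seed, 5)
        sem = "async" if seed % 2 else "sync"
        fair = sem == "async"
        f = random_formula(seed * 11 + 3, net, 3)
        ts = TransitionSystem(net, Scenario(), sem)
        expected = check(ts, f, fair).holds
        got = check_decomposed(net, Scenario(), f, sem, fair).holds
        assert got == expected

    def test_cone_reduction_drops_unrelated_nodes(self, er_net):
        from qualmc.ctl import reduce_to_cone
        f = parse_ctl("AG ((NFkB >= 1 -> AF (NFkB = 0)))", er_net)
        rnet = reduce_to_cone(er_net, f)
        names = {n.name for n in rnet.nodes}
        assert names == {"NFkB", "IkB", "IKK", "A20", "TRAF2", "IRE1"}
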