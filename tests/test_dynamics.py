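import itertools
import random

import pytest

from qualmc.dynamics import (INIT_TAG, Scenario, State, TransitionSystem,
                             async_successors, initial_level_sets,
                             initial_states, simulate, sync_successor,
                             trace_tsv)
from qualmc.explicit import random_network
from qualmc.logic_model import ModelError


class TestInitialStates:
    def test_er_conventions(self, er_net):
        sets = initial_level_sets(er_net, Scenario())
        assert sets["PERK"] == (0, 1, 2)
        assert sets["TRAF2"] == (0, 1)
        assert sets["Apoptosis"] == (0,)

    def test_input_fix(self, er_net):
        sets = initial_level_sets(er_net, Scenario(input_fix={"IRE1": 2}))
        assert sets["IRE1"] == (2,)

    def test_singleton_overrides(self, chain_net):
        scen = Scenario(input_fix={"A": 1},
                        init_overrides={"B": (0,), "C": (1,)})
        states = list(initial_states(chain_net, scen))
        assert states == [State((1, 0, 1))]

    def test_async_states_carry_init_tag(self, chain_net):
        st = next(initial_states(chain_net, Scenario(), "async"))
        assert st.sched == INIT_TAG

    def test_bad_scenario_rejected(self, chain_net):
        with pytest.raises(ModelError):
            Scenario(input_fix={"B": 1}).validate(chain_net)   # not an input
        with pytest.raises(ModelError):
            Scenario(input_fix={"A": 7}).validate(chain_net)


class TestSyncSuccessor:
    def test_chain_propagates_one_step(self, chain_net):
        nxt = sync_successor(chain_net, State((1, 0, 0)))
        assert nxt.assignment == (1, 1, 0)

    def test_all_zero_fixed_point(self, chain_net):
        z = State((0, 0, 0))
        assert sync_successor(chain_net, z) == z

    def test_nfkb_toy_period_four(self, nfkb_toy):
        cycle = [(0, 0), (2, 0), (2, 2), (0, 2)]
        st = State(cycle[0])
        for expected in cycle[1:] + cycle[:1]:
            st = sync_successor(nfkb_toy, st)
            assert st.assignment == expected

    def test_deterministic(self, er_net):
        rng = random.Random(0)
        asg = tuple(rng.randrange(n.levels) for n in er_net.nodes)
        assert sync_successor(er_net, State(asg)) == sync_successor(er_net, State(asg))


class TestAsyncSuccessors:
    def test_er_process_count(self, er_net):
        st = next(initial_states(er_net, Scenario(), "async"))
        succs = async_successors(er_net, st)
        assert len(succs) == 26  # 23 internal + 3 output processes

    def test_fixed_point_stutters(self, chain_net):
        st = State((0, 0, 0), INIT_TAG)
        for name, s in async_successors(chain_net, st):
            assert s.assignment == st.assignment
            assert s.sched == name

    def test_frame_condition(self, er_net):
        rng = random.Random(1)
        names = [n.name for n in er_net.nodes]
        inputs = {i for i, n in enumerate(er_net.nodes) if n.kind == "input"}
        for _ in range(25):
            asg = tuple(rng.randrange(n.levels) for n in er_net.nodes)
            st = State(asg, INIT_TAG)
            for name, s in async_successors(er_net, st):
                diff = [i for i in range(len(names))
                        if s.assignment[i] != asg[i]]
                assert len(diff) <= 1
                assert not (set(diff) & inputs)

    def test_totality(self, nfkb_toy):
        for asg in itertools.product(range(3), repeat=2):
            assert len(async_successors(nfkb_toy, State(asg, INIT_TAG))) == 2


class TestSimulate:
    def test_sync_reproduces_cycle(self, nfkb_toy):
        trace = simulate(nfkb_toy, State((0, 0)), 8, "sync")
        assert [t.assignment for t in trace[:5]] == \
            [(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)]

    def test_zero_steps(self, nfkb_toy):
        assert len(simulate(nfkb_toy, State((0, 0)), 0)) == 1

    def test_async_seed_determinism(self, er_net):
        st = next(initial_states(er_net, Scenario(), "async"))
        t1 = simulate(er_net, st, 30, "async", choice_seed=42)
        t2 = simulate(er_net, st, 30, "async", choice_seed=42)
        t3 = simulate(er_net, st, 30, "async", choice_seed=43)
        assert t1 == t2
        assert t1 != t3

    def test_inputs_frozen_along_paths(self, er_net):
        st = next(initial_states(er_net, Scenario(input_fix={"PERK": 2}), "async"))
        idx = [i for i, n in enumerate(er_net.nodes) if n.kind == "input"]
        for sem in ("sync", "async"):
            for s in simulate(er_net, st, 25, sem, choice_seed=5):
                assert all(s.assignment[i] == st.assignment[i] for i in idx)

    def test_trace_tsv(self, nfkb_toy):
        out = trace_tsv(nfkb_toy, simulate(nfkb_toy, State((0, 0)), 2))
        assert out.splitlines()[0] == "step\tnode\tlevel"
        assert len(out.splitlines()) == 1 + 3 * 2


class TestSymbolicEncoding:
    def test_sync_image_of_state_is_unique_successor(self, nfkb_toy):
        ts = TransitionSystem(nfkb_toy, Scenario(), "sync")
        for asg in itertools.product(range(3), repeat=2):
            st = State(asg)
            succ = sync_successor(nfkb_toy, st)
            # preimage of {succ} must contain st
            target = ts.bdd.conj(
                ts.node_equals(n.name, v)
                for n, v in zip(nfkb_toy.nodes, succ.assignment))
            assert ts.contains(ts.preimage(target), st)

    @pytest.mark.parametrize("seed", range(15))
    def test_image_process_matches_explicit(self, seed):
        net = random_network(seed, 4)
        ts = TransitionSystem(net, Scenario(), "async")
        rng = random.Random(seed)
        asg = tuple(rng.randrange(n.levels) for n in net.nodes)
        st = State(asg, INIT_TAG)
        src = ts.bdd.conj(ts.node_equals(n.name, v)
                          for n, v in zip(net.nodes, asg))
        succs = async_successors(net, st)
        for i, name in enumerate(ts.processes):
            img = ts.image_process(i, src)
            expected = dict(succs)[name]
            assert ts.contains(img, expected)

    def test_initial_set_counts(self, er_net):
        ts = TransitionSystem(er_net, Scenario(), "sync")
        nbits = ts.bdd.nvars - len(ts.aux_bits)   # scratch bits excluded
        assert ts.bdd.count(ts.initial, nbits) == 3 ** 4 * 2 ** 23

    def test_compact_preserves_sets(self, nfkb_toy):
        ts = TransitionSystem(nfkb_toy, Scenario(), "async")
        from qualmc.ctl import check, parse_ctl
        f = parse_ctl("AF (NFkB = 0)", nfkb_toy)
        before = check(ts, f, fair=True).holds
        care_states = {asg for asg in itertools.product(range(3), repeat=2)
                       if ts.contains(ts.care, State(asg, INIT_TAG))}
        ts.compact()
        after_states = {asg for asg in itertools.product(range(3), repeat=2)
                        if ts.contains(ts.care, State(asg, INIT_TAG))}
        assert care_states == after_states
        assert check(ts, f, fair=True).holds == before
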