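import pytest

from mvnet.engine import (
    Configuration,
    Dependency,
    Edge,
    Network,
    NetworkValidationError,
    Node,
    Polarity,
    UnknownNodeError,
    Verdict,
    compute_sum,
    simulate,
    step,
    unit_magnitude,
    update_magnitude,
)
from mvnet.fixtures import make_random_network


def net_of(nodes, edges, U=9):
    return Network(U=U, nodes=tuple(nodes), edges=tuple(edges))


class TestUpdateMagnitude:
    @pytest.mark.parametrize("s, expected", [
        (0, 0), (1, 1), (-1, 1), (2, 1), (4, 2), (9, 2), (-9, 2),
        (27, 3), (-27, 3), (17, 3),
    ])
    def test_log_rounding(self, s, expected):
        """[ln(|s|+1)] rounded half-up; sign-symmetric; zero only at zero."""
        assert update_magnitude(s) == expected

    def test_zero_iff_zero(self):
        assert all(update_magnitude(s) > 0 for s in range(1, 200))

    def test_unit_rule(self):
        assert unit_magnitude(0) == 0
        assert all(unit_magnitude(s) == 1 for s in (-50, -1, 1, 7))

    def test_sign_symmetry_and_monotonicity(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=200)
        @given(st.integers(min_value=-10**6, max_value=10**6))
        def check(s):
            assert update_magnitude(s) == update_magnitude(-s)
            assert update_magnitude(abs(s) + 1) >= update_magnitude(s)

        check()


class TestComputeSum:
    def test_no_incoming_edges(self):
        net = net_of([Node("X")], [])
        assert compute_sum(net, net.initial_configuration(), "X") == 0

    def test_weighted_sum(self):
        net = net_of(
            [Node("A", initial_state=3), Node("B", initial_state=1), Node("X")],
            [Edge("A", "X", 1), Edge("B", "X", -2)],
        )
        assert compute_sum(net, net.initial_configuration(), "X") == 1

    def test_dependency_requires_inactive_blocks(self):
        net = net_of(
            [Node("A", initial_state=9), Node("C", initial_state=2), Node("X")],
            [Edge("A", "X", 1,
                  dependencies=(Dependency("C", Polarity.REQUIRES_INACTIVE),))],
        )
        assert compute_sum(net, net.initial_configuration(), "X") == 0

    def test_source_gate(self):
        """A gated source contributes only when strictly above the gate."""
        edges = [Edge("F", "T", 1, source_gate=8)]
        for state, expected in ((8, 0), (9, 9)):
            net = net_of([Node("F", initial_state=state), Node("T")], edges)
            assert compute_sum(net, net.initial_configuration(), "T") == expected

    def test_unknown_target(self):
        net = net_of([Node("A")], [])
        with pytest.raises(UnknownNodeError):
            compute_sum(net, net.initial_configuration(), "nope")


class TestStep:
    def test_no_edges_is_identity(self):
        net = net_of([Node("A", initial_state=4), Node("B", initial_state=0)], [])
        nxt = step(net, net.initial_configuration())
        assert nxt.states == {"A": 4, "B": 0}
        assert nxt.step == 1

    def test_ceiling_clip(self):
        net = net_of([Node("S", initial_state=9), Node("X", initial_state=8)],
                     [Edge("S", "X", 1)])
        assert step(net, net.initial_configuration())["X"] == 9

    def test_floor_clip(self):
        net = net_of([Node("S", initial_state=9), Node("X", initial_state=1)],
                     [Edge("S", "X", -1)])
        assert step(net, net.initial_configuration())["X"] == 0

    def test_clamped_node_ignores_input(self):
        net = net_of([Node("S", initial_state=9), Node("C", initial_state=9, clamp=9)],
                     [Edge("S", "C", -3)])
        assert step(net, net.initial_configuration())["C"] == 9

    def test_thresholds_are_strict(self):
        """A sum equal to a threshold leaves the state unchanged."""
        net = net_of(
            [Node("S", initial_state=2), Node("X", initial_state=5,
                                              threshold_plus=2, threshold_minus=-2)],
            [Edge("S", "X", 1)],
        )
        assert step(net, net.initial_configuration())["X"] == 5

    def test_synchronous_evaluation(self):
        """Both nodes read the input configuration, not partial updates."""
        net = net_of(
            [Node("A", initial_state=9), Node("B", initial_state=0)],
            [Edge("A", "B", 1), Edge("B", "A", -1), Edge("A", "A", -1)],
        )
        nxt = step(net, net.initial_configuration())
        # B sees A=9 (rises); A sees B=0 and itself (decays)
        assert nxt["B"] == 2 and nxt["A"] == 7


class TestSimulate:
    def test_fixed_point_immediately(self):
        net = net_of([Node("A", initial_state=3)], [])
        traj = simulate(net)
        assert traj.verdict is Verdict.STEADY_STATE
        assert traj.verdict_step == 0
        assert len(traj.configurations) == 2

    def test_max_steps_validation(self):
        net = net_of([Node("A")], [])
        with pytest.raises(ValueError):
            simulate(net, max_steps=0)

    def test_cap_reached(self):
        net = net_of([Node("A", initial_state=1), Node("B")],
                     [Edge("A", "B", 1), Edge("B", "A", -1), Edge("B", "B", -1),
                      Edge("A", "A", 1)], U=3)
        traj = simulate(net, max_steps=2)
        assert traj.verdict in (Verdict.CAP_REACHED, Verdict.CYCLE, Verdict.STEADY_STATE)
        assert len(traj.configurations) <= 3

    def test_incomplete_initial_rejected(self):
        net = net_of([Node("A"), Node("B")], [])
        with pytest.raises(NetworkValidationError):
            simulate(net, Configuration(states={"A": 0}))

    def test_determinism(self):
        net = make_random_network(5, density=0.6, seed=11, U=4)
        t1 = simulate(net)
        t2 = simulate(net)
        assert [c.states for c in t1.configurations] == \
               [c.states for c in t2.configurations]
        assert (t1.verdict, t1.verdict_step, t1.cycle_period) == \
               (t2.verdict, t2.verdict_step, t2.cycle_period)

    @pytest.mark.parametrize("seed", range(6))
    def test_synchrony_order_invariance(self, seed):
        """Permuting node declaration order never changes the dynamics."""
        import random

        net = make_random_network(5, density=0.5, seed=seed, U=3)
        rng = random.Random(seed)
        order = list(net.nodes)
        rng.shuffle(order)
        permuted = Network(U=net.U, nodes=tuple(order), edges=net.edges)
        t1, t2 = simulate(net), simulate(permuted)
        assert (t1.verdict, t1.verdict_step, t1.cycle_period) == \
               (t2.verdict, t2.verdict_step, t2.cycle_period)
        for c1, c2 in zip(t1.configurations, t2.configurations):
            assert c1.states == c2.states

    @pytest.mark.parametrize("seed", range(8))
    def test_boundedness(self, seed):
        net = make_random_network(5, density=0.7, seed=seed, U=3,
                                  with_clamps=True)
        traj = simulate(net)
        for cfg in traj.configurations:
            assert all(0 <= v <= net.U for v in cfg.states.values())

    def test_monotone_clip_at_bounds(self):
        """At the ceiling a positive sum keeps U; at the floor a negative keeps 0."""
        net = net_of([Node("hi", initial_state=9), Node("lo", initial_state=0)],
                     [Edge("hi", "hi", 1), Edge("hi", "lo", -1)])
        traj = simulate(net, max_steps=5)
        assert traj.last["hi"] == 9 and traj.last["lo"] == 0


class TestValidation:
    def test_duplicate_edge_rejected(self):
        with pytest.raises(NetworkValidationError, match="duplicate edge"):
            net_of([Node("A"), Node("B")], [Edge("A", "B", 1), Edge("A", "B", 2)])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(NetworkValidationError, match="unknown target"):
            net_of([Node("A")], [Edge("A", "B", 1)])

    def test_unknown_dependency_controller_rejected(self):
        with pytest.raises(NetworkValidationError, match="controller"):
            net_of([Node("A"), Node("B")],
                   [Edge("A", "B", 1, dependencies=(Dependency("C"),))])

    def test_zero_weight_rejected(self):
        with pytest.raises(NetworkValidationError, match="nonzero"):
            Edge("A", "B", 0)

    def test_clamp_initial_mismatch_rejected(self):
        with pytest.raises(NetworkValidationError, match="clamp"):
            net_of([Node("A", initial_state=3, clamp=9)], [])

    def test_out_of_range_initial_rejected(self):
        with pytest.raises(NetworkValidationError, match="outside"):
            Network(U=3, nodes=(Node("A", initial_state=7),), edges=())

    def test_threshold_order_rejected(self):
        with pytest.raises(NetworkValidationError, match="threshold"):
            Node("A", threshold_plus=0, threshold_minus=1)


def test_unit_magnitude_reduces_to_predecessor_model(naive):
    """With f = 1 the engine reproduces the unit-step predecessor dynamics."""
    naive_successor, naive_orbit = naive
    for seed in range(10):
        net = make_random_network(4, density=0.6, seed=seed, U=3)
        verdict, entry, period = naive_orbit(
            net, {n.name: n.initial_state for n in net.nodes},
            magnitude=lambda s: 0 if s == 0 else 1)
        traj = simulate(net, magnitude=unit_magnitude)
        assert traj.verdict.value == verdict
        assert traj.verdict_step == entry
        if verdict == "cycle":
            assert traj.cycle_period == period
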