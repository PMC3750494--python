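import math

import pytest

from mvnet.cellcycle import build_wildtype
from mvnet.engine import Configuration, Network, Verdict, simulate


@pytest.fixture(scope="session")
def wildtype():
    net, cfg = build_wildtype()
    return net, cfg


@pytest.fixture(scope="session")
def wildtype_trajectory(wildtype):
    net, cfg = wildtype
    traj = simulate(net, cfg)
    assert traj.verdict is Verdict.CYCLE
    return traj


def naive_successor(network: Network, states: dict, magnitude=None) -> dict:
    """Independent re-derivation of the synchronous update, for oracle tests.

    Deliberately written from the rule definition rather than sharing code
    with the engine.
    """
    if magnitude is None:
        def magnitude(x):
            return math.floor(math.log(abs(x) + 1) + 0.5)
    new = {}
    for node in network.nodes:
        if node.clamp is not None:
            new[node.name] = node.clamp
            continue
        total = 0
        for e in network.edges:
            if e.target != node.name:
                continue
            if states[e.source] <= e.source_gate:
                continue
            ok = True
            for dep in e.dependencies:
                s = states[dep.controller]
                if dep.polarity.value == "requires_active" and s < 1:
                    ok = False
                if dep.polarity.value == "requires_inactive" and s != 0:
                    ok = False
            if ok:
                total += e.weight * states[e.source]
        s = states[node.name]
        if total > node.threshold_plus:
            s = min(network.U, s + magnitude(total))
        elif total < node.threshold_minus:
            s = max(0, s - magnitude(total))
        new[node.name] = s
    return new


def naive_orbit(network: Network, initial: dict, magnitude=None, cap: int = 5000):
    """Walk the deterministic orbit exhaustively; return (verdict, entry, period).

    The state space is finite, so the orbit must reach a fixed point or a
    previously visited configuration within (U+1)^n steps.
    """
    seen = {}
    states = dict(initial)
    t = 0
    while t <= cap:
        key = tuple(states[n] for n in network.node_names)
        if key in seen:
            first = seen[key]
            if t - first == 0:
                raise AssertionError("zero period impossible")
            return ("cycle", first, t - first)
        seen[key] = t
        nxt = naive_successor(network, states, magnitude)
        if nxt == states:
            return ("steady_state", t, None)
        states = nxt
        t += 1
    return ("cap_reached", t, None)


@pytest.fixture
def naive():
    return naive_successor, naive_orbit
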