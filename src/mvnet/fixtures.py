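"""Small synthetic networks with known behavior, for testing and demos.

These generators are the only stochastic code in the package and every
random one takes an explicit seed.
"""

from __future__ import annotations

import random

from .engine import Configuration, Dependency, Edge, Network, Node, NodeKind, Polarity

__all__ = [
    "make_checkpoint_motif",
    "make_negative_feedback_ring",
    "make_random_network",
]


def make_checkpoint_motif(U: int = 9) -> tuple[Network, Configuration]:
    """The conditional-activation motif used to model biological checkpoints.

    ``A`` activates the checkpoint only while the monitored process ``C`` is
    running (controller active); the checkpoint in turn activates ``B`` only
    once ``C`` has finished (controller inactive).  So ``B`` can rise only
    after a completed ``C`` episode, never during one and never without one.
    """
    nodes = (
        Node("A", NodeKind.PROTEIN),
        Node("B", NodeKind.PROTEIN),
        Node("C", NodeKind.EVENT),
        Node("checkpoint", NodeKind.CHECKPOINT),
    )
    edges = (
        Edge("A", "checkpoint", 1,
             dependencies=(Dependency("C", Polarity.REQUIRES_ACTIVE),)),
        Edge("checkpoint", "B", 1,
             dependencies=(Dependency("C", Polarity.REQUIRES_INACTIVE),)),
    )
    net = Network(U=U, nodes=nodes, edges=edges,
                  metadata={"name": "checkpoint-motif"})
    return net, net.initial_configuration()


def make_negative_feedback_ring(n: int, U: int = 9) -> Network:
    """A driven ring of ``n`` nodes whose loop sign is negative.

    A clamped source feeds the first ring node, the ring relays activation
    forward, and the last node represses the first (weight -2, so repression
    beats the constitutive drive); every relay node decays when its input is
    gone.  Negative feedback with regeneration is the canonical oscillation
    test-bed, and the tiny state space keeps exhaustive verification cheap.
    """
    if n < 2:
        raise ValueError(f"ring needs n >= 2, got {n}")
    nodes = [Node("src", NodeKind.SIGNAL, initial_state=U, clamp=U)]
    nodes += [Node(f"R{i}", NodeKind.PROTEIN) for i in range(n)]
    edges = [Edge("src", "R0", 1)]
    for i in range(n - 1):
        edges.append(Edge(f"R{i}", f"R{i + 1}", 1))
    edges.append(Edge(f"R{n - 1}", "R0", -2))
    for i in range(n):
        edges.append(Edge(f"R{i}", f"R{i}", -1))
    return Network(U=U, nodes=tuple(nodes), edges=tuple(edges),
                   metadata={"name": f"negative-ring-{n}"})


def make_random_network(
    n: int,
    density: float = 0.5,
    seed: int = 0,
    U: int = 3,
    with_dependencies: bool = True,
    with_clamps: bool = False,
) -> Network:
    """Random signed weighted digraph for property tests (reproducible by seed)."""
    rng = random.Random(seed)
    names = [f"n{i}" for i in range(n)]
    nodes = []
    for name in names:
        clamp = None
        initial = rng.randint(0, U)
        if with_clamps and rng.random() < 0.15:
            clamp = initial
        nodes.append(Node(name, NodeKind.PROTEIN, initial_state=initial, clamp=clamp))
    edges = []
    for src in names:
        for dst in names:
            if rng.random() >= density:
                continue
            weight = rng.choice([-2, -1, 1, 2])
            deps = ()
            if with_dependencies and rng.random() < 0.3:
                deps = (
                    Dependency(
                        rng.choice(names),
                        rng.choice(
                            [Polarity.REQUIRES_ACTIVE, Polarity.REQUIRES_INACTIVE]
                        ),
                    ),
                )
            gate = rng.choice([0, 0, 0, 1]) if U > 1 else 0
            edges.append(Edge(src, dst, weight, source_gate=gate, dependencies=deps))
    return Network(U=U, nodes=tuple(nodes), edges=tuple(edges),
                   metadata={"name": f"random-{n}-{seed}"})
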