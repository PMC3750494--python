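"""Deterministic synchronous simulator for multi-valued logical networks.

Each node carries an integer activity level in ``{0, ..., U}``.  Regulation
is encoded by signed, weighted edges; an edge may additionally be gated by
*dependency* conditions (a controller node must be active or inactive for the
edge to count) and by a *source gate* (the source contributes only when its
own state strictly exceeds the gate).  All nodes update simultaneously: the
incoming influence on node *i* at time *t* is

    sum_i(t) = sum_j  w(j, i) * s_j(t) * cond(j, i)

and the state moves up by ``f(sum_i)`` (clipped at ``U``) when the sum exceeds
the node's upper threshold, down by ``f(sum_i)`` (clipped at 0) when it falls
below the lower threshold, and stays put otherwise.  The default update
magnitude is logarithmic, ``f(s) = [ln(|s| + 1)]`` rounded half-up, so strong
regulation moves a node faster without the overshoot a linear rule would
cause; ``f(s) = 1`` (the predecessor unit-step rule) is available for
regression comparisons.

Dynamics are fully deterministic, so a revisited configuration proves a limit
cycle and two consecutive identical configurations prove a fixed point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Polarity",
    "NodeKind",
    "Dependency",
    "Edge",
    "Node",
    "Network",
    "Configuration",
    "Verdict",
    "Trajectory",
    "NetworkValidationError",
    "UnknownNodeError",
    "compute_sum",
    "update_magnitude",
    "unit_magnitude",
    "step",
    "simulate",
]


class NetworkValidationError(ValueError):
    """A network document violates a structural invariant."""


class UnknownNodeError(KeyError):
    """A node name does not resolve to a declared node."""


class Polarity(str, enum.Enum):
    """How a dependency controller gates its edge."""

    REQUIRES_ACTIVE = "requires_active"    # controller state >= 1
    REQUIRES_INACTIVE = "requires_inactive"  # controller state == 0


class NodeKind(str, enum.Enum):
    RNA = "rna"
    PROTEIN = "protein"
    COMPLEX = "complex"
    EVENT = "event"
    CHECKPOINT = "checkpoint"
    SIGNAL = "signal"


@dataclass(frozen=True)
class Dependency:
    """A condition attached to an edge: ``controller`` must be active/inactive."""

    controller: str
    polarity: Polarity = Polarity.REQUIRES_ACTIVE

    def holds(self, states: Mapping[str, int]) -> bool:
        s = states[self.controller]
        if self.polarity is Polarity.REQUIRES_ACTIVE:
            return s >= 1
        return s == 0


@dataclass(frozen=True)
class Edge:
    """Signed, weighted regulation from ``source`` to ``target``.

    ``source_gate`` suppresses the contribution unless the source state
    strictly exceeds the gate (default 0, i.e. any positive state counts).
    All ``dependencies`` must hold for the edge to contribute (conjunctive).
    """

    source: str
    target: str
    weight: int
    source_gate: int = 0
    dependencies: tuple[Dependency, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.weight == 0:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: weight must be nonzero"
            )
        if self.source_gate < 0:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: source_gate must be >= 0"
            )
        object.__setattr__(self, "dependencies", tuple(self.dependencies))

    def contributes(self, states: Mapping[str, int]) -> bool:
        if states[self.source] <= self.source_gate:
            return False
        return all(dep.holds(states) for dep in self.dependencies)


@dataclass(frozen=True)
class Node:
    """One network component with its thresholds and initial state.

    A node with ``clamp`` set is constitutive: it is held at the clamped state
    and bypasses the transition function entirely.
    """

    name: str
    kind: NodeKind = NodeKind.PROTEIN
    initial_state: int = 0
    threshold_plus: int = 0
    threshold_minus: int = 0
    clamp: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkValidationError("node name must be nonempty")
        if self.threshold_minus > self.threshold_plus:
            raise NetworkValidationError(
                f"node {self.name}: threshold_minus > threshold_plus"
            )


@dataclass(frozen=True)
class Network:
    """Immutable model structure: nodes, edges and the state ceiling ``U``."""

    U: int
    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", tuple(self.edges))
        if self.U < 1:
            raise NetworkValidationError(f"U must be >= 1, got {self.U}")
        names = [n.name for n in self.nodes]
        name_set = set(names)
        if len(names) != len(name_set):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise NetworkValidationError(f"duplicate node names: {dup}")
        for n in self.nodes:
            if not 0 <= n.initial_state <= self.U:
                raise NetworkValidationError(
                    f"node {n.name}: initial_state {n.initial_state} outside [0, {self.U}]"
                )
            if n.clamp is not None:
                if not 0 <= n.clamp <= self.U:
                    raise NetworkValidationError(
                        f"node {n.name}: clamp {n.clamp} outside [0, {self.U}]"
                    )
                if n.initial_state != n.clamp:
                    raise NetworkValidationError(
                        f"node {n.name}: initial_state {n.initial_state} != clamp {n.clamp}"
                    )
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.source not in name_set:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: unknown source {e.source!r}"
                )
            if e.target not in name_set:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: unknown target {e.target!r}"
                )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise NetworkValidationError(
                    f"duplicate edge {e.source}->{e.target}"
                )
            seen_pairs.add(pair)
            for dep in e.dependencies:
                if dep.controller not in name_set:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target}: unknown dependency "
                        f"controller {dep.controller!r}"
                    )
        incoming: dict[str, list[Edge]] = {name: [] for name in names}
        for e in self.edges:
            incoming[e.target].append(e)
        object.__setattr__(self, "_incoming", {k: tuple(v) for k, v in incoming.items()})
        object.__setattr__(self, "_node_by_name", {n.name: n for n in self.nodes})

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def node(self, name: str) -> Node:
        try:
            return self._node_by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownNodeError(name) from None

    def incoming(self, target: str) -> tuple[Edge, ...]:
        try:
            return self._incoming[target]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownNodeError(target) from None

    def initial_configuration(self) -> "Configuration":
        return Configuration(
            states={n.name: n.initial_state for n in self.nodes}, step=0
        )

    # -- convenience constructors for derived networks ---------------------

    def with_edges(self, edges: Iterable[Edge]) -> "Network":
        return Network(U=self.U, nodes=self.nodes, edges=tuple(edges),
                       metadata=self.metadata)

    def with_node_replaced(self, node: Node) -> "Network":
        nodes = tuple(node if n.name == node.name else n for n in self.nodes)
        return Network(U=self.U, nodes=nodes, edges=self.edges,
                       metadata=self.metadata)


@dataclass(frozen=True)
class Configuration:
    """The vector of all node states at one discrete time step."""

    states: Mapping[str, int]
    step: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", dict(self.states))

    def __getitem__(self, name: str) -> int:
        return self.states[name]

    def key(self) -> tuple[int, ...]:
        """Hashable state vector (insertion order of the mapping)."""
        return tuple(self.states.values())


class Verdict(str, enum.Enum):
    STEADY_STATE = "steady_state"
    CYCLE = "cycle"
    CAP_REACHED = "cap_reached"


@dataclass(frozen=True)
class Trajectory:
    """Ordered configurations starting at step 0, plus the termination verdict.

    For ``steady_state`` the verdict step is the first step whose successor is
    identical (the entry into the fixed point); the trajectory also records
    that identical successor.  For ``cycle`` the verdict step is the first
    visit of the revisited configuration and ``cycle_period`` the gap to its
    revisit, which closes the recorded trajectory.
    """

    network: Network
    configurations: tuple[Configuration, ...]
    verdict: Verdict
    verdict_step: int
    cycle_period: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "configurations", tuple(self.configurations))

    @property
    def last(self) -> Configuration:
        return self.configurations[-1]

    def states_of(self, name: str) -> list[int]:
        if name not in self.configurations[0].states:
            raise UnknownNodeError(name)
        return [c.states[name] for c in self.configurations]

    def period_slice(self) -> list[Configuration]:
        """One full period of a cyclic trajectory, starting at verdict_step."""
        if self.verdict is not Verdict.CYCLE:
            raise ValueError("period_slice requires a cycle verdict")
        assert self.cycle_period is not None
        return list(
            self.configurations[self.verdict_step: self.verdict_step + self.cycle_period]
        )


# ---------------------------------------------------------------------------
# Transition function


def compute_sum(network: Network, config: Configuration, target: str) -> int:
    """Total incoming influence on ``target`` under ``config``.

    Each incoming edge contributes ``weight * source_state`` if the source
    state strictly exceeds the edge's source gate and every dependency on the
    edge holds; otherwise it contributes 0.
    """
    states = config.states
    total = 0
    for e in network.incoming(target):
        if e.contributes(states):
            total += e.weight * states[e.source]
    return total


def update_magnitude(s: int) -> int:
    """Logarithmic step size ``[ln(|s| + 1)]``, rounded half-up.

    Half-up rounding keeps unit-strength regulation effective (``f(1) = 1``);
    flooring would make it inert.  Zero iff the sum is zero.
    """
    return math.floor(math.log(abs(s) + 1) + 0.5)


def unit_magnitude(s: int) -> int:
    """Constant unit step (the predecessor model's rule): 1 for any nonzero sum."""
    return 0 if s == 0 else 1


def step(
    network: Network,
    config: Configuration,
    magnitude: Callable[[int], int] = update_magnitude,
) -> Configuration:
    """One synchronous update: every sum is evaluated against ``config``."""
    U = network.U
    states = config.states
    new_states: dict[str, int] = {}
    for node in network.nodes:
        if node.clamp is not None:
            new_states[node.name] = node.clamp
            continue
        s = states[node.name]
        total = compute_sum(network, config, node.name)
        if total > node.threshold_plus:
            s = min(U, s + magnitude(total))
        elif total < node.threshold_minus:
            s = max(0, s - magnitude(total))
        new_states[node.name] = s
    return Configuration(states=new_states, step=config.step + 1)


def simulate(
    network: Network,
    initial: Configuration | None = None,
    max_steps: int = 1000,
    magnitude: Callable[[int], int] = update_magnitude,
) -> Trajectory:
    """Iterate the synchronous update until a fixed point or a revisit.

    Determinism makes the first revisit of any configuration a proof of a
    limit cycle; a full history hash map keeps detection O(1) per step.
    """
    if max_steps < 1:
        raise ValueError(f"max_steps must be >= 1, got {max_steps}")
    if initial is None:
        initial = network.initial_configuration()
    missing = set(network.node_names) - set(initial.states)
    if missing:
        raise NetworkValidationError(f"initial configuration misses nodes: {sorted(missing)}")
    extra = set(initial.states) - set(network.node_names)
    if extra:
        raise NetworkValidationError(f"initial configuration has unknown nodes: {sorted(extra)}")
    for name, value in initial.states.items():
        if not 0 <= value <= network.U:
            raise NetworkValidationError(
                f"initial state {name}={value} outside [0, {network.U}]"
            )
    # normalize ordering so Configuration.key() is comparable across inputs
    order = network.node_names
    current = Configuration(
        states={n: initial.states[n] for n in order}, step=initial.step
    )
    history: list[Configuration] = [current]
    seen: dict[tuple[int, ...], int] = {current.key(): 0}
    for _ in range(max_steps):
        nxt = step(network, current, magnitude)
        history.append(nxt)
        if nxt.states == current.states:
            return Trajectory(
                network=network,
                configurations=history,
                verdict=Verdict.STEADY_STATE,
                verdict_step=current.step,
            )
        key = nxt.key()
        if key in seen:
            first = seen[key]
            return Trajectory(
                network=network,
                configurations=history,
                verdict=Verdict.CYCLE,
                verdict_step=first,
                cycle_period=nxt.step - first,
            )
        seen[key] = nxt.step
        current = nxt
    return Trajectory(
        network=network,
        configurations=history,
        verdict=Verdict.CAP_REACHED,
        verdict_step=history[-1].step,
    )
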