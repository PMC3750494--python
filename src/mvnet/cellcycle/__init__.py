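"""The bundled budding-yeast cell-cycle network and its perturbation variants.

`build_wildtype` returns the curated 67-node network together with its
early-G1 initial configuration.  `apply_variant` derives the perturbed
networks used throughout the analyses: gene knockouts (outgoing edges of the
transcript node removed), signal re-clamping (pheromone, nitrogen), the three
nitrogen-depletion target hypotheses, the stable-Cln1 mutant, and the three
alternative wirings of Hcm1 activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from ..engine import (
    Configuration,
    Dependency,
    Edge,
    Network,
    Node,
    Polarity,
    UnknownNodeError,
)
from .. import netio

__all__ = [
    "VariantSpec",
    "STRUCTURAL_VARIANTS",
    "build_wildtype",
    "apply_variant",
    "build_variant",
    "load_variant_spec",
    "list_bundled_variants",
]

#: structural rewirings with a dedicated builder
STRUCTURAL_VARIANTS = (
    "nitrogen_hyp1",
    "nitrogen_hyp2",
    "nitrogen_hyp3",
    "stable_cln1",
    "hcm1_by_cln3cdk",
    "hcm1_by_cln1cdk",
    "hcm1_by_clb5cdk",
)

_HCM1_KINASE = {
    "hcm1_by_cln3cdk": "Cln3/Cdk",
    "hcm1_by_cln1cdk": "Cln1/Cdk",
    "hcm1_by_clb5cdk": "Clb5/Cdk",
}

# nitrogen-depletion hypotheses: repression edges added from the N node
_NITROGEN_TARGETS = {
    "nitrogen_hyp1": ("Cln3", "Cln3/Cdk"),
    "nitrogen_hyp2": ("Cln3", "Cln3/Cdk", "SIC1"),
    "nitrogen_hyp3": ("Cln3", "Cln3/Cdk", "Cln1", "Cln1/Cdk"),
}


@dataclass(frozen=True)
class VariantSpec:
    """A declarative description of one simulated perturbation experiment."""

    base: str = "wildtype"
    knockouts: tuple[str, ...] = ()
    signal_settings: Mapping[str, int] = field(default_factory=dict)
    initial_overrides: Mapping[str, int] = field(default_factory=dict)
    structural_variants: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "knockouts", tuple(self.knockouts))
        object.__setattr__(self, "signal_settings", dict(self.signal_settings))
        object.__setattr__(self, "initial_overrides", dict(self.initial_overrides))
        object.__setattr__(self, "structural_variants", tuple(self.structural_variants))
        if self.base != "wildtype":
            raise ValueError(f"unknown base network {self.base!r}")
        for sv in self.structural_variants:
            if sv not in STRUCTURAL_VARIANTS:
                raise ValueError(
                    f"unknown structural variant {sv!r}; "
                    f"expected one of {STRUCTURAL_VARIANTS}"
                )


def _data_text(relative: str) -> str:
    return (
        resources.files(__package__).joinpath("data").joinpath(relative)
        .read_text(encoding="utf-8")
    )


def build_wildtype() -> tuple[Network, Configuration]:
    """The curated 67-node wild-type network and its early-G1 initial state."""
    net = netio.loads_network(_data_text("cellcycle_wt.yaml"))
    return net, net.initial_configuration()


def _knockout(network: Network, gene: str) -> Network:
    """Remove the transcript node's outgoing edges to other nodes.

    The self (stability) edge stays, and the protein node keeps functioning,
    so pre-existing protein persists after the deletion — this is what makes
    a cdc6 deletion with a full Cdc6 store arrest only in the *next* cycle.
    """
    if gene not in network.node_names:
        raise UnknownNodeError(gene)
    kept = tuple(
        e for e in network.edges
        if not (e.source == gene and e.target != gene)
    )
    if len(kept) == len(network.edges):
        raise ValueError(f"knockout {gene!r} removes no edges; is it a transcript node?")
    return network.with_edges(kept)


def _reclamp(network: Network, initial: Configuration,
             node_name: str, level: int) -> tuple[Network, Configuration]:
    node = network.node(node_name)
    network = network.with_node_replaced(
        Node(name=node.name, kind=node.kind, initial_state=level,
             threshold_plus=node.threshold_plus,
             threshold_minus=node.threshold_minus, clamp=level, note=node.note)
    )
    states = dict(initial.states)
    states[node_name] = level
    return network, Configuration(states=states, step=initial.step)


def _add_nitrogen_edges(network: Network, hypothesis: str) -> Network:
    edges = list(network.edges)
    for target in _NITROGEN_TARGETS[hypothesis]:
        edges.append(Edge(
            source="N", target=target, weight=-1,
            note=f"nitrogen-depletion target ({hypothesis})",
        ))
    return network.with_edges(edges)


def _stable_cln1(network: Network) -> Network:
    """Delete every negative (degradation) edge into the Cln1 protein node."""
    kept = tuple(
        e for e in network.edges
        if not (e.target == "Cln1" and e.weight < 0)
    )
    return network.with_edges(kept)


def _rewire_hcm1(network: Network, kinase: str) -> Network:
    edges = []
    for e in network.edges:
        if e.source == "Hcm1" and e.target == "Hcm1*":
            e = Edge(
                source=e.source, target=e.target, weight=e.weight,
                source_gate=e.source_gate,
                dependencies=(Dependency(kinase, Polarity.REQUIRES_ACTIVE),),
                note=f"activating phosphorylation of Hcm1 by {kinase}",
            )
        edges.append(e)
    return network.with_edges(tuple(edges))


def apply_variant(network: Network, initial: Configuration,
                  spec: VariantSpec) -> tuple[Network, Configuration]:
    """Derive the perturbed network and initial configuration for ``spec``.

    Order of application: structural rewirings, knockouts, signal clamps,
    then explicit initial-state overrides (which win over everything).
    """
    for sv in spec.structural_variants:
        if sv in _NITROGEN_TARGETS:
            network = _add_nitrogen_edges(network, sv)
        elif sv == "stable_cln1":
            network = _stable_cln1(network)
        else:
            network = _rewire_hcm1(network, _HCM1_KINASE[sv])
    for gene in spec.knockouts:
        network = _knockout(network, gene)
    for signal, level in spec.signal_settings.items():
        if not 0 <= level <= network.U:
            raise ValueError(f"signal {signal}={level} outside [0, {network.U}]")
        network, initial = _reclamp(network, initial, signal, level)
    if spec.initial_overrides:
        states = dict(initial.states)
        for name, level in spec.initial_overrides.items():
            if name not in states:
                raise UnknownNodeError(name)
            if not 0 <= level <= network.U:
                raise ValueError(f"override {name}={level} outside [0, {network.U}]")
            states[name] = level
        initial = Configuration(states=states, step=initial.step)
    return network, initial


def build_variant(spec: VariantSpec) -> tuple[Network, Configuration]:
    net, cfg = build_wildtype()
    return apply_variant(net, cfg, spec)


def load_variant_spec(source: str) -> VariantSpec:
    """Load a variant spec from a bundled name (e.g. ``cdc20_delete``) or a path."""
    import os
    import yaml

    if os.path.exists(source):
        text = open(source, encoding="utf-8").read()
        name = os.path.splitext(os.path.basename(source))[0]
    else:
        try:
            text = _data_text(f"variants/{source}.yaml")
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no such variant {source!r}; bundled: {list_bundled_variants()}"
            ) from None
        name = source
    doc = yaml.safe_load(text) or {}
    return VariantSpec(
        base=doc.get("base", "wildtype"),
        knockouts=tuple(doc.get("knockouts", []) or []),
        signal_settings=doc.get("signal_settings", {}) or {},
        initial_overrides=doc.get("initial_overrides", {}) or {},
        structural_variants=tuple(doc.get("structural_variants", []) or []),
        name=doc.get("name", name),
    )


def list_bundled_variants() -> list[str]:
    files = resources.files(__package__).joinpath("data").joinpath("variants")
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".yaml"))
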