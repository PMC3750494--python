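"""Reading, validating and writing network documents and simulation output.

The canonical network document is YAML (a JSON file with the same tree is
accepted everywhere a YAML one is); all quantities are integers.  A document
looks like::

    format_version: "1"
    U: 9
    metadata: {name: toy}
    nodes:
      - {name: A, kind: protein, initial: 0}
      - {name: X, kind: event, threshold_plus: 0}
    edges:
      - source: A
        target: X
        weight: 1
        gate: 0
        depends:
          - {node: C, when: active}   # or: inactive
        note: free-text provenance

Time courses are written as TSV with a ``step`` column first and one column
per node.  Node names may contain ``/``, ``*`` and ``-``; headers are
sanitized and the exact originals preserved in a JSON sidecar next to the
table.  The termination verdict is appended as ``#``-prefixed footer lines.
"""

from __future__ import annotations

import json
import io
import os
from pathlib import Path
from typing import Any, Mapping

import yaml

from .engine import (
    Configuration,
    Dependency,
    Edge,
    Network,
    NetworkValidationError,
    Node,
    NodeKind,
    Polarity,
    Trajectory,
    Verdict,
)

__all__ = [
    "ParseError",
    "load_network",
    "loads_network",
    "serialize_network",
    "save_network",
    "write_trajectory",
    "read_trajectory",
    "save_snapshot",
    "load_snapshot",
    "sanitize_name",
    "export_dot",
    "export_sbml_qual",
]

FORMAT_VERSION = "1"

_POLARITY_WORDS = {
    "active": Polarity.REQUIRES_ACTIVE,
    "inactive": Polarity.REQUIRES_INACTIVE,
    "requires_active": Polarity.REQUIRES_ACTIVE,
    "requires_inactive": Polarity.REQUIRES_INACTIVE,
}


class ParseError(ValueError):
    """Malformed document (syntax or missing/ill-typed fields)."""


def _require_int(record: Mapping[str, Any], key: str, where: str,
                 default: int | None = None) -> int:
    if key not in record:
        if default is None:
            raise ParseError(f"{where}: missing required field {key!r}")
        return default
    v = record[key]
    if isinstance(v, bool) or not isinstance(v, int):
        raise ParseError(f"{where}: field {key!r} must be an integer, got {v!r}")
    return v


def _parse_node(record: Any, idx: int) -> Node:
    where = f"node #{idx}"
    if not isinstance(record, Mapping):
        raise ParseError(f"{where}: expected a mapping, got {type(record).__name__}")
    name = record.get("name")
    if not isinstance(name, str) or not name:
        raise ParseError(f"{where}: missing or non-string 'name'")
    where = f"node {name!r}"
    kind_raw = record.get("kind", "protein")
    try:
        kind = NodeKind(kind_raw)
    except ValueError:
        raise ParseError(
            f"{where}: unknown kind {kind_raw!r} "
            f"(expected one of {[k.value for k in NodeKind]})"
        ) from None
    clamp = record.get("clamp")
    if clamp is not None and (isinstance(clamp, bool) or not isinstance(clamp, int)):
        raise ParseError(f"{where}: 'clamp' must be an integer")
    initial_default = clamp if clamp is not None else 0
    return Node(
        name=name,
        kind=kind,
        initial_state=_require_int(record, "initial", where, initial_default),
        threshold_plus=_require_int(record, "threshold_plus", where, 0),
        threshold_minus=_require_int(record, "threshold_minus", where, 0),
        clamp=clamp,
        note=str(record.get("note", "")),
    )


def _parse_edge(record: Any, idx: int) -> Edge:
    where = f"edge #{idx}"
    if not isinstance(record, Mapping):
        raise ParseError(f"{where}: expected a mapping, got {type(record).__name__}")
    source = record.get("source")
    target = record.get("target")
    if not isinstance(source, str) or not isinstance(target, str):
        raise ParseError(f"{where}: 'source' and 'target' must be strings")
    where = f"edge {source}->{target}"
    deps = []
    for d in record.get("depends", []) or []:
        if not isinstance(d, Mapping) or "node" not in d:
            raise ParseError(f"{where}: dependency records need a 'node' field")
        when = d.get("when", "active")
        if when not in _POLARITY_WORDS:
            raise ParseError(
                f"{where}: dependency 'when' must be active/inactive, got {when!r}"
            )
        deps.append(Dependency(controller=str(d["node"]), polarity=_POLARITY_WORDS[when]))
    return Edge(
        source=source,
        target=target,
        weight=_require_int(record, "weight", where),
        source_gate=_require_int(record, "gate", where, 0),
        dependencies=tuple(deps),
        note=str(record.get("note", "")),
    )


def loads_network(text: str) -> Network:
    """Parse a network document from YAML/JSON text."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"document is not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ParseError("document root must be a mapping")
    U = _require_int(doc, "U", "document")
    nodes = doc.get("nodes")
    if not isinstance(nodes, list) or not nodes:
        raise ParseError("document needs a nonempty 'nodes' list")
    edges = doc.get("edges", []) or []
    if not isinstance(edges, list):
        raise ParseError("'edges' must be a list")
    metadata = doc.get("metadata", {}) or {}
    if not isinstance(metadata, Mapping):
        raise ParseError("'metadata' must be a mapping")
    try:
        return Network(
            U=U,
            nodes=tuple(_parse_node(n, i) for i, n in enumerate(nodes)),
            edges=tuple(_parse_edge(e, i) for i, e in enumerate(edges)),
            metadata=dict(metadata),
        )
    except NetworkValidationError:
        raise


def load_network(path: str | os.PathLike[str]) -> Network:
    """Load and validate a network document from a file."""
    return loads_network(Path(path).read_text(encoding="utf-8"))


def serialize_network(network: Network) -> str:
    """Render a network back to its canonical YAML document."""
    doc: dict[str, Any] = {"format_version": FORMAT_VERSION, "U": network.U}
    if network.metadata:
        doc["metadata"] = dict(network.metadata)
    nodes = []
    for n in network.nodes:
        rec: dict[str, Any] = {"name": n.name, "kind": n.kind.value}
        if n.clamp is not None:
            rec["clamp"] = n.clamp
        if n.initial_state != (n.clamp if n.clamp is not None else 0):
            rec["initial"] = n.initial_state
        elif n.clamp is None and n.initial_state:
            rec["initial"] = n.initial_state
        if n.threshold_plus:
            rec["threshold_plus"] = n.threshold_plus
        if n.threshold_minus:
            rec["threshold_minus"] = n.threshold_minus
        if n.note:
            rec["note"] = n.note
        nodes.append(rec)
    doc["nodes"] = nodes
    edges = []
    for e in network.edges:
        rec = {"source": e.source, "target": e.target, "weight": e.weight}
        if e.source_gate:
            rec["gate"] = e.source_gate
        if e.dependencies:
            rec["depends"] = [
                {"node": d.controller,
                 "when": "active" if d.polarity is Polarity.REQUIRES_ACTIVE else "inactive"}
                for d in e.dependencies
            ]
        if e.note:
            rec["note"] = e.note
        edges.append(rec)
    doc["edges"] = edges
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=100)


def save_network(network: Network, path: str | os.PathLike[str]) -> None:
    Path(path).write_text(serialize_network(network), encoding="utf-8")


# ---------------------------------------------------------------------------
# Time courses

_SANITIZE = (("*", "_star"), ("/", "_"), ("-", "_"), (" ", "_"))


def sanitize_name(name: str) -> str:
    """TSV-header-safe version of a node name (exact original in sidecar)."""
    for old, new in _SANITIZE:
        name = name.replace(old, new)
    return name


def write_trajectory(trajectory: Trajectory, destination: str | os.PathLike[str],
                     sidecar: bool = True) -> Path:
    """Write a trajectory as a TSV time course.

    One row per configuration (``step`` first), a ``#`` footer carrying the
    verdict, and a ``<dest>.columns.json`` sidecar mapping sanitized headers
    back to original node names.
    """
    if not trajectory.configurations:
        raise ValueError("trajectory is empty")
    dest = Path(destination)
    names = list(trajectory.configurations[0].states)
    headers = [sanitize_name(n) for n in names]
    if len(set(headers)) != len(headers):
        raise ValueError("sanitized column names collide; rename nodes")
    buf = io.StringIO()
    buf.write("step\t" + "\t".join(headers) + "\n")
    for cfg in trajectory.configurations:
        buf.write(str(cfg.step) + "\t"
                  + "\t".join(str(cfg.states[n]) for n in names) + "\n")
    buf.write(f"# verdict={trajectory.verdict.value}\n")
    buf.write(f"# verdict_step={trajectory.verdict_step}\n")
    if trajectory.cycle_period is not None:
        buf.write(f"# cycle_period={trajectory.cycle_period}\n")
    dest.write_text(buf.getvalue(), encoding="utf-8")
    if sidecar:
        mapping = dict(zip(headers, names))
        dest.with_name(dest.name + ".columns.json").write_text(
            json.dumps(mapping, indent=1, ensure_ascii=False), encoding="utf-8"
        )
    return dest


def read_trajectory(path: str | os.PathLike[str]) -> tuple[list[dict[str, int]], dict[str, str]]:
    """Read back a written time course.

    Returns ``(rows, meta)`` where each row maps original node names (via the
    sidecar when present) plus ``step`` to integers, and ``meta`` holds the
    footer fields as strings.
    """
    p = Path(path)
    sidecar = p.with_name(p.name + ".columns.json")
    mapping: dict[str, str] = {}
    if sidecar.exists():
        mapping = json.loads(sidecar.read_text(encoding="utf-8"))
    rows: list[dict[str, int]] = []
    meta: dict[str, str] = {}
    header: list[str] | None = None
    for line in p.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = [mapping.get(c, c) for c in cells]
            continue
        rows.append({h: int(c) for h, c in zip(header, cells)})
    return rows, meta


# ---------------------------------------------------------------------------
# Snapshots


def save_snapshot(trajectory: Trajectory, step: int,
                  destination: str | os.PathLike[str] | None = None) -> str:
    """Serialize the configuration recorded at ``step`` for later restart."""
    first = trajectory.configurations[0].step
    last = trajectory.configurations[-1].step
    if not first <= step <= last:
        raise ValueError(f"step {step} outside recorded range [{first}, {last}]")
    cfg = trajectory.configurations[step - first]
    doc = {"format_version": FORMAT_VERSION, "step": cfg.step,
           "states": dict(cfg.states)}
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8")
    return text


def load_snapshot(source: str | os.PathLike[str]) -> Configuration:
    """Inverse of :func:`save_snapshot`; accepts a path or document text."""
    text = source
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"snapshot is not valid YAML: {exc}") from exc
    if not isinstance(doc, Mapping) or "states" not in doc:
        raise ParseError("snapshot document needs a 'states' mapping")
    states = doc["states"]
    if not isinstance(states, Mapping):
        raise ParseError("'states' must map node names to integers")
    for k, v in states.items():
        if isinstance(v, bool) or not isinstance(v, int):
            raise ParseError(f"snapshot state {k!r} must be an integer")
    return Configuration(states=dict(states),
                         step=_require_int(doc, "step", "snapshot", 0))


# ---------------------------------------------------------------------------
# Lossy visualization / exchange exports


def export_dot(network: Network) -> str:
    """Graphviz DOT rendering (weights as labels, dependencies as dashed edges)."""
    lines = ["digraph network {", "  rankdir=LR;"]
    qid = {n.name: f'"{n.name}"' for n in network.nodes}
    for n in network.nodes:
        shape = {"event": "box", "checkpoint": "box", "signal": "diamond"}.get(
            n.kind.value, "ellipse")
        style = ' style="dashed"' if n.clamp is not None else ""
        lines.append(f"  {qid[n.name]} [shape={shape}{style}];")
    for i, e in enumerate(network.edges):
        color = "black" if e.weight > 0 else "red"
        arrow = "normal" if e.weight > 0 else "tee"
        label = str(e.weight) + (f" (>{e.source_gate})" if e.source_gate else "")
        eid = f"e{i}"
        lines.append(
            f'  {qid[e.source]} -> {qid[e.target]} '
            f'[label="{label}", color={color}, arrowhead={arrow}];'
        )
        for d in e.dependencies:
            style = "dashed" if d.polarity is Polarity.REQUIRES_ACTIVE else "dotted"
            lines.append(
                f'  {qid[d.controller]} -> {qid[e.target]} '
                f'[style={style}, color=gray, label="dep:{eid}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_sbml_qual(network: Network) -> str:
    """SBML-qual-flavored XML export (lossy: weights/gates become annotations)."""
    import xml.etree.ElementTree as ET

    sbml = ET.Element("sbml", {
        "xmlns": "http://www.sbml.org/sbml/level3/version1/core",
        "xmlns:qual": "http://www.sbml.org/sbml/level3/version1/qual/version1",
        "level": "3", "version": "1",
    })
    model = ET.SubElement(sbml, "model", {"id": "network"})
    species = ET.SubElement(model, "qual:listOfQualitativeSpecies")
    for n in network.nodes:
        ET.SubElement(species, "qual:qualitativeSpecies", {
            "qual:id": sanitize_name(n.name),
            "qual:name": n.name,
            "qual:maxLevel": str(network.U),
            "qual:initialLevel": str(n.initial_state),
            "qual:constant": "true" if n.clamp is not None else "false",
        })
    transitions = ET.SubElement(model, "qual:listOfTransitions")
    for i, e in enumerate(network.edges):
        tr = ET.SubElement(transitions, "qual:transition", {"qual:id": f"tr_{i}"})
        inputs = ET.SubElement(tr, "qual:listOfInputs")
        ET.SubElement(inputs, "qual:input", {
            "qual:qualitativeSpecies": sanitize_name(e.source),
            "qual:sign": "positive" if e.weight > 0 else "negative",
            "qual:thresholdLevel": str(e.source_gate + 1),
        })
        for d in e.dependencies:
            ET.SubElement(inputs, "qual:input", {
                "qual:qualitativeSpecies": sanitize_name(d.controller),
                "qual:sign": "positive"
                if d.polarity is Polarity.REQUIRES_ACTIVE else "negative",
                "qual:thresholdLevel": "1",
            })
        outputs = ET.SubElement(tr, "qual:listOfOutputs")
        ET.SubElement(outputs, "qual:output", {
            "qual:qualitativeSpecies": sanitize_name(e.target),
        })
        note = ET.SubElement(tr, "notes")
        body = ET.SubElement(note, "p")
        body.text = f"weight={e.weight} gate={e.source_gate} {e.note}".strip()
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True) + "\n"
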