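"""Model file I/O (YAML/JSON), the structure-table CSV, and graph exports.

The model document schema (version "1"):

.. code-block:: yaml

    schema_version: "1"
    services:
      - name: Sun
        role: raw          # raw | intermediate | product; default intermediate
    units:
      - name: Plant1
        inputs: [Sun]
        outputs: [Habitat]

YAML is the primary dialect (human-authored ecological knowledge); JSON is
accepted as the mechanical twin. Unknown top-level keys are rejected so
typos fail loudly. All writers emit UTF-8 with ``\\n`` newlines and
deterministic ordering, so reruns are byte-identical and diffs are clean.
"""

from __future__ import annotations

import json
import warnings
from fractions import Fraction
from pathlib import Path

import networkx as nx
import yaml

from .model import (
    EcosystemModel,
    INTERMEDIATE,
    ModelWarning,
    Structure,
    build_model,
)
from .metrics import format_ratio
from .ssg import EnumerationResult

__all__ = [
    "SCHEMA_VERSION",
    "read_model",
    "write_model",
    "model_to_document",
    "write_structures_csv",
    "structures_csv_text",
    "export_graph",
    "to_networkx",
]

SCHEMA_VERSION = "1"
_TOP_KEYS = {"schema_version", "services", "units"}


def _open_maybe(stream_or_path, mode: str):
    if isinstance(stream_or_path, (str, Path)):
        return open(stream_or_path, mode, encoding="utf-8", newline=""), True
    return stream_or_path, False


def _infer_format(stream_or_path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    if isinstance(stream_or_path, (str, Path)):
        suffix = Path(stream_or_path).suffix.lower()
        if suffix == ".json":
            return "json"
    return "yaml"


def read_model(stream_or_path, fmt: str | None = None) -> EcosystemModel:
    """Parse a model document and validate it through :func:`build_model`.

    ``fmt`` is ``"yaml"`` or ``"json"``; when omitted it is inferred from
    the file suffix (defaulting to YAML, of which JSON is a subset anyway).
    Schema problems raise :class:`ValueError`; semantic problems raise
    :class:`~ecopgraph.model.ModelError` with the full violation list.
    """
    fmt = _infer_format(stream_or_path, fmt)
    if fmt not in {"yaml", "json"}:
        raise ValueError(f"unsupported model format {fmt!r}")
    handle, close = _open_maybe(stream_or_path, "r")
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    if fmt == "json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return document_to_model(doc)


def document_to_model(doc) -> EcosystemModel:
    """Turn a parsed model document into a validated model."""
    if not isinstance(doc, dict):
        raise ValueError("model document must be a mapping at top level")
    unknown = sorted(set(doc) - _TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown top-level key(s) in model document: {unknown}")
    version = str(doc.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    services = []
    for i, entry in enumerate(doc.get("services", []) or []):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValueError(f"services[{i}]: each service needs at least a name")
        if "role" not in entry:
            warnings.warn(
                f"service {entry['name']!r}: no role declared, defaulting to "
                f"{INTERMEDIATE!r}",
                ModelWarning,
            )
        services.append(entry)
    units = []
    for i, entry in enumerate(doc.get("units", []) or []):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ValueError(f"units[{i}]: each unit needs at least a name")
        units.append(entry)
    return build_model(services, units)


def model_to_document(model: EcosystemModel) -> dict:
    """Canonical plain-data document for a model (round-trip stable)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "services": [
            {"name": s.name, "role": s.role} for s in model.services.values()
        ],
        "units": [
            {
                "name": u.name,
                "inputs": sorted(u.inputs),
                "outputs": sorted(u.outputs),
            }
            for u in model.units.values()
        ],
    }


def write_model(model: EcosystemModel, stream_or_path, fmt: str = "yaml") -> None:
    """Serialize a model as YAML or JSON (UTF-8, ``\\n`` newlines)."""
    doc = model_to_document(model)
    if fmt == "json":
        text = json.dumps(doc, indent=2) + "\n"
    elif fmt == "yaml":
        text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
    else:
        raise ValueError(f"unsupported model format {fmt!r}")
    handle, close = _open_maybe(stream_or_path, "w")
    try:
        handle.write(text)
    finally:
        if close:
            handle.close()


def structures_csv_text(result: EnumerationResult, model: EcosystemModel) -> str:
    """The structure table as RFC-4180 CSV text.

    Header ``structure,<unit names...>``, one 0/1 row per structure labelled
    S1..SN in canonical order, then an ``N_i`` footer row; an ``IC_i``
    footer follows whenever at least one structure exists. Columns are the
    units of the maximal structure in model-file order (all model units when
    the enumeration is empty). Node names are restricted to
    ``[A-Za-z0-9_.-]`` so no CSV quoting is ever needed.
    """
    in_any: set[str] = set()
    for s in result.structures:
        in_any |= s.units
    columns = [u for u in model.units if u in in_any] if in_any else list(model.units)

    lines = ["structure," + ",".join(columns)]
    for i, s in enumerate(result.structures):
        cells = ",".join("1" if u in s.units else "0" for u in columns)
        lines.append(f"S{i + 1},{cells}")
    n_i = [result.occurrences(u) for u in columns]
    lines.append("N_i," + ",".join(str(v) for v in n_i))
    if result.count > 0:
        lines.append(
            "IC_i,"
            + ",".join(format_ratio(Fraction(v, result.count)) for v in n_i)
        )
    return "\n".join(lines) + "\n"


def write_structures_csv(
    result: EnumerationResult, model: EcosystemModel, stream_or_path
) -> None:
    """Write :func:`structures_csv_text` to a file or stream."""
    text = structures_csv_text(result, model)
    handle, close = _open_maybe(stream_or_path, "w")
    try:
        handle.write(text)
    finally:
        if close:
            handle.close()


def _graph_nodes(model: EcosystemModel, structure: Structure | None):
    if structure is None:
        services = list(model.services)
        units = list(model.units)
    else:
        services = [s for s in model.services if s in structure.services]
        units = [u for u in model.units if u in structure.units]
    return services, units


def to_networkx(
    model: EcosystemModel, structure: Structure | None = None
) -> nx.DiGraph:
    """The (possibly restricted) bipartite digraph as a networkx DiGraph.

    Node attribute ``ptype`` is ``"M"`` for services and ``"O"`` for units;
    service nodes additionally carry ``role``. Arcs run service -> unit for
    inputs and unit -> service for outputs. Node and edge insertion order is
    sorted, hence deterministic.
    """
    services, units = _graph_nodes(model, structure)
    unit_set = set(units)
    g = nx.DiGraph()
    for s in sorted(services):
        g.add_node(s, ptype="M", role=model.services[s].role)
    for u in sorted(units):
        g.add_node(u, ptype="O")
    for u in sorted(units):
        node = model.units[u]
        for s in sorted(node.inputs):
            if structure is None or s in structure.services:
                g.add_edge(s, u)
        for s in sorted(node.outputs):
            if structure is None or s in structure.services:
                g.add_edge(u, s)
    assert all(u in g for u in unit_set)
    return g


def export_graph(
    model: EcosystemModel,
    stream_or_path,
    fmt: str = "dot",
    structure: Structure | None = None,
) -> None:
    """Export the model (or one structure of it) as DOT or GraphML.

    DOT follows the field's drawing convention for process graphs: service
    (M-type) nodes as ellipses, functional-unit (O-type) nodes as boxes.
    GraphML carries the same information as ``ptype``/``role`` attributes.
    """
    if fmt == "dot":
        text = _dot_text(model, structure)
    elif fmt == "graphml":
        g = to_networkx(model, structure)
        text = "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
    else:
        raise ValueError(f"unsupported graph format {fmt!r}")
    handle, close = _open_maybe(stream_or_path, "w")
    try:
        handle.write(text)
    finally:
        if close:
            handle.close()


def _dot_text(model: EcosystemModel, structure: Structure | None) -> str:
    services, units = _graph_nodes(model, structure)
    lines = ["digraph pgraph {"]
    for s in sorted(services):
        role = model.services[s].role
        lines.append(f'  "{s}" [shape=ellipse, role="{role}"];')
    for u in sorted(units):
        lines.append(f'  "{u}" [shape=box];')
    for u in sorted(units):
        node = model.units[u]
        for s in sorted(node.inputs):
            if structure is None or s in structure.services:
                lines.append(f'  "{s}" -> "{u}";')
        for s in sorted(node.outputs):
            if structure is None or s in structure.services:
                lines.append(f'  "{u}" -> "{s}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
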