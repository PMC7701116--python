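"""Processing history: every derived file carries, inside its JSON
sidecar, the ordered list of module executions that produced it.

Each execution appends one :class:`HistoryRecord` (module id, parameters,
input/output filenames, timestamp, engine version) under the sidecar key
``"History"``. Records are append-only; walking the inputs of each record
back through their own sidecars reconstructs the full provenance chain
down to the raw data. ROI files produced by modules get sidecars too, so
provenance is uniform across Scans and ROIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__ as _ENGINE_VERSION
from .project import DatabaseEntry, Project

__all__ = [
    "HistoryRecord",
    "append_history",
    "read_history",
    "trace_to_raw",
    "ProvenanceNode",
    "file_history_report",
]

HISTORY_KEY = "History"


@dataclass(frozen=True)
class HistoryRecord:
    """One module execution, as stored in an output's sidecar."""

    module_id: str
    parameters: dict[str, Any]
    inputs: tuple[str, ...]      # filenames relative to project root
    outputs: tuple[str, ...]
    timestamp: str
    engine_version: str = _ENGINE_VERSION

    def __post_init__(self) -> None:
        if not self.inputs or not self.outputs:
            raise ValueError("a history record needs >=1 input and output")

    def to_json(self) -> dict:
        return {
            "ModuleId": self.module_id,
            "Parameters": dict(self.parameters),
            "Inputs": list(self.inputs),
            "Outputs": list(self.outputs),
            "Timestamp": self.timestamp,
            "EngineVersion": self.engine_version,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "HistoryRecord":
        return cls(
            module_id=payload["ModuleId"],
            parameters=dict(payload["Parameters"]),
            inputs=tuple(payload["Inputs"]),
            outputs=tuple(payload["Outputs"]),
            timestamp=payload["Timestamp"],
            engine_version=payload.get("EngineVersion", "unknown"),
        )


def append_history(sidecar: dict, record: HistoryRecord) -> dict:
    """Append one record to a sidecar's History list (prior records untouched)."""
    history = list(sidecar.get(HISTORY_KEY, []))
    history.append(record.to_json())
    out = dict(sidecar)
    out[HISTORY_KEY] = history
    return out


def read_history(sidecar: dict) -> list[HistoryRecord]:
    return [HistoryRecord.from_json(p) for p in sidecar.get(HISTORY_KEY, [])]


@dataclass
class ProvenanceNode:
    """A node in the provenance tree: one file and the record that made it."""

    filename: str                       # relative to project root
    record: HistoryRecord | None        # None for raw files
    parents: list["ProvenanceNode"] = field(default_factory=list)
    truncated: bool = False             # missing intermediate sidecar

    def leaves(self) -> list["ProvenanceNode"]:
        if not self.parents:
            return [self]
        out: list[ProvenanceNode] = []
        for p in self.parents:
            out.extend(p.leaves())
        return out


def _sidecar_for(project: Project, rel_file: str) -> dict | None:
    path = Path(project.root) / rel_file
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    sc = path.with_name(name + ".json")
    if not sc.exists():
        return None
    return json.loads(sc.read_text())


def trace_to_raw(project: Project, entry: DatabaseEntry) -> "ProvenanceChain":
    """Reconstruct the chain of module executions back to the raw data.

    Walks the last History record of the entry's sidecar, then each
    input's sidecar recursively, until files with empty History (raw
    data) are reached. Missing intermediate sidecars truncate that
    branch and are flagged. A cycle raises.
    """
    rel = str(Path(entry.path) / entry.filename)
    node = _trace_file(project, rel, frozenset())
    return ProvenanceChain(root=node)


def _trace_file(project: Project, rel_file: str,
                visiting: frozenset) -> ProvenanceNode:
    if rel_file in visiting:
        raise RuntimeError(f"provenance cycle at {rel_file}")
    sidecar = _sidecar_for(project, rel_file)
    if sidecar is None:
        return ProvenanceNode(filename=rel_file, record=None, truncated=True)
    records = read_history(sidecar)
    if not records:
        return ProvenanceNode(filename=rel_file, record=None)
    last = records[-1]
    node = ProvenanceNode(filename=rel_file, record=last)
    for inp in last.inputs:
        node.parents.append(_trace_file(project, inp, visiting | {rel_file}))
    return node


@dataclass
class ProvenanceChain:
    """The provenance tree of one entry plus flat, raw-first record order."""

    root: ProvenanceNode

    @property
    def records(self) -> list[HistoryRecord]:
        ordered: list[HistoryRecord] = []
        seen: set[int] = set()

        def visit(node: ProvenanceNode) -> None:
            for p in node.parents:
                visit(p)
            if node.record is not None and id(node.record) not in seen:
                seen.add(id(node.record))
                ordered.append(node.record)

        visit(self.root)
        return ordered

    @property
    def truncated(self) -> bool:
        def any_trunc(node: ProvenanceNode) -> bool:
            return node.truncated or any(any_trunc(p) for p in node.parents)
        return any_trunc(self.root)


def file_history_report(project: Project, entry: DatabaseEntry) -> str:
    """Human-readable rendering of an entry's provenance chain."""
    chain = trace_to_raw(project, entry)
    lines = [f"History of {entry.filename}"]
    if chain.root.record is None and not chain.root.truncated:
        lines.append("  raw data, no history")
        return "\n".join(lines)
    for i, rec in enumerate(chain.records, start=1):
        lines.append(f"  step {i}: {rec.module_id} at {rec.timestamp} "
                     f"(engine {rec.engine_version})")
        for k in sorted(rec.parameters):
            lines.append(f"    param {k} = {rec.parameters[k]!r}")
        lines.append("    inputs: " + ", ".join(rec.inputs))
        lines.append("    outputs: " + ", ".join(rec.outputs))
    if chain.truncated:
        lines.append("  [chain truncated: missing intermediate sidecar]")
    return "\n".join(lines)
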