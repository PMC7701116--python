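"""Pipeline engine: module discovery, job expansion, scheduling, execution.

A *module* is a declared computation (parameter schema + run function)
found by scanning module folders. Adding a module to a pipeline under a
database filter expands it into *jobs* — one per (subject, timepoint)
session whose rows match the module's selectors — and declares each
job's outputs as *virtual* database entries, visible to later modules.
That construction makes the job dependency graph acyclic by design.

Execution stages every output in the project's ``Tmp`` folder and only
promotes files of successful jobs into ``Derived_data`` / ``ROI_data``,
flipping the database row from virtual to derived/roi and appending a
provenance record to the output sidecar. ``single`` mode runs jobs in
module order; ``multi`` mode runs them with a process pool respecting
the dependency graph, capped at the requested worker count. Both modes
produce byte-identical outputs.

Module compliance colors: green (jobs generated), red (selector matches
nothing in the database), orange (some outputs already exist on disk
from a previous execution; re-run only with ``overwrite``).
"""

from __future__ import annotations

import importlib
import importlib.util
import json
import shutil
import traceback
import zlib
from concurrent.futures import FIRST_COMPLETED, ProcessPoolExecutor, wait
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Sequence

import networkx as nx
import pandas as pd

from . import convert
from .project import (DatabaseEntry, Project, ProjectError, filter_database,
                      save_project)
from .provenance import HISTORY_KEY, HistoryRecord, append_history

__all__ = [
    "Param", "OutputSpec", "ModuleSpec", "Job", "ModuleInstance", "Pipeline",
    "ExecutionReport", "discover_modules", "builtin_module_dir",
    "add_module", "build_dependency_graph", "save_pipeline", "load_pipeline",
    "execute", "module_status_color",
]

PARAM_KINDS = ("sequence_selector", "roi_selector", "number", "choice", "string")
PIPELINE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class Param:
    """One declared module parameter."""

    name: str
    kind: str
    default: Any = None
    choices: tuple | None = None

    def validate(self, value: Any) -> Any:
        if self.kind not in PARAM_KINDS:
            raise ValueError(f"param {self.name!r}: unknown kind {self.kind!r}")
        if self.kind in ("sequence_selector", "roi_selector", "string"):
            if not isinstance(value, str) or (self.kind != "string" and not value):
                raise ValueError(f"param {self.name!r}: expected a non-empty "
                                 f"string, got {value!r}")
        elif self.kind == "number":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError(f"param {self.name!r}: expected a number, "
                                 f"got {value!r}")
        elif self.kind == "choice":
            if self.choices is None or value not in self.choices:
                raise ValueError(f"param {self.name!r}: {value!r} not in "
                                 f"{self.choices}")
        return value


@dataclass(frozen=True)
class OutputSpec:
    """One declared job output.

    ``type`` is Scan, ROI or File; Scan/ROI outputs become database
    entries named ``<input sequence>_<extension>`` where the extension
    string comes from the parameter named by ``extension_param``. File
    outputs (CSV, HTML) are promoted to Derived_data but not tracked as
    database rows.
    """

    name: str
    type: str = "Scan"
    extension_param: str = "extension"
    file_suffix: str = ".nii.gz"


@dataclass
class ModuleSpec:
    """A declared computation: id, category, schema, outputs, run function."""

    id: str
    category: str
    params: list[Param]
    outputs: list[OutputSpec]
    run: Callable | None = None
    arity: str = "per-session"          # per-session | per-subject
    source: str = ""                    # "builtin:<module>" or a file path
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id.startswith("Module_"):
            raise ValueError(f"module id must start with 'Module_': {self.id!r}")
        if self.arity not in ("per-session", "per-subject"):
            raise ValueError(f"unknown arity {self.arity!r}")
        selectors = [p for p in self.params
                     if p.kind in ("sequence_selector", "roi_selector")]
        if not selectors:
            raise ValueError(f"{self.id}: needs >=1 selector parameter")
        for p in self.params:
            if p.default is not None:
                p.validate(p.default)
        for out in self.outputs:
            if out.type not in ("Scan", "ROI", "File"):
                raise ValueError(f"{self.id}: bad output type {out.type!r}")
            if out.type != "File" and not any(
                    p.name == out.extension_param for p in self.params):
                raise ValueError(f"{self.id}: output {out.name!r} references "
                                 f"unknown extension param {out.extension_param!r}")

    def selector_params(self) -> list[Param]:
        return [p for p in self.params
                if p.kind in ("sequence_selector", "roi_selector")]

    def bind_params(self, values: dict) -> dict:
        bound = {}
        known = {p.name for p in self.params}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"{self.id}: unknown parameter(s) {sorted(unknown)}")
        for p in self.params:
            v = values.get(p.name, p.default)
            if v is None:
                raise ValueError(f"{self.id}: parameter {p.name!r} has no value")
            bound[p.name] = p.validate(v)
        return bound


# ---------------------------------------------------------------------------
# Discovery


def builtin_module_dir() -> Path:
    from . import modules as _m
    return Path(_m.__file__).parent


def _load_spec_from_file(path: Path) -> ModuleSpec:
    spec = importlib.util.spec_from_file_location(f"voxpipe_ext_{path.stem}", path)
    if spec is None or spec.loader is None:
        raise ImportError(f"cannot import {path}")
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    declared = getattr(mod, "MODULE", None)
    if not isinstance(declared, ModuleSpec):
        raise ValueError(f"{path.name}: no MODULE ModuleSpec declared")
    return declared


def discover_modules(search_paths: Sequence[str | Path] | None = None,
                     include_builtin: bool = True,
                     ) -> tuple[list[ModuleSpec], list[tuple[str, str]]]:
    """Scan module folders (recursively) for ``module_*.py`` declarations.

    Returns (specs sorted by category then id, broken files as
    (path, reason) pairs). Malformed declarations are reported, never
    fatal. Builtin modules are importable package modules; external
    files are loaded from their path both here and inside workers.
    """
    specs: list[ModuleSpec] = []
    broken: list[tuple[str, str]] = []
    paths = [Path(p) for p in (search_paths or [])]
    if include_builtin:
        paths.insert(0, builtin_module_dir())
    builtin_dir = builtin_module_dir()
    for base in paths:
        if not base.is_dir():
            continue
        for file in sorted(base.rglob("module_*.py")):
            try:
                if file.parent == builtin_dir or file.is_relative_to(builtin_dir):
                    mod = importlib.import_module(f"voxpipe.modules.{file.stem}")
                    spec = getattr(mod, "MODULE", None)
                    if not isinstance(spec, ModuleSpec):
                        raise ValueError(f"{file.name}: no MODULE declared")
                    spec.source = f"builtin:{file.stem}"
                else:
                    spec = _load_spec_from_file(file)
                    spec.source = str(file)
                if not spec.category:
                    spec.category = file.parent.name
                specs.append(spec)
            except Exception as exc:
                broken.append((str(file), f"{type(exc).__name__}: {exc}"))
    specs.sort(key=lambda s: (s.category, s.id))
    return specs, broken


def get_module(module_id: str,
               search_paths: Sequence[str | Path] | None = None) -> ModuleSpec:
    specs, _ = discover_modules(search_paths)
    for s in specs:
        if s.id == module_id:
            return s
    raise KeyError(f"no module named {module_id!r}")


# ---------------------------------------------------------------------------
# Jobs and pipelines

EntryKey = tuple  # (subject, timepoint, sequence_name, type)


@dataclass
class Job:
    """One concrete invocation of a module bound to database entries."""

    id: str
    module_index: int
    module_id: str
    subject: str
    timepoint: str
    inputs: dict[str, EntryKey]
    params: dict
    outputs: dict[str, EntryKey] = field(default_factory=dict)
    file_outputs: dict[str, str] = field(default_factory=dict)  # name -> rel path
    state: str = "pending"      # pending|running|done|failed|skipped
    already_executed: bool = False
    log: str = ""

    def set_state(self, new: str) -> None:
        allowed = {
            "pending": {"running", "skipped"},
            "running": {"done", "failed"},
        }
        if new not in allowed.get(self.state, set()):
            raise ValueError(f"illegal job state transition {self.state} -> {new}")
        self.state = new


@dataclass
class ModuleInstance:
    """A module added to a pipeline: spec + bound params + insertion filter."""

    spec: ModuleSpec
    params: dict
    criteria: dict | None
    state: str = "green"        # green|orange|red
    jobs: list[Job] = field(default_factory=list)


class Pipeline:
    """Ordered module instances over one project, with their job set."""

    def __init__(self, project: Project, name: str = "pipeline"):
        self.project = project
        self.name = name
        self.modules: list[ModuleInstance] = []

    @property
    def jobs(self) -> list[Job]:
        return [j for m in self.modules for j in m.jobs]

    def job_by_id(self, job_id: str) -> Job:
        for j in self.jobs:
            if j.id == job_id:
                return j
        raise KeyError(job_id)


def module_status_color(instance: ModuleInstance) -> str:
    """Compliance color of a pipeline module: green, orange or red."""
    return instance.state


def _session_groups(df: pd.DataFrame, arity: str) -> list[tuple[tuple[str, str], pd.DataFrame]]:
    if arity == "per-subject":
        groups = []
        for subj, g in df.groupby("subject", sort=True):
            tp = sorted(g["timepoint"].unique())[0]
            groups.append(((str(subj), str(tp)), g))
        return groups
    return [((str(s), str(t)), g)
            for (s, t), g in df.groupby(["subject", "timepoint"], sort=True)]


def _entry_already_executed(project: Project, entry: DatabaseEntry,
                            module_id: str) -> bool:
    img = entry.image_path(project.root)
    if not img.exists():
        return False
    sc = entry.sidecar_path(project.root)
    if not sc.exists():
        return False
    try:
        history = json.loads(sc.read_text()).get(HISTORY_KEY, [])
    except json.JSONDecodeError:
        return False
    return any(rec.get("ModuleId") == module_id for rec in history)


def add_module(pipeline: Pipeline, spec: ModuleSpec, params: dict | None = None,
               criteria: dict | None = None) -> ModuleInstance:
    """Bind a module to the (filtered) database, expanding it into jobs.

    One job is created per distinct (subject, timepoint) session whose
    rows satisfy every selector; each declared Scan/ROI output becomes a
    virtual database entry named ``<input sequence>_<extension>``,
    immediately visible to subsequent ``add_module`` calls. A selector
    that matches nothing leaves the module red with zero jobs.
    """
    project = pipeline.project
    bound = spec.bind_params(params or {})
    instance = ModuleInstance(spec=spec, params=bound, criteria=criteria)
    module_index = len(pipeline.modules)
    db = filter_database(project, criteria)
    selectors = spec.selector_params()
    primary_seq = bound[selectors[0].name]

    new_entries: list[DatabaseEntry] = []
    jobs: list[Job] = []
    for (subject, timepoint), group in _session_groups(db, spec.arity):
        inputs: dict[str, EntryKey] = {}
        complete = True
        for p in selectors:
            want_type = "ROI" if p.kind == "roi_selector" else "Scan"
            # a "<selector>_timepoint" string param pins the selector to one
            # timepoint of the same subject (e.g. align visits onto the first)
            scope_tp = bound.get(f"{p.name}_timepoint", "")
            if scope_tp:
                pool = db[(db["subject"] == subject)
                          & (db["timepoint"] == scope_tp)]
            else:
                pool = group
            match = pool[(pool["sequence_name"] == bound[p.name])
                         & (pool["type"] == want_type)]
            if len(match) == 0:
                complete = False
                break
            row = match.iloc[0]
            inputs[p.name] = (row["subject"], row["timepoint"],
                              row["sequence_name"], row["type"])
        if not complete:
            continue
        job = Job(
            id=f"m{module_index:02d}_{spec.id}_{subject}_{timepoint}",
            module_index=module_index, module_id=spec.id,
            subject=subject, timepoint=timepoint,
            inputs=inputs, params=dict(bound),
        )
        any_oranges = False
        for out in spec.outputs:
            ext = bound.get(out.extension_param, out.name)
            if out.type == "File":
                rel = f"Derived_data/{subject}_{timepoint}_{primary_seq}_{ext}{out.file_suffix}"
                job.file_outputs[out.name] = rel
                continue
            out_seq = f"{primary_seq}_{ext}"
            key = (subject, timepoint, out_seq, "Scan" if out.type == "Scan" else "ROI")
            existing = project.find(*key)
            if existing is None:
                entry = DatabaseEntry(
                    type=key[3], subject=subject, timepoint=timepoint,
                    sequence_name=out_seq, status="virtual",
                    path="Derived_data" if out.type == "Scan" else "ROI_data",
                )
                entry.filename = entry.canonical_filename()
                project.add_entry(entry)
                new_entries.append(entry)
            else:
                entry = existing
                if _entry_already_executed(project, entry, spec.id):
                    any_oranges = True
            job.outputs[out.name] = key
        if any_oranges:
            job.already_executed = True
        jobs.append(job)

    instance.jobs = jobs
    if not jobs:
        instance.state = "red"
    elif any(j.already_executed for j in jobs):
        instance.state = "orange"
    pipeline.modules.append(instance)
    save_project(project)
    return instance


def build_dependency_graph(pipeline: Pipeline) -> nx.DiGraph:
    """DAG over jobs: edge j1 -> j2 iff an output of j1 is an input of j2."""
    g = nx.DiGraph()
    for j in pipeline.jobs:
        g.add_node(j.id)
    producers: dict[EntryKey, str] = {}
    for j in pipeline.jobs:
        for key in j.outputs.values():
            producers[key] = j.id
    for j in pipeline.jobs:
        for key in j.inputs.values():
            if key in producers and producers[key] != j.id:
                g.add_edge(producers[key], j.id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise RuntimeError(f"job dependency cycle: {cycle}")
    return g


# ---------------------------------------------------------------------------
# Persistence


def save_pipeline(pipeline: Pipeline, path: str | Path | None = None) -> Path:
    """Serialize the module sequence + parameters (never the jobs)."""
    if path is None:
        path = pipeline.project.subdir("Saved_Pipelines") / f"{pipeline.name}.json"
    payload = {
        "format_version": PIPELINE_FORMAT_VERSION,
        "name": pipeline.name,
        "modules": [
            {"id": m.spec.id, "params": m.params, "criteria": m.criteria}
            for m in pipeline.modules
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_pipeline(path: str | Path, project: Project,
                  search_paths: Sequence[str | Path] | None = None) -> Pipeline:
    """Re-bind a saved pipeline against a (possibly different) project.

    Each stored module is re-expanded with :func:`add_module` against the
    whole current database; modules whose selector values are absent
    come back red (and their downstream consumers with them), and
    modules whose outputs already exist on disk come back orange.
    """
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != PIPELINE_FORMAT_VERSION:
        raise ValueError(
            f"incompatible pipeline file version {version!r} "
            f"(supported: {PIPELINE_FORMAT_VERSION})")
    pipeline = Pipeline(project, name=payload.get("name", "pipeline"))
    specs, _ = discover_modules(search_paths)
    by_id = {s.id: s for s in specs}
    for m in payload["modules"]:
        if m["id"] not in by_id:
            raise KeyError(f"pipeline references unknown module {m['id']!r}")
        add_module(pipeline, by_id[m["id"]], m.get("params"), m.get("criteria"))
    return pipeline


# ---------------------------------------------------------------------------
# Execution


@dataclass
class ExecutionReport:
    """Per-job outcome of one pipeline execution."""

    job_records: list[dict] = field(default_factory=list)
    log_path: str = ""

    @property
    def counts(self) -> dict[str, int]:
        c = {"done": 0, "failed": 0, "skipped": 0}
        for r in self.job_records:
            if r["state"] in c:
                c[r["state"]] += 1
        return c


def _job_payload(pipeline: Pipeline, job: Job, spec: ModuleSpec,
                 tmp_dir: Path, seed: int | None) -> dict:
    project = pipeline.project
    inputs = []
    for role, key in job.inputs.items():
        entry = project.find(*key)
        if entry is None:
            raise ProjectError(f"job {job.id}: missing input entry {key}")
        inputs.append({
            "role": role,
            "path": str(entry.image_path(project.root)),
            "is_roi": entry.type == "ROI",
        })
    outputs = []
    for name, key in job.outputs.items():
        entry = project.find(*key)
        assert entry is not None
        outputs.append({"name": name, "filename": entry.filename,
                        "is_roi": entry.type == "ROI"})
    for name, rel in job.file_outputs.items():
        outputs.append({"name": name, "filename": Path(rel).name, "is_file": True})
    job_seed = None
    if seed is not None:
        job_seed = (int(seed) + zlib.crc32(job.id.encode())) % (2 ** 31)
    return {
        "job_id": job.id,
        "module_source": spec.source,
        "inputs": inputs,
        "outputs": outputs,
        "params": job.params,
        "tmp_dir": str(tmp_dir),
        "context": {"subject": job.subject, "timepoint": job.timepoint,
                    "seed": job_seed,
                    "input_names": {r: k[2] for r, k in job.inputs.items()}},
    }


def _resolve_run(module_source: str) -> Callable:
    if module_source.startswith("builtin:"):
        mod = importlib.import_module(f"voxpipe.modules.{module_source[8:]}")
        return mod.MODULE.run
    return _load_spec_from_file(Path(module_source)).run


def _run_job_payload(payload: dict) -> dict:
    """Execute one job: load inputs, run the module, stage outputs in Tmp.

    Runs either in-process (single mode) or inside a worker process
    (multi mode); everything it needs arrives in the picklable payload.
    """
    tmp_dir = Path(payload["tmp_dir"])
    try:
        run = _resolve_run(payload["module_source"])
        if run is None:
            raise RuntimeError("module has no run function")
        inputs = {}
        for item in payload["inputs"]:
            if item["is_roi"]:
                inputs[item["role"]] = convert.read_roi(item["path"])
            else:
                inputs[item["role"]] = convert.read_scan(item["path"])
        results = run(inputs, payload["params"], payload["context"])
        tmp_dir.mkdir(parents=True, exist_ok=True)
        staged = []
        for out in payload["outputs"]:
            if out["name"] not in results:
                raise RuntimeError(f"module did not produce output {out['name']!r}")
            value = results[out["name"]]
            target = tmp_dir / out["filename"]
            if out.get("is_file"):
                if isinstance(value, bytes):
                    target.write_bytes(value)
                else:
                    target.write_text(str(value))
                staged.append({"name": out["name"], "tmp": str(target),
                               "is_file": True})
            else:
                convert.write_scan(value, target)
                staged.append({"name": out["name"], "tmp": str(target),
                               "is_file": False})
        return {"job_id": payload["job_id"], "ok": True, "staged": staged,
                "log": ""}
    except Exception:
        return {"job_id": payload["job_id"], "ok": False, "staged": [],
                "log": traceback.format_exc()}


def _promote_job(pipeline: Pipeline, job: Job, result: dict,
                 timestamp: str) -> None:
    """Move staged outputs to their final folders and record provenance."""
    project = pipeline.project
    input_rels = []
    for key in job.inputs.values():
        entry = project.find(*key)
        assert entry is not None
        input_rels.append(str(Path(entry.path) / entry.filename))
    output_rels = []
    for name, key in job.outputs.items():
        entry = project.find(*key)
        assert entry is not None
        output_rels.append(str(Path(entry.path) / entry.filename))
    output_rels.extend(job.file_outputs.values())
    record = HistoryRecord(
        module_id=job.module_id, parameters=dict(job.params),
        inputs=tuple(input_rels), outputs=tuple(output_rels),
        timestamp=timestamp,
    )
    staged_by_name = {s["name"]: s for s in result["staged"]}
    for name, key in job.outputs.items():
        entry = project.find(*key)
        assert entry is not None
        staged = Path(staged_by_name[name]["tmp"])
        final = entry.image_path(project.root)
        final.parent.mkdir(parents=True, exist_ok=True)
        # stamp provenance into the sidecar before promotion
        sc_tmp = staged.with_name(staged.name.replace(".nii.gz", ".json"))
        sidecar = json.loads(sc_tmp.read_text()) if sc_tmp.exists() else {}
        sidecar = append_history(sidecar, record)
        sc_tmp.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        shutil.move(str(staged), str(final))
        shutil.move(str(sc_tmp), str(entry.sidecar_path(project.root)))
        entry.status = "derived" if entry.type == "Scan" else "roi"
    for name, rel in job.file_outputs.items():
        staged = Path(staged_by_name[name]["tmp"])
        final = project.root / rel
        final.parent.mkdir(parents=True, exist_ok=True)
        shutil.move(str(staged), str(final))
    save_project(project)


def _utc_now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def execute(pipeline: Pipeline, mode: str = "single", workers: int = 1,
            overwrite: bool = False, seed: int | None = None,
            timestamp: str | None = None) -> ExecutionReport:
    """Run the pipeline's jobs and return a per-job report.

    ``single`` mode executes all jobs of module 1, then module 2, ...
    sequentially in-process. ``multi`` mode distributes jobs over a
    process pool of ``workers``, a job becoming eligible once all its
    dependency-graph parents are done. Jobs whose outputs already exist
    from a previous execution (orange) are skipped unless ``overwrite``;
    a failed job marks all transitive descendants skipped and leaves no
    partial files outside Tmp.
    """
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    runnable = [m for m in pipeline.modules if m.state != "red"]
    if not runnable:
        raise ProjectError("pipeline has no runnable (non-red) module")
    ts = timestamp or _utc_now()
    project = pipeline.project
    tmp_root = project.subdir("Tmp") / "jobs"
    tmp_root.mkdir(parents=True, exist_ok=True)
    log_dir = project.subdir("Tmp") / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)

    graph = build_dependency_graph(pipeline)
    jobs = {j.id: j for m in runnable for j in m.jobs}
    specs = {m.spec.id: m.spec for m in pipeline.modules}

    # refresh orange detection against the current disk state
    for j in jobs.values():
        j.already_executed = all(
            _entry_already_executed(project, e, j.module_id)
            for e in (project.find(*k) for k in j.outputs.values()) if e is not None
        ) and bool(j.outputs)
        j.state = "pending"
        j.log = ""

    skipped: set[str] = set()
    for j in jobs.values():
        if j.already_executed and not overwrite:
            j.set_state("skipped")
            j.log = "outputs already present; skipped (no overwrite)"
            skipped.add(j.id)

    def mark_descendants_skipped(job_id: str) -> None:
        for desc in nx.descendants(graph, job_id):
            if desc in jobs and jobs[desc].state == "pending":
                jobs[desc].set_state("skipped")
                jobs[desc].log = f"ancestor {job_id} failed"

    records: list[dict] = []

    def finish(job: Job, result: dict) -> None:
        if result["ok"]:
            _promote_job(pipeline, job, result, ts)
            job.set_state("done")
        else:
            job.set_state("failed")
            job.log = result["log"]
            mark_descendants_skipped(job.id)
        shutil.rmtree(tmp_root / job.id, ignore_errors=True)

    def payload_for(job: Job) -> dict:
        return _job_payload(pipeline, job, specs[job.module_id],
                            tmp_root / job.id, seed)

    if mode == "single":
        for m in runnable:
            for job in m.jobs:
                if job.state != "pending":
                    continue
                if any(p in jobs and jobs[p].state in ("failed", "skipped")
                       and p not in skipped
                       for p in graph.predecessors(job.id)):
                    job.set_state("skipped")
                    job.log = "ancestor failed"
                    continue
                job.set_state("running")
                finish(job, _run_job_payload(payload_for(job)))
    else:
        _execute_multi(pipeline, graph, jobs, workers, payload_for, finish)

    for j in jobs.values():
        records.append({"job_id": j.id, "module_id": j.module_id,
                        "state": j.state, "log": j.log})
    for m in runnable:
        if any(j.already_executed for j in m.jobs):
            m.state = "orange"
    report = ExecutionReport(job_records=records)
    log_path = log_dir / f"run_{ts.replace(':', '').replace('-', '')}.log"
    lines = [f"pipeline {pipeline.name} mode={mode} workers={workers} at {ts}"]
    lines += [f"{r['state']:8s} {r['job_id']}" for r in records]
    c = report.counts
    lines.append(f"done={c['done']} failed={c['failed']} skipped={c['skipped']}")
    log_path.write_text("\n".join(lines) + "\n")
    report.log_path = str(log_path)
    return report


def _execute_multi(pipeline: Pipeline, graph: nx.DiGraph, jobs: dict[str, Job],
                   workers: int, payload_for: Callable, finish: Callable) -> None:
    """Dependency-aware parallel scheduler over a process pool.

    At most ``workers`` jobs run concurrently; a job is submitted once
    every parent is done (parents outside the runnable set count as
    satisfied if their outputs exist).
    """
    pending = {jid for jid, j in jobs.items() if j.state == "pending"}

    def ready(jid: str) -> bool:
        for p in graph.predecessors(jid):
            if p in jobs:
                st = jobs[p].state
                if st in ("pending", "running"):
                    return False
                if st in ("failed",):
                    return False
                if st == "skipped" and not jobs[p].already_executed:
                    return False
        return True

    with ProcessPoolExecutor(max_workers=workers) as pool:
        futures = {}
        while pending or futures:
            # cascade skips from failures before scheduling
            for jid in sorted(pending):
                if jobs[jid].state != "pending":   # e.g. skipped via a failure
                    pending.discard(jid)
                    continue
                preds = [p for p in graph.predecessors(jid) if p in jobs]
                if any(jobs[p].state == "failed"
                       or (jobs[p].state == "skipped" and not jobs[p].already_executed)
                       for p in preds):
                    jobs[jid].set_state("skipped")
                    jobs[jid].log = "ancestor failed or skipped"
                    pending.discard(jid)
            for jid in sorted(pending):
                if len(futures) >= workers:
                    break
                if ready(jid):
                    jobs[jid].set_state("running")
                    futures[pool.submit(_run_job_payload, payload_for(jobs[jid]))] = jid
                    pending.discard(jid)
            if not futures:
                if pending:
                    # nothing ready and nothing running: all remaining blocked
                    for jid in sorted(pending):
                        jobs[jid].set_state("skipped")
                        jobs[jid].log = "unsatisfiable dependencies"
                    pending.clear()
                continue
            done_set, _ = wait(list(futures), return_when=FIRST_COMPLETED)
            for fut in done_set:
                jid = futures.pop(fut)
                try:
                    result = fut.result()
                except Exception:
                    result = {"job_id": jid, "ok": False, "staged": [],
                              "log": traceback.format_exc()}
                finish(jobs[jid], result)
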