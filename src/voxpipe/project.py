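"""On-disk project store: folder architecture plus a tag-driven database.

A project is a directory with five fixed sub-folders::

    Raw_data/         imported scans (NIfTI + JSON sidecar)
    Derived_data/     pipeline outputs
    ROI_data/         binary masks
    Tmp/              staging area for running jobs, logs
    Saved_Pipelines/  portable pipeline definition files

Every image is one row of a flat tag database (subject, timepoint,
sequence name, group, type, status, relative path, filename) persisted as
a TSV next to the data. The database alone describes the project, so a
project directory can be moved between machines: all paths are stored
relative to the root.

File naming is reconstructible from tags:
``<subject>_<timepoint>_<sequence_name>.nii.gz`` (+ ``.json``), which is
why renaming a tag value also renames files on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from . import convert
from .volume import ScanVolume

__all__ = [
    "SUBDIRS",
    "DB_FILENAME",
    "STATUS_DIRS",
    "DatabaseEntry",
    "FilterCriteria",
    "Project",
    "ProjectError",
    "create_project",
    "load_project",
    "save_project",
    "register_entry",
    "filter_database",
    "rename_tag_value",
    "delete_entries",
    "import_bids",
    "audit_project",
    "entry_status_color",
]

SUBDIRS = ("Raw_data", "Derived_data", "ROI_data", "Tmp", "Saved_Pipelines")
DB_FILENAME = "voxpipe_database.tsv"
STATUS_DIRS = {"raw": "Raw_data", "derived": "Derived_data", "roi": "ROI_data"}
DB_COLUMNS = ["type", "subject", "timepoint", "sequence_name", "group",
              "path", "filename", "status"]
RENAMEABLE_TAGS = ("subject", "timepoint", "sequence_name", "group")
FILTERABLE_TAGS = ("subject", "timepoint", "sequence_name", "type", "status", "group")

STATUS_COLORS = {"raw": "blue", "derived": "green", "roi": "pink", "virtual": "yellow"}


class ProjectError(RuntimeError):
    """Raised for project-level contract violations (collisions, missing data)."""


@dataclass
class DatabaseEntry:
    """One row of the cohort database: tags plus file pointers and status."""

    type: str                 # "Scan" | "ROI"
    subject: str
    timepoint: str
    sequence_name: str
    group: str = ""
    path: str = ""            # directory relative to project root
    filename: str = ""        # image file name (.nii or .nii.gz); "" for virtual
    status: str = "raw"       # raw | derived | roi | virtual
    missing: bool = False     # set by load_project when the file is absent

    def key(self) -> tuple[str, str, str, str]:
        return (self.subject, self.timepoint, self.sequence_name, self.type)

    def is_virtual(self) -> bool:
        return self.status == "virtual"

    def image_path(self, root: Path) -> Path:
        return Path(root) / self.path / self.filename

    def sidecar_path(self, root: Path) -> Path:
        name = self.filename
        for ext in (".nii.gz", ".nii"):
            if name.endswith(ext):
                name = name[: -len(ext)]
                break
        return Path(root) / self.path / (name + ".json")

    def canonical_filename(self) -> str:
        return f"{self.subject}_{self.timepoint}_{self.sequence_name}.nii.gz"


def entry_status_color(status_or_entry) -> str:
    """Map an entry status to the display color convention.

    Raw data is blue, derived green, ROI pink, virtual (not yet computed)
    yellow. Module compliance colors (green/orange/red) live in the
    pipeline engine.
    """
    status = getattr(status_or_entry, "status", status_or_entry)
    try:
        return STATUS_COLORS[status]
    except KeyError:
        raise ValueError(f"unknown status {status!r}") from None


@dataclass
class FilterCriteria:
    """Per-tag value sets, combined conjunctively.

    ``None`` for a tag means "no constraint"; empty criteria select the
    whole database. Filtering is idempotent.
    """

    subject: set[str] | None = None
    timepoint: set[str] | None = None
    sequence_name: set[str] | None = None
    type: set[str] | None = None
    status: set[str] | None = None
    group: set[str] | None = None

    @classmethod
    def from_dict(cls, criteria: dict) -> "FilterCriteria":
        unknown = set(criteria) - set(FILTERABLE_TAGS)
        if unknown:
            raise ValueError(f"unknown filter tag(s): {sorted(unknown)}")
        kwargs = {}
        for tag, values in criteria.items():
            if values is None:
                continue
            if isinstance(values, str):
                values = {values}
            kwargs[tag] = set(values)
        return cls(**kwargs)

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=df.index)
        for tag in FILTERABLE_TAGS:
            values = getattr(self, tag)
            if values is not None:
                m &= df[tag].isin(values)
        return m


class Project:
    """A cohort project: root directory plus the in-memory tag database."""

    def __init__(self, root: str | Path, entries: list[DatabaseEntry] | None = None):
        self.root = Path(root)
        self.entries: list[DatabaseEntry] = entries or []

    # -- database views -----------------------------------------------------

    @property
    def database(self) -> pd.DataFrame:
        """The tag database as a DataFrame (one row per entry)."""
        rows = [
            {c: getattr(e, c) for c in DB_COLUMNS} | {"missing": e.missing}
            for e in self.entries
        ]
        return pd.DataFrame(rows, columns=DB_COLUMNS + ["missing"])

    def find(self, subject: str, timepoint: str, sequence_name: str,
             type: str = "Scan") -> DatabaseEntry | None:
        # cached key index, rebuilt when the entry list changes size or a
        # rename invalidates it (keys mutate only through rename_tag_value)
        index = getattr(self, "_key_index", None)
        if index is None or len(index) != len(self.entries):
            index = {e.key(): e for e in self.entries}
            self._key_index = index
        return index.get((subject, timepoint, sequence_name, type))

    def _invalidate_index(self) -> None:
        self._key_index = None

    def _check_unique(self, entry: DatabaseEntry,
                      ignore: DatabaseEntry | None = None) -> None:
        for e in self.entries:
            if e is ignore:
                continue
            if e.key() == entry.key():
                raise ProjectError(
                    f"entry already exists for key (subject={entry.subject!r}, "
                    f"timepoint={entry.timepoint!r}, "
                    f"sequence_name={entry.sequence_name!r}, type={entry.type!r})"
                )

    def add_entry(self, entry: DatabaseEntry) -> DatabaseEntry:
        self._check_unique(entry)
        self.entries.append(entry)
        self._invalidate_index()
        return entry

    # -- paths --------------------------------------------------------------

    def subdir(self, name: str) -> Path:
        return self.root / name

    def db_path(self) -> Path:
        return self.root / DB_FILENAME

    def save(self) -> Path:
        return save_project(self)


# ---------------------------------------------------------------------------
# Creation / persistence


def create_project(root: str | Path) -> Project:
    """Create the project skeleton; refuses to overwrite an existing project."""
    root = Path(root)
    if (root / DB_FILENAME).exists():
        raise ProjectError(f"project exists at {root}")
    root.mkdir(parents=True, exist_ok=True)
    for sub in SUBDIRS:
        (root / sub).mkdir(exist_ok=True)
    project = Project(root)
    save_project(project)
    return project


def save_project(project: Project) -> Path:
    """Persist the database as a TSV with relative paths."""
    path = project.db_path()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(DB_COLUMNS)
        for e in project.entries:
            writer.writerow([getattr(e, c) for c in DB_COLUMNS])
    return path


def load_project(root: str | Path) -> Project:
    """Reopen a project from its database; flags (not fails on) missing files."""
    root = Path(root)
    db_file = root / DB_FILENAME
    if not db_file.exists():
        raise ProjectError(f"no project database at {root}")
    entries: list[DatabaseEntry] = []
    with open(db_file, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ProjectError(f"{db_file}: empty database file") from None
        if header != DB_COLUMNS:
            raise ProjectError(
                f"{db_file}: line 1: unexpected columns {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(DB_COLUMNS):
                raise ProjectError(
                    f"{db_file}: line {lineno}: expected "
                    f"{len(DB_COLUMNS)} fields, got {len(row)}: {row!r}"
                )
            entries.append(DatabaseEntry(**dict(zip(DB_COLUMNS, row))))
    project = Project(root, entries)
    for e in project.entries:
        if not e.is_virtual() and not e.image_path(root).exists():
            e.missing = True
    return project


# ---------------------------------------------------------------------------
# Registration


def register_entry(project: Project, image_file: str | Path,
                   tags: dict, sidecar: dict | None = None,
                   move: bool = False) -> DatabaseEntry:
    """Import one NIfTI image (+ optional sidecar dict) into the project.

    The image is normalized to canonical ``.nii.gz`` inside the
    status-appropriate sub-folder; Scan entries always get a JSON sidecar
    written next to the image. Registering a ``.nii`` or ``.nii.gz`` of the
    same payload yields bit-identical loaded arrays.
    """
    for required in ("subject", "timepoint", "sequence_name"):
        if not tags.get(required):
            raise ValueError(f"tag {required!r} must be non-empty")
    entry_type = tags.get("type", "Scan")
    if entry_type not in ("Scan", "ROI"):
        raise ValueError(f"type must be 'Scan' or 'ROI', got {entry_type!r}")
    status = "roi" if entry_type == "ROI" else "raw"
    entry = DatabaseEntry(
        type=entry_type,
        subject=str(tags["subject"]),
        timepoint=str(tags["timepoint"]),
        sequence_name=str(tags["sequence_name"]),
        group=str(tags.get("group", "") or ""),
        path=STATUS_DIRS[status],
        status=status,
    )
    entry.filename = entry.canonical_filename()
    project._check_unique(entry)

    image_file = Path(image_file)
    try:
        if entry_type == "ROI":
            vol: ScanVolume = convert.read_roi(image_file)
        else:
            vol = convert.read_scan(image_file)
    except Exception as exc:
        raise ValueError(f"not a readable NIfTI file: {image_file} ({exc})") from exc
    meta = dict(vol.sidecar)
    if sidecar:
        meta.update(sidecar)
    meta.setdefault("History", [])
    convert.write_scan(vol, entry.image_path(project.root), sidecar=meta)
    if move:
        image_file.unlink()
        stem = image_file.name
        for ext in (".nii.gz", ".nii"):
            if stem.endswith(ext):
                stem = stem[: -len(ext)]
        json_src = image_file.with_name(stem + ".json")
        if json_src.exists():
            json_src.unlink()
    project.entries.append(entry)
    project._invalidate_index()
    save_project(project)
    return entry


# ---------------------------------------------------------------------------
# Filtering and edits


def filter_database(db: pd.DataFrame | Project,
                    criteria: FilterCriteria | dict | None = None) -> pd.DataFrame:
    """Return the rows matching the conjunction of per-tag membership tests."""
    df = db.database if isinstance(db, Project) else db
    if criteria is None:
        return df.copy()
    if isinstance(criteria, dict):
        criteria = FilterCriteria.from_dict(criteria)
    return df[criteria.mask(df)].copy()


def rename_tag_value(project: Project, tag: str, old: str, new: str) -> int:
    """Rename a tag value across the database, atomically.

    On-disk filenames are regenerated so they stay consistent with tags.
    A rename that would collide two rows is rejected with no change.
    """
    if tag not in RENAMEABLE_TAGS:
        raise ValueError(f"tag must be one of {RENAMEABLE_TAGS}, got {tag!r}")
    targets = [e for e in project.entries if getattr(e, tag) == old]
    if not targets:
        return 0
    # simulate the rename and check uniqueness before touching anything
    new_keys = []
    for e in project.entries:
        sim = replace(e)
        if getattr(sim, tag) == old:
            setattr(sim, tag, new)
        new_keys.append(sim.key())
    if len(set(new_keys)) != len(new_keys):
        raise ProjectError(
            f"renaming {tag} {old!r} -> {new!r} would collide database keys"
        )
    project._invalidate_index()
    for e in targets:
        old_img = e.image_path(project.root)
        old_sc = e.sidecar_path(project.root)
        setattr(e, tag, new)
        if tag != "group" and not e.is_virtual() and e.filename:
            e.filename = e.canonical_filename()
            new_img = e.image_path(project.root)
            new_sc = e.sidecar_path(project.root)
            if old_img.exists() and old_img != new_img:
                old_img.rename(new_img)
            if old_sc.exists() and old_sc != new_sc:
                old_sc.rename(new_sc)
    save_project(project)
    return len(targets)


def _entries_for_selection(project: Project, selection: pd.DataFrame) -> list[DatabaseEntry]:
    keys = {
        (r.subject, r.timepoint, r.sequence_name, r.type)
        for r in selection.itertuples()
    }
    return [e for e in project.entries if e.key() in keys]


def delete_entries(project: Project, selection: pd.DataFrame,
                   remove_files: bool = False) -> int:
    """Remove the selected rows; delete their files only if ``remove_files``.

    Virtual rows are always removable. A file that cannot be deleted keeps
    its row and is reported in the raised error at the end.
    """
    targets = _entries_for_selection(project, selection)
    failures: list[str] = []
    removed = 0
    for e in targets:
        if remove_files and not e.is_virtual():
            try:
                img = e.image_path(project.root)
                if img.exists():
                    img.unlink()
                sc = e.sidecar_path(project.root)
                if sc.exists():
                    sc.unlink()
            except OSError as exc:
                failures.append(f"{e.filename}: {exc}")
                continue
        project.entries.remove(e)
        removed += 1
    project._invalidate_index()
    save_project(project)
    if failures:
        raise ProjectError("could not delete: " + "; ".join(failures))
    return removed


# ---------------------------------------------------------------------------
# BIDS import


def _bids_entities(stem: str) -> dict[str, str]:
    parts = stem.split("_")
    entities = {}
    for part in parts[:-1]:
        if "-" in part:
            k, v = part.split("-", 1)
            entities[k] = v
    entities["suffix"] = parts[-1]
    return entities


def import_bids(project: Project, bids_root: str | Path) -> list[DatabaseEntry]:
    """Import a BIDS-organized tree into the project.

    ``sub-XX`` maps to the subject tag, ``ses-YY`` to the timepoint tag
    (trees without a session level get a single default timepoint
    ``ses-01``), and the acq label + suffix to the sequence name. Existing
    BIDS JSON sidecars are carried over.
    """
    bids_root = Path(bids_root)
    subjects = sorted(p for p in bids_root.glob("sub-*") if p.is_dir())
    if not subjects:
        raise ProjectError(f"not a BIDS tree: no sub-* directories in {bids_root}")
    imported: list[DatabaseEntry] = []
    for sub_dir in subjects:
        subject = sub_dir.name[len("sub-"):]
        sessions = sorted(p for p in sub_dir.glob("ses-*") if p.is_dir())
        ses_dirs = [(p.name[len("ses-"):], p) for p in sessions] or [("01", sub_dir)]
        for ses_label, ses_dir in ses_dirs:
            for img in sorted(ses_dir.glob("*/*.nii*")):
                if not (img.name.endswith(".nii") or img.name.endswith(".nii.gz")):
                    continue
                stem = img.name
                for ext in (".nii.gz", ".nii"):
                    if stem.endswith(ext):
                        stem = stem[: -len(ext)]
                ent = _bids_entities(stem)
                seq = ent["suffix"]
                if "acq" in ent:
                    seq = f"{ent['acq']}_{seq}"
                sidecar_file = img.parent / (stem + ".json")
                sidecar = None
                if sidecar_file.exists():
                    import json as _json
                    sidecar = _json.loads(sidecar_file.read_text())
                imported.append(
                    register_entry(
                        project, img,
                        tags={"subject": subject, "timepoint": f"ses-{ses_label}",
                              "sequence_name": seq},
                        sidecar=sidecar,
                    )
                )
    return imported


# ---------------------------------------------------------------------------
# Integrity audit


def audit_project(project: Project) -> dict:
    """fsck-style referential-integrity audit.

    Returns a report with rows whose files are missing and data files that
    have no (or more than one) database row. Sidecar JSONs are paired with
    their image and not counted separately.
    """
    missing_rows = []
    for e in project.entries:
        if not e.is_virtual() and not e.image_path(project.root).exists():
            missing_rows.append(e.key())
    claimed: dict[Path, int] = {}
    for e in project.entries:
        if not e.is_virtual():
            p = e.image_path(project.root)
            claimed[p] = claimed.get(p, 0) + 1
    orphans = []
    duplicates = [str(p) for p, n in claimed.items() if n > 1]
    for sub in ("Raw_data", "Derived_data", "ROI_data"):
        for f in sorted(project.subdir(sub).rglob("*.nii*")):
            if not (f.name.endswith(".nii") or f.name.endswith(".nii.gz")):
                continue
            if f not in claimed:
                orphans.append(str(f.relative_to(project.root)))
    return {
        "missing_files": missing_rows,
        "orphan_files": orphans,
        "duplicate_claims": duplicates,
        "clean": not (missing_rows or orphans or duplicates),
    }
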