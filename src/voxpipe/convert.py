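"""Conversion of source image dialects into canonical NIfTI + JSON pairs.

The canonical on-disk unit is a NIfTI-1 volume (``.nii`` or ``.nii.gz``)
plus a UTF-8 JSON sidecar holding acquisition metadata and the processing
``History`` list. Supported read dialects are classic single-frame DICOM
series and NIfTI(+JSON); further dialects (e.g. vendor-specific raw
formats) can be plugged in through :func:`register_dialect`.

Metadata extraction from DICOM is table-driven: a YAML mapping file lists
``{target_key, source_dialect, source_address, unit_conversion}`` rules.
A BIDS-compatible default mapping ships with the package; echo and
repetition times are stored in milliseconds.
"""

from __future__ import annotations

import gzip
import io
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable

import nibabel as nib
import numpy as np
import pydicom
import yaml

from .volume import RoiMask, ScanVolume

__all__ = [
    "MetadataMapping",
    "MappingRule",
    "load_metadata_mapping",
    "default_metadata_mapping",
    "convert_dicom_series",
    "convert_nifti",
    "read_scan",
    "write_scan",
    "read_roi",
    "register_dialect",
    "available_dialects",
]

_DICOM_TAG_RE = re.compile(r"^\(\s*([0-9a-fA-F]{4})\s*,\s*([0-9a-fA-F]{4})\s*\)$")

# LPS (DICOM patient space) -> RAS (NIfTI world) flips the first two axes.
_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# Metadata mapping


@dataclass(frozen=True)
class MappingRule:
    """One extraction rule: copy a source field into a sidecar key."""

    target_key: str
    source_dialect: str
    source_address: str
    unit_conversion: float = 1.0

    def dicom_tag(self) -> tuple[int, int]:
        m = _DICOM_TAG_RE.match(self.source_address)
        if m is None:
            raise ValueError(
                f"rule for {self.target_key!r}: invalid DICOM tag syntax "
                f"{self.source_address!r} (expected '(gggg,eeee)')"
            )
        return int(m.group(1), 16), int(m.group(2), 16)


@dataclass
class MetadataMapping:
    """A validated list of metadata extraction rules loaded from YAML."""

    rules: list[MappingRule] = field(default_factory=list)

    _KNOWN_DIALECTS = frozenset({"dicom", "nifti"})

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for i, rule in enumerate(self.rules):
            known = self._KNOWN_DIALECTS | set(_DIALECTS)
            if rule.source_dialect not in known:
                raise ValueError(
                    f"rule {i} ({rule.target_key!r}): unknown dialect "
                    f"{rule.source_dialect!r}"
                )
            if not rule.target_key:
                raise ValueError(f"rule {i}: empty target_key")
            if rule.target_key in seen and rule.source_dialect == "dicom":
                raise ValueError(
                    f"rule {i}: duplicate target_key {rule.target_key!r}"
                )
            seen.add(rule.target_key)
            if rule.source_dialect == "dicom":
                rule.dicom_tag()  # validates syntax eagerly

    def dump(self, path: str | Path) -> Path:
        payload = {
            "rules": [
                {
                    "target_key": r.target_key,
                    "source_dialect": r.source_dialect,
                    "source_address": r.source_address,
                    "unit_conversion": r.unit_conversion,
                }
                for r in self.rules
            ]
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path


def _mapping_from_dict(payload: dict) -> MetadataMapping:
    if not isinstance(payload, dict) or "rules" not in payload:
        raise ValueError("mapping YAML must contain a top-level 'rules' list")
    rules = []
    for i, raw in enumerate(payload["rules"]):
        try:
            rules.append(
                MappingRule(
                    target_key=raw["target_key"],
                    source_dialect=raw.get("source_dialect", "dicom"),
                    source_address=raw.get("source_address", ""),
                    unit_conversion=float(raw.get("unit_conversion", 1.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed mapping rule {i}: {exc}") from exc
    return MetadataMapping(rules=rules)


def load_metadata_mapping(path: str | Path) -> MetadataMapping:
    """Load and validate a metadata mapping from a YAML file."""
    payload = yaml.safe_load(Path(path).read_text())
    return _mapping_from_dict(payload)


def default_metadata_mapping() -> MetadataMapping:
    """The BIDS-compatible mapping shipped with the package."""
    text = resources.files("voxpipe.data").joinpath("default_mapping.yaml").read_text()
    return _mapping_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Dialect plug-in registry

# A dialect reader receives a source directory and returns
# (array, affine, metadata-dict); registering one makes it usable in
# metadata mapping rules and importable through the converter.
_DIALECTS: dict[str, Callable[[Path], tuple[np.ndarray, np.ndarray, dict]]] = {}


def register_dialect(name: str,
                     reader: Callable[[Path], tuple[np.ndarray, np.ndarray, dict]]) -> None:
    """Register a reader for an additional source dialect (e.g. vendor raw)."""
    if name in ("dicom", "nifti"):
        raise ValueError(f"dialect {name!r} is built in")
    _DIALECTS[name] = reader


def available_dialects() -> list[str]:
    return ["dicom", "nifti", *sorted(_DIALECTS)]


# ---------------------------------------------------------------------------
# Deterministic NIfTI + JSON writing


def _nifti_bytes(img: nib.Nifti1Image) -> bytes:
    return img.to_bytes()


def write_scan(volume: ScanVolume, path: str | Path,
               sidecar: dict | None = None) -> tuple[Path, Path | None]:
    """Write a ScanVolume as NIfTI(.gz) plus JSON sidecar.

    The affine is stored verbatim in both sform and qform-compatible
    fields; gzip output uses a fixed mtime so identical volumes produce
    byte-identical files. Returns (image path, sidecar path or None).
    """
    path = Path(path)
    meta = volume.sidecar if sidecar is None else sidecar
    img = nib.Nifti1Image(np.asanyarray(volume.array), volume.affine)
    img.header.set_sform(volume.affine, code=1)
    img.header.set_qform(volume.affine, code=1)
    raw = _nifti_bytes(img)
    if path.name.endswith(".nii.gz"):
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
            gz.write(raw)
        path.write_bytes(buf.getvalue())
    elif path.suffix == ".nii":
        path.write_bytes(raw)
    else:
        raise ValueError(f"unsupported image extension: {path.name}")
    sidecar_path: Path | None = None
    if meta is not None:
        sidecar_path = path.with_name(_stem(path.name) + ".json")
        sidecar_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path, sidecar_path


def _stem(name: str) -> str:
    if name.endswith(".nii.gz"):
        return name[: -len(".nii.gz")]
    if name.endswith(".nii"):
        return name[: -len(".nii")]
    return Path(name).stem


def read_scan(path: str | Path, *, require_sidecar: bool = False) -> ScanVolume:
    """Load a NIfTI file plus its JSON sidecar into a ScanVolume."""
    path = Path(path)
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    sidecar_path = path.with_name(_stem(path.name) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        if require_sidecar:
            warnings.warn(f"missing sidecar for {path.name}; using empty metadata")
        meta = {}
    return ScanVolume(array=arr, affine=img.affine, sidecar=meta)


def read_roi(path: str | Path) -> RoiMask:
    """Load a binary-mask NIfTI as a RoiMask."""
    path = Path(path)
    img = nib.load(path)
    arr = np.asanyarray(img.dataobj)
    sidecar_path = path.with_name(_stem(path.name) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RoiMask(array=arr, affine=img.affine, sidecar=meta)


# ---------------------------------------------------------------------------
# DICOM series conversion


def _dicom_value(ds: pydicom.Dataset, tag: tuple[int, int]) -> Any:
    elem = ds.get(tag)
    if elem is None:
        return None
    value = elem.value
    if value in (None, ""):
        return None
    if elem.VR in ("DS", "FL", "FD"):
        return float(value)
    if elem.VR in ("IS", "SL", "SS", "UL", "US"):
        return int(value)
    return str(value)


def extract_sidecar(ds: pydicom.Dataset, mapping: MetadataMapping) -> dict:
    """Apply mapping rules to one DICOM dataset; absent fields are omitted."""
    meta: dict[str, Any] = {}
    for rule in mapping.rules:
        if rule.source_dialect != "dicom":
            continue
        value = _dicom_value(ds, rule.dicom_tag())
        if value is None:
            continue
        if isinstance(value, (int, float)) and rule.unit_conversion != 1.0:
            value = value * rule.unit_conversion
        meta[rule.target_key] = value
    meta.setdefault("History", [])
    return meta


def _series_geometry(slices: list[pydicom.Dataset]) -> tuple[np.ndarray, list[int]]:
    """Sort slices along the normal and build the RAS+ affine.

    DICOM stores row/column direction cosines and per-slice positions in
    LPS patient space; the affine returned maps (row, col, slice) voxel
    indices to RAS world mm.
    """
    iop = np.array([float(v) for v in slices[0].ImageOrientationPatient])
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    positions = [np.array([float(v) for v in s.ImagePositionPatient]) for s in slices]
    order = sorted(range(len(slices)), key=lambda i: float(np.dot(positions[i], normal)))
    # the normal's sign is arbitrary; follow InstanceNumber when it is
    # monotonic with position so acquisition slice order is preserved
    numbers = [getattr(slices[i], "InstanceNumber", None) for i in order]
    if all(n is not None for n in numbers) and len(numbers) > 1:
        nums = [int(n) for n in numbers]
        if all(b < a for a, b in zip(nums, nums[1:])):
            order = order[::-1]
    pos_sorted = [positions[i] for i in order]
    if len(pos_sorted) > 1:
        steps = np.diff([float(np.dot(p, normal)) for p in pos_sorted])
        spacing = float(np.median(steps))
        bad = np.where(np.abs(steps - spacing) > 1e-3 * max(abs(spacing), 1.0))[0]
        if bad.size:
            gaps = ", ".join(
                f"slice {int(b)}->{int(b) + 1}: {steps[b]:.4f} mm" for b in bad
            )
            raise ValueError(
                f"inconsistent slice spacing (expected {spacing:.4f} mm): {gaps}"
            )
        slice_vec = pos_sorted[1] - pos_sorted[0]
    else:
        thickness = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)
        slice_vec = normal * thickness
    ps = [float(v) for v in slices[0].PixelSpacing]  # [row spacing, col spacing]
    affine_lps = np.eye(4)
    affine_lps[:3, 0] = col_dir * ps[0]   # row index advances along column direction
    affine_lps[:3, 1] = row_dir * ps[1]   # column index advances along row direction
    affine_lps[:3, 2] = slice_vec
    affine_lps[:3, 3] = pos_sorted[0]
    return _LPS_TO_RAS @ affine_lps, order


def convert_dicom_series(series_dir: str | Path,
                         mapping: MetadataMapping | None = None,
                         out_dir: str | Path | None = None,
                         out_name: str = "series") -> tuple[Path, Path]:
    """Convert one single-frame DICOM series directory to a NIfTI+JSON pair.

    Slices are sorted by position along the slice normal; the affine is
    reconstructed from ImageOrientationPatient / ImagePositionPatient /
    PixelSpacing in RAS+ convention.
    """
    series_dir = Path(series_dir)
    mapping = mapping or default_metadata_mapping()
    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(f))
        except Exception:
            continue
    if not slices:
        raise ValueError(f"no readable DICOM files in {series_dir}")
    uids = {str(s.SeriesInstanceUID) for s in slices}
    if len(uids) > 1:
        raise ValueError(f"mixed SeriesInstanceUIDs in {series_dir}: {sorted(uids)}")
    affine, order = _series_geometry(slices)
    stack = np.stack([slices[i].pixel_array for i in order], axis=-1)
    slope = float(getattr(slices[0], "RescaleSlope", 1.0) or 1.0)
    intercept = float(getattr(slices[0], "RescaleIntercept", 0.0) or 0.0)
    if slope != 1.0 or intercept != 0.0:
        stack = stack.astype(np.float64) * slope + intercept
        if float(stack.max(initial=0)) <= np.iinfo(np.int32).max and np.allclose(stack, np.round(stack)):
            stack = stack.astype(np.int32)
    meta = extract_sidecar(slices[0], mapping)
    volume = ScanVolume(array=stack, affine=affine, sidecar=meta)
    out_dir = Path(out_dir) if out_dir is not None else series_dir.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path, sc_path = write_scan(volume, out_dir / f"{out_name}.nii.gz")
    assert sc_path is not None
    return img_path, sc_path


def convert_nifti(image: str | Path, sidecar: str | Path | None = None,
                  out_dir: str | Path | None = None,
                  out_name: str | None = None) -> tuple[Path, Path]:
    """Normalize a NIfTI(+JSON) input to a canonical .nii.gz + JSON pair.

    The array and affine are preserved exactly; a minimal sidecar
    (Modality "unknown", empty History) is synthesized when none exists.
    """
    image = Path(image)
    try:
        img = nib.load(image)
        affine = img.affine
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI {image}: {exc}") from exc
    if sidecar is not None and Path(sidecar).exists():
        meta = json.loads(Path(sidecar).read_text())
    else:
        implicit = image.with_name(_stem(image.name) + ".json")
        if implicit.exists():
            meta = json.loads(implicit.read_text())
        else:
            meta = {"Modality": "unknown"}
    meta.setdefault("History", [])
    out_dir = Path(out_dir) if out_dir is not None else image.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    name = out_name or _stem(image.name)
    vol = ScanVolume(array=arr, affine=affine, sidecar=meta)
    img_path, sc_path = write_scan(vol, out_dir / f"{name}.nii.gz")
    assert sc_path is not None
    return img_path, sc_path
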