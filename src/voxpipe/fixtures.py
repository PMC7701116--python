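"""Deterministic synthetic data: phantoms, cohorts and DICOM series.

Everything any test or example needs is generated here, seeded, with the
ground truth returned alongside, so no download is ever required.
Phantom kinds:

``ellipsoid_brain``
    Bright ellipsoid "brain" plus a thin bright shell "skull" separated
    by a dark gap; truth is the ellipsoid mask.
``ct_head``
    Hounsfield-valued head: air -1000 HU, skull shell ~1000 HU, interior
    brain ~40 HU (plus noise); truth is the interior mask.
``ramp``
    Voxel value = flattened index (handy for counting oracles).
``checkerboard``
    Two alternating values by index parity (known local entropy).
``perfusion4d``
    4D volume whose in-brain voxels follow a gamma-variate bolus curve
    with known parameters.

The default cohort emulates a small preclinical study: 2 subjects, 3
timepoints each, 10 MR sequences per timepoint, with one brain ROI per
session — and scales up for stress scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from . import convert
from .project import (DatabaseEntry, Project, create_project, save_project)
from .volume import RoiMask, ScanVolume

__all__ = ["CohortSpec", "make_cohort", "make_stress_cohort", "make_volume",
           "make_dicom_series", "random_affine"]

DEFAULT_SEQUENCES = ("T2w", "T1w", "FLAIR", "ADC", "CBF", "CBV",
                     "T2star", "MTR", "DWI", "Perf")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort; generation is a pure function of it."""

    n_subjects: int = 2
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    sequences: tuple[str, ...] = DEFAULT_SEQUENCES
    shape: tuple[int, int, int] = (16, 16, 12)
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kind: str = "ellipsoid_brain"
    roi_per_session: bool = False
    noise_sigma: float = 2.0
    seed: int = 0

    def subject_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def _ellipsoid(shape: Sequence[int], semi_frac: Sequence[float]) -> np.ndarray:
    """Boolean ellipsoid centred in the volume, semi-axes as shape fractions."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, n, f in zip(grids, shape, semi_frac):
        c = (n - 1) / 2.0
        acc = acc + ((g - c) / (f * n / 2.0)) ** 2
    return acc <= 1.0


def _radial(shape: Sequence[int]) -> np.ndarray:
    """Normalized elliptic radius (1.0 at the box faces)."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, n in zip(grids, shape):
        c = (n - 1) / 2.0
        acc = acc + ((g - c) / (n / 2.0)) ** 2
    return np.sqrt(acc)


def make_volume(kind: str, shape: Sequence[int] = (16, 16, 12),
                voxel_mm: Sequence[float] = (1.0, 1.0, 1.0),
                params: dict | None = None,
                seed: int = 0) -> tuple[ScanVolume, dict]:
    """Generate one phantom volume plus its ground truth."""
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    affine = np.diag(list(voxel_mm) + [1.0])
    affine[:3, 3] = -np.asarray(voxel_mm) * (np.asarray(shape[:3]) - 1) / 2.0
    truth: dict = {}

    if kind == "ellipsoid_brain":
        noise = float(params.get("noise_sigma", 2.0))
        brain_frac = params.get("brain_frac", (0.6, 0.6, 0.6))
        brain = _ellipsoid(shape, brain_frac)
        r = _radial(shape)
        # thin shell, strictly smaller than the brain so the brain is the
        # largest bright connected component
        skull = (r >= 0.86) & (r <= 0.91)
        arr = np.zeros(shape, dtype=float)
        arr[brain] = 100.0
        arr[skull] = 120.0
        if noise > 0:
            arr = arr + rng.normal(0.0, noise, size=shape)
        truth["brain_mask"] = brain.astype(np.uint8)
        truth["semi_axes_mm"] = tuple(
            f * n / 2.0 * v for f, n, v in zip(brain_frac, shape, voxel_mm))
    elif kind == "ct_head":
        noise = float(params.get("noise_sigma", 5.0))
        r = _radial(shape)
        arr = np.full(shape, -1000.0)
        skull = (r >= 0.74) & (r <= 0.88)
        interior = r < 0.74
        arr[skull] = 1000.0
        arr[interior] = 40.0
        if noise > 0:
            arr[interior] += rng.normal(0.0, noise, size=int(interior.sum()))
        truth["brain_mask"] = interior.astype(np.uint8)
    elif kind == "ramp":
        arr = np.arange(int(np.prod(shape)), dtype=float).reshape(shape)
        truth["min"], truth["max"] = 0.0, float(arr.size - 1)
    elif kind == "checkerboard":
        lo, hi = params.get("values", (0.0, 100.0))
        idx = np.indices(shape).sum(axis=0)
        arr = np.where(idx % 2 == 0, float(lo), float(hi))
        truth["values"] = (float(lo), float(hi))
    elif kind == "perfusion4d":
        nt = int(params.get("n_timepoints", 20))
        t0, alpha, beta = (float(params.get(k, d))
                           for k, d in (("t0", 3.0), ("alpha", 2.0), ("beta", 1.5)))
        brain = _ellipsoid(shape, (0.55, 0.55, 0.55))
        t = np.arange(nt, dtype=float)
        dt = np.clip(t - t0, 0.0, None)
        series = 100.0 * (dt ** alpha) * np.exp(-dt / beta)
        arr = np.zeros(shape + (nt,), dtype=float)
        arr[brain] = 50.0 + series
        truth.update({"brain_mask": brain.astype(np.uint8), "series": 50.0 + series,
                      "t0": t0, "alpha": alpha, "beta": beta})
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    sidecar = {"Modality": "MR" if kind != "ct_head" else "CT",
               "SeriesDescription": f"synthetic {kind}", "History": []}
    return ScanVolume(array=arr, affine=affine, sidecar=sidecar), truth


def _register_volume(project: Project, vol: ScanVolume, tags: dict) -> DatabaseEntry:
    """Fast-path registration: write straight into the project tree."""
    entry_type = tags.get("type", "Scan")
    status = "roi" if entry_type == "ROI" else "raw"
    entry = DatabaseEntry(
        type=entry_type, subject=tags["subject"], timepoint=tags["timepoint"],
        sequence_name=tags["sequence_name"], group=tags.get("group", ""),
        path={"raw": "Raw_data", "roi": "ROI_data"}[status], status=status,
    )
    entry.filename = entry.canonical_filename()
    project._check_unique(entry)
    convert.write_scan(vol, entry.image_path(project.root))
    project.entries.append(entry)
    project._invalidate_index()
    return entry


def make_cohort(spec: CohortSpec, root: str | Path) -> Project:
    """Create and fully register a synthetic cohort project.

    Ground-truth masks are saved under ``<root>/truth/`` (outside the
    database) so oracle tests can compare against them.
    """
    project = create_project(root)
    truth_dir = Path(root) / "truth"
    truth_dir.mkdir(exist_ok=True)
    for si, subject in enumerate(spec.subject_names()):
        for ti, tp in enumerate(spec.timepoints):
            session_truth = None
            for qi, seq in enumerate(spec.sequences):
                vseed = (spec.seed * 1_000_003 + si * 10_007 + ti * 101 + qi) % (2 ** 31)
                vol, truth = make_volume(
                    spec.kind, spec.shape, spec.voxel_mm,
                    params={"noise_sigma": spec.noise_sigma}, seed=vseed)
                vol.sidecar["SeriesDescription"] = seq
                _register_volume(project, vol, {
                    "subject": subject, "timepoint": tp, "sequence_name": seq})
                if session_truth is None:
                    session_truth = truth
            if spec.roi_per_session and session_truth is not None \
                    and "brain_mask" in session_truth:
                affine = np.diag(list(spec.voxel_mm) + [1.0])
                affine[:3, 3] = -np.asarray(spec.voxel_mm) * \
                    (np.asarray(spec.shape) - 1) / 2.0
                roi = RoiMask(array=session_truth["brain_mask"], affine=affine)
                _register_volume(project, roi, {
                    "subject": subject, "timepoint": tp,
                    "sequence_name": "brainROI", "type": "ROI"})
                convert.write_scan(
                    ScanVolume(array=session_truth["brain_mask"], affine=affine),
                    truth_dir / f"{subject}_{tp}_brain_truth.nii.gz",
                    sidecar=None)
    save_project(project)
    return project


def make_stress_cohort(root: str | Path, n_subjects: int = 45,
                       n_sessions: int = 110, n_sequences: int = 9,
                       shape: tuple[int, int, int] = (8, 8, 6),
                       seed: int = 0) -> Project:
    """A larger, heterogeneous cohort for scheduler stress scenarios.

    Sessions are spread unevenly over subjects (2 or 3 visits each) so the
    total session count can be chosen independently of the subject count;
    every session carries ``n_sequences`` small scans.
    """
    if not n_subjects <= n_sessions <= 3 * n_subjects:
        raise ValueError("n_sessions must lie in [n_subjects, 3*n_subjects]")
    project = create_project(root)
    extra = n_sessions - 2 * n_subjects  # subjects with a third visit
    sequences = [f"Q{i}" for i in range(n_sequences)]
    sequences[0] = "T2w"
    session_count = 0
    for si in range(n_subjects):
        subject = f"S{si + 1:03d}"
        n_tp = 3 if si < extra else 2
        for ti in range(n_tp):
            session_count += 1
            for qi, seq in enumerate(sequences):
                vseed = (seed * 7_919 + si * 1_009 + ti * 97 + qi) % (2 ** 31)
                vol, _ = make_volume("ellipsoid_brain", shape, (1.0, 1.0, 1.0),
                                     params={"noise_sigma": 2.0}, seed=vseed)
                _register_volume(project, vol, {
                    "subject": subject, "timepoint": f"T{ti}",
                    "sequence_name": seq})
    assert session_count == n_sessions
    save_project(project)
    return project


def random_affine(rng: np.random.Generator,
                  voxel_mm: Sequence[float] = (1.0, 1.0, 2.0)) -> np.ndarray:
    """Random rigid affine: uniform random rotation, random origin."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    affine = np.eye(4)
    affine[:3, :3] = rot @ np.diag(voxel_mm)
    affine[:3, 3] = rng.uniform(-50, 50, size=3)
    return affine


_UID_ROOT = "1.2.826.0.1.3680043.8.498."


def make_dicom_series(volume: ScanVolume, meta: dict | None = None,
                      out_dir: str | Path = ".", seed: int = 0) -> Path:
    """Write a 3D volume as one single-frame DICOM file per slice.

    Geometry tags (ImageOrientationPatient, ImagePositionPatient,
    PixelSpacing) are derived from the volume's RAS+ affine, so
    :func:`voxpipe.convert.convert_dicom_series` recovers the array and
    affine. Pixel data is int16.
    """
    meta = dict(meta or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(volume.array)
    if arr.ndim != 3:
        raise ValueError("DICOM series writer expects a 3D volume")
    arr16 = np.round(arr).astype(np.int16)
    affine_lps = np.diag([-1.0, -1.0, 1.0, 1.0]) @ volume.affine
    col_step = affine_lps[:3, 0]          # row index direction
    row_step = affine_lps[:3, 1]          # column index direction
    slice_step = affine_lps[:3, 2]
    ps_row = float(np.linalg.norm(col_step))
    ps_col = float(np.linalg.norm(row_step))
    iop = list(np.concatenate([row_step / ps_col, col_step / ps_row]))
    series_uid = generate_uid(prefix=_UID_ROOT,
                              entropy_srcs=[f"series-{seed}"])
    study_uid = generate_uid(prefix=_UID_ROOT, entropy_srcs=[f"study-{seed}"])
    n_slices = arr16.shape[2]
    for k in range(n_slices):
        fm = FileMetaDataset()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        fm.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        fm.MediaStorageSOPInstanceUID = generate_uid(
            prefix=_UID_ROOT, entropy_srcs=[f"sop-{seed}-{k}"])
        ds = FileDataset(None, {}, file_meta=fm, preamble=b"\x00" * 128)
        ds.SOPClassUID = fm.MediaStorageSOPClassUID
        ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = meta.get("SeriesInstanceUID", series_uid)
        ds.StudyInstanceUID = study_uid
        ds.Modality = meta.get("Modality", "MR")
        ds.SeriesDescription = meta.get("SeriesDescription", "synthetic")
        ds.PatientName = meta.get("PatientName", "PHANTOM")
        ds.PatientID = meta.get("PatientID", "PHANTOM")
        if "RepetitionTime" in meta:
            ds.RepetitionTime = str(meta["RepetitionTime"])
        if "EchoTime" in meta:
            ds.EchoTime = str(meta["EchoTime"])
        if "FlipAngle" in meta:
            ds.FlipAngle = str(meta["FlipAngle"])
        if "AcquisitionDateTime" in meta:
            ds.AcquisitionDateTime = meta["AcquisitionDateTime"]
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [f"{v:.10f}" for v in iop]
        pos = affine_lps[:3, 3] + k * slice_step
        ds.ImagePositionPatient = [f"{v:.10f}" for v in pos]
        ds.PixelSpacing = [f"{ps_row:.10f}", f"{ps_col:.10f}"]
        ds.SliceThickness = f"{float(np.linalg.norm(slice_step)):.10f}"
        ds.Rows, ds.Columns = arr16.shape[0], arr16.shape[1]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = np.ascontiguousarray(arr16[:, :, k]).tobytes()
        ds.save_as(out_dir / f"slice_{k:04d}.dcm", enforce_file_format=True)
    return out_dir
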