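"""Quantitative read-outs: per-ROI first-order statistics, histograms,
paired values, time-courses, world-point sampling and longitudinal tables.

Conventions: standard deviation is the population form (divides by N);
voxel indices are 0-based; world coordinates are mm, RAS+. ROI masks are
resampled to the scan grid with nearest-neighbour interpolation so they
stay binary; scans sampled on foreign grids use trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import ops
from .volume import RoiMask, ScanVolume, voxel_volume_mm3

__all__ = [
    "RoiStats",
    "roi_first_order_stats",
    "voxel_timecourse",
    "roi_histogram",
    "joint_values",
    "sample_at_world_point",
    "longitudinal_compare",
]


@dataclass(frozen=True)
class RoiStats:
    """First-order intensity statistics within a mask."""

    mean: float
    std: float
    median: float
    min: float
    max: float
    n_voxels: int
    volume_mm3: float
    n_nan: int = 0


def _in_mask_values(scan: ScanVolume, roi: RoiMask) -> tuple[np.ndarray, int]:
    mask = ops._roi_on_grid(roi, scan).astype(bool)
    if scan.array.ndim > 3:
        raise ValueError("first-order stats expect a 3D scan (select a frame first)")
    if not mask.any():
        raise ValueError("empty ROI")
    vals = scan.array[mask].astype(np.float64)
    finite = np.isfinite(vals)
    return vals[finite], int((~finite).sum())


def roi_first_order_stats(scan: ScanVolume, roi: RoiMask) -> RoiStats:
    """Mean/std/median/extrema/voxel count/volume within the ROI.

    NaN voxels are excluded from the moments and reported via ``n_nan``;
    ``n_voxels`` and the mm^3 volume (``n_voxels x |det|`` of the affine's
    3x3 block) count every in-mask voxel on the scan grid, NaN included.
    """
    vals, n_nan = _in_mask_values(scan, roi)
    if vals.size == 0:
        raise ValueError("empty ROI (all in-mask voxels are NaN)")
    n_total = vals.size + n_nan
    return RoiStats(
        mean=float(vals.mean()),
        std=float(vals.std()),          # population (N), not N-1
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        n_voxels=int(n_total),
        volume_mm3=float(n_total * voxel_volume_mm3(scan.affine)),
        n_nan=n_nan,
    )


def voxel_timecourse(scan4d: ScanVolume, voxel_index: Sequence[int]) -> np.ndarray:
    """Values of one voxel along the fourth dimension."""
    if scan4d.array.ndim < 4:
        raise ValueError("time-course requires a 4D (or higher) scan")
    i, j, k = (int(v) for v in voxel_index[:3])
    series = scan4d.array[i, j, k]
    return np.asarray(series[..., 0] if series.ndim > 1 else series)


def roi_histogram(scan: ScanVolume, roi: RoiMask,
                  bins: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of in-mask finite intensities; edges span min..max."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    vals, _ = _in_mask_values(scan, roi)
    if vals.size == 0:
        raise ValueError("empty ROI (all in-mask voxels are NaN)")
    counts, edges = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
    return edges, counts


def joint_values(scan_a: ScanVolume, scan_b: ScanVolume,
                 roi: RoiMask) -> pd.DataFrame:
    """Paired (a, b) intensities over the ROI grid, NaN pairs dropped.

    Both scans are resampled (trilinear) onto the ROI's own grid so that
    each in-mask voxel contributes exactly one pair; pair order follows
    the voxel scan order of the ROI grid.
    """
    ref = ScanVolume(array=roi.array, affine=roi.affine)
    a = ops.reslice_to_reference(scan_a, ref).array
    b = ops.reslice_to_reference(scan_b, ref).array
    mask = roi.array.astype(bool)
    pa, pb = a[mask], b[mask]
    ok = np.isfinite(pa) & np.isfinite(pb)
    return pd.DataFrame({"a": pa[ok], "b": pb[ok]})


def sample_at_world_point(scans: Sequence[ScanVolume],
                          xyz_mm: Sequence[float]) -> list[float]:
    """Sample each scan at the same world point (trilinear); outside -> NaN."""
    from scipy import ndimage
    point = np.asarray(list(xyz_mm) + [1.0], dtype=float)
    out = []
    for scan in scans:
        vox = (np.linalg.inv(scan.affine) @ point)[:3]
        arr = scan.array
        if arr.ndim > 3:
            arr = arr[(...,) + (0,) * (arr.ndim - 3)]
        value = ndimage.map_coordinates(arr.astype(np.float64),
                                        vox.reshape(3, 1), order=1,
                                        mode="constant", cval=np.nan)[0]
        out.append(float(value))
    return out


def longitudinal_compare(scans_by_timepoint: dict[str, ScanVolume],
                         roi: RoiMask) -> dict:
    """Compare one subject's scans across timepoints within a ROI.

    All scans are resliced (trilinear) onto the first timepoint's grid;
    the result carries per-timepoint first-order statistics plus pairwise
    mean-absolute-difference summaries — enough to check a coregistration
    and run volumetric follow-up.
    """
    if len(scans_by_timepoint) < 2:
        raise ValueError("longitudinal comparison needs >= 2 timepoints")
    tps = list(scans_by_timepoint)
    ref = scans_by_timepoint[tps[0]]
    resliced = {tps[0]: ref}
    for tp in tps[1:]:
        resliced[tp] = ops.reslice_to_reference(scans_by_timepoint[tp], ref)
    mask = ops._roi_on_grid(roi, ref).astype(bool)
    per_tp = {
        tp: roi_first_order_stats(vol, RoiMask(array=mask.astype(np.uint8),
                                               affine=ref.affine))
        for tp, vol in resliced.items()
    }
    pairwise = []
    for i, t1 in enumerate(tps):
        for t2 in tps[i + 1:]:
            d = resliced[t1].array[mask].astype(float) - resliced[t2].array[mask].astype(float)
            ok = np.isfinite(d)
            pairwise.append({
                "timepoint_a": t1, "timepoint_b": t2,
                "mean_abs_diff": float(np.abs(d[ok]).mean()) if ok.any() else float("nan"),
                "max_abs_diff": float(np.abs(d[ok]).max()) if ok.any() else float("nan"),
            })
    stats_table = pd.DataFrame(
        [{"timepoint": tp, **vars(st)} for tp, st in per_tp.items()]
    )
    return {"per_timepoint": stats_table, "pairwise": pd.DataFrame(pairwise)}
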