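"""Image-processing primitives behind the built-in pipeline modules.

All functions consume and produce :class:`~voxpipe.volume.ScanVolume` /
:class:`~voxpipe.volume.RoiMask` objects and are affine-honest: the output
affine equals the input (or reference) affine exactly; only
:func:`reslice_to_reference` (and ROI resampling inside
:func:`mask_with_roi`) moves data between grids.
"""

from __future__ import annotations

import base64
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import RoiMask, ScanVolume, voxel_sizes

__all__ = [
    "smooth", "threshold", "mask_with_roi", "reslice_to_reference",
    "resample_isotropic", "brain_extract", "ct_preprocess", "entropy_map",
    "active_contour_roi", "export_stats_csv", "html_report",
]


def _per_axis_sigma_voxels(vol: ScanVolume, size: float, unit: str) -> np.ndarray:
    if unit == "mm":
        return size / voxel_sizes(vol.affine)
    if unit == "voxel":
        return np.full(3, float(size))
    raise ValueError(f"unit must be 'mm' or 'voxel', got {unit!r}")


def smooth(scan: ScanVolume, dimension: str = "3D", size: float = 2.0,
           unit: str = "mm") -> ScanVolume:
    """Gaussian smoothing, per-slice (2D) or volumetric (3D).

    ``size`` is the Gaussian standard deviation, in mm by default
    (converted per axis by the voxel size) or directly in voxels with
    ``unit="voxel"``. Borders are handled by reflection; output dtype is
    float.
    """
    if size <= 0:
        raise ValueError(f"filter size must be > 0, got {size}")
    if dimension not in ("2D", "3D"):
        raise ValueError(f"dimension must be '2D' or '3D', got {dimension!r}")
    sigma3 = _per_axis_sigma_voxels(scan, size, unit)
    if dimension == "2D":
        sigma3[2] = 0.0
    sigma = np.concatenate([sigma3, np.zeros(scan.ndim - 3)])
    out = ndimage.gaussian_filter(scan.array.astype(np.float64), sigma=sigma,
                                  mode="reflect")
    return scan.copy_with(array=out)


def threshold(scan: ScanVolume, cutoff: float, direction: str = "above",
              output: str = "mask") -> ScanVolume | RoiMask:
    """Strict intensity threshold.

    ``direction="above"`` keeps voxels strictly greater than ``cutoff``,
    ``"below"`` strictly smaller. ``output="mask"`` returns a binary ROI
    (3D input only); ``"clipped"`` zeroes the out-of-range voxels.
    """
    if direction not in ("above", "below"):
        raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")
    if output not in ("mask", "clipped"):
        raise ValueError(f"output must be 'mask' or 'clipped', got {output!r}")
    arr = scan.array
    with np.errstate(invalid="ignore"):
        keep = arr > cutoff if direction == "above" else arr < cutoff
    keep &= np.isfinite(arr)
    if output == "mask":
        if arr.ndim != 3:
            raise ValueError("mask output requires a 3D scan")
        return RoiMask(array=keep.astype(np.uint8), affine=scan.affine.copy(),
                       sidecar=dict(scan.sidecar))
    out = np.where(keep, arr, 0)
    return scan.copy_with(array=out)


def _roi_on_grid(roi: RoiMask, target: ScanVolume) -> np.ndarray:
    """ROI mask resampled (nearest-neighbour) onto the target's 3D grid."""
    same_grid = (roi.array.shape == target.array.shape[:3]
                 and np.allclose(roi.affine, target.affine, atol=1e-9))
    if same_grid:
        return roi.array
    res = reslice_to_reference(roi, target, interpolation="nearest")
    return res.array.astype(np.uint8)


def mask_with_roi(scan: ScanVolume, roi: RoiMask, fill: float = 0) -> ScanVolume:
    """Set voxels outside the ROI to ``fill`` (0 or NaN); inside untouched.

    The ROI is resampled to the scan grid with nearest-neighbour
    interpolation when the grids differ; extra (4th/5th) dimensions are
    masked slice-wise with the same 3D mask.
    """
    mask = _roi_on_grid(roi, scan).astype(bool)
    arr = scan.array
    if np.isnan(fill) and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
    full_mask = mask.reshape(mask.shape + (1,) * (arr.ndim - 3))
    out = np.where(full_mask, arr, fill)
    return scan.copy_with(array=out)


def reslice_to_reference(scan: ScanVolume, reference: ScanVolume,
                         interpolation: str = "trilinear") -> ScanVolume:
    """Resample a volume onto a reference grid (shape + affine).

    Each output voxel is sampled at the world point obtained by composing
    the reference affine with the inverse of the scan affine. Out-of-field
    voxels are NaN for float output (trilinear) and 0 for nearest /
    integer output. Extra dimensions are resliced frame by frame.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    transform = np.linalg.inv(scan.affine) @ reference.affine
    matrix, offset = transform[:3, :3], transform[:3, 3]
    out_shape = reference.array.shape[:3]
    arr = scan.array
    is_mask = isinstance(scan, RoiMask)
    if interpolation == "nearest":
        order, cval, dtype = 0, 0, arr.dtype
        src = arr
    else:
        order, cval, dtype = 1, np.nan, np.float64
        src = arr.astype(np.float64)
    extra = arr.shape[3:]
    flat = src.reshape(arr.shape[:3] + (-1,))
    frames = []
    for f in range(flat.shape[3]):
        frames.append(ndimage.affine_transform(
            flat[..., f], matrix, offset=offset, output_shape=out_shape,
            order=order, mode="constant", cval=cval))
    out = np.stack(frames, axis=-1).reshape(out_shape + extra).astype(dtype, copy=False)
    if is_mask:
        return RoiMask(array=out, affine=reference.affine.copy(),
                       sidecar=dict(scan.sidecar))
    return scan.copy_with(array=out, affine=reference.affine.copy())


def resample_isotropic(scan: ScanVolume, voxel_mm: float = 1.0,
                       interpolation: str = "trilinear") -> ScanVolume:
    """Resample onto an isotropic grid of the requested voxel size.

    The new grid keeps the world origin and axis directions of the input
    and covers the same field of view.
    """
    if voxel_mm <= 0:
        raise ValueError("voxel_mm must be > 0")
    old_sizes = voxel_sizes(scan.affine)
    shape3 = np.array(scan.array.shape[:3])
    new_shape = np.maximum(1, np.ceil(shape3 * old_sizes / voxel_mm)).astype(int)
    directions = scan.affine[:3, :3] / old_sizes
    new_affine = np.eye(4)
    new_affine[:3, :3] = directions * voxel_mm
    new_affine[:3, 3] = scan.affine[:3, 3]
    ref = ScanVolume(array=np.zeros(tuple(new_shape), dtype=np.uint8),
                     affine=new_affine)
    return reslice_to_reference(scan, ref, interpolation=interpolation)


def _largest_component(mask: np.ndarray, connectivity: int = 3) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _ellipsoid_structure(radius_mm: float, vox_sizes: np.ndarray) -> np.ndarray:
    r_vox = np.maximum(1, np.round(radius_mm / vox_sizes)).astype(int)
    zz, yy, xx = np.ogrid[-r_vox[0]:r_vox[0] + 1,
                          -r_vox[1]:r_vox[1] + 1,
                          -r_vox[2]:r_vox[2] + 1]
    return ((zz / r_vox[0]) ** 2 + (yy / r_vox[1]) ** 2
            + (xx / r_vox[2]) ** 2) <= 1.0


def brain_extract(scan: ScanVolume, closing_radius_mm: float = 2.0) -> RoiMask:
    """Simplified intensity/morphology brain extraction.

    Otsu threshold on the finite intensities, keep the largest
    26-connected foreground component, morphologically close it with an
    ellipsoidal element of the given radius (mm), and fill internal
    holes. The result is a single connected component with no holes.
    """
    if scan.array.ndim != 3:
        raise ValueError("brain extraction expects a 3D anatomical scan")
    arr = np.nan_to_num(scan.array.astype(np.float64), nan=0.0)
    if not np.any(arr != arr.flat[0]):
        raise ValueError("no foreground: image is constant")
    thr = threshold_otsu(arr)
    fg = arr > thr
    if not fg.any():
        raise ValueError("no foreground after threshold")
    comp = _largest_component(fg)
    selem = _ellipsoid_structure(closing_radius_mm, voxel_sizes(scan.affine))
    closed = ndimage.binary_closing(comp, structure=selem)
    filled = ndimage.binary_fill_holes(closed)
    final = _largest_component(filled)
    return RoiMask(array=final.astype(np.uint8), affine=scan.affine.copy(),
                   sidecar=dict(scan.sidecar))


def ct_preprocess(ct_scan: ScanVolume, hu_window: Sequence[float] = (0.0, 100.0),
                  smooth_sigma: float = 1.0,
                  resample_mm: float | None = None) -> tuple[ScanVolume, RoiMask]:
    """CT preparation: resize, clip, filter and extract the brain.

    Stages: optional isotropic resampling (``resample_mm``), clamping the
    intensities to the Hounsfield window (default 0..100 HU), Gaussian
    filtering (default sigma 1 mm), thresholding the filtered
    soft-tissue-window image above zero, keeping the largest component
    and filling holes. Voxels outside the open HU window (skull, air)
    never enter the mask. Returns (clipped scan, brain ROI).
    """
    lo, hi = float(hu_window[0]), float(hu_window[1])
    if not hi > lo:
        raise ValueError("hu_window must be (low, high) with high > low")
    scan = ct_scan
    if resample_mm is not None:
        scan = resample_isotropic(scan, resample_mm)
    arr = np.nan_to_num(scan.array.astype(np.float64), nan=lo)
    if arr.ndim != 3:
        raise ValueError("CT preprocessing expects a 3D volume")
    clipped = np.clip(arr, lo, hi)
    inside = (arr > lo) & (arr < hi)
    soft = np.where(inside, arr, 0.0)
    smoothed = smooth(scan.copy_with(array=soft), dimension="3D",
                      size=smooth_sigma, unit="mm").array
    fg = smoothed > 0
    comp = _largest_component(fg)
    filled = ndimage.binary_fill_holes(comp)
    mask = filled & inside
    mask = _largest_component(mask)
    clipped_scan = scan.copy_with(array=clipped)
    roi = RoiMask(array=mask.astype(np.uint8), affine=scan.affine.copy(),
                  sidecar=dict(scan.sidecar))
    return clipped_scan, roi


def entropy_map(scan: ScanVolume, radius: int = 3, bins: int = 32,
                window: str = "2D") -> ScanVolume:
    """Local Shannon entropy map, in bits.

    For every voxel, the intensity histogram (``bins`` equal-width bins
    over the global finite intensity range of the input) is computed in a
    square (2D, per slice) or cubic (3D) neighbourhood of side
    ``2*radius + 1``; the value is −Σ p·log2 p. Neighbours outside the
    image (or non-finite) are excluded, so border voxels use smaller
    neighbourhoods. Values lie in [0, log2(bins)].
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if window not in ("2D", "3D"):
        raise ValueError(f"window must be '2D' or '3D', got {window!r}")
    arr = scan.array
    if arr.ndim != 3:
        raise ValueError("entropy map expects a 3D volume")
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("no finite voxels")
    vals = arr[finite]
    vmin, vmax = float(vals.min()), float(vals.max())
    arr_filled = np.where(finite, arr, vmin)
    if vmax > vmin:
        idx = np.floor((arr_filled - vmin) / (vmax - vmin) * bins).astype(np.int64)
        idx = np.clip(idx, 0, bins - 1)
    else:
        idx = np.zeros(arr.shape, dtype=np.int64)
    side = 2 * radius + 1
    kshape = (side, side, 1) if window == "2D" else (side, side, side)
    kernel = np.ones(kshape, dtype=np.float64)

    def boxsum(x: np.ndarray) -> np.ndarray:
        return ndimage.correlate(x, kernel, mode="constant", cval=0.0)

    n_valid = boxsum(finite.astype(np.float64))
    entropy = np.zeros(arr.shape, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        for b in range(bins):
            ind = ((idx == b) & finite).astype(np.float64)
            counts = boxsum(ind)
            p = np.where(n_valid > 0, counts / np.maximum(n_valid, 1), 0.0)
            term = np.where(p > 0, -p * np.log2(p), 0.0)
            entropy += term
    # tiny negative values from float error are clamped; bound by log2(bins)
    entropy = np.clip(entropy, 0.0, np.log2(bins))
    out = scan.copy_with(array=entropy)
    return out


def active_contour_roi(scan: ScanVolume, seed: Sequence[int],
                       tolerance_k: float = 2.5, smoothness_m: int = 2,
                       max_iter: int = 500) -> RoiMask:
    """Seeded iterative region growth producing a connected ROI.

    Starting from the seed voxel, boundary candidates (26-neighbourhood)
    join the region when their intensity lies within ``tolerance_k``
    standard deviations of the current region mean and they touch the
    region through at least ``smoothness_m`` of their 26 neighbours (the
    smoothness term discourages single-voxel tendrils while letting a
    convex front advance). Iterates until a fixed point or ``max_iter``.
    The result always contains the seed.
    """
    arr = scan.array
    if arr.ndim != 3:
        raise ValueError("region growth expects a 3D volume")
    seed = tuple(int(s) for s in seed)
    if len(seed) != 3 or any(s < 0 or s >= n for s, n in zip(seed, arr.shape)):
        raise ValueError(f"seed {seed} outside volume of shape {arr.shape}")
    if not np.isfinite(arr[seed]):
        raise ValueError("seed voxel is not finite")
    region = np.zeros(arr.shape, dtype=bool)
    region[seed] = True
    struct26 = ndimage.generate_binary_structure(3, 3)
    kernel26 = struct26.astype(np.float64)
    kernel26[1, 1, 1] = 0.0
    finite = np.isfinite(arr)
    arrf = np.nan_to_num(arr.astype(np.float64), nan=0.0)
    for _ in range(max_iter):
        vals = arrf[region]
        mean, std = float(vals.mean()), float(vals.std())
        candidates = ndimage.binary_dilation(region, structure=struct26) & ~region & finite
        n_touch = ndimage.correlate(region.astype(np.float64), kernel26,
                                    mode="constant")
        ok = candidates & (np.abs(arrf - mean) <= tolerance_k * std)
        # the smoothness constraint never blocks the very first shell
        if region.sum() > 1:
            ok &= n_touch >= smoothness_m
        if not ok.any():
            break
        region |= ok
    return RoiMask(array=region.astype(np.uint8), affine=scan.affine.copy(),
                   sidecar=dict(scan.sidecar))


# ---------------------------------------------------------------------------
# Reporting


def _stats_row(subject: str, timepoint: str, scan_name: str, roi_name: str,
               scan: ScanVolume, roi: RoiMask) -> dict:
    from .stats import roi_first_order_stats
    st = roi_first_order_stats(scan, roi)
    return {
        "subject": subject, "timepoint": timepoint,
        "scan": scan_name, "roi": roi_name,
        "mean": st.mean, "std": st.std, "median": st.median,
        "min": st.min, "max": st.max,
        "n_voxels": st.n_voxels, "volume_mm3": st.volume_mm3,
    }


def export_stats_csv(items: Iterable[tuple], out_path: str | Path) -> Path:
    """Write first-order ROI statistics as a CSV (one row per pairing).

    ``items`` yields tuples ``(subject, timepoint, scan_name, roi_name,
    ScanVolume, RoiMask)``. Columns: subject, timepoint, scan, roi, mean,
    std, median, min, max, n_voxels, volume_mm3.
    """
    rows = [_stats_row(*item) for item in items]
    if not rows:
        raise ValueError("no scan/ROI pairings to export")
    df = pd.DataFrame(rows)
    out_path = Path(out_path)
    df.to_csv(out_path, index=False, lineterminator="\n")
    return out_path


def merge_stats_csv(fragments: Iterable[str | Path], out_path: str | Path) -> Path:
    """Concatenate per-session stats CSV fragments into one cohort table."""
    frames = [pd.read_csv(f) for f in sorted(Path(p) for p in fragments)]
    if not frames:
        raise ValueError("no fragments to merge")
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(list(df.columns[:4])).reset_index(drop=True)
    out_path = Path(out_path)
    df.to_csv(out_path, index=False, lineterminator="\n")
    return out_path


def _mid_slice_png(scan: ScanVolume, roi: RoiMask | None) -> str:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    z = scan.array.shape[2] // 2
    sl = scan.array[..., z] if scan.array.ndim == 3 else scan.array[..., z, 0]
    fig, ax = plt.subplots(figsize=(2.4, 2.4), dpi=72)
    ax.imshow(np.asarray(sl, dtype=float).T, cmap="gray", origin="lower")
    if roi is not None:
        mask = _roi_on_grid(roi, scan)[..., z]
        if mask.any():
            ax.contour(mask.T, levels=[0.5], colors="r", linewidths=0.8)
    ax.axis("off")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", bbox_inches="tight", pad_inches=0,
                metadata={"Software": None})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def html_report_string(items: Iterable[tuple], timestamp: str = "") -> str:
    """Build the self-contained HTML report body (see :func:`html_report`)."""
    items = list(items)
    if not items:
        raise ValueError("no scan/ROI pairings to report")
    rows = []
    figures = []
    for item in items:
        subject, timepoint, scan_name, roi_name, scan, roi = item
        rows.append(_stats_row(*item))
        png = _mid_slice_png(scan, roi)
        figures.append(
            f'<figure><img src="data:image/png;base64,{png}" '
            f'alt="{subject} {timepoint} {scan_name}"/>'
            f"<figcaption>{subject} / {timepoint} / {scan_name}"
            f" (ROI: {roi_name})</figcaption></figure>"
        )
    df = pd.DataFrame(rows)
    table = df.to_html(index=False, float_format=lambda v: f"{v:.4f}")
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<title>ROI report</title></head><body>"
        f"<h1>ROI statistics report</h1><p>Generated: {timestamp}</p>"
        + "\n".join(figures)
        + table
        + "</body></html>\n"
    )


def html_report(items: Iterable[tuple], out_path: str | Path,
                timestamp: str = "") -> Path:
    """Write a self-contained HTML report: thumbnails + stats table.

    ``items`` as in :func:`export_stats_csv`. Thumbnails are mid-axial
    slices with the ROI contour overlaid, embedded as base64 PNGs so the
    file opens without external assets. Pass a fixed ``timestamp`` string
    for deterministic output.
    """
    out_path = Path(out_path)
    out_path.write_text(html_report_string(items, timestamp))
    return out_path


def delete_files_module(project, selection, remove_files: bool = True) -> int:
    """Prune intermediates: thin delegation to the project store's
    :func:`~voxpipe.project.delete_entries` so pipelines' byproducts can
    be removed with the same referential-integrity guarantees."""
    from .project import delete_entries
    return delete_entries(project, selection, remove_files=remove_files)
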