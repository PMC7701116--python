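"""In-memory image unit: an N-D array plus its 4x4 world affine and sidecar.

Every computational module consumes and produces :class:`ScanVolume` objects.
World coordinates are millimetres in RAS+ orientation; the affine maps
0-based voxel indices to world coordinates and must be invertible with last
row (0, 0, 0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["ScanVolume", "RoiMask", "validate_affine", "voxel_sizes", "voxel_volume_mm3"]


def validate_affine(affine: np.ndarray) -> np.ndarray:
    """Check an affine is 4x4, invertible, with homogeneous last row."""
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.allclose(affine[3], [0, 0, 0, 1]):
        raise ValueError("affine last row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def voxel_sizes(affine: np.ndarray) -> np.ndarray:
    """Per-axis voxel edge lengths in mm (column norms of the 3x3 block)."""
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Volume of one voxel in mm^3 (|det| of the 3x3 block)."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


@dataclass
class ScanVolume:
    """An image array (3D up to 5D) with its world affine and metadata.

    Parameters
    ----------
    array : numpy.ndarray
        Voxel data, at least 3 dimensions (x, y, z[, t[, e]]).
    affine : numpy.ndarray
        4x4 voxel-to-world (mm, RAS+) transform.
    sidecar : dict
        JSON-serializable acquisition metadata; processing history lives
        under the ``"History"`` key.
    """

    array: np.ndarray
    affine: np.ndarray
    sidecar: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim < 3:
            raise ValueError(f"array must be >=3D, got {self.array.ndim}D")
        self.affine = validate_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.array.shape

    @property
    def ndim(self) -> int:
        return self.array.ndim

    @property
    def voxel_sizes(self) -> np.ndarray:
        return voxel_sizes(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return voxel_volume_mm3(self.affine)

    def copy_with(self, array: np.ndarray | None = None,
                  affine: np.ndarray | None = None,
                  sidecar: dict | None = None) -> "ScanVolume":
        import copy
        return ScanVolume(
            array=self.array.copy() if array is None else array,
            affine=self.affine.copy() if affine is None else affine,
            sidecar=copy.deepcopy(self.sidecar) if sidecar is None else sidecar,
        )


class RoiMask(ScanVolume):
    """A binary 3D mask with its own affine.

    Values are coerced to uint8 {0, 1}; any nonzero voxel counts as inside.
    """

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3:
            raise ValueError(f"ROI mask must be 3D, got {arr.ndim}D")
        self.array = (np.nan_to_num(arr, nan=0.0) != 0).astype(np.uint8)
        self.affine = validate_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())
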