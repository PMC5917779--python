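"""Individualized region-of-interest selection and mirror projection.

Visual hand-selective ROIs are the 250 highest-Z voxels per hemisphere
(hands-versus-objects contrast, Z > 2, restricted to occipitotemporal
anatomy), merged bilaterally.  The sensorimotor intact-hand ROI is the 200
highest-Z voxels (hand-versus-feet) in the contralateral pericentral
cortex; the putative missing-hand ROI is its reflection across the
mid-sagittal plane.  A flip-validation utility correlates COPEs sampled
under flipped versus directly localized ROIs across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["RoiMask", "select_roi", "mirror_roi", "merge_bilateral",
           "flip_validation"]


@dataclass
class RoiMask:
    """A set of 0-based voxel indices on a known grid."""

    voxel_indices: np.ndarray  # (n, 3) int array, unique rows
    grid_dims: tuple[int, int, int]
    hemisphere: str = "bilateral"  # left | right | bilateral
    n_requested: int | None = None
    z_threshold: float | None = None
    source_contrast: str = ""

    def __post_init__(self):
        idx = np.asarray(self.voxel_indices, dtype=int)
        if idx.size == 0:
            idx = idx.reshape(0, 3)
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("voxel_indices must be (n, 3)")
        dims = np.asarray(self.grid_dims, dtype=int)
        if np.any(idx < 0) or np.any(idx >= dims):
            raise ValueError("voxel index outside grid")
        # canonical order: sorted by linear index; enforces uniqueness
        lin = np.ravel_multi_index(idx.T, self.grid_dims)
        if np.unique(lin).size != lin.size:
            raise ValueError("duplicate voxel indices")
        order = np.argsort(lin)
        self.voxel_indices = idx[order]
        if self.hemisphere not in ("left", "right", "bilateral"):
            raise ValueError("hemisphere must be left, right or bilateral")

    def __len__(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def linear_indices(self) -> np.ndarray:
        """Row-major flat indices, for indexing T x V arrays."""
        return np.ravel_multi_index(self.voxel_indices.T, self.grid_dims)

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_dims, dtype=np.uint8)
        vol[tuple(self.voxel_indices.T)] = 1
        return vol


def select_roi(z_values: np.ndarray, anatomical_mask: np.ndarray,
               n: int, z_min: float = 2.0, hemisphere: str = "bilateral",
               source_contrast: str = "") -> RoiMask:
    """Top-``n`` voxels of a Z map within an anatomical mask, Z > ``z_min``.

    ``z_values`` is a 3-D Z map, ``anatomical_mask`` a boolean volume of the
    same shape.  Fewer than ``n`` voxels are returned when fewer qualify.
    Ties at the cutoff rank are broken toward the smaller row-major linear
    index, making selection deterministic and invariant to any strictly
    monotone transform of the Z map.
    """
    z_values = np.asarray(z_values, dtype=float)
    mask = np.asarray(anatomical_mask, dtype=bool)
    if z_values.shape != mask.shape:
        raise ValueError("Z map and anatomical mask must share a grid")
    if n <= 0:
        raise ValueError("n must be positive")
    if not mask.any():
        raise ValueError("anatomical mask is empty")

    lin = np.nonzero(mask.ravel())[0]
    z_in = z_values.ravel()[lin]
    qualify = z_in > z_min
    lin, z_in = lin[qualify], z_in[qualify]
    if lin.size == 0:
        raise ValueError(
            f"no voxels exceed Z > {z_min} within the anatomical mask")
    # sort by (-Z, linear index): lexsort's last key is primary
    order = np.lexsort((lin, -z_in))
    keep = lin[order[:n]]
    idx = np.column_stack(np.unravel_index(keep, z_values.shape))
    return RoiMask(voxel_indices=idx, grid_dims=z_values.shape,
                   hemisphere=hemisphere, n_requested=n, z_threshold=z_min,
                   source_contrast=source_contrast)


def mirror_roi(roi: RoiMask, midline_x: float) -> RoiMask:
    """Reflect an ROI across the mid-sagittal plane x = ``midline_x``.

    Each voxel (x, y, z) maps to (2*midline_x - x, y, z); the hemisphere tag
    is swapped.  ``midline_x`` may be half-integral (even-dimension grids);
    the reflected indices must land on the grid.
    """
    new_x = 2.0 * midline_x - roi.voxel_indices[:, 0]
    if not np.allclose(new_x, np.round(new_x)):
        raise ValueError("midline produces non-integral voxel indices")
    new_idx = roi.voxel_indices.copy()
    new_idx[:, 0] = np.round(new_x).astype(int)
    if np.any(new_idx[:, 0] < 0) or np.any(new_idx[:, 0] >= roi.grid_dims[0]):
        raise ValueError("mirrored ROI exits the grid")
    swap = {"left": "right", "right": "left", "bilateral": "bilateral"}
    return RoiMask(voxel_indices=new_idx, grid_dims=roi.grid_dims,
                   hemisphere=swap[roi.hemisphere],
                   n_requested=roi.n_requested, z_threshold=roi.z_threshold,
                   source_contrast=f"mirror({roi.source_contrast})")


def merge_bilateral(left: RoiMask, right: RoiMask) -> RoiMask:
    """Disjoint union of the two per-hemisphere selections."""
    if left.grid_dims != right.grid_dims:
        raise ValueError("ROIs live on different grids")
    both = np.vstack([left.voxel_indices, right.voxel_indices])
    lin = np.ravel_multi_index(both.T, left.grid_dims)
    if np.unique(lin).size != lin.size:
        raise ValueError("hemisphere ROIs overlap; expected disjoint sets")
    n_req = (left.n_requested or 0) + (right.n_requested or 0) or None
    return RoiMask(voxel_indices=both, grid_dims=left.grid_dims,
                   hemisphere="bilateral", n_requested=n_req,
                   z_threshold=left.z_threshold,
                   source_contrast=left.source_contrast)


def flip_validation(copes_flipped, copes_direct) -> tuple[float, int, float]:
    """Pearson correlation across subjects between COPEs sampled under the
    mirrored ROI and under the directly localized ROI.

    Returns ``(r, df, p)`` with df = n - 2.
    """
    a = np.asarray(copes_flipped, dtype=float).ravel()
    b = np.asarray(copes_direct, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector; correlation undefined")
    r, p = sps.pearsonr(a, b)
    return float(r), a.size - 2, float(p)
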