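"""Anatomical component correction (aCompCor-style) for resting-state data.

White-matter and CSF compartments are defined by intensity rules (top
30 000 WM voxels within a standard mask, eroded one voxel in each
direction; bottom 2000 CSF voxels, no erosion).  The first five principal
time courses of each compartment plus six motion traces form the 16-column
nuisance model, which is regressed out of every voxel; residuals are
z-scored per voxel before any connectivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "NuisanceModel",
    "build_wm_mask",
    "build_csf_mask",
    "compcor_eigenvectors",
    "regress_nuisance",
]


@dataclass
class NuisanceModel:
    """T x 16 nuisance design: 5 WM + 5 CSF eigenvariates + 6 motion."""

    wm_eigenvectors: np.ndarray
    csf_eigenvectors: np.ndarray
    motion: np.ndarray

    def __post_init__(self):
        self.wm_eigenvectors = np.asarray(self.wm_eigenvectors, dtype=float)
        self.csf_eigenvectors = np.asarray(self.csf_eigenvectors, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        T = self.motion.shape[0]
        for blk, name in ((self.wm_eigenvectors, "wm"),
                          (self.csf_eigenvectors, "csf")):
            if blk.shape[0] != T:
                raise ValueError(f"{name} eigenvectors disagree on T")
        if self.motion.shape[1] != 6:
            raise ValueError("motion must have 6 columns")

    @property
    def combined(self) -> np.ndarray:
        """The full nuisance block (motion demeaned), 16 columns when both
        compartments yield their 5 components."""
        demeaned = self.motion - self.motion.mean(axis=0)
        return np.column_stack([self.wm_eigenvectors,
                                self.csf_eigenvectors, demeaned])


def _top_k_linear(values: np.ndarray, k: int, largest: bool) -> np.ndarray:
    """Flat indices of the k largest (or smallest) values; ties at the
    cutoff resolved toward the smaller linear index."""
    flat = values.ravel()
    order = np.lexsort((np.arange(flat.size),
                        -flat if largest else flat))
    return np.sort(order[:min(k, flat.size)])


def build_wm_mask(intensity_map: np.ndarray, standard_wm_mask: np.ndarray,
                  n_top: int = 30_000, erode_voxels: int = 1) -> np.ndarray:
    """White-matter noise compartment as a boolean volume.

    Restrict the intensity map to the standard WM mask, keep the ``n_top``
    highest-intensity voxels (all of them if fewer exist), then erode with a
    6-connectivity (face-adjacency) structuring element, one pass per
    ``erode_voxels``, to limit partial voluming with grey matter.
    """
    intensity = np.asarray(intensity_map, dtype=float)
    standard = np.asarray(standard_wm_mask, dtype=bool)
    if intensity.shape != standard.shape:
        raise ValueError("intensity map and standard mask must share a grid")
    if not standard.any():
        raise ValueError("standard WM mask is empty")

    masked = np.where(standard, intensity, -np.inf)
    k = min(n_top, int(standard.sum()))
    keep = _top_k_linear(masked, k, largest=True)
    sel = np.zeros(intensity.shape, dtype=bool)
    sel.ravel()[keep] = True
    sel &= standard

    if erode_voxels > 0:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        sel = ndimage.binary_erosion(sel, structure=structure,
                                     iterations=erode_voxels)
    return sel


def build_csf_mask(intensity_map: np.ndarray, n_bottom: int = 2000,
                   restrict_mask: np.ndarray | None = None) -> np.ndarray:
    """CSF compartment: the ``n_bottom`` lowest-intensity voxels, no erosion."""
    intensity = np.asarray(intensity_map, dtype=float)
    if intensity.size == 0:
        raise ValueError("empty intensity map")
    if restrict_mask is not None:
        restrict = np.asarray(restrict_mask, dtype=bool)
        if restrict.shape != intensity.shape:
            raise ValueError("restrict mask must share the grid")
        working = np.where(restrict, intensity, np.inf)
        limit = int(restrict.sum())
    else:
        working = intensity
        limit = intensity.size
    keep = _top_k_linear(working, min(n_bottom, limit), largest=False)
    sel = np.zeros(intensity.shape, dtype=bool)
    sel.ravel()[keep] = True
    return sel


def compcor_eigenvectors(series: np.ndarray, k: int = 5) -> np.ndarray:
    """First ``k`` principal time courses of a compartment's T x V series.

    Columns (voxels) are demeaned, then the left singular vectors of the
    resulting matrix are returned in order of decreasing singular value
    (these are the eigenvectors of the time-by-time covariance).  Signs are
    fixed by making each component's largest-magnitude sample positive.
    Returns fewer columns if the data have rank below ``k``.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be T x V")
    T, V = X.shape
    if T <= k:
        raise ValueError("need more time points than components")
    if V < 1:
        raise ValueError("compartment has no voxels")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = max(T, V) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    kk = min(k, rank)
    U = U[:, :kk]
    # sign convention: largest-|loading| sample positive
    for j in range(kk):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def regress_nuisance(series: np.ndarray, model: NuisanceModel,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Regress the nuisance model (plus intercept) out of every voxel and
    z-score the residuals.

    Returns ``(residuals, flagged)``: residuals are T x V with per-voxel mean
    0 and sample SD 1; ``flagged`` marks voxels whose residual variance is
    (numerically) zero — these are left as zeros and must be excluded from
    ROI means.
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim != 2:
        raise ValueError("series must be T x V")
    X = np.column_stack([np.ones(Y.shape[0]), model.combined])
    if X.shape[0] != Y.shape[0]:
        raise ValueError("series and nuisance model disagree on T")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    scale = np.nan_to_num(np.abs(Y).max(axis=0), nan=1.0)
    flagged = sd <= 1e-10 * np.maximum(1.0, scale)
    out = np.zeros_like(resid)
    ok = ~flagged
    out[:, ok] = (resid[:, ok] - resid[:, ok].mean(axis=0)) / sd[ok]
    return out, flagged
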