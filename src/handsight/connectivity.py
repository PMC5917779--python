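"""Seed-based visuomotor resting-state connectivity.

For each subject, the mean nuisance-cleaned time series of the missing-hand
(mirrored) and intact-hand sensorimotor ROIs are correlated with the mean
series of the bilateral visual hand-selective ROI; correlations are Fisher
z-transformed.  Because the two sensorimotor hand areas share resting-state
variance, the missing-hand measure is adjusted across the cohort by
regressing out intact-hand visuomotor connectivity, leaving the unique
missing-hand contribution (semi-partial convention: the covariate is
removed from the brain measure only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import RoiMask
from .stats import residualize

__all__ = ["ConnectivityRecord", "roi_mean_series", "fisher_z",
           "adjust_for_intact", "seed_connectivity"]


@dataclass
class ConnectivityRecord:
    """One subject's visuomotor coupling, in Fisher-z units."""

    subject_id: str
    z_missing_visual: float
    z_intact_visual: float
    adjusted_missing: float | None = None  # cohort-level residual


def roi_mean_series(residuals: np.ndarray, roi: RoiMask,
                    flagged: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean time course over an ROI's member voxels.

    ``residuals`` is T x V in the grid's row-major voxel order; voxels
    marked in ``flagged`` (zero-variance after nuisance regression) are
    excluded from the average.
    """
    lin = roi.linear_indices
    if flagged is not None:
        lin = lin[~np.asarray(flagged, dtype=bool)[lin]]
    if lin.size == 0:
        raise ValueError("ROI has no usable voxels after flag exclusion")
    return np.asarray(residuals, dtype=float)[:, lin].mean(axis=1)


def fisher_z(r: float) -> float:
    """Variance-stabilizing Fisher transform, arctanh(r)."""
    r = float(r)
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return float(np.arctanh(r))


def seed_connectivity(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Fisher-z correlation between two ROI mean time courses."""
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant series; correlation undefined")
    return fisher_z(float(np.corrcoef(a, b)[0, 1]))


def adjust_for_intact(z_missing, z_intact) -> np.ndarray:
    """Cohort-level adjustment of missing-hand visuomotor connectivity.

    Returns the residuals of an OLS regression (with intercept) of
    ``z_missing`` on ``z_intact`` across subjects; the result is exactly
    orthogonal to the intact-hand measure and sums to zero.
    """
    z_missing = np.asarray(z_missing, dtype=float).ravel()
    z_intact = np.asarray(z_intact, dtype=float).ravel()
    if z_missing.size != z_intact.size:
        raise ValueError("cohort vectors must have equal length")
    if z_missing.size < 3:
        raise ValueError("need at least 3 subjects")
    return residualize(z_missing, z_intact)
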