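"""First-level general linear model for task fMRI.

Builds design matrices (double-gamma HRF convolution of event or block
timing, six motion regressors, one-hot spike regressors for >1 mm
frame-to-frame movement, discrete-cosine high-pass drift terms, intercept),
fits ordinary least squares per voxel, and combines runs by inverse-variance
fixed effects.

Synthetic data carry white noise, so no prewhitening is applied; residual
degrees of freedom are ``T - rank(X)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DesignMatrix",
    "ContrastMap",
    "GlmFit",
    "double_gamma_hrf",
    "build_design",
    "fit_glm",
    "fixed_effects_combine",
    "spike_volumes",
]

# z statistics are capped at this magnitude; noiseless fits would otherwise
# produce infinities
Z_CAP = 40.0

# rotations (radians) are converted to mm of displacement on a sphere of
# this radius when screening for >1 mm frame-to-frame movement
ROTATION_RADIUS_MM = 50.0


@dataclass
class DesignMatrix:
    """T x P design with labelled, role-tagged columns."""

    values: np.ndarray
    column_labels: list[str]
    column_roles: list[str]  # condition | motion | spike | drift | intercept
    tr: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        T, P = self.values.shape
        if len(self.column_labels) != P or len(self.column_roles) != P:
            raise ValueError("labels/roles must match column count")
        cond = [j for j, r in enumerate(self.column_roles) if r == "condition"]
        for j in cond:
            if np.allclose(self.values[:, j], 0):
                raise ValueError(
                    f"condition column {self.column_labels[j]!r} is all zero")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    def condition_contrast(self, weights: dict[str, float]) -> np.ndarray:
        """Length-P contrast vector from named condition weights."""
        unknown = set(weights) - set(self.column_labels)
        if unknown:
            raise KeyError(f"unknown condition labels: {sorted(unknown)}")
        c = np.zeros(self.n_regressors)
        for name, w in weights.items():
            c[self.column_labels.index(name)] = w
        return c


@dataclass
class ContrastMap:
    """Per-voxel COPE (contrast of parameter estimates), its variance, and
    the associated Z statistic."""

    cope: np.ndarray
    var_cope: np.ndarray
    z: np.ndarray
    contrast_vector: np.ndarray
    dof: int


def double_gamma_hrf(dt: float, duration: float = 32.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response function sampled at dt.

    Difference of two gamma densities: response peak at 6 s, undershoot peak
    at 16 s, dispersion 1 s each, undershoot scaled by ``undershoot_ratio``.
    The kernel is normalized to unit peak and is 0 at t = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    # gamma density parametrized by peak delay d and dispersion 1:
    # shape a = d, scale 1  ->  mode at d - 1... use the standard SPM-style
    # parametrization: shape = delay/dispersion, scale = dispersion
    peak = sps.gamma.pdf(t, a=6.0, scale=1.0)
    under = sps.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot_ratio * under
    m = np.abs(h).max()
    if m > 0:
        h = h / h.max()
    return h


def spike_volumes(motion: np.ndarray, threshold_mm: float = 1.0,
                  rotation_radius_mm: float = ROTATION_RADIUS_MM) -> np.ndarray:
    """Indices of volumes whose frame-to-frame motion exceeds threshold.

    Motion is T x 6 (three rotations in radians, three translations in mm, or
    any 6-parameter layout whose last three columns are translations).  The
    metric is the maximum absolute parameter change between consecutive
    volumes, with rotations expressed as arc displacement on a 50 mm sphere.
    The later volume of an offending pair is flagged.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    diffs = np.abs(np.diff(motion, axis=0))
    diffs[:, :3] *= rotation_radius_mm  # radians -> mm on sphere
    exceeded = diffs.max(axis=1) > threshold_mm
    return np.nonzero(exceeded)[0] + 1


def _dct_drift_basis(n_vols: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors for frequencies below 1/cutoff."""
    duration = n_vols * tr
    order = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_vols)
    cols = [np.cos(np.pi * (t + 0.5) * k / n_vols) for k in range(1, order + 1)]
    if not cols:
        return np.empty((n_vols, 0))
    return np.column_stack(cols)


def build_design(
    events: pd.DataFrame,
    motion: np.ndarray | None,
    tr: float,
    n_vols: int,
    spike_threshold_mm: float = 1.0,
    hp_cutoff_s: float = 100.0,
    microtime: int = 16,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    ``events`` is a BIDS-style table with columns onset, duration, trial_type
    (seconds).  Each condition is modelled by a boxcar at microtime
    resolution convolved with the double-gamma HRF and sampled at volume
    acquisition times; six motion columns (demeaned), one one-hot spike
    column per >1 mm movement volume, cosine drift terms below the high-pass
    cutoff, and an intercept complete the matrix.
    """
    if tr <= 0 or n_vols < 1:
        raise ValueError("tr and n_vols must be positive")
    scan_end = n_vols * tr
    cols: list[np.ndarray] = []
    labels: list[str] = []
    roles: list[str] = []

    if events is not None and len(events):
        required = {"onset", "duration", "trial_type"}
        if not required.issubset(events.columns):
            raise ValueError(f"events table needs columns {sorted(required)}")
        if (events["onset"] < 0).any() or \
           ((events["onset"] + events["duration"]) > scan_end).any():
            raise ValueError("event extends beyond scan duration")
        dt = tr / microtime
        hrf = double_gamma_hrf(dt)
        n_fine = n_vols * microtime
        sample_idx = np.arange(n_vols) * microtime
        for cond in sorted(events["trial_type"].unique()):
            sub = events[events["trial_type"] == cond]
            boxcar = np.zeros(n_fine)
            for onset, dur in zip(sub["onset"], sub["duration"]):
                i0 = int(round(onset / dt))
                i1 = max(i0 + 1, int(round((onset + dur) / dt)))
                boxcar[i0:min(i1, n_fine)] = 1.0
            conv = np.convolve(boxcar, hrf)[:n_fine]
            cols.append(conv[sample_idx])
            labels.append(str(cond))
            roles.append("condition")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_vols, 6):
            raise ValueError(f"motion must be {n_vols} x 6, got {motion.shape}")
        demeaned = motion - motion.mean(axis=0)
        for j in range(6):
            cols.append(demeaned[:, j])
            labels.append(f"motion_{j}")
            roles.append("motion")
        for k in spike_volumes(motion, spike_threshold_mm):
            onehot = np.zeros(n_vols)
            onehot[k] = 1.0
            cols.append(onehot)
            labels.append(f"spike_{k:03d}")
            roles.append("spike")

    drift = _dct_drift_basis(n_vols, tr, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        labels.append(f"drift_{k + 1}")
        roles.append("drift")

    cols.append(np.ones(n_vols))
    labels.append("intercept")
    roles.append("intercept")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(values=X, column_labels=labels, column_roles=roles,
                        tr=tr)


class GlmFit:
    """A voxelwise OLS fit of one run, reusable across contrasts."""

    def __init__(self, data: np.ndarray, design: DesignMatrix):
        X = design.values
        T, P = X.shape
        data = np.asarray(data, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
        if data.shape[0] != T:
            raise ValueError("data and design disagree on volume count")
        if T <= P:
            raise ValueError("need more volumes than regressors")
        self.design = design
        self.pinv = np.linalg.pinv(X)
        self.beta = self.pinv @ data          # P x V
        resid = data - X @ self.beta
        self.dof = int(T - np.linalg.matrix_rank(X))
        self.sigma2 = np.sum(resid ** 2, axis=0) / self.dof

    def contrast(self, contrast_vector: np.ndarray) -> ContrastMap:
        c = np.asarray(contrast_vector, dtype=float)
        if c.shape != (self.beta.shape[0],):
            raise ValueError(
                f"contrast vector must have length {self.beta.shape[0]}")
        cXXc = float(c @ self.pinv @ self.pinv.T @ c)   # c'(X'X)^-1 c
        cope = c @ self.beta
        var_cope = cXXc * self.sigma2
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = cope / np.sqrt(var_cope)
        tstat = np.nan_to_num(tstat, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP)
        # t -> z via matching tail probabilities
        z = sps.norm.isf(sps.t.sf(np.clip(tstat, -Z_CAP, Z_CAP), self.dof))
        z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP),
                    -Z_CAP, Z_CAP)
        return ContrastMap(cope=cope.squeeze(), var_cope=var_cope.squeeze(),
                           z=z.squeeze(), contrast_vector=c, dof=self.dof)


def fit_glm(data: np.ndarray, design: DesignMatrix,
            contrast_vector: np.ndarray) -> ContrastMap:
    """Voxelwise OLS fit and contrast.

    ``data`` is T x V (V voxels).  Returns per-voxel COPE = c'beta, its
    variance c'(X'X)^-1 c * sigma2, and a Z statistic from the t statistic
    with ``T - rank(X)`` dof via the normal quantile transform (capped at
    +/- 40 where noiseless voxels would diverge).  To evaluate several
    contrasts on one run, construct :class:`GlmFit` once and call its
    ``contrast`` method.
    """
    return GlmFit(data, design).contrast(contrast_vector)


def fixed_effects_combine(maps: list[ContrastMap]) -> ContrastMap:
    """Second-level fixed-effects average of run-level contrast maps.

    COPEs are combined with inverse-variance weights; the combined variance
    is ``1 / sum(1/var)`` and Z is the combined effect over its standard
    error (normal reference, df pooled across runs).
    """
    if not maps:
        raise ValueError("no maps to combine")
    if len(maps) == 1:
        return maps[0]
    copes = np.stack([np.atleast_1d(m.cope) for m in maps])
    varis = np.stack([np.atleast_1d(m.var_cope) for m in maps])
    with np.errstate(divide="ignore"):
        w = 1.0 / varis
    # voxels with zero variance in any run: fall back to equal weights there
    bad = ~np.all(np.isfinite(w), axis=0)
    w[:, bad] = 1.0
    combined = np.sum(w * copes, axis=0) / np.sum(w, axis=0)
    var_combined = 1.0 / np.sum(w, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = combined / np.sqrt(var_combined)
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP),
                -Z_CAP, Z_CAP)
    dof = int(sum(m.dof for m in maps))
    return ContrastMap(cope=combined.squeeze(), var_cope=var_combined.squeeze(),
                       z=z.squeeze(), contrast_vector=maps[0].contrast_vector,
                       dof=dof)
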