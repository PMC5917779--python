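"""Synthetic cohort generator.

Emulates the study population every downstream stage assumes: one-handers
(congenital or acquired hand loss) with zero-inflated prosthesis-usage
questionnaires and age-matched controls with a prosthesis observation
analogue, plus per-subject "preprocessed" imaging: an event-related visual
task (hands / objects / active / cosmetic prosthesis images, 1.5 s stimuli,
2.5 s fixation, 9 trials per condition per run, 4 runs), a block motor
localizer (12 s movement/rest), a resting-state run, tissue intensity maps
and 6-column motion traces with occasional >1 mm jumps.

Effect planting: after the behavioural cohort is drawn, per-subject latent
variables are mixed with the standardized usage (or observation) composite
so that their empirical correlation equals the configured rho exactly
(Cholesky-style mixing with an orthogonalized noise vector).  Those latents
scale (a) the visual-cortex response amplitude to prosthesis images and
(b) the resting-state coupling between the missing-hand sensorimotor blob
and the visual blobs.  Everything is deterministic given the master seed;
per-subject noise streams derive from a stable hash of the subject id, so a
subject's data do not change when the cohort is resized.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .behaviour import usage_table
from .glm import build_design

__all__ = [
    "CohortConfig", "SubjectData", "GridLabels", "plant_bivariate",
    "build_labels", "make_behaviour", "make_truth", "generate_subject_data",
    "iter_subject_data", "generate_cohort",
]

VISUAL_CONDITIONS = ("hands", "objects", "prosthesis_active",
                     "prosthesis_cosmetic")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the emulated study: 31 analysis-eligible one-handers
    and 24 controls (of whom 3 lack the observation questionnaire and 2 the
    motor localizer), 4 visual runs, a 230-volume rest scan, and planted
    usage-activity / usage-connectivity correlations of 0.5 / 0.55.
    """

    n_onehanders: int = 31
    n_controls: int = 24
    grid_dims: tuple[int, int, int] = (24, 24, 16)
    tr_task: float = 1.3
    tr_rest: float = 1.3
    tr_localizer: float = 2.0
    n_vols_task: int = 120
    n_vols_rest: int = 230
    n_runs_task: int = 4
    trials_per_condition: int = 9
    stim_duration_s: float = 1.5
    fixation_s: float = 2.5
    localizer_block_s: float = 12.0
    localizer_reps: int = 4
    rho_usage_activity: float = 0.5
    rho_usage_activity_cosmetic: float = 0.33
    rho_usage_connectivity: float = 0.55
    rho_observation_activity: float = 0.0
    rho_observation_connectivity: float = 0.0
    noise_sd: float = 1.0
    rest_noise_sd: float = 0.5
    seed: int = 0
    frac_congenital: float = 0.5
    frac_cosmetic_primary: float = 0.5
    controls_missing_questionnaire: int = 3
    controls_without_localizer: int = 2
    spike_rate: float = 0.02
    baseline: float = 100.0

    def __post_init__(self):
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.n_onehanders < 4 or self.n_controls < 4:
            raise ValueError("need at least 4 subjects per group")
        nx, ny, nz = self.grid_dims
        if nx < 12 or ny < 12 or nz < 8:
            raise ValueError("grid too small for the anatomical layout")
        for name in ("rho_usage_activity", "rho_usage_activity_cosmetic",
                     "rho_usage_connectivity", "rho_observation_activity",
                     "rho_observation_connectivity"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"{name} must lie in [-1, 1]")
            if abs(getattr(self, name)) == 1 and self.noise_sd == 0:
                raise ValueError(f"degenerate config: |{name}| = 1 with zero noise")
        if self.noise_sd < 0 or self.rest_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.tr_task <= 0 or self.tr_rest <= 0 or self.tr_localizer <= 0:
            raise ValueError("TRs must be positive")
        if self.controls_missing_questionnaire > self.n_controls - 4:
            raise ValueError("too few controls would retain questionnaires")
        scan_s = self.n_vols_task * self.tr_task
        need_s = 8.0 + len(VISUAL_CONDITIONS) * self.trials_per_condition * (
            self.stim_duration_s + self.fixation_s)
        if scan_s < need_s:
            raise ValueError(
                f"n_vols_task covers {scan_s:.0f} s but the event schedule "
                f"needs {need_s:.0f} s")

    @property
    def midline_x(self) -> float:
        """Mid-sagittal plane index; half-integral on even-width grids."""
        return (self.grid_dims[0] - 1) / 2.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# anatomical layout
# ---------------------------------------------------------------------------

@dataclass
class GridLabels:
    """Boolean anatomical compartments on the synthetic grid.

    Stand-ins for the atlas restrictions used with real data: bilateral
    occipitotemporal ("visual") and pericentral ("sensorimotor") grey-matter
    boxes, a central white-matter block and a CSF block, mirror-symmetric
    about the mid-sagittal plane where lateralized.
    """

    grid_dims: tuple[int, int, int]
    visual_left: np.ndarray
    visual_right: np.ndarray
    sm_left: np.ndarray
    sm_right: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def hemisphere_mask(self, side: str, kind: str) -> np.ndarray:
        return getattr(self, f"{kind}_{side}")

    def label_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid_dims, dtype=np.int16)
        for code, mask in enumerate(
                [self.visual_left, self.visual_right, self.sm_left,
                 self.sm_right, self.wm, self.csf], start=1):
            vol[mask] = code
        return vol


def _box(shape, xs, ys, zs) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[xs, ys, zs] = True
    return m


def build_labels(grid_dims) -> GridLabels:
    nx, ny, nz = grid_dims
    half = nx // 2
    wx = max(3, half // 2)
    x_left = slice(1, 1 + wx)
    x_right = slice(nx - 1 - wx, nx - 1)

    vis_y = slice(max(1, ny // 8), max(1, ny // 8) + max(3, ny // 4))
    vis_z = slice(max(1, nz // 4), max(1, nz // 4) + max(3, nz // 3))
    sm_y = slice(ny - max(3, ny // 6) - 2, ny - 2)
    sm_z = slice(nz // 2, min(nz - 1, nz // 2 + max(3, nz // 3)))
    wm_x = slice(half - max(2, nx // 8), half + max(2, nx // 8))
    wm_y = slice(1, max(4, ny // 2 - 2))
    wm_z = slice(1, nz - 1)
    csf_y = slice(vis_y.stop + 1, sm_y.start - 1)
    csf_z = slice(1, max(4, nz // 2 - 1))
    if csf_y.stop - csf_y.start < 2:
        raise ValueError("grid too small to separate CSF from grey matter")

    shape = tuple(grid_dims)
    return GridLabels(
        grid_dims=shape,
        visual_left=_box(shape, x_left, vis_y, vis_z),
        visual_right=_box(shape, x_right, vis_y, vis_z),
        sm_left=_box(shape, x_left, sm_y, sm_z),
        sm_right=_box(shape, x_right, sm_y, sm_z),
        wm=_box(shape, wm_x, wm_y, wm_z),
        csf=_box(shape, x_right, csf_y, csf_z),
    )


def _radial_profile(mask: np.ndarray, floor: float = 0.6) -> np.ndarray:
    """Amplitude profile over a blob: 1 at the centroid, ``floor`` at the
    rim. Gives top-voxel selection a stable spatial gradient."""
    idx = np.argwhere(mask)
    center = idx.mean(axis=0)
    d = np.linalg.norm(idx - center, axis=1)
    dmax = d.max() if d.max() > 0 else 1.0
    prof = np.zeros(mask.shape)
    prof[tuple(idx.T)] = 1.0 - (1.0 - floor) * d / dmax
    return prof


# ---------------------------------------------------------------------------
# effect planting
# ---------------------------------------------------------------------------

def _std0(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (v - v.mean()) / sd


def plant_bivariate(scores, rho: float, noise_sd: float | None = None,
                    seed=None) -> np.ndarray:
    """A latent vector whose correlation with ``scores`` is ``rho``.

    The standardized score vector is mixed with a standardized noise vector
    orthogonalized against it: ``y = rho * z(scores) + noise_sd * e_perp``.
    With the default ``noise_sd = sqrt(1 - rho^2)`` the output has unit
    variance and its empirical Pearson correlation with the scores is
    exactly ``rho``; any other noise scale yields
    ``r = rho / sqrt(rho^2 + noise_sd^2)``.

    ``seed`` may be an int, None, or a ``numpy.random.Generator``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 4:
        raise ValueError("need at least 4 scores")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; cannot plant a correlation")
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    zs = _std0(scores)
    if noise_sd is None:
        noise_sd = math.sqrt(max(0.0, 1.0 - rho ** 2))
    if noise_sd == 0:
        return rho * zs
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    e = rng.standard_normal(scores.size)
    e_perp = e - e.mean() - zs * float(zs @ (e - e.mean())) / float(zs @ zs)
    if np.ptp(e_perp) == 0:  # astronomically unlikely; retry deterministic
        e_perp = np.arange(scores.size) - (scores.size - 1) / 2.0
        e_perp = e_perp - zs * float(zs @ e_perp) / float(zs @ zs)
    return rho * zs + noise_sd * _std0(e_perp)


# ---------------------------------------------------------------------------
# behavioural cohort
# ---------------------------------------------------------------------------

def _subject_seed(master_seed: int, subject_id: str, stream: int) -> np.random.Generator:
    """Per-subject noise stream from a stable hash of the subject id."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    h = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(master_seed), h, stream)))


def _draw_onehander(rng: np.random.Generator) -> dict:
    wear = int(rng.choice(6, p=[0.30, 0.10, 0.13, 0.07, 0.07, 0.33]))
    if wear == 0:
        f = 0.0 if rng.random() < 0.7 else float(rng.uniform(0.02, 0.15))
    else:
        f = float(rng.uniform(0.05, 0.62))
    items = rng.binomial(2, f, 27)
    cause = "congenital" if rng.random() < 0.5 else "acquired"
    side = "right" if rng.random() < 0.25 else "left"
    if wear == 0 and items.sum() == 0 and rng.random() < 0.4:
        prosthesis = "none"
    elif rng.random() < 0.5:
        prosthesis = "cosmetic"
    else:
        prosthesis = "mechanical" if rng.random() < 0.7 else "myoelectric"
    return dict(items=items, wear_time=wear, cause=cause,
                missing_side=side, primary_prosthesis=prosthesis)


def _draw_control(rng: np.random.Generator) -> dict:
    obs_time = int(rng.choice(6, p=[0.25, 0.20, 0.20, 0.15, 0.10, 0.10]))
    if obs_time == 0:
        f = 0.0 if rng.random() < 0.6 else float(rng.uniform(0.02, 0.1))
    else:
        f = float(rng.uniform(0.03, 0.5))
    items = rng.binomial(2, f, 27)
    side = "right" if rng.random() < 0.33 else "left"  # non-dominant side
    return dict(items=items, wear_time=obs_time, cause="not_applicable",
                missing_side="not_applicable", primary_prosthesis="none",
                nondominant_side=side)


def make_behaviour(config: CohortConfig) -> pd.DataFrame:
    """Behavioural table: one row per subject, MAL/POL items and wear time.

    One-handers follow a zero-inflated usage distribution (a point mass of
    non-users, the rest roughly uniform); the configured number of controls
    get missing questionnaires (NaN items) and the first of them also lack
    the motor localizer.
    """
    rows = []
    for i in range(config.n_onehanders):
        sid = f"sub-oh{i + 1:02d}"
        rng = _subject_seed(config.seed, sid, stream=0)
        d = _draw_onehander(rng)
        # respect configured subgroup fractions at the margin
        d["cause"] = ("congenital"
                      if rng.random() < config.frac_congenital else "acquired")
        if d["primary_prosthesis"] in ("cosmetic", "mechanical", "myoelectric"):
            if rng.random() < config.frac_cosmetic_primary:
                d["primary_prosthesis"] = "cosmetic"
            else:
                d["primary_prosthesis"] = (
                    "mechanical" if rng.random() < 0.7 else "myoelectric")
        rows.append(_behaviour_row(sid, "one_hander", d,
                                   nondominant_side=d["missing_side"],
                                   has_localizer=True))
    for i in range(config.n_controls):
        sid = f"sub-ctl{i + 1:02d}"
        rng = _subject_seed(config.seed, sid, stream=0)
        d = _draw_control(rng)
        missing_q = i < config.controls_missing_questionnaire
        no_loc = i < config.controls_without_localizer
        if missing_q:
            d["items"] = np.full(27, np.nan)
            d["wear_time"] = np.nan
        rows.append(_behaviour_row(sid, "control", d,
                                   nondominant_side=d["nondominant_side"],
                                   has_localizer=not no_loc))
    df = pd.DataFrame(rows)
    # guard against a degenerate draw (all scored subjects identical)
    for grp in ("one_hander", "control"):
        sub = df[(df.group == grp) & df.wear_time.notna()]
        if sub["wear_time"].nunique() <= 1 and \
           sub[[f"mal_{i:02d}" for i in range(1, 28)]].sum(axis=1).nunique() <= 1:
            raise ValueError(f"degenerate cohort: no usage variance in {grp}")
    return df


def _behaviour_row(sid, group, d, nondominant_side, has_localizer) -> dict:
    row = {
        "subject_id": sid, "group": group, "cause": d["cause"],
        "primary_prosthesis": d["primary_prosthesis"],
        "missing_side": d["missing_side"],
        "nondominant_side": nondominant_side,
        "has_localizer": bool(has_localizer),
        "wear_time": d["wear_time"],
    }
    for j in range(27):
        row[f"mal_{j + 1:02d}"] = d["items"][j]
    return row


# ---------------------------------------------------------------------------
# ground-truth latent table
# ---------------------------------------------------------------------------

def make_truth(config: CohortConfig, behaviour: pd.DataFrame) -> pd.DataFrame:
    """Per-subject planted amplitudes and connectivity targets.

    Latents correlated with the group's standardized composite score are
    planted at the configured rho (exactly, within each scored group); the
    unscored subjects receive independent latents.
    """
    scored = usage_table(behaviour)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(int(config.seed), 0x7478)))
    records = {}
    for grp, rho_act, rho_cos, rho_conn in (
        ("one_hander", config.rho_usage_activity,
         config.rho_usage_activity_cosmetic, config.rho_usage_connectivity),
        ("control", config.rho_observation_activity,
         config.rho_observation_activity, config.rho_observation_connectivity),
    ):
        sub = scored[scored.group == grp]
        if len(sub) == 0:
            continue
        u = sub["usage_score"].to_numpy()
        lat_act = plant_bivariate(u, rho_act, seed=rng)
        lat_cos = plant_bivariate(u, rho_cos, seed=rng)
        lat_conn = plant_bivariate(u, rho_conn, seed=rng)
        for k, sid in enumerate(sub["subject_id"]):
            records[sid] = (lat_act[k], lat_cos[k], lat_conn[k])
    rows = []
    for _, b in behaviour.iterrows():
        sid = b["subject_id"]
        la, lc, lk = records.get(
            sid, tuple(rng.standard_normal(3)))  # unscored subjects
        c_obj = float(rng.standard_normal())     # shared visual-load latent
        # one-handers respond more strongly to prosthesis images overall
        grp_off = 0.20 if b["group"] == "one_hander" else 0.0
        rows.append({
            "subject_id": sid,
            "amp_hands": 1.2 + 0.10 * float(rng.standard_normal()),
            "amp_objects": 0.30 + 0.12 * c_obj,
            "amp_active": 0.45 + grp_off + 0.12 * c_obj + 0.30 * float(la),
            "amp_cosmetic": 0.55 + grp_off + 0.12 * c_obj + 0.30 * float(lc),
            "amp_motor_hand": 1.0 + 0.10 * float(rng.standard_normal()),
            "amp_motor_nondom": 0.8 + 0.20 * float(rng.standard_normal()),
            "z_missing_true": 0.35 + 0.40 * float(lk),
            "z_intact_true": 0.35 + 0.40 * float(rng.standard_normal()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-subject imaging data
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One subject's in-memory synthetic session."""

    subject_id: str
    grid_dims: tuple[int, int, int]
    task_runs: list = field(default_factory=list)       # (data4d, events, motion)
    localizer: tuple | None = None                      # (data4d, events, motion)
    rest: tuple | None = None                           # (data4d, motion)
    wm_intensity: np.ndarray | None = None
    csf_intensity: np.ndarray | None = None


def _motion_trace(rng, n_vols: int, spike_rate: float) -> np.ndarray:
    steps = np.empty((n_vols, 6))
    steps[:, :3] = rng.normal(0.0, 4e-4, (n_vols, 3))   # radians
    steps[:, 3:] = rng.normal(0.0, 0.02, (n_vols, 3))   # mm
    spikes = rng.random(n_vols) < spike_rate
    spikes[0] = False
    for t in np.nonzero(spikes)[0]:
        axis = 3 + int(rng.integers(3))
        steps[t, axis] += float(rng.choice([-1, 1]) * rng.uniform(1.1, 1.8))
    return np.cumsum(steps, axis=0)


def _visual_events(config: CohortConfig, rng) -> pd.DataFrame:
    labels = np.repeat(VISUAL_CONDITIONS, config.trials_per_condition)
    order = rng.permutation(labels.size)
    trial_len = config.stim_duration_s + config.fixation_s
    onsets = 8.0 + np.arange(labels.size) * trial_len
    return pd.DataFrame({
        "onset": onsets,
        "duration": config.stim_duration_s,
        "trial_type": labels[order],
    })


def _localizer_events(config: CohortConfig, conditions) -> pd.DataFrame:
    block = config.localizer_block_s
    rows = []
    t = block  # initial rest
    for _ in range(config.localizer_reps):
        for cond in conditions:
            rows.append({"onset": t, "duration": block, "trial_type": cond})
            t += 2 * block  # movement block then rest block
    return pd.DataFrame(rows)


def _condition_columns(events, tr, n_vols):
    design = build_design(events, motion=None, tr=tr, n_vols=n_vols,
                          hp_cutoff_s=math.inf)
    cond = [j for j, r in enumerate(design.column_roles) if r == "condition"]
    labels = [design.column_labels[j] for j in cond]
    return design.values[:, cond], labels


def _slow_drift(rng, n_vols: int, tr: float, amp: float = 0.4) -> np.ndarray:
    period = float(rng.uniform(180.0, 320.0))
    phase = float(rng.uniform(0, 2 * np.pi))
    t = np.arange(n_vols) * tr
    return amp * np.sin(2 * np.pi * t / period + phase)


def generate_subject_data(config: CohortConfig, behaviour_row: pd.Series,
                          truth_row: pd.Series,
                          labels: GridLabels | None = None) -> SubjectData:
    """All imaging data for one subject, deterministic given the master seed."""
    if labels is None:
        labels = build_labels(config.grid_dims)
    sid = str(behaviour_row["subject_id"])
    dims = config.grid_dims
    n_vox = int(np.prod(dims))
    vis_prof = (_radial_profile(labels.visual_left) +
                _radial_profile(labels.visual_right)).ravel()

    # hemisphere bookkeeping: the hemisphere contralateral to the intact
    # (or dominant) hand carries intact-hand signal; its mirror is the
    # missing-hand (non-dominant) territory
    affected = str(behaviour_row["nondominant_side"])  # missing/non-dominant
    # a hand is controlled by the contralateral hemisphere
    missing_hemi = "right" if affected == "left" else "left"
    intact_hemi = "left" if missing_hemi == "right" else "right"
    sm_intact = labels.hemisphere_mask(intact_hemi, "sm")
    sm_missing = labels.hemisphere_mask(missing_hemi, "sm")
    sm_intact_prof = _radial_profile(sm_intact).ravel()
    sm_missing_prof = _radial_profile(sm_missing).ravel()

    out = SubjectData(subject_id=sid, grid_dims=dims)

    # ---- visual task runs -------------------------------------------------
    amps = {
        "hands": float(truth_row["amp_hands"]),
        "objects": float(truth_row["amp_objects"]),
        "prosthesis_active": float(truth_row["amp_active"]),
        "prosthesis_cosmetic": float(truth_row["amp_cosmetic"]),
    }
    for run in range(config.n_runs_task):
        rng = _subject_seed(config.seed, sid, stream=10 + run)
        events = _visual_events(config, rng)
        X, cond_labels = _condition_columns(events, config.tr_task,
                                            config.n_vols_task)
        amp_vec = np.array([amps[c] for c in cond_labels])
        signal_t = X @ np.diag(amp_vec)          # T x C
        data = rng.normal(0.0, config.noise_sd,
                          (config.n_vols_task, n_vox))
        data += config.baseline
        data += _slow_drift(rng, config.n_vols_task, config.tr_task)[:, None]
        # condition responses live in the visual blobs only
        blob = vis_prof > 0
        data[:, blob] += (signal_t.sum(axis=1))[:, None] * vis_prof[blob][None, :]
        motion = _motion_trace(rng, config.n_vols_task, config.spike_rate)
        out.task_runs.append(
            (data.reshape(config.n_vols_task, *dims), events, motion))

    # ---- motor localizer --------------------------------------------------
    if bool(behaviour_row.get("has_localizer", True)):
        conds = ["hand", "feet"]
        if behaviour_row["group"] == "control":
            conds = ["hand", "nondominant_hand", "feet"]
        events = _localizer_events(config, conds)
        total_s = float(events["onset"].iloc[-1] + 2 * config.localizer_block_s)
        n_vols = int(np.ceil(total_s / config.tr_localizer))
        rng = _subject_seed(config.seed, sid, stream=20)
        X, cond_labels = _condition_columns(events, config.tr_localizer, n_vols)
        data = rng.normal(0.0, config.noise_sd, (n_vols, n_vox))
        data += config.baseline
        data += _slow_drift(rng, n_vols, config.tr_localizer)[:, None]
        hand_col = X[:, cond_labels.index("hand")]
        data += np.outer(hand_col * float(truth_row["amp_motor_hand"]),
                         sm_intact_prof)
        if "nondominant_hand" in cond_labels:
            nd_col = X[:, cond_labels.index("nondominant_hand")]
            data += np.outer(nd_col * float(truth_row["amp_motor_nondom"]),
                             sm_missing_prof)
        motion = _motion_trace(rng, n_vols, config.spike_rate)
        out.localizer = (data.reshape(n_vols, *dims), events, motion)

    # ---- resting state ----------------------------------------------------
    rng = _subject_seed(config.seed, sid, stream=30)
    T = config.n_vols_rest
    v = rng.standard_normal(T)      # visual network latent
    w = rng.standard_normal(T)      # missing-hand specific latent
    u = rng.standard_normal(T)      # intact-hand specific latent
    g = rng.standard_normal(T)      # global physiological component
    q = rng.standard_normal((T, 2))  # WM components
    c = rng.standard_normal((T, 2))  # CSF components

    r_m = math.tanh(float(truth_row["z_missing_true"]))
    r_i = math.tanh(float(truth_row["z_intact_true"]))
    m = r_m * v + math.sqrt(1 - r_m ** 2) * w
    i_sig = r_i * v + math.sqrt(1 - r_i ** 2) * u

    data = rng.normal(0.0, config.rest_noise_sd, (T, n_vox))
    data += config.baseline
    data += 0.3 * g[:, None]        # weak global component everywhere
    vis_mask = (labels.visual_left | labels.visual_right).ravel()
    data[:, vis_mask] += v[:, None]
    data[:, sm_missing.ravel()] += m[:, None]
    data[:, sm_intact.ravel()] += i_sig[:, None]
    wm_flat = labels.wm.ravel()
    n_wm = int(wm_flat.sum())
    load = rng.uniform(0.5, 1.0, (2, n_wm))
    data[:, wm_flat] += 1.2 * g[:, None] + q @ (0.8 * load)
    csf_flat = labels.csf.ravel()
    n_csf = int(csf_flat.sum())
    load_c = rng.uniform(0.5, 1.0, (2, n_csf))
    data[:, csf_flat] += c @ (0.9 * load_c)
    motion = _motion_trace(rng, T, config.spike_rate)
    out.rest = (data.reshape(T, *dims), motion)

    # ---- tissue intensity maps -------------------------------------------
    rng = _subject_seed(config.seed, sid, stream=40)
    wm_int = np.zeros(dims)
    idx = np.argwhere(labels.wm)
    center = idx.mean(axis=0)
    d2 = np.sum((idx - center) ** 2, axis=1)
    wm_int[tuple(idx.T)] = 100.0 - d2 / max(d2.max(), 1.0) * 50.0
    wm_int += rng.uniform(0, 0.05, dims)
    csf_int = np.full(dims, 100.0)
    idx = np.argwhere(labels.csf)
    center = idx.mean(axis=0)
    d2 = np.sum((idx - center) ** 2, axis=1)
    csf_int[tuple(idx.T)] = d2 / max(d2.max(), 1.0) * 20.0
    csf_int += rng.uniform(0, 0.05, dims)
    out.wm_intensity = wm_int
    out.csf_intensity = csf_int
    return out


def iter_subject_data(config: CohortConfig, behaviour: pd.DataFrame,
                      truth: pd.DataFrame, labels: GridLabels | None = None):
    """Yield ``(behaviour_row, SubjectData)`` per subject, generated lazily."""
    if labels is None:
        labels = build_labels(config.grid_dims)
    truth_by_id = truth.set_index("subject_id")
    for _, row in behaviour.iterrows():
        yield row, generate_subject_data(
            config, row, truth_by_id.loc[row["subject_id"]], labels)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, out_dir) -> Path:
    """Write a full synthetic cohort to ``out_dir``.

    Layout: ``behaviour.tsv``, ``truth.tsv``, ``labels.nii.gz``,
    ``config.yaml`` at the root; per subject ``<sid>/func/`` holds task
    runs, localizer, rest (.nii.gz), events.tsv and motion .par files,
    and ``<sid>/anat/`` the WM/CSF intensity maps.
    """
    import yaml

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise OSError(f"not a writable directory: {out_dir}")
    behaviour = make_behaviour(config)
    truth = make_truth(config, behaviour)
    labels = build_labels(config.grid_dims)
    hio.write_table(behaviour, out_dir / "behaviour.tsv")
    hio.write_table(truth, out_dir / "truth.tsv")
    hio.save_nifti(labels.label_volume(), out_dir / "labels.nii.gz")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    for row, subj in iter_subject_data(config, behaviour, truth, labels):
        sid = subj.subject_id
        func = out_dir / sid / "func"
        anat = out_dir / sid / "anat"
        for k, (data, events, motion) in enumerate(subj.task_runs, start=1):
            hio.save_nifti(np.moveaxis(data, 0, -1),
                           func / f"task-visual_run-{k}_bold.nii.gz",
                           tr_s=config.tr_task)
            hio.write_events(events, func / f"task-visual_run-{k}_events.tsv")
            hio.write_motion(motion, func / f"task-visual_run-{k}_motion.par")
        if subj.localizer is not None:
            data, events, motion = subj.localizer
            hio.save_nifti(np.moveaxis(data, 0, -1),
                           func / "task-motor_bold.nii.gz",
                           tr_s=config.tr_localizer)
            hio.write_events(events, func / "task-motor_events.tsv")
            hio.write_motion(motion, func / "task-motor_motion.par")
        data, motion = subj.rest
        hio.save_nifti(np.moveaxis(data, 0, -1),
                       func / "task-rest_bold.nii.gz", tr_s=config.tr_rest)
        hio.write_motion(motion, func / "task-rest_motion.par")
        hio.save_nifti(subj.wm_intensity, anat / "wm_intensity.nii.gz")
        hio.save_nifti(subj.csf_intensity, anat / "csf_intensity.nii.gz")
    return out_dir
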