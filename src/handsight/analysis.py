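"""End-to-end in-memory analysis of a (synthetic) cohort.

Chains the pipeline stages without touching disk: first-level GLM on the
visual task and motor localizer, individualized ROI selection with mirror
projection, CompCor nuisance regression of the rest run, seed connectivity,
and the cohort-level statistical battery (part correlations with
permutation p-values, Fisher r-to-z group comparisons, commonality
analysis, ANCOVA, group tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import stats as hstats
from .behaviour import usage_table
from .cohort import (CohortConfig, GridLabels, SubjectData, build_labels,
                     iter_subject_data, make_behaviour, make_truth)
from .connectivity import adjust_for_intact, roi_mean_series, seed_connectivity
from .glm import ContrastMap, GlmFit, build_design, fixed_effects_combine
from .nuisance import (NuisanceModel, build_csf_mask, build_wm_mask,
                       compcor_eigenvectors, regress_nuisance)
from .roi import RoiMask, flip_validation, merge_bilateral, mirror_roi, select_roi

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "StudyResults", "task_contrast_maps",
           "visual_rois", "motor_rois", "rest_connectivity",
           "subject_measures", "cohort_measures", "cohort_statistics",
           "run_study"]


@dataclass
class AnalysisParams:
    """Tunable analysis parameters (counts scale with the synthetic grid)."""

    n_visual_per_hemi: int = 250
    n_motor: int = 200
    z_min: float = 2.0
    wm_n_top: int = 400
    wm_erode: int = 1
    csf_n_bottom: int = 150
    n_compcor: int = 5
    hp_task_s: float = 100.0
    spike_threshold_mm: float = 1.0
    n_permutations: int = 10_000

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown analysis params: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# subject level
# ---------------------------------------------------------------------------

def task_contrast_maps(runs, tr: float, params: AnalysisParams,
                       conditions) -> dict[str, ContrastMap]:
    """Fixed-effects condition-vs-baseline and pairwise contrast maps.

    ``runs`` is a list of ``(data4d, events, motion)``; returns one combined
    map per condition plus the hands-versus-objects selection contrast.
    """
    per_contrast: dict[str, list[ContrastMap]] = {}
    for data, events, motion in runs:
        T = data.shape[0]
        flat = data.reshape(T, -1)
        design = build_design(events, motion, tr=tr, n_vols=T,
                              spike_threshold_mm=params.spike_threshold_mm,
                              hp_cutoff_s=params.hp_task_s)
        fit = GlmFit(flat, design)
        for cond in conditions:
            c = design.condition_contrast({cond: 1.0})
            per_contrast.setdefault(cond, []).append(fit.contrast(c))
        c = design.condition_contrast({"hands": 1.0, "objects": -1.0})
        per_contrast.setdefault("hands_vs_objects", []).append(fit.contrast(c))
    return {k: fixed_effects_combine(v) for k, v in per_contrast.items()}


def visual_rois(zmap: np.ndarray, labels: GridLabels,
                params: AnalysisParams) -> RoiMask:
    """Bilateral visual hand-selective ROI: per-hemisphere top voxels of the
    hands-versus-objects Z map within the occipitotemporal labels, merged."""
    left = select_roi(zmap, labels.visual_left, params.n_visual_per_hemi,
                      params.z_min, hemisphere="left",
                      source_contrast="hands_vs_objects")
    right = select_roi(zmap, labels.visual_right, params.n_visual_per_hemi,
                       params.z_min, hemisphere="right",
                       source_contrast="hands_vs_objects")
    return merge_bilateral(left, right)


def motor_rois(localizer, tr: float, labels: GridLabels, intact_hemi: str,
               midline_x: float, params: AnalysisParams,
               has_nondominant: bool = False) -> dict:
    """Sensorimotor ROIs from the block localizer.

    The intact/dominant-hand ROI is selected from the hand-versus-feet Z map
    in the contralateral pericentral label; the missing-hand ROI is its
    mirror projection.  For subjects with a non-dominant-hand condition the
    directly localized ROI and the COPEs needed for flip validation are
    returned as well.
    """
    data, events, motion = localizer
    T = data.shape[0]
    flat = data.reshape(T, -1)
    design = build_design(events, motion, tr=tr, n_vols=T,
                          spike_threshold_mm=params.spike_threshold_mm,
                          hp_cutoff_s=params.hp_task_s)
    fit = GlmFit(flat, design)
    c_hand = design.condition_contrast({"hand": 1.0, "feet": -1.0})
    map_hand = fit.contrast(c_hand)
    zvol = map_hand.z.reshape(labels.grid_dims)
    sm_mask = labels.hemisphere_mask(intact_hemi, "sm")
    intact = select_roi(zvol, sm_mask, params.n_motor, params.z_min,
                        hemisphere=intact_hemi, source_contrast="hand_vs_feet")
    mirrored = mirror_roi(intact, midline_x)
    out = {"intact": intact, "mirrored": mirrored}
    if has_nondominant:
        c_nd = design.condition_contrast({"nondominant_hand": 1.0,
                                          "feet": -1.0})
        map_nd = fit.contrast(c_nd)
        zvol_nd = map_nd.z.reshape(labels.grid_dims)
        other = "left" if intact_hemi == "right" else "right"
        direct = select_roi(zvol_nd, labels.hemisphere_mask(other, "sm"),
                            params.n_motor, params.z_min, hemisphere=other,
                            source_contrast="nondominant_vs_feet")
        out["direct_nondominant"] = direct
        out["flip_cope_flipped"] = float(
            map_nd.cope[mirrored.linear_indices].mean())
        out["flip_cope_direct"] = float(
            map_nd.cope[direct.linear_indices].mean())
    return out


def rest_connectivity(rest, wm_intensity, csf_intensity, labels: GridLabels,
                      visual_roi: RoiMask, missing_roi: RoiMask,
                      intact_roi: RoiMask, params: AnalysisParams) -> dict:
    """CompCor-cleaned seed connectivity for one subject.

    Returns Fisher-z couplings of the missing- and intact-hand sensorimotor
    ROIs with the bilateral visual ROI, plus mask-size QC counts.
    """
    data, motion = rest
    T = data.shape[0]
    flat = data.reshape(T, -1)
    wm_mask = build_wm_mask(wm_intensity, labels.wm, n_top=params.wm_n_top,
                            erode_voxels=params.wm_erode)
    csf_mask = build_csf_mask(csf_intensity, n_bottom=params.csf_n_bottom,
                              restrict_mask=labels.csf)
    wm_eig = compcor_eigenvectors(flat[:, wm_mask.ravel()], k=params.n_compcor)
    csf_eig = compcor_eigenvectors(flat[:, csf_mask.ravel()],
                                   k=params.n_compcor)
    model = NuisanceModel(wm_eigenvectors=wm_eig, csf_eigenvectors=csf_eig,
                          motion=motion)
    resid, flagged = regress_nuisance(flat, model)
    vis = roi_mean_series(resid, visual_roi, flagged)
    miss = roi_mean_series(resid, missing_roi, flagged)
    intact = roi_mean_series(resid, intact_roi, flagged)
    return {
        "z_missing": seed_connectivity(miss, vis),
        "z_intact": seed_connectivity(intact, vis),
        "wm_mask_size": int(wm_mask.sum()),
        "csf_mask_size": int(csf_mask.sum()),
        "n_flagged_voxels": int(flagged.sum()),
        "n_nuisance_regressors": model.combined.shape[1],
    }


def subject_measures(config: CohortConfig, labels: GridLabels,
                     behaviour_row: pd.Series, subj: SubjectData,
                     params: AnalysisParams) -> dict:
    """All per-subject derived measures for the cohort-level statistics."""
    from .cohort import VISUAL_CONDITIONS

    maps = task_contrast_maps(subj.task_runs, config.tr_task, params,
                              VISUAL_CONDITIONS)
    zvol = maps["hands_vs_objects"].z.reshape(config.grid_dims)
    vroi = visual_rois(zvol, labels, params)
    out = {
        "subject_id": subj.subject_id,
        "n_visual_roi": len(vroi),
    }
    for cond in VISUAL_CONDITIONS:
        out[f"cope_{cond}"] = float(
            maps[cond].cope[vroi.linear_indices].mean())

    affected = str(behaviour_row["nondominant_side"])
    missing_hemi = "right" if affected == "left" else "left"
    intact_hemi = "left" if missing_hemi == "right" else "right"
    if subj.localizer is not None:
        rois = motor_rois(subj.localizer, config.tr_localizer, labels,
                          intact_hemi, config.midline_x, params,
                          has_nondominant=(behaviour_row["group"] == "control"))
        out["n_motor_roi"] = len(rois["intact"])
        out["flip_cope_flipped"] = rois.get("flip_cope_flipped", np.nan)
        out["flip_cope_direct"] = rois.get("flip_cope_direct", np.nan)
        conn = rest_connectivity(subj.rest, subj.wm_intensity,
                                 subj.csf_intensity, labels, vroi,
                                 rois["mirrored"], rois["intact"], params)
        out.update(conn)
    else:
        # no localizer: sensorimotor ROIs undefined; flagged, connectivity
        # measures withheld (group-map substitution is not implemented)
        logger.warning("%s: no motor localizer; connectivity skipped",
                       subj.subject_id)
        out.update({"n_motor_roi": 0, "flip_cope_flipped": np.nan,
                    "flip_cope_direct": np.nan, "z_missing": np.nan,
                    "z_intact": np.nan, "wm_mask_size": 0,
                    "csf_mask_size": 0, "n_flagged_voxels": 0,
                    "n_nuisance_regressors": 0})
    return out


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

def cohort_measures(config: CohortConfig,
                    params: AnalysisParams | None = None,
                    behaviour: pd.DataFrame | None = None,
                    truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate (lazily, subject by subject) and analyze a whole cohort.

    Returns the per-subject measures table joined with behavioural scores;
    subjects without questionnaires keep NaN usage scores.
    """
    params = params or AnalysisParams()
    if behaviour is None:
        behaviour = make_behaviour(config)
    if truth is None:
        truth = make_truth(config, behaviour)
    labels = build_labels(config.grid_dims)
    rows = []
    for row, subj in iter_subject_data(config, behaviour, truth, labels):
        rows.append(subject_measures(config, labels, row, subj, params))
    measures = pd.DataFrame(rows)

    scored = usage_table(behaviour)[["subject_id", "mal_fraction",
                                     "usage_score"]]
    meta_cols = ["subject_id", "group", "cause", "primary_prosthesis",
                 "missing_side", "nondominant_side", "has_localizer",
                 "wear_time"]
    merged = behaviour[meta_cols].merge(scored, on="subject_id", how="left")
    return merged.merge(measures, on="subject_id", how="left")


@dataclass
class StudyResults:
    """Cohort-level outputs: per-subject measures, a tidy statistics table,
    and a dictionary of headline values."""

    measures: pd.DataFrame
    stats_table: pd.DataFrame
    values: dict = field(default_factory=dict)


def _stat_row(analysis, n, statistic, df=None, p=None, seed=None, B=None):
    return {"analysis": analysis, "n": n, "statistic": statistic,
            "df": str(df) if df is not None else "",
            "p": p if p is not None else np.nan,
            "seed": seed if seed is not None else "",
            "n_permutations": B if B is not None else ""}


def cohort_statistics(measures: pd.DataFrame, params: AnalysisParams,
                      seed: int | None = None) -> StudyResults:
    """The full statistical battery on a cohort measures table."""
    rows = []
    values: dict[str, float] = {}
    B = params.n_permutations
    rng = np.random.default_rng(seed)

    def perm_seed() -> int:
        return int(rng.integers(2 ** 31))

    oh = measures[(measures.group == "one_hander")
                  & measures.usage_score.notna()].reset_index(drop=True)
    ctl = measures[(measures.group == "control")
                   & measures.usage_score.notna()].reset_index(drop=True)

    # --- usage / observation vs visual activity (part corr + permutation)
    corr_by = {}
    for name, grp in (("onehanders", oh), ("controls", ctl)):
        for cond in ("prosthesis_active", "prosthesis_cosmetic"):
            res = hstats.permutation_pvalue(
                grp["usage_score"], grp[f"cope_{cond}"], grp["cope_objects"],
                n_permutations=B, tails="two", seed=perm_seed())
            key = f"activity_{cond.split('_')[1]}_{name}"
            corr_by[key] = res
            rows.append(_stat_row(f"part_corr_{key}", res.n, res.r_part,
                                  df=res.df, p=res.p_perm, seed=res.seed, B=B))
            values[f"r_{key}"] = res.r_part
            values[f"p_perm_{key}"] = res.p_perm

    # --- connectivity (adjusted for intact hand)
    for name, grp in (("onehanders", oh), ("controls", ctl)):
        sub = grp[grp.z_missing.notna()]
        res = hstats.permutation_pvalue(
            sub["usage_score"], sub["z_missing"], sub["z_intact"],
            n_permutations=B, tails="two", seed=perm_seed())
        corr_by[f"connectivity_{name}"] = res
        rows.append(_stat_row(f"part_corr_connectivity_{name}", res.n,
                              res.r_part, df=res.df, p=res.p_perm,
                              seed=res.seed, B=B))
        values[f"r_connectivity_{name}"] = res.r_part
        values[f"p_perm_connectivity_{name}"] = res.p_perm

    # --- Fisher r-to-z group comparisons (one-handers > controls, one-tailed)
    for meas in ("activity_active", "activity_cosmetic", "connectivity"):
        r1 = corr_by[f"{meas}_onehanders"]
        r2 = corr_by[f"{meas}_controls"]
        cmp_ = hstats.fisher_rz_compare(r1.r_part, r1.n, r2.r_part, r2.n,
                                        tails="one")
        rows.append(_stat_row(f"fisher_group_{meas}", r1.n + r2.n,
                              cmp_.statistic, p=cmp_.p))
        values[f"fisher_z_group_{meas}"] = cmp_.statistic

    # --- active vs cosmetic within one-handers (independent formula)
    ra = corr_by["activity_active_onehanders"]
    rc = corr_by["activity_cosmetic_onehanders"]
    cmp_ac = hstats.fisher_rz_compare(ra.r_part, ra.n, rc.r_part, rc.n,
                                      tails="two")
    rows.append(_stat_row("fisher_active_vs_cosmetic", ra.n, cmp_ac.statistic,
                          p=cmp_ac.p))
    values["fisher_z_active_vs_cosmetic"] = cmp_ac.statistic

    # --- commonality: activity ~ usage + adjusted connectivity
    com_sub = oh[oh.z_missing.notna()]
    y_act = hstats.residualize(com_sub["cope_prosthesis_active"].to_numpy(),
                               com_sub["cope_objects"].to_numpy())
    z_conn = adjust_for_intact(com_sub["z_missing"].to_numpy(),
                               com_sub["z_intact"].to_numpy())
    part = hstats.commonality_two_predictor(
        com_sub["usage_score"].to_numpy(), z_conn, y_act)
    rows.append(_stat_row("commonality_R2_full", len(com_sub), part.R2_full,
                          df=part.df_change))
    for key in ("R2_full", "R2_x", "R2_z", "unique_x", "unique_z", "shared"):
        values[f"commonality_{key}"] = getattr(part, key)
    values["commonality_F_change_usage"] = part.F_change_x
    values["commonality_F_change_connectivity"] = part.F_change_z

    # --- ANCOVA: usage effect controlling for subgroup
    users = oh[oh.primary_prosthesis.isin(
        ["cosmetic", "mechanical", "myoelectric"])].copy()
    users["ptype"] = np.where(users.primary_prosthesis == "cosmetic",
                              "cosmetic", "active")
    y_users = hstats.residualize(users["cope_prosthesis_active"].to_numpy(),
                                 users["cope_objects"].to_numpy())
    if users["ptype"].nunique() == 2 and \
            users["ptype"].value_counts().min() >= 2:
        anc = hstats.ancova_usage(y_users, users["usage_score"], users["ptype"])
        rows.append(_stat_row("ancova_ptype_usage", len(users),
                              anc["usage"].statistic, df=anc["usage"].dof,
                              p=anc["usage"].p))
        rows.append(_stat_row("ancova_ptype_subgroup", len(users),
                              anc["subgroup"].statistic,
                              df=anc["subgroup"].dof, p=anc["subgroup"].p))
        values["ancova_ptype_F_usage"] = anc["usage"].statistic
    y_oh = hstats.residualize(oh["cope_prosthesis_active"].to_numpy(),
                              oh["cope_objects"].to_numpy())
    if oh["cause"].nunique() == 2 and oh["cause"].value_counts().min() >= 2:
        anc = hstats.ancova_usage(y_oh, oh["usage_score"], oh["cause"])
        rows.append(_stat_row("ancova_cause_usage", len(oh),
                              anc["usage"].statistic, df=anc["usage"].dof,
                              p=anc["usage"].p))

    # --- distribution overlap of usage vs observation scores (KS)
    ks = hstats.group_tests(oh["usage_score"], ctl["usage_score"], kind="ks")
    rows.append(_stat_row("ks_usage_vs_observation", len(oh) + len(ctl),
                          ks.extra["Z"], p=ks.p))
    values["ks_Z_usage_vs_observation"] = ks.extra["Z"]

    # --- 2x2 ANOVA: group x prosthesis type on adjusted activity
    ctl_all = measures[measures.group == "control"]
    oh_all = measures[measures.group == "one_hander"]
    vals, f_group, f_type = [], [], []
    for grp_name, grp in (("one_hander", oh_all), ("control", ctl_all)):
        for cond in ("active", "cosmetic"):
            v = grp[f"cope_prosthesis_{cond}"].to_numpy()
            vals.append(v)
            f_group += [grp_name] * v.size
            f_type += [cond] * v.size
    anova = hstats.group_tests(None, kind="anova2x2",
                               values=np.concatenate(vals),
                               factor_a=f_group, factor_b=f_type)
    rows.append(_stat_row("anova2x2_group", len(f_group),
                          anova.extra["A"]["F"], df=anova.extra["A"]["df"],
                          p=anova.extra["A"]["p"]))
    rows.append(_stat_row("anova2x2_interaction", len(f_group),
                          anova.extra["interaction"]["F"],
                          df=anova.extra["interaction"]["df"],
                          p=anova.extra["interaction"]["p"]))

    # --- users vs controls on active-prosthesis activity (t test)
    t = hstats.group_tests(users["cope_prosthesis_active"],
                           ctl_all["cope_prosthesis_active"], kind="t")
    rows.append(_stat_row("t_users_vs_controls_active", t.dof + 2,
                          t.statistic, df=t.dof, p=t.p))

    # --- flip validation across controls with a localizer
    flip = measures[measures.flip_cope_flipped.notna()]
    if len(flip) >= 3:
        r, df, p = flip_validation(flip["flip_cope_flipped"],
                                   flip["flip_cope_direct"])
        rows.append(_stat_row("flip_validation", len(flip), r, df=df, p=p))
        values["flip_validation_r"] = r
        values["flip_validation_df"] = df

    return StudyResults(measures=measures, stats_table=pd.DataFrame(rows),
                        values=values)


def run_study(config: CohortConfig, params: AnalysisParams | None = None,
              stats_seed: int | None = None) -> StudyResults:
    """Simulate a cohort and run the complete analysis in memory."""
    params = params or AnalysisParams()
    measures = cohort_measures(config, params)
    seed = config.seed if stats_seed is None else stats_seed
    return cohort_statistics(measures, params, seed=seed)
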