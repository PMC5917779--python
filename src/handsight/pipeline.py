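"""Staged, on-disk pipeline with provenance capture.

Stages (dependency order): simulate -> glm -> roi -> nuisance ->
connectivity -> stats.  Each stage reads only the outputs of its
predecessors from the run directory and writes its own subdirectory, so
stages are independently re-runnable; a missing prerequisite raises an
error naming the stage that should have produced it.  A JSON manifest
records the config hash, seeds, stage outputs and software version;
re-running with the same config and seed reproduces identical statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as hio
from .analysis import AnalysisParams, cohort_statistics
from .behaviour import usage_table
from .cohort import (VISUAL_CONDITIONS, CohortConfig, build_labels,
                     generate_cohort)
from .glm import GlmFit, build_design, fixed_effects_combine
from .nuisance import (NuisanceModel, build_csf_mask, build_wm_mask,
                       compcor_eigenvectors, regress_nuisance)
from .connectivity import roi_mean_series, seed_connectivity
from .roi import RoiMask, mirror_roi, select_roi, merge_bilateral

logger = logging.getLogger(__name__)

STAGES = ("simulate", "glm", "roi", "nuisance", "connectivity", "stats")

__all__ = ["STAGES", "PipelineConfig", "run_pipeline", "demo_config"]


class StageError(RuntimeError):
    """A stage prerequisite is missing or a stage failed."""


class PipelineConfig:
    """Validated per-stage configuration loaded from a single YAML file.

    Top-level blocks: ``cohort`` (CohortConfig fields), ``analysis``
    (AnalysisParams fields) and ``stats`` (``seed``).  Unknown keys at any
    level are rejected.
    """

    def __init__(self, cohort: CohortConfig, analysis: AnalysisParams,
                 stats_seed: int | None = None):
        self.cohort = cohort
        self.analysis = analysis
        self.stats_seed = stats_seed if stats_seed is not None \
            else cohort.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = hio.load_yaml(path)
        unknown = set(raw) - {"cohort", "analysis", "stats"}
        if unknown:
            raise ValueError(f"unknown config blocks: {sorted(unknown)}")
        cohort = CohortConfig.from_dict(raw.get("cohort", {}))
        analysis = AnalysisParams.from_dict(raw.get("analysis", {}))
        stats_block = raw.get("stats", {})
        bad = set(stats_block) - {"seed"}
        if bad:
            raise ValueError(f"unknown stats config keys: {sorted(bad)}")
        return cls(cohort, analysis, stats_block.get("seed"))

    def to_dict(self) -> dict:
        return {"cohort": self.cohort.to_dict(),
                "analysis": self.analysis.to_dict(),
                "stats": {"seed": self.stats_seed}}

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small cohort that exercises every stage in well under a minute."""
    cohort = CohortConfig(n_onehanders=10, n_controls=8,
                          grid_dims=(16, 16, 10), n_vols_rest=120,
                          controls_missing_questionnaire=1,
                          controls_without_localizer=1, seed=seed)
    return PipelineConfig(cohort, AnalysisParams(n_permutations=500))


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _need(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            f"missing input {path}; run the '{producer}' stage first")
    return path


def _subjects(run_dir: Path) -> pd.DataFrame:
    return hio.read_table(_need(run_dir / "cohort" / "behaviour.tsv",
                                "simulate"))


def _sid_hemis(row) -> tuple[str, str]:
    affected = str(row["nondominant_side"])
    missing = "right" if affected == "left" else "left"
    return ("left" if missing == "right" else "right"), missing  # intact, missing


def _load_mask(path: Path, producer: str) -> np.ndarray:
    return hio.load_nifti(_need(path, producer)) > 0.5


def _mask_to_roi(mask: np.ndarray) -> RoiMask:
    return RoiMask(voxel_indices=np.argwhere(mask), grid_dims=mask.shape)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run_dir: Path, cfg: PipelineConfig) -> None:
    generate_cohort(cfg.cohort, run_dir / "cohort")
    logger.info("simulate: cohort written to %s", run_dir / "cohort")


def stage_glm(run_dir: Path, cfg: PipelineConfig) -> None:
    params, cc = cfg.analysis, cfg.cohort
    behaviour = _subjects(run_dir)
    for _, row in behaviour.iterrows():
        sid = row["subject_id"]
        func = run_dir / "cohort" / sid / "func"
        out = run_dir / "glm" / sid
        per_contrast: dict[str, list] = {}
        for k in range(1, cc.n_runs_task + 1):
            data = hio.load_nifti(
                _need(func / f"task-visual_run-{k}_bold.nii.gz", "simulate"))
            data = np.moveaxis(data, -1, 0)
            events = hio.read_events(func / f"task-visual_run-{k}_events.tsv")
            motion = hio.read_motion(func / f"task-visual_run-{k}_motion.par")
            design = build_design(events, motion, tr=cc.tr_task,
                                  n_vols=data.shape[0],
                                  spike_threshold_mm=params.spike_threshold_mm,
                                  hp_cutoff_s=params.hp_task_s)
            fit = GlmFit(data.reshape(data.shape[0], -1), design)
            for cond in VISUAL_CONDITIONS:
                per_contrast.setdefault(cond, []).append(
                    fit.contrast(design.condition_contrast({cond: 1.0})))
            per_contrast.setdefault("hands_vs_objects", []).append(
                fit.contrast(design.condition_contrast(
                    {"hands": 1.0, "objects": -1.0})))
        for name, maps in per_contrast.items():
            combined = fixed_effects_combine(maps)
            hio.save_nifti(combined.cope.reshape(cc.grid_dims),
                           out / f"cope_{name}.nii.gz")
            hio.save_nifti(combined.z.reshape(cc.grid_dims),
                           out / f"z_{name}.nii.gz")

        loc_path = func / "task-motor_bold.nii.gz"
        if loc_path.exists():
            data = np.moveaxis(hio.load_nifti(loc_path), -1, 0)
            events = hio.read_events(func / "task-motor_events.tsv")
            motion = hio.read_motion(func / "task-motor_motion.par")
            design = build_design(events, motion, tr=cc.tr_localizer,
                                  n_vols=data.shape[0],
                                  spike_threshold_mm=params.spike_threshold_mm,
                                  hp_cutoff_s=params.hp_task_s)
            fit = GlmFit(data.reshape(data.shape[0], -1), design)
            m = fit.contrast(design.condition_contrast(
                {"hand": 1.0, "feet": -1.0}))
            hio.save_nifti(m.z.reshape(cc.grid_dims),
                           out / "motor_z_hand_vs_feet.nii.gz")
            if "nondominant_hand" in design.column_labels:
                m = fit.contrast(design.condition_contrast(
                    {"nondominant_hand": 1.0, "feet": -1.0}))
                hio.save_nifti(m.z.reshape(cc.grid_dims),
                               out / "motor_z_nondominant_vs_feet.nii.gz")
                hio.save_nifti(m.cope.reshape(cc.grid_dims),
                               out / "motor_cope_nondominant_vs_feet.nii.gz")
        logger.info("glm: %s done", sid)


def stage_roi(run_dir: Path, cfg: PipelineConfig) -> None:
    params, cc = cfg.analysis, cfg.cohort
    labels = build_labels(cc.grid_dims)
    behaviour = _subjects(run_dir)
    manifest, measures = [], []
    for _, row in behaviour.iterrows():
        sid = row["subject_id"]
        glm_dir = run_dir / "glm" / sid
        out = run_dir / "roi" / sid
        zvol = hio.load_nifti(_need(glm_dir / "z_hands_vs_objects.nii.gz",
                                    "glm"))
        left = select_roi(zvol, labels.visual_left, params.n_visual_per_hemi,
                          params.z_min, hemisphere="left",
                          source_contrast="hands_vs_objects")
        right = select_roi(zvol, labels.visual_right,
                           params.n_visual_per_hemi, params.z_min,
                           hemisphere="right",
                           source_contrast="hands_vs_objects")
        vroi = merge_bilateral(left, right)
        hio.save_nifti(vroi.to_volume(), out / "visual_bilateral.nii.gz")
        manifest.append({"subject_id": sid, "roi": "visual_bilateral",
                         "n_voxels": len(vroi), "z_threshold": params.z_min})
        meas = {"subject_id": sid, "n_visual_roi": len(vroi)}
        for cond in VISUAL_CONDITIONS:
            cope = hio.load_nifti(_need(glm_dir / f"cope_{cond}.nii.gz",
                                        "glm"))
            meas[f"cope_{cond}"] = float(cope.ravel()[
                vroi.linear_indices].mean())

        intact_hemi, missing_hemi = _sid_hemis(row)
        motor_z = glm_dir / "motor_z_hand_vs_feet.nii.gz"
        if motor_z.exists():
            zvol_m = hio.load_nifti(motor_z)
            intact = select_roi(zvol_m,
                                labels.hemisphere_mask(intact_hemi, "sm"),
                                params.n_motor, params.z_min,
                                hemisphere=intact_hemi,
                                source_contrast="hand_vs_feet")
            mirrored = mirror_roi(intact, cc.midline_x)
            hio.save_nifti(intact.to_volume(), out / "sm_intact.nii.gz")
            hio.save_nifti(mirrored.to_volume(), out / "sm_missing.nii.gz")
            manifest.append({"subject_id": sid, "roi": "sm_intact",
                             "n_voxels": len(intact),
                             "z_threshold": params.z_min})
            meas["n_motor_roi"] = len(intact)
            nd_z = glm_dir / "motor_z_nondominant_vs_feet.nii.gz"
            if nd_z.exists():
                direct = select_roi(hio.load_nifti(nd_z),
                                    labels.hemisphere_mask(missing_hemi, "sm"),
                                    params.n_motor, params.z_min,
                                    hemisphere=missing_hemi,
                                    source_contrast="nondominant_vs_feet")
                hio.save_nifti(direct.to_volume(),
                               out / "sm_nondominant_direct.nii.gz")
                nd_cope = hio.load_nifti(
                    glm_dir / "motor_cope_nondominant_vs_feet.nii.gz").ravel()
                meas["flip_cope_flipped"] = float(
                    nd_cope[mirrored.linear_indices].mean())
                meas["flip_cope_direct"] = float(
                    nd_cope[direct.linear_indices].mean())
        else:
            logger.warning("roi: %s has no localizer; sensorimotor ROIs "
                           "not defined", sid)
            meas["n_motor_roi"] = 0
        measures.append(meas)
    hio.write_table(pd.DataFrame(manifest), run_dir / "roi" / "manifest.tsv")
    hio.write_table(pd.DataFrame(measures), run_dir / "roi" / "measures.tsv")


def stage_nuisance(run_dir: Path, cfg: PipelineConfig) -> None:
    params, cc = cfg.analysis, cfg.cohort
    labels = build_labels(cc.grid_dims)
    behaviour = _subjects(run_dir)
    qc = []
    for _, row in behaviour.iterrows():
        sid = row["subject_id"]
        func = run_dir / "cohort" / sid / "func"
        anat = run_dir / "cohort" / sid / "anat"
        out = run_dir / "nuisance" / sid
        data = np.moveaxis(hio.load_nifti(
            _need(func / "task-rest_bold.nii.gz", "simulate")), -1, 0)
        flat = data.reshape(data.shape[0], -1)
        motion = hio.read_motion(func / "task-rest_motion.par")
        wm_int = hio.load_nifti(_need(anat / "wm_intensity.nii.gz",
                                      "simulate"))
        csf_int = hio.load_nifti(anat / "csf_intensity.nii.gz")
        wm_mask = build_wm_mask(wm_int, labels.wm, n_top=params.wm_n_top,
                                erode_voxels=params.wm_erode)
        csf_mask = build_csf_mask(csf_int, n_bottom=params.csf_n_bottom,
                                  restrict_mask=labels.csf)
        wm_eig = compcor_eigenvectors(flat[:, wm_mask.ravel()],
                                      k=params.n_compcor)
        csf_eig = compcor_eigenvectors(flat[:, csf_mask.ravel()],
                                       k=params.n_compcor)
        model = NuisanceModel(wm_eigenvectors=wm_eig,
                              csf_eigenvectors=csf_eig, motion=motion)
        resid, flagged = regress_nuisance(flat, model)
        cols = ([f"wm_pc{i + 1}" for i in range(wm_eig.shape[1])]
                + [f"csf_pc{i + 1}" for i in range(csf_eig.shape[1])]
                + [f"motion_{i}" for i in range(6)])
        hio.write_table(pd.DataFrame(model.combined, columns=cols),
                        out / "nuisance.tsv")
        hio.save_nifti(wm_mask.astype(np.uint8), out / "wm_mask.nii.gz")
        hio.save_nifti(csf_mask.astype(np.uint8), out / "csf_mask.nii.gz")
        hio.save_nifti(np.moveaxis(
            resid.reshape(data.shape).astype(np.float32), 0, -1),
            out / "rest_residuals.nii.gz", tr_s=cc.tr_rest)
        np.savetxt(out / "flagged_voxels.txt",
                   np.nonzero(flagged)[0], fmt="%d")
        qc.append({"subject_id": sid, "wm_mask_size": int(wm_mask.sum()),
                   "csf_mask_size": int(csf_mask.sum()),
                   "n_regressors": model.combined.shape[1],
                   "n_flagged": int(flagged.sum())})
        logger.info("nuisance: %s wm=%d csf=%d", sid, wm_mask.sum(),
                    csf_mask.sum())
    hio.write_table(pd.DataFrame(qc), run_dir / "nuisance" / "qc.tsv")


def stage_connectivity(run_dir: Path, cfg: PipelineConfig) -> None:
    behaviour = _subjects(run_dir)
    rows = []
    for _, row in behaviour.iterrows():
        sid = row["subject_id"]
        roi_dir = run_dir / "roi" / sid
        nui_dir = run_dir / "nuisance" / sid
        rec = {"subject_id": sid, "z_missing": np.nan, "z_intact": np.nan}
        if (roi_dir / "sm_intact.nii.gz").exists():
            resid = np.moveaxis(hio.load_nifti(
                _need(nui_dir / "rest_residuals.nii.gz", "nuisance")), -1, 0)
            resid = resid.reshape(resid.shape[0], -1)
            flagged_idx = np.loadtxt(nui_dir / "flagged_voxels.txt",
                                     dtype=int, ndmin=1)
            flagged = np.zeros(resid.shape[1], dtype=bool)
            flagged[flagged_idx] = True
            vroi = _mask_to_roi(_load_mask(
                roi_dir / "visual_bilateral.nii.gz", "roi"))
            missing = _mask_to_roi(_load_mask(
                roi_dir / "sm_missing.nii.gz", "roi"))
            intact = _mask_to_roi(_load_mask(
                roi_dir / "sm_intact.nii.gz", "roi"))
            vis = roi_mean_series(resid, vroi, flagged)
            rec["z_missing"] = seed_connectivity(
                roi_mean_series(resid, missing, flagged), vis)
            rec["z_intact"] = seed_connectivity(
                roi_mean_series(resid, intact, flagged), vis)
        rows.append(rec)
    hio.write_table(pd.DataFrame(rows),
                    run_dir / "connectivity" / "connectivity.tsv")


def stage_stats(run_dir: Path, cfg: PipelineConfig) -> None:
    behaviour = _subjects(run_dir)
    measures = hio.read_table(_need(run_dir / "roi" / "measures.tsv", "roi"))
    conn = hio.read_table(_need(
        run_dir / "connectivity" / "connectivity.tsv", "connectivity"))
    scored = usage_table(behaviour)[["subject_id", "mal_fraction",
                                     "usage_score"]]
    meta_cols = ["subject_id", "group", "cause", "primary_prosthesis",
                 "missing_side", "nondominant_side", "has_localizer",
                 "wear_time"]
    full = (behaviour[meta_cols]
            .merge(scored, on="subject_id", how="left")
            .merge(measures, on="subject_id", how="left")
            .merge(conn, on="subject_id", how="left"))
    results = cohort_statistics(full, cfg.analysis, seed=cfg.stats_seed)
    out = run_dir / "stats"
    hio.write_table(results.stats_table, out / "statistics.tsv")
    hio.write_table(results.measures, out / "measures.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(results.values, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(_render_report(results))
    logger.info("stats: written to %s", out)


def _render_report(results) -> str:
    lines = ["handsight cohort report", "=" * 40, ""]
    for _, r in results.stats_table.iterrows():
        p = f"p={r['p']:.4f}" if np.isfinite(r["p"]) else ""
        lines.append(f"{r['analysis']:<40s} n={r['n']:<4} "
                     f"stat={r['statistic']:+.4f} {p}")
    return "\n".join(lines) + "\n"


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "glm": stage_glm,
    "roi": stage_roi,
    "nuisance": stage_nuisance,
    "connectivity": stage_connectivity,
    "stats": stage_stats,
}


def run_pipeline(cfg: PipelineConfig, run_dir,
                 stages=None) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    ``stages`` is a subset of :data:`STAGES` (default: all).  Prerequisite
    outputs for partial runs must already exist in ``run_dir``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    wanted = list(STAGES) if stages is None else [
        s for s in STAGES if s in set(stages)]
    unknown = (set(stages) - set(STAGES)) if stages is not None else set()
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    manifest = {
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "config": cfg.to_dict(),
        "seeds": {"cohort": cfg.cohort.seed, "stats": cfg.stats_seed},
        "stages": {},
    }
    for stage in wanted:
        t0 = time.time()
        logger.info("running stage %s", stage)
        _STAGE_FUNCS[stage](run_dir, cfg)
        manifest["stages"][stage] = {
            "elapsed_s": round(time.time() - t0, 2),
            "out": str(run_dir / ("cohort" if stage == "simulate" else stage)),
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
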