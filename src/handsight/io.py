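"""On-disk formats: NIfTI volumes, BIDS-style events, motion traces, tables.

Conventions: NIfTI-1 (.nii.gz) with an axis-aligned affine; events.tsv with
columns onset/duration/trial_type in seconds; motion parameters as
whitespace-delimited 6-column text (three rotations in radians, three
translations in mm); behavioural and result tables as TSV.  Voxel indices
are 0-based row-major throughout.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "save_nifti", "load_nifti", "write_events", "read_events",
    "write_motion", "read_motion", "write_table", "read_table",
    "load_yaml",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 2.0,
               tr_s: float | None = None) -> Path:
    """Write a 3-D or 4-D array as .nii.gz (float32 for data, uint8/int16
    preserved for masks and labels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(data)
    if arr.dtype not in (np.uint8, np.int16, np.int32):
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, _affine(voxel_size_mm))
    if tr_s is not None and arr.ndim == 4:
        img.header.set_zooms((voxel_size_mm,) * 3 + (tr_s,))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    events[["onset", "duration", "trial_type"]].to_csv(
        path, sep="\t", index=False, float_format="%.3f")
    return path


def read_events(path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(ev.columns):
        raise ValueError(f"{path}: events file needs columns {sorted(required)}")
    return ev


def write_motion(motion: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    np.savetxt(path, motion, fmt="%.8f")
    return path


def read_motion(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, got {m.shape[1]}")
    return m


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return out
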