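"""NIfTI-1 / TSV input-output helpers.

All volumetric files are NIfTI-1 (nibabel), with the voxel size and the
repetition time recorded in ``pixdim`` and gzip compression decided by the
file extension. Motion traces and the participants table are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def centered_affine(grid_shape, voxel_size_mm: float) -> np.ndarray:
    """Affine for an isotropic grid with mm origin at the central voxel."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.asarray(grid_shape) // 2)
    return affine


def save_nifti(path, data: np.ndarray, affine: np.ndarray, tr_s: float | None = None,
               description: str = "") -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(img.header.get_zooms())
    if tr_s is not None and np.asarray(data).ndim == 4:
        img.header.set_zooms((*zooms[:3], tr_s))
        img.header.set_xyzt_units(xyz="mm", t="sec")
    else:
        img.header.set_xyzt_units(xyz="mm")
    if description:
        img.header["descrip"] = description.encode()[:79]
    img.to_filename(str(path))
    return path


def load_nifti(path):
    """Return (data, affine, tr_s). TR is None for 3D images."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else None
    return data, img.affine, tr


def save_motion_tsv(path, motion: np.ndarray) -> Path:
    path = Path(path)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be t x 6")
    pd.DataFrame(motion, columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def load_motion_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV {path} lacks columns {missing}")
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def save_participants_tsv(path, subject_ids, groups) -> Path:
    path = Path(path)
    pd.DataFrame({"participant_id": list(subject_ids), "group": list(groups)}).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_participants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("participant_id", "group"):
        if col not in df.columns:
            raise ValueError(f"participants TSV {path} lacks column {col!r}")
    return df


def dump_json(path, obj) -> Path:
    """Write deterministic JSON (sorted keys, fixed float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
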