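"""Reading and writing the pipeline's on-disk formats.

Trial tables and labelled tables travel as TSV; run series as a NumPy
``.npz`` archive with a JSON sidecar carrying TR and block boundaries;
masks and label volumes as NIfTI (synthetic 2 mm isotropic RAS+ affine by
default).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import RunSeries
from .roi import default_affine

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "save_run_series",
    "load_run_series",
    "save_volume_nifti",
    "load_volume_nifti",
]


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_run_series(run: RunSeries, path: str | Path) -> None:
    """Write ``<path>.npz`` (arrays) and ``<path>.json`` (timing metadata)."""
    path = Path(path)
    arrays = {"data": run.data, "voxel_ids": run.voxel_ids}
    if run.voxel_coords is not None:
        arrays["voxel_coords"] = run.voxel_coords
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "tr_s": run.tr_s,
        "block_bounds": [list(b) for b in run.block_bounds],
        "participant_id": run.participant_id,
        "run": run.run,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_run_series(path: str | Path) -> RunSeries:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return RunSeries(
        data=arrays["data"],
        tr_s=meta["tr_s"],
        block_bounds=[tuple(b) for b in meta["block_bounds"]],
        voxel_ids=arrays["voxel_ids"],
        voxel_coords=arrays["voxel_coords"] if "voxel_coords" in arrays else None,
        participant_id=meta["participant_id"],
        run=meta["run"],
    )


def save_volume_nifti(
    volume: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> None:
    """Write a 3-D mask or integer label volume as NIfTI."""
    volume = np.asarray(volume)
    if affine is None:
        affine = default_affine(volume.shape)
    dtype = np.int16 if volume.dtype != float else np.float32
    nib.save(nib.Nifti1Image(volume.astype(dtype), affine), str(path))


def load_volume_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
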