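"""Volume and table I/O: NIfTI-1 via nibabel, TSV via pandas, JSON sidecars."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid

__all__ = ["save_volume", "load_volume", "save_labels", "write_table",
           "read_table", "write_json", "read_json", "file_sha256"]


def save_volume(vol: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1 with the grid's affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), np.asarray(grid.affine))
    img.header.set_zooms((*grid.voxel_size_mm, 1.0)[: vol.ndim])
    nib.save(img, str(path))
    return path


def save_labels(labels: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.asarray(grid.affine))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(tuple(int(s) for s in data.shape[:3]),
                      tuple(float(z) for z in zooms), np.asarray(img.affine))
    return data, grid


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
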