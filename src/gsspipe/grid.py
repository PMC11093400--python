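"""Common volumetric analysis grid.

All stages of the pipeline operate on a single shared grid: every subject
map, parcel atlas and fROI mask is a 3-D array with the same shape, and
world coordinates are obtained through a NIfTI-style RAS+ affine.  Nothing
in the pipeline resamples; a grid mismatch is always an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel grid with isotropic-or-not voxel sizes and an affine.

    Parameters
    ----------
    shape : tuple of int
        Voxels along each axis; every entry >= 1.
    voxel_size_mm : tuple of float
        Voxel edge length per axis in millimetres; every entry > 0.
    affine : (4, 4) ndarray, optional
        Voxel-index -> world-mm map.  Defaults to a diagonal RAS+ affine
        built from ``voxel_size_mm`` with the origin at voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be three entries >= 1, got {self.shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size_mm must be three positive entries, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        if self.affine is None:
            aff = np.diag((*vox, 1.0))
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError("affine must be invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def zeros(self, dtype=np.float64) -> np.ndarray:
        return np.zeros(self.shape, dtype=dtype)

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Index grids (i, j, k), each with ``self.shape``."""
        return np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")

    def check_volume(self, vol: np.ndarray, name: str = "volume") -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape[:3] != self.shape:
            raise ValueError(f"{name} shape {vol.shape[:3]} does not match grid {self.shape}")
        return vol

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)
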