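"""Ground-truth functional networks and per-subject topographies.

A phantom study consists of a small number of spatially distinct "networks"
(here: ellipsoidal regions on the common grid) with per-subject response
amplitudes, plus a per-subject topography obtained by jittering the truth
mask — an explicit, controllable stand-in for the large cross-subject
spatial variability of real functional networks that motivates
subject-specific ROI definition in the first place.

Voxel membership of the geometric shapes is decided by the voxel-centre
distance, so every mask has an exactly countable brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = ["NetworkSpec", "NetworkTruth", "SubjectTopography",
           "make_phantom", "sample_subject_topography"]


@dataclass(frozen=True)
class NetworkSpec:
    """Geometry + response amplitudes for one truth network.

    ``radii_vox`` are ellipsoid semi-axes in voxels (a single float gives a
    sphere).  ``amplitudes`` maps condition label -> response amplitude in
    percent of baseline; ``amplitude_subject_sd`` adds seeded between-subject
    variation to every condition amplitude.
    """

    name: str
    center_vox: tuple[float, float, float]
    radii_vox: float | tuple[float, float, float]
    amplitudes: dict[str, float] = field(default_factory=dict)
    amplitude_subject_sd: float = 0.0


@dataclass(frozen=True)
class NetworkTruth:
    name: str
    mask: np.ndarray  # bool volume on the grid
    subject_amplitudes: dict[str, dict[str, float]]  # subject -> condition -> %


@dataclass(frozen=True)
class SubjectTopography:
    subject_id: str
    network: str
    mask: np.ndarray  # bool volume
    shift_vox: tuple[int, int, int]
    grow_steps: int  # dilation (>0) or erosion (<0) steps applied


def _ellipsoid_mask(grid: VolumeGrid, center: tuple[float, float, float],
                    radii: tuple[float, float, float]) -> np.ndarray:
    ii, jj, kk = grid.voxel_coords()
    d2 = sum(((ax - c) / r) ** 2 for ax, c, r in zip((ii, jj, kk), center, radii))
    return d2 <= 1.0 + 1e-12


def make_phantom(grid: VolumeGrid, network_specs: list[NetworkSpec],
                 subject_ids: list[str], seed: int = 0,
                 disjoint: bool = False) -> list[NetworkTruth]:
    """Materialise truth networks on ``grid`` with per-subject amplitudes.

    With ``disjoint=True`` any pairwise mask overlap is an error (the
    phantom used for network-dissociation experiments must keep its
    networks spatially separate).
    """
    rng = np.random.default_rng(seed)
    truths: list[NetworkTruth] = []
    for spec in network_specs:
        radii = spec.radii_vox
        if np.isscalar(radii):
            radii = (float(radii),) * 3
        if any(r <= 0 for r in radii):
            raise ValueError(f"network {spec.name!r}: radii must be positive")
        lo = [c - r for c, r in zip(spec.center_vox, radii)]
        hi = [c + r for c, r in zip(spec.center_vox, radii)]
        if any(l < -0.5 or h > s - 0.5 for l, h, s in zip(lo, hi, grid.shape)):
            raise ValueError(f"network {spec.name!r} extends outside the grid")
        mask = _ellipsoid_mask(grid, spec.center_vox, radii)
        if not mask.any():
            raise ValueError(f"network {spec.name!r} has an empty mask")
        amps = {}
        for sid in subject_ids:
            jitter = rng.normal(0.0, spec.amplitude_subject_sd) if spec.amplitude_subject_sd else 0.0
            amps[sid] = {cond: float(a + jitter) for cond, a in spec.amplitudes.items()}
        truths.append(NetworkTruth(spec.name, mask, amps))
    if disjoint:
        for i in range(len(truths)):
            for j in range(i + 1, len(truths)):
                n_shared = int((truths[i].mask & truths[j].mask).sum())
                if n_shared:
                    raise ValueError(
                        f"networks {truths[i].name!r} and {truths[j].name!r} overlap "
                        f"in {n_shared} voxels but were requested disjoint")
    return truths


def _shift_mask(mask: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = [slice(max(0, -s), mask.shape[a] - max(0, s)) for a, s in enumerate(shift)]
    dst = [slice(max(0, s), mask.shape[a] - max(0, -s)) for a, s in enumerate(shift)]
    out[tuple(dst)] = mask[tuple(src)]
    return out


def sample_subject_topography(truth: NetworkTruth, subject_id: str, seed: int,
                              max_shift_vox: int = 2,
                              grow_prob: float = 0.0,
                              min_overlap: float = 0.5,
                              max_tries: int = 200) -> SubjectTopography:
    """Jitter the truth mask into a subject-specific responsive region.

    A uniform integer shift within ``±max_shift_vox`` per axis (plus an
    optional single dilation/erosion step with probability ``grow_prob``
    each) is applied; candidates are redrawn until
    ``|subject ∩ truth| / |truth| >= min_overlap``.  Deterministic given
    ``seed``; raises if the constraint cannot be met.
    """
    if not 0.0 <= min_overlap <= 1.0:
        raise ValueError("min_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_truth = int(truth.mask.sum())
    for _ in range(max_tries):
        shift = tuple(int(s) for s in rng.integers(-max_shift_vox, max_shift_vox + 1, size=3))
        grow = 0
        if grow_prob and rng.uniform() < grow_prob:
            grow = int(rng.choice([-1, 1]))
        mask = _shift_mask(truth.mask, shift)
        if grow > 0:
            mask = ndimage.binary_dilation(mask, iterations=grow)
        elif grow < 0:
            eroded = ndimage.binary_erosion(mask, iterations=-grow)
            if eroded.any():
                mask = eroded
        if (mask & truth.mask).sum() / n_truth >= min_overlap:
            return SubjectTopography(subject_id, truth.name, mask, shift, grow)
    raise RuntimeError(
        f"could not satisfy min_overlap={min_overlap} for subject {subject_id!r} "
        f"within {max_tries} draws; reduce max_shift_vox or min_overlap")
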