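"""Subject-specific functional ROIs and percent-signal-change extraction.

Inside every group parcel, a subject's fROI is the top 10% most responsive
voxels of that subject's localizer z-map (floor rounding, minimum 1 voxel;
top-k is taken over the whole parcel even when the subject shows no
supra-threshold voxels there, which is flagged).  Estimates extracted from
an fROI must never come from the run that defined it: the across-run
cross-validation path defines the fROI on the held-in localizer run(s) and
averages the held-out run's estimate, removing the selection bias that a
circular (same-run) estimate carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .gss import ParcelAtlas
from .firstlevel import fixed_effects_combine

__all__ = ["FROIConfig", "SubjectFROI", "define_subject_froi", "FROIExtractor",
           "crossvalidated_psc", "extract_psc_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FROIConfig:
    top_fraction: float = 0.10
    min_voxels: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


@dataclass(frozen=True)
class SubjectFROI:
    subject_id: str
    parcel_id: int
    mask: np.ndarray
    n_voxels: int
    #: True when the subject had no positive z voxel inside the parcel
    empty_overlap: bool = False


def froi_size(parcel_size: int, top_fraction: float = 0.10, min_voxels: int = 1) -> int:
    """k = max(min_voxels, floor(top_fraction * parcel size))."""
    return max(min_voxels, int(np.floor(top_fraction * parcel_size)))


def define_subject_froi(parcel_mask: np.ndarray, z_map: np.ndarray,
                        top_fraction: float = 0.10, min_voxels: int = 1,
                        subject_id: str = "", parcel_id: int = 0) -> SubjectFROI:
    """Select the top-fraction highest-z voxels within the parcel.

    Ties are broken by lexicographic voxel index.  If the subject has no
    positive z inside the parcel the top-k voxels are still selected
    (flagged via ``empty_overlap`` and a log record).
    """
    parcel_mask = np.asarray(parcel_mask, dtype=bool)
    z_map = np.asarray(z_map, dtype=float)
    if parcel_mask.shape != z_map.shape:
        raise ValueError("parcel mask and z-map are not on the same grid")
    n_parcel = int(parcel_mask.sum())
    if n_parcel == 0:
        raise ValueError("parcel is empty")
    k = froi_size(n_parcel, top_fraction, min_voxels)
    flat_idx = np.flatnonzero(parcel_mask)
    vals = z_map.ravel()[flat_idx]
    order = np.lexsort((flat_idx, -vals))
    mask = np.zeros(z_map.shape, dtype=bool)
    mask.ravel()[flat_idx[order[:k]]] = True
    empty = bool((vals <= 0).all())
    if empty:
        log.warning("subject %s has no positive z in parcel %s; top-%d voxels "
                    "selected regardless", subject_id or "?", parcel_id or "?", k)
    return SubjectFROI(subject_id, parcel_id, mask, k, empty)


class FROIExtractor(BaseEstimator):
    """fROI definition + mean-PSC extraction for one subject and atlas.

    ``fit`` stores one :class:`SubjectFROI` per parcel from the defining
    z-map; ``transform`` averages a PSC volume within each fROI, returning a
    parcel-id -> value dict.
    """

    def __init__(self, top_fraction: float = 0.10, min_voxels: int = 1):
        self.top_fraction = top_fraction
        self.min_voxels = min_voxels

    def fit(self, atlas: ParcelAtlas, z_map: np.ndarray,
            subject_id: str = "") -> "FROIExtractor":
        self.frois_ = {
            pid: define_subject_froi(atlas.parcel_mask(pid), z_map,
                                     self.top_fraction, self.min_voxels,
                                     subject_id, pid)
            for pid in atlas.parcel_ids()}
        self.subject_id_ = subject_id
        return self

    def transform(self, psc_map: np.ndarray) -> dict[int, float]:
        return {pid: float(psc_map[froi.mask].mean())
                for pid, froi in self.frois_.items()}


def crossvalidated_psc(run_z_maps: list[np.ndarray],
                       run_psc_maps: list[dict[str, np.ndarray]],
                       parcel_mask: np.ndarray,
                       top_fraction: float = 0.10, min_voxels: int = 1,
                       allow_single_run: bool = False) -> dict[str, float]:
    """Across-run cross-validated PSC per condition for one parcel.

    For each fold, the fROI is defined on the fixed-effects z of the held-in
    runs and the held-out run's PSC maps are averaged within it; folds are
    then averaged.  ``run_psc_maps[i]`` maps condition -> PSC volume of run i.
    With a single run the estimate is circular; that path must be requested
    explicitly with ``allow_single_run=True``.
    """
    n_runs = len(run_z_maps)
    if n_runs != len(run_psc_maps):
        raise ValueError("z-map and PSC-map run counts differ")
    if n_runs < 2 and not allow_single_run:
        raise ValueError("cross-validation needs >= 2 runs; pass "
                         "allow_single_run=True for a circular estimate")
    conditions = list(run_psc_maps[0])
    fold_vals: dict[str, list[float]] = {c: [] for c in conditions}
    for held_out in range(n_runs):
        held_in = [i for i in range(n_runs) if i != held_out] or [held_out]
        if len(held_in) == 1:
            z_def = run_z_maps[held_in[0]]
        else:
            # pool defining runs by fixed effects with unit variances
            z_def = fixed_effects_combine([run_z_maps[i] for i in held_in],
                                          [np.ones_like(run_z_maps[i]) for i in held_in])[0]
        froi = define_subject_froi(parcel_mask, z_def, top_fraction, min_voxels)
        for cond in conditions:
            fold_vals[cond].append(float(run_psc_maps[held_out][cond][froi.mask].mean()))
    return {c: float(np.mean(v)) for c, v in fold_vals.items()}


def extract_psc_table(subject_frois: dict[str, dict[int, SubjectFROI]],
                      subject_psc_maps: dict[str, dict[str, np.ndarray]],
                      network_of_parcel: dict[int, str],
                      condition_codes: dict[str, float]) -> pd.DataFrame:
    """Long-format PSC table: one row per subject x parcel x condition.

    ``subject_frois[sid][pid]`` is the subject's fROI; ``subject_psc_maps
    [sid][condition]`` the subject's PSC volume for that condition.  Missing
    fROIs are skipped with a log record; a missing condition map is an error.
    """
    rows = []
    for sid, frois in subject_frois.items():
        psc_maps = subject_psc_maps[sid]
        for cond in condition_codes:
            if cond not in psc_maps:
                raise KeyError(f"subject {sid!r} has no PSC map for condition {cond!r}")
        for pid, froi in sorted(frois.items()):
            if froi is None or froi.n_voxels == 0:
                log.warning("skipping empty fROI: subject %s parcel %s", sid, pid)
                continue
            for cond, code in condition_codes.items():
                rows.append({"subject": sid, "roi": pid,
                             "network": network_of_parcel.get(pid, ""),
                             "condition": cond, "condition_code": float(code),
                             "psc": float(psc_maps[cond][froi.mask].mean())})
    return pd.DataFrame(rows, columns=["subject", "roi", "network", "condition",
                                       "condition_code", "psc"])
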