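"""First-level GLM: design matrices, OLS fits, contrasts, and PSC.

Each run is fitted voxelwise by ordinary least squares against a design
with one double-gamma-convolved regressor per task condition, an intercept,
a discrete-cosine high-pass basis (cutoff 100 s by default, kept inside the
design so degrees-of-freedom bookkeeping stays explicit), and optional
nuisance columns.  Contrast t statistics are mapped to z through the t
distribution at the model's residual degrees of freedom; per-condition
percent signal change scales the beta by the isolated-event response peak
and divides by the baseline (intercept) estimate.  Within-subject runs are
combined by voxelwise inverse-variance (fixed-effects) weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .bold import BOLDRun, DEFAULT_DT, condition_regressor, _condition_event_duration
from .hrf import HRFParams, isolated_response_peak
from .schedules import DesignSchedule

__all__ = ["DesignMatrix", "build_design_matrix", "FirstLevelGLM", "fit_glm",
           "contrast_z_map", "percent_signal_change", "fixed_effects_combine",
           "t_to_z"]


@dataclass(frozen=True)
class DesignMatrix:
    """Time x regressors matrix with labelled column groups."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    condition_cols: tuple[int, ...]
    highpass_cols: tuple[int, ...]
    nuisance_cols: tuple[int, ...]
    tr_s: float
    #: per-condition peak response of one isolated event (PSC scaling)
    isolated_peaks: dict[str, float] = field(default_factory=dict)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.condition_cols)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def _dct_basis(n_vols: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: K = floor(2 * T / cutoff) columns."""
    T = n_vols * tr_s
    k_max = int(np.floor(2.0 * T / cutoff_s))
    i = np.arange(n_vols)
    cols = [np.sqrt(2.0 / n_vols) * np.cos(np.pi * k * (2 * i + 1) / (2 * n_vols))
            for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


def build_design_matrix(schedule: DesignSchedule, tr_s: float,
                        n_vols: int | None = None,
                        hrf_params: HRFParams = HRFParams(),
                        highpass_cutoff_s: float | None = 100.0,
                        nuisance: np.ndarray | None = None,
                        nuisance_labels: tuple[str, ...] | None = None,
                        dt: float = DEFAULT_DT) -> DesignMatrix:
    """Intercept + convolved condition regressors + DCT high-pass + nuisance.

    Raises on rank deficiency, naming the collinear columns.
    """
    if n_vols is None:
        n_vols = schedule.n_volumes(tr_s)
    if n_vols < schedule.n_volumes(tr_s):
        raise ValueError("n_vols shorter than the schedule requires")
    cols = [np.ones(n_vols)]
    labels = ["intercept"]
    condition_cols = []
    peaks = {}
    for cond in schedule.conditions:
        condition_cols.append(len(cols))
        cols.append(condition_regressor(schedule, cond, tr_s, n_vols, hrf_params, dt))
        labels.append(cond)
        peaks[cond] = isolated_response_peak(
            _condition_event_duration(schedule, cond), hrf_params, dt)
    hp_cols = []
    if highpass_cutoff_s is not None:
        basis = _dct_basis(n_vols, tr_s, highpass_cutoff_s)
        for k in range(basis.shape[1]):
            hp_cols.append(len(cols))
            cols.append(basis[:, k])
            labels.append(f"dct{k + 1}")
    nu_cols = []
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_vols:
            nuisance = nuisance.T
        if nuisance.shape[0] != n_vols:
            raise ValueError("nuisance rows must equal n_vols")
        for k in range(nuisance.shape[1]):
            nu_cols.append(len(cols))
            cols.append(nuisance[:, k])
            label = (nuisance_labels[k] if nuisance_labels is not None
                     else f"nuisance{k + 1}")
            labels.append(label)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name offending columns via the QR diagonal
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [labels[i] for i in np.where(r_diag < 1e-8 * r_diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"collinear columns: {bad or 'undetermined'}")
    return DesignMatrix(X, tuple(labels), tuple(condition_cols), tuple(hp_cols),
                        tuple(nu_cols), float(tr_s), peaks)


class FirstLevelGLM(BaseEstimator):
    """Voxelwise OLS of a single BOLD run against a :class:`DesignMatrix`.

    Fitted attributes
    -----------------
    beta_ : (p, *vol_shape) ndarray
        Coefficient volumes, one per design column.
    sigma2_ : (*vol_shape) ndarray
        Residual variance with ``dof_`` degrees of freedom.
    dof_ : int
        n_volumes - rank(X).
    mask_ : bool volume
        Voxels with nonzero residual variance (or nonzero data).
    """

    def fit(self, run: "BOLDRun | np.ndarray", design: DesignMatrix) -> "FirstLevelGLM":
        data = run.data if isinstance(run, BOLDRun) else np.asarray(run, dtype=float)
        if data.ndim != 4:
            raise ValueError("run data must be 4-D (x, y, z, t)")
        X = design.matrix
        if data.shape[3] != X.shape[0]:
            raise ValueError(
                f"run has {data.shape[3]} volumes but design has {X.shape[0]} rows")
        vol_shape = data.shape[:3]
        Y = data.reshape(-1, data.shape[3]).T  # time x voxels
        rank = np.linalg.matrix_rank(X)
        pinv = np.linalg.pinv(X)
        beta = pinv @ Y
        resid = Y - X @ beta
        dof = X.shape[0] - rank
        sigma2 = (resid ** 2).sum(axis=0) / dof
        # numerically perfect fits (constant or noiseless data): variance is
        # round-off, not noise -> treat as exactly 0 so z gets masked
        scale = (Y ** 2).mean(axis=0)
        sigma2[sigma2 <= 1e-24 * np.maximum(scale, 1e-300)] = 0.0
        self.design_ = design
        self.beta_ = beta.reshape(X.shape[1], *vol_shape)
        self.sigma2_ = sigma2.reshape(vol_shape)
        self.dof_ = int(dof)
        self.xtx_inv_ = pinv @ pinv.T  # (X'X)^-1 for full-rank X
        self.mask_ = self.sigma2_ > 0
        return self

    # -- downstream quantities -------------------------------------------
    def condition_beta(self, condition: str) -> np.ndarray:
        idx = self.design_.conditions.index(condition)
        return self.beta_[self.design_.condition_cols[idx]]

    def contrast(self, weights) -> tuple[np.ndarray, np.ndarray]:
        """Effect and variance volumes for a condition-space contrast.

        ``weights`` is either a vector over the condition regressors in
        design order, or — safer when block order is counterbalanced — a
        ``{condition: weight}`` mapping (missing conditions weigh 0).
        """
        cols = self.design_.condition_cols
        if isinstance(weights, dict):
            unknown = set(weights) - set(self.design_.conditions)
            if unknown:
                raise ValueError(f"unknown contrast conditions: {sorted(unknown)}")
            w = np.array([float(weights.get(c, 0.0)) for c in self.design_.conditions])
        else:
            w = np.asarray(weights, dtype=float)
        if w.size != len(cols):
            raise ValueError(f"contrast length {w.size} != {len(cols)} condition regressors")
        c = np.zeros(self.design_.matrix.shape[1])
        c[list(cols)] = w
        effect = np.tensordot(c, self.beta_, axes=(0, 0))
        var = self.sigma2_ * float(c @ self.xtx_inv_ @ c)
        return effect, var

    def contrast_z(self, weights) -> np.ndarray:
        effect, var = self.contrast(weights)
        return t_to_z(np.divide(effect, np.sqrt(var), out=np.zeros_like(effect),
                                where=var > 0), self.dof_)

    def psc(self, condition: str, baseline_estimate: str = "intercept") -> np.ndarray:
        """Percent signal change of one condition.

        psc = 100 * beta * (isolated-event regressor peak) / baseline, with
        the baseline taken from the intercept column (default) or the voxel
        temporal mean.  Nonpositive-baseline voxels are masked to 0.
        """
        beta = self.condition_beta(condition)
        peak = self.design_.isolated_peaks[condition]
        if baseline_estimate == "intercept":
            base = self.beta_[0]
        elif baseline_estimate == "mean":
            base = np.tensordot(self.design_.matrix.mean(axis=0), self.beta_, axes=(0, 0))
        else:
            raise ValueError("baseline_estimate must be 'intercept' or 'mean'")
        out = np.zeros_like(beta)
        np.divide(100.0 * beta * peak, base, out=out, where=base > 0)
        return out


def t_to_z(t_map: np.ndarray, dof: float) -> np.ndarray:
    """Map t values to standard-normal z at finite dof (identity above 1000)."""
    t_map = np.asarray(t_map, dtype=float)
    if dof > 1000:
        return t_map.copy()
    # two one-sided conversions keep tail precision
    z = np.empty_like(t_map)
    pos = t_map >= 0
    # clamp the tail probability so z stays finite when sf underflows
    z[pos] = stats.norm.isf(np.clip(stats.t.sf(t_map[pos], dof), 1e-300, 1.0))
    z[~pos] = -stats.norm.isf(np.clip(stats.t.sf(-t_map[~pos], dof), 1e-300, 1.0))
    return z


# ------------------------------------------------------- module-level wrappers

def fit_glm(run: "BOLDRun | np.ndarray", design: DesignMatrix) -> FirstLevelGLM:
    return FirstLevelGLM().fit(run, design)


def contrast_z_map(glm: FirstLevelGLM, weights) -> np.ndarray:
    return glm.contrast_z(weights)


def percent_signal_change(glm: FirstLevelGLM, condition: str,
                          baseline_estimate: str = "intercept") -> np.ndarray:
    return glm.psc(condition, baseline_estimate)


def fixed_effects_combine(effects: list[np.ndarray], variances: list[np.ndarray]
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse-variance-weighted within-subject combination across runs.

    Returns (combined effect, combined variance, z).  Voxels where a run has
    infinite variance simply drop that run; all-degenerate voxels are 0.
    """
    if len(effects) < 2:
        raise ValueError("need at least two runs to combine")
    shapes = {e.shape for e in effects} | {v.shape for v in variances}
    if len(shapes) != 1:
        raise ValueError("runs are not on the same grid")
    w_sum = np.zeros_like(effects[0])
    ew_sum = np.zeros_like(effects[0])
    for e, v in zip(effects, variances):
        w = np.zeros_like(v)
        good = np.isfinite(v) & (v > 0)
        w[good] = 1.0 / v[good]
        w_sum += w
        ew_sum += np.where(good, e * w, 0.0)
    effect = np.divide(ew_sum, w_sum, out=np.zeros_like(ew_sum), where=w_sum > 0)
    var = np.divide(1.0, w_sum, out=np.full_like(w_sum, np.inf), where=w_sum > 0)
    z = np.divide(effect, np.sqrt(var), out=np.zeros_like(effect),
                  where=np.isfinite(var) & (var > 0))
    return effect, var, z
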