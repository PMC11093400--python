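"""Forward BOLD simulation on the phantom.

signal(v, t) = baseline * (1 + sum_c amp_c(v)/100 * r_c(t))  + drift + noise

where r_c is the double-gamma-convolved regressor of condition ``c`` scaled
so that an isolated event of that condition peaks at 1 — i.e. a planted
amplitude of ``a`` means the response to one isolated trial/block peaks at
``a`` percent of baseline.  Amplitudes are nonzero only inside the subject's
responsive topography.  Noise is white Gaussian passed through an AR(1)
recursion plus an optional per-voxel linear drift; everything is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .grid import VolumeGrid
from .hrf import HRFParams, isolated_response_peak
from .phantom import NetworkTruth, SubjectTopography
from .schedules import DesignSchedule

__all__ = ["NoiseParams", "BOLDRun", "simulate_bold_run"]

#: time step (s) of the oversampled grid used for HRF convolution; shared
#: with the first-level design matrix so simulation and analysis use the
#: same regressor convention.
DEFAULT_DT = 0.05


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise: white innovation sd (signal units), AR(1) coefficient
    in [0, 1), and the half-range of per-voxel linear drift over the run."""
    white_sd: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class BOLDRun:
    data: np.ndarray  # (x, y, z, t)
    tr_s: float
    schedule: DesignSchedule
    subject_id: str
    run_id: str
    seed: int

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def fine_time_grid(total_duration_s: float, dt: float = DEFAULT_DT) -> np.ndarray:
    return np.arange(0.0, total_duration_s + 32.0, dt)


def convolved_regressor(schedule: DesignSchedule, condition: str,
                        hrf_params: HRFParams = HRFParams(),
                        dt: float = DEFAULT_DT) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved boxcar of one condition on the oversampled grid.

    Returns ``(t_fine, regressor)``; the dt-weighted convolution makes the
    regressor's integral equal (total event time) x (HRF integral / peak).
    """
    from .hrf import double_gamma_hrf  # local import keeps module load cheap

    t = fine_time_grid(schedule.total_duration_s, dt)
    box = np.zeros_like(t)
    for ev in schedule.task_events(condition):
        i0 = int(round(ev.onset_s / dt))
        i1 = int(round((ev.onset_s + ev.duration_s) / dt))
        box[i0:i1] = 1.0
    kernel = double_gamma_hrf(dt, hrf_params, duration_s=32.0)
    reg = sps.fftconvolve(box, kernel)[: t.size] * dt
    return t, reg


def condition_regressor(schedule: DesignSchedule, condition: str, tr_s: float,
                        n_vols: int, hrf_params: HRFParams = HRFParams(),
                        dt: float = DEFAULT_DT) -> np.ndarray:
    """Convolved regressor sampled at volume acquisition times i * tr."""
    t, reg = convolved_regressor(schedule, condition, hrf_params, dt)
    t_vol = np.arange(n_vols) * tr_s
    return np.interp(t_vol, t, reg)


def _condition_event_duration(schedule: DesignSchedule, condition: str) -> float:
    durs = [ev.duration_s for ev in schedule.task_events(condition)]
    if not durs:
        raise ValueError(f"schedule has no events of condition {condition!r}")
    return float(np.median(durs))


def scaled_condition_regressor(schedule: DesignSchedule, condition: str, tr_s: float,
                               n_vols: int, hrf_params: HRFParams = HRFParams(),
                               dt: float = DEFAULT_DT) -> np.ndarray:
    """Regressor normalised by the isolated-event response peak, so a unit
    coefficient corresponds to a 1-unit peak response to one event."""
    peak = isolated_response_peak(_condition_event_duration(schedule, condition),
                                  hrf_params, dt)
    return condition_regressor(schedule, condition, tr_s, n_vols, hrf_params, dt) / peak


def simulate_bold_run(grid: VolumeGrid,
                      truths: list[NetworkTruth],
                      topographies: list[SubjectTopography],
                      schedule: DesignSchedule,
                      subject_id: str,
                      run_id: str,
                      seed: int,
                      tr_s: float = 1.4,
                      noise: NoiseParams = NoiseParams(),
                      baseline: float = 100.0,
                      hrf_params: HRFParams = HRFParams()) -> BOLDRun:
    """Simulate one 4-D BOLD run for one subject.

    Amplitudes come from each network's ``subject_amplitudes[subject_id]``
    and apply inside that subject's responsive topography for the network.
    Deterministic given ``seed``.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    n_vols = schedule.n_volumes(tr_s)
    topo_by_net = {t.network: t for t in topographies if t.subject_id == subject_id}

    data = np.full((*grid.shape, n_vols), float(baseline))
    conds = schedule.conditions
    regs = {c: scaled_condition_regressor(schedule, c, tr_s, n_vols, hrf_params)
            for c in conds}
    for truth in truths:
        topo = topo_by_net.get(truth.name)
        if topo is None:
            continue
        amps = truth.subject_amplitudes.get(subject_id, {})
        resp = np.zeros(n_vols)
        for cond, amp in amps.items():
            if cond in regs and amp != 0.0:
                resp = resp + amp / 100.0 * regs[cond]
        if np.any(resp):
            data[grid.check_volume(topo.mask, "topography")] += baseline * resp

    rng = np.random.default_rng(seed)
    n_vox = grid.n_voxels
    if noise.drift_amplitude > 0:
        slopes = rng.uniform(-noise.drift_amplitude, noise.drift_amplitude, size=n_vox)
        ramp = np.linspace(-0.5, 0.5, n_vols)
        data += (slopes[:, None] * ramp[None, :]).reshape(*grid.shape, n_vols)
    if noise.white_sd > 0:
        w = rng.normal(0.0, noise.white_sd, size=(n_vox, n_vols))
        if noise.ar1 > 0:
            w = sps.lfilter([1.0], [1.0, -noise.ar1], w, axis=1)
        data += w.reshape(*grid.shape, n_vols)
    return BOLDRun(data, tr_s, schedule, subject_id, run_id, int(seed))
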