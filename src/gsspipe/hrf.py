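"""Double-gamma hemodynamic response function.

The canonical BOLD impulse response is modelled as the difference of two
gamma densities: a positive lobe peaking ~5 s after stimulus onset and a
late negative undershoot, scaled so the continuous-time peak equals 1.
Normalising by the *continuous* peak (located numerically on a millisecond
grid) rather than the peak of the sampled kernel makes kernels sampled at
different repetition times consistent decimations of one another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFParams:
    """Shape parameters of the double-gamma impulse response (seconds).

    ``peak_delay_s`` / ``undershoot_delay_s`` are the gamma means,
    ``*_dispersion_s`` their scale, and ``undershoot_ratio`` the relative
    amplitude of the negative lobe (SPM-style defaults).
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("peak_delay_s", "undershoot_delay_s",
                     "peak_dispersion_s", "undershoot_dispersion_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")


def _raw_hrf(t: np.ndarray, params: HRFParams) -> np.ndarray:
    """Unnormalised double-gamma evaluated at times ``t`` (s)."""
    peak = stats.gamma.pdf(t, params.peak_delay_s / params.peak_dispersion_s,
                           scale=params.peak_dispersion_s)
    under = stats.gamma.pdf(t, params.undershoot_delay_s / params.undershoot_dispersion_s,
                            scale=params.undershoot_dispersion_s)
    return peak - params.undershoot_ratio * under

_PEAK_DT = 0.001  # s; grid used to locate the continuous-time peak


def hrf_peak_value(params: HRFParams = HRFParams(), duration_s: float = 32.0) -> float:
    """Continuous-time peak of the unnormalised kernel (ms-grid search)."""
    t = np.arange(0.0, duration_s, _PEAK_DT)
    return float(_raw_hrf(t, params).max())


def double_gamma_hrf(tr_s: float, params: HRFParams = HRFParams(),
                     duration_s: float = 32.0) -> np.ndarray:
    """Sample the peak-normalised double-gamma HRF at multiples of ``tr_s``.

    Parameters
    ----------
    tr_s : float
        Sampling interval in seconds (> 0).
    params : HRFParams
        Shape parameters; defaults give a peak between 4 and 7 s and a
        negative undershoot around 10-20 s.
    duration_s : float
        Kernel support; should cover the undershoot (default 32 s).

    Returns
    -------
    ndarray
        Kernel sampled at t = 0, tr, 2*tr, ... < duration_s, with the
        continuous-time maximum normalised to 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    t = np.arange(0.0, duration_s, tr_s)
    return _raw_hrf(t, params) / hrf_peak_value(params, duration_s)


def isolated_response_peak(event_duration_s: float,
                           params: HRFParams = HRFParams(),
                           dt: float = 0.05) -> float:
    """Peak of the normalised HRF convolved with one isolated boxcar event.

    This is the percent-signal-change scaling convention used throughout the
    pipeline: a planted amplitude of ``a`` percent means the response to an
    isolated event/block of this duration peaks at ``a`` percent above
    baseline.  The same factor converts a GLM beta back into percent signal
    change, which makes simulate -> fit -> PSC the identity.
    """
    if event_duration_s <= 0:
        raise ValueError("event_duration_s must be > 0")
    kernel = double_gamma_hrf(dt, params, duration_s=32.0)
    box = np.ones(max(1, int(round(event_duration_s / dt))))
    # dt-weighted discrete convolution approximates the continuous integral
    return float(np.convolve(box, kernel).max() * dt)
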