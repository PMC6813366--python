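"""Jackknife CV profiles of EPSP amplitude trains.

The coefficient of variation (CV = SD/mean) of EPSP amplitudes across
protocol repetitions is the variability statistic the pool-size
estimator matches.  Measuring amplitudes on raw sweeps confounds the
release variability with membrane noise; the jackknife variant instead
measures each amplitude on a leave-one-out average trace (which
suppresses the noise by averaging) and reconstructs the per-observation
spread with the jackknife scaling

    std_n = sqrt((N - 1) * sum_i (A_in - Abar_n)^2)

which equals the plain sample SD exactly whenever the amplitude is a
linear functional of the single sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol

__all__ = [
    "CVProfile",
    "PowerLawFit",
    "jkk_mean_traces",
    "epsp_amplitudes",
    "sweep_amplitude_matrix",
    "cv_profile",
    "profile_distance",
    "fit_power_law",
]


@dataclass
class CVProfile:
    """Per-pulse CV and mean amplitude for one connection.

    ``cv`` entries are NaN where the mean amplitude is zero (flagged,
    not raised).
    """

    cv: np.ndarray
    mean_amp_mv: np.ndarray
    n_sweeps: int

    def __post_init__(self) -> None:
        self.cv = np.asarray(self.cv, dtype=float)
        self.mean_amp_mv = np.asarray(self.mean_amp_mv, dtype=float)
        if self.cv.shape != self.mean_amp_mv.shape:
            raise ValueError("cv and mean amplitude lengths differ")
        if self.n_sweeps < 2:
            raise ValueError("a CV profile needs at least 2 sweeps")


@dataclass
class PowerLawFit:
    """CV = a * N^b fitted by log-log least squares."""

    amplitude: float
    index: float
    residual: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("power-law amplitude must be positive")

    def __call__(self, n: np.ndarray) -> np.ndarray:
        return self.amplitude * np.asarray(n, dtype=float) ** self.index


def jkk_mean_traces(sweeps_mv: np.ndarray) -> np.ndarray:
    """Leave-one-out average traces: row i is the mean of all sweeps but i."""
    v = np.atleast_2d(np.asarray(sweeps_mv, dtype=float))
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sweeps for leave-one-out averages")
    total = v.sum(axis=0, keepdims=True)
    return (total - v) / (n - 1)


def _window_indices(
    protocol: StimulusProtocol, dt_ms: float, n_samples: int
) -> list[tuple[slice, slice]]:
    out = []
    for pre_start, t, post_end in protocol.amplitude_windows():
        i_pre = slice(int(round(pre_start / dt_ms)), int(round(t / dt_ms)))
        i_post = slice(int(round(t / dt_ms)), int(round(post_end / dt_ms)))
        if i_pre.start < 0 or i_post.stop > n_samples:
            raise ValueError("amplitude window falls outside the trace")
        out.append((i_pre, i_post))
    return out


def sweep_amplitude_matrix(
    sweeps_mv: np.ndarray, dt_ms: float, protocol: StimulusProtocol
) -> np.ndarray:
    """EPSP amplitudes for every sweep and pulse, shape (n_sweeps, n_stimuli).

    amplitude_n = max(V in post window of pulse n) - min(V in the 50 ms
    pre window); the post window runs to the next pulse, capped at
    300 ms.
    """
    v = np.atleast_2d(np.asarray(sweeps_mv, dtype=float))
    windows = _window_indices(protocol, dt_ms, v.shape[1])
    amps = np.empty((v.shape[0], len(windows)))
    for n, (i_pre, i_post) in enumerate(windows):
        amps[:, n] = v[:, i_post].max(axis=1) - v[:, i_pre].min(axis=1)
    return amps


def epsp_amplitudes(
    trace_mv: np.ndarray, dt_ms: float, protocol: StimulusProtocol
) -> np.ndarray:
    """Amplitudes of the 9 EPSPs on a single (typically averaged) trace."""
    return sweep_amplitude_matrix(trace_mv[None, :], dt_ms, protocol)[0]


def cv_profile(
    sweeps_mv: np.ndarray,
    dt_ms: float,
    protocol: StimulusProtocol,
    use_jkk: bool = True,
) -> CVProfile:
    """CV profile of one connection's sweep set.

    With ``use_jkk`` the amplitudes are measured on the N leave-one-out
    average traces and the SD is reconstructed with the jackknife
    scaling; without it ("analytical" CV) the plain sample SD/mean of
    the per-sweep amplitudes is used.
    """
    v = np.atleast_2d(np.asarray(sweeps_mv, dtype=float))
    n = v.shape[0]
    if use_jkk:
        amps = sweep_amplitude_matrix(jkk_mean_traces(v), dt_ms, protocol)
        mean_amp = amps.mean(axis=0)
        std = np.sqrt((n - 1) * ((amps - mean_amp) ** 2).sum(axis=0))
    else:
        amps = sweep_amplitude_matrix(v, dt_ms, protocol)
        mean_amp = amps.mean(axis=0)
        std = amps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_amp != 0.0, std / mean_amp, np.nan)
    return CVProfile(cv=cv, mean_amp_mv=mean_amp, n_sweeps=n)


def profile_distance(p: CVProfile | np.ndarray, q: CVProfile | np.ndarray) -> float:
    """Mean squared difference between two CV profiles."""
    pv = p.cv if isinstance(p, CVProfile) else np.asarray(p, dtype=float)
    qv = q.cv if isinstance(q, CVProfile) else np.asarray(q, dtype=float)
    if pv.shape != qv.shape:
        raise ValueError("profiles must have the same length")
    return float(np.mean((pv - qv) ** 2))


def fit_power_law(n_rrp: np.ndarray, cv: np.ndarray) -> PowerLawFit:
    """Least-squares fit of CV = a * N^b on log-log axes."""
    n = np.asarray(n_rrp, dtype=float)
    y = np.asarray(cv, dtype=float)
    if n.size < 3:
        raise ValueError("need at least 3 pool-size levels")
    if np.any(n <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive N and CV values")
    b, log_a = np.polyfit(np.log(n), np.log(y), 1)
    resid = float(np.mean((np.log(y) - (log_a + b * np.log(n))) ** 2))
    return PowerLawFit(amplitude=float(np.exp(log_a)), index=float(b), residual=resid)
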