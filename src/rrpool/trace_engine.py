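"""Membrane-voltage sweep synthesis and Ornstein-Uhlenbeck noise.

Release events are turned into voltage sweeps through a linear passive
membrane: each released quantum injects a current with instantaneous
rise and exponential decay (time constant ``tau_syn``) at a fixed
driving force ``E_rev - V_rest``, which the RC membrane (time constant
``tau_mem``, input resistance ``R_input``) filters into the familiar
two-exponential EPSP shape.  Because the drive is current-based the
membrane is exactly linear, so sweep synthesis commutes with event
superposition and is the exact inverse of the voltage deconvolution
operator used for fitting.

Background membrane noise is modelled as a stationary Ornstein-Uhlenbeck
process with standard deviation ``sigma`` and correlation time ``tau``,
discretized as

    X(t+dt) = X(t) - X(t)/tau * dt + sigma * sqrt(2 dt / tau) * W_t
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .protocol import StimulusProtocol
from .synapse_model import ReleaseEventSeries

__all__ = [
    "MembraneModel",
    "NoiseParams",
    "SweepTrace",
    "psp_kernel",
    "synthesize_sweep",
    "synthesize_sweep_matrix",
    "ou_generate",
    "estimate_ou_params",
    "estimate_connection_noise",
    "OUFit",
]


@dataclass(frozen=True)
class MembraneModel:
    """Passive postsynaptic membrane and synaptic conductance kinetics.

    Defaults reproduce juvenile-rat L5 thick-tufted pyramidal cells:
    resting potential -65.3 mV, input resistance 59.7 MOhm, membrane
    time constant 28.2 ms, AMPA-like synaptic decay 1.7 ms, glutamatergic
    reversal potential 0 mV.
    """

    tau_mem_ms: float = 28.2
    r_input_mohm: float = 59.7
    v_rest_mv: float = -65.3
    tau_syn_ms: float = 1.7
    e_rev_mv: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau_mem_ms > self.tau_syn_ms > 0:
            raise ValueError("require tau_mem > tau_syn > 0")
        if self.r_input_mohm <= 0:
            raise ValueError("R_input must be positive")

    @property
    def driving_force_mv(self) -> float:
        return self.e_rev_mv - self.v_rest_mv

    def to_dict(self) -> dict:
        return {
            "tau_mem_ms": self.tau_mem_ms,
            "r_input_mohm": self.r_input_mohm,
            "v_rest_mv": self.v_rest_mv,
            "tau_syn_ms": self.tau_syn_ms,
            "e_rev_mv": self.e_rev_mv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneModel":
        return cls(**d)


@dataclass(frozen=True)
class NoiseParams:
    """Stationary OU noise: SD sigma (mV) and correlation time tau (ms)."""

    sigma_mv: float = 0.22
    tau_ms: float = 28.2

    def __post_init__(self) -> None:
        if self.sigma_mv < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")

    def to_dict(self) -> dict:
        return {"sigma_mv": self.sigma_mv, "tau_ms": self.tau_ms}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseParams":
        return cls(**d)


@dataclass
class SweepTrace:
    """Voltage samples (mV) on a uniform time grid with step dt (ms)."""

    dt_ms: float
    v_mv: np.ndarray

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        v = np.asarray(self.v_mv, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("voltage samples must be a finite 1-D array")
        self.v_mv = v

    @property
    def t_ms(self) -> np.ndarray:
        return self.dt_ms * np.arange(self.v_mv.size)

    def __len__(self) -> int:
        return self.v_mv.size


def psp_kernel(membrane: MembraneModel, dt_ms: float, n_samples: int) -> np.ndarray:
    """Voltage response (mV) to one 1-nS conductance quantum at t = 0.

    Closed form for the RC membrane driven by I(t) = g0 e^{-t/tau_syn}
    (E_rev - V_rest):

        dV(t) = R g0 (E - Vr) tau_s / (tau_m - tau_s)
                * (exp(-t/tau_m) - exp(-t/tau_s))

    with g0 = 1 nS; units work out to mV with R in MOhm.
    """
    t = dt_ms * np.arange(n_samples)
    i0_na = 1e-3 * membrane.driving_force_mv  # 1 nS * mV -> nA
    coef = (
        membrane.r_input_mohm
        * i0_na
        * membrane.tau_syn_ms
        / (membrane.tau_mem_ms - membrane.tau_syn_ms)
    )
    return coef * (np.exp(-t / membrane.tau_mem_ms) - np.exp(-t / membrane.tau_syn_ms))


def _ar1_coeffs(noise: NoiseParams, dt_ms: float) -> tuple[float, float]:
    if dt_ms >= noise.tau_ms:
        raise ValueError("dt must be smaller than the noise correlation time")
    a = 1.0 - dt_ms / noise.tau_ms
    b = noise.sigma_mv * np.sqrt(2.0 * dt_ms / noise.tau_ms)
    return a, b


def ou_generate(
    noise: NoiseParams,
    dt_ms: float,
    n_samples: int,
    x0_mv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One OU realization of length ``n_samples`` starting at x0."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return _ou_batch(noise, dt_ms, (1, n_samples), rng, x0=np.array([x0_mv]))[0]


def _ou_batch(
    noise: NoiseParams,
    dt_ms: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Batch of independent OU traces, shape (n_traces, n_samples).

    With ``x0`` omitted, initial values are drawn from the stationary
    distribution N(0, sigma^2).
    """
    a, b = _ar1_coeffs(noise, dt_ms)
    n_traces, n_samples = shape
    if x0 is None:
        x0 = noise.sigma_mv * rng.standard_normal(n_traces)
    if noise.sigma_mv == 0.0:
        k = np.arange(n_samples)
        return np.outer(x0, a**k)
    w = rng.standard_normal((n_traces, n_samples - 1))
    out = np.empty((n_traces, n_samples))
    out[:, 0] = x0
    # X[k] = a X[k-1] + b W[k]: AR(1) recursion via an IIR filter
    zi = (a * x0)[:, None]
    out[:, 1:], _ = signal.lfilter([b], [1.0, -a], w, axis=1, zi=zi)
    return out


def synthesize_sweep(
    membrane: MembraneModel,
    events: ReleaseEventSeries,
    protocol: StimulusProtocol,
    noise: NoiseParams,
    dt_ms: float = 0.1,
    rng: np.random.Generator | None = None,
    duration_ms: float | None = None,
) -> SweepTrace:
    """Synthesize one voltage sweep from a release-event series."""
    if rng is None:
        rng = np.random.default_rng()
    if duration_ms is None:
        duration_ms = protocol.sweep_duration_ms()
    v = synthesize_sweep_matrix(
        membrane,
        events.conductances_ns[None, :],
        events.spike_times_ms,
        duration_ms,
        dt_ms,
        noise,
        rng,
    )[0]
    return SweepTrace(dt_ms, v)


def synthesize_sweep_matrix(
    membrane: MembraneModel,
    conductances_ns: np.ndarray,
    spike_times_ms: np.ndarray,
    duration_ms: float,
    dt_ms: float,
    noise: NoiseParams | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Synthesize many sweeps at once.

    ``conductances_ns`` has shape (n_sweeps, n_spikes).  Returns the
    (n_sweeps, n_samples) voltage matrix in mV, resting potential
    included.  Pass ``noise=None`` for noiseless sweeps.
    """
    if dt_ms >= membrane.tau_syn_ms:
        raise ValueError("dt must resolve the synaptic decay (dt < tau_syn)")
    g = np.asarray(conductances_ns, dtype=float)
    n_sweeps, n_spikes = g.shape
    n_samples = int(round(duration_ms / dt_ms))
    if np.any(np.asarray(spike_times_ms) >= duration_ms):
        raise ValueError("event times must fall within the sweep duration")
    kernel = psp_kernel(membrane, dt_ms, n_samples)
    v = np.zeros((n_sweeps, n_samples))
    for k in range(n_spikes):
        i0 = int(round(spike_times_ms[k] / dt_ms))
        seg = n_samples - i0
        v[:, i0:] += g[:, k, None] * kernel[:seg]
    if noise is not None and noise.sigma_mv > 0:
        if rng is None:
            raise ValueError("rng required when noise is enabled")
        v += _ou_batch(noise, dt_ms, (n_sweeps, n_samples), rng)
    return v + membrane.v_rest_mv


@dataclass
class OUFit:
    """Outcome of OU parameter estimation on a stimulus-free segment."""

    params: NoiseParams | None
    sigma_mv: float
    tau_ms: float  # nan when undefined
    ok: bool
    message: str = ""


def estimate_ou_params(segment: SweepTrace, max_lag_ms: float = 80.0) -> OUFit:
    """Estimate sigma and tau from one detrended stimulus-free segment.

    tau comes from a least-squares fit of ``(1 - c) exp(-lag/tau) + c``
    to the empirical autocorrelation; the free offset c absorbs the
    downward bias (about 2 tau / length) that subtracting the sample
    mean imprints on the autocorrelation of a short segment.  sigma is
    the sample SD corrected for the same finite-segment effect by
    ``1 / sqrt(1 - 2 tau / T)``.  Flags, rather than raises, on
    degenerate input (constant segment, non-decaying autocorrelation).
    """
    x = segment.v_mv - segment.v_mv.mean()
    sigma = float(x.std())
    if sigma == 0.0:
        return OUFit(None, 0.0, np.nan, False, "constant segment: tau undefined")
    n = x.size
    max_lag = min(int(max_lag_ms / segment.dt_ms), n - 2)
    acov = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    rho = acov / acov[0] * (n / (n - np.arange(max_lag + 1)))  # per-lag norm
    lags = segment.dt_ms * np.arange(max_lag + 1)
    try:
        (tau, _c), _ = optimize.curve_fit(
            lambda l, tau, c: (1.0 - c) * np.exp(-l / tau) + c,
            lags,
            rho,
            p0=[max(lags[-1] / 5.0, segment.dt_ms), 0.0],
            bounds=([1e-9, -0.5], [np.inf, 0.5]),
            maxfev=2000,
        )
    except RuntimeError:
        return OUFit(None, sigma, np.nan, False, "autocorrelation fit failed")
    tau = float(tau)
    # variance of a mean-subtracted segment underestimates the stationary
    # variance by a factor of about (1 - 2 tau / T)
    t_total = segment.dt_ms * n
    sigma = float(sigma / np.sqrt(max(1.0 - 2.0 * tau / t_total, 0.25)))
    if tau <= 2.0 * segment.dt_ms:
        warnings.warn(
            "fitted noise correlation time is at the sampling resolution; "
            "segment is white-noise-like",
            stacklevel=2,
        )
    return OUFit(NoiseParams(sigma, tau), sigma, tau, True)


def estimate_connection_noise(
    sweeps_mv: np.ndarray,
    dt_ms: float,
    protocol: StimulusProtocol,
    guard_ms: float = 50.0,
) -> OUFit:
    """Per-connection noise estimate: fit each sweep's stimulus-free
    segment separately and average sigma and tau across sweeps."""
    start, stop = protocol.noise_window_ms(guard_ms)
    i0, i1 = int(round(start / dt_ms)), int(round(stop / dt_ms))
    sigmas, taus = [], []
    for row in np.atleast_2d(sweeps_mv):
        fit = estimate_ou_params(SweepTrace(dt_ms, row[i0:i1]))
        if fit.ok:
            sigmas.append(fit.sigma_mv)
            taus.append(fit.tau_ms)
    if not sigmas:
        return OUFit(None, 0.0, np.nan, False, "no sweep yielded a valid fit")
    sigma, tau = float(np.mean(sigmas)), float(np.mean(taus))
    return OUFit(NoiseParams(sigma, tau), sigma, tau, True)
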