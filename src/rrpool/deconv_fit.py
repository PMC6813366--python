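"""Recovering synapse parameters from sweep sets.

The fitting pipeline mirrors the classical quantal-analysis workflow:

1. estimate the membrane time constant from a single-exponential fit to
   the decay of the recovery (9th) EPSP of the averaged trace;
2. deconvolve the averaged, normalized trace with the passive-membrane
   operator ``tau_mem * dV/dt + V``, which undoes the RC low-pass
   filtering and exposes the synaptic drive as sharp peaks;
3. extract the nine per-pulse peaks;
4. fit U, D, F of the deterministic short-term-plasticity recursion to
   the normalized peaks with a genetic algorithm (best of 50 restarts
   of 500 generations each, minimizing the mean squared peak distance);
5. at population level, select the best-fitting family (beta, gamma or
   normal) for each parameter's distribution by Kolmogorov-Smirnov
   goodness of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .cv_stats import epsp_amplitudes
from .protocol import StimulusProtocol
from .synapse_model import TMParams
from .trace_engine import SweepTrace

__all__ = [
    "PeakVector",
    "GAConfig",
    "TauMemFit",
    "DistributionFit",
    "ConnectionFit",
    "fit_tau_mem",
    "deconvolve",
    "extract_peaks",
    "fit_tm_ga",
    "fit_param_distributions",
    "fit_connection",
]


@dataclass
class PeakVector:
    """Deconvolved EPSP peak values (normalized units) and pulse times."""

    values: np.ndarray
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != self.times_ms.shape:
            raise ValueError("values and times must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("peak values must be finite")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the U/D/F fit.

    Parameter search ranges: U in [0, 1], D in [0, 1000] ms, F in
    [0, 2000] ms.  The GA internals (tournament selection of size 3,
    uniform crossover, Gaussian mutation with SD 5% of each range,
    one-elite survival) are conventional choices; any configuration
    keeping the best-of-generation error non-increasing works.
    """

    generations: int = 500
    restarts: int = 50
    population: int = 100
    tournament: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    mutation_sigma_frac: float = 0.05
    u_range: tuple[float, float] = (0.0, 1.0)
    d_range: tuple[float, float] = (0.0, 1000.0)
    f_range: tuple[float, float] = (0.0, 2000.0)

    def __post_init__(self) -> None:
        if self.generations < 1 or self.restarts < 1 or self.population < 2:
            raise ValueError("generations, restarts >= 1 and population >= 2")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.u_range[0], self.d_range[0], self.f_range[0]])
        hi = np.array([self.u_range[1], self.d_range[1], self.f_range[1]])
        return lo, hi


@dataclass
class TauMemFit:
    tau_mem_ms: float
    ok: bool
    message: str = ""
    amplitude_mv: float = np.nan
    offset_mv: float = np.nan


def fit_tau_mem(
    mean_trace: SweepTrace,
    protocol: StimulusProtocol,
    skip_ms: float = 5.0,
    fit_span_ms: float = 250.0,
) -> TauMemFit:
    """Membrane time constant from the decay of the recovery EPSP.

    The decay is fitted to ``a exp(-t/tau) + c`` starting ``skip_ms``
    after the recovery peak (skipping the fast synaptic component).
    """
    dt = mean_trace.dt_ms
    v = mean_trace.v_mv
    t_rec = protocol.pulse_times_ms[-1]
    i_rec = int(round(t_rec / dt))
    i_search = slice(i_rec, min(i_rec + int(round(50.0 / dt)), v.size))
    i_peak = i_search.start + int(np.argmax(v[i_search]))
    i0 = i_peak + int(round(skip_ms / dt))
    i1 = min(i0 + int(round(fit_span_ms / dt)), v.size)
    if (i1 - i0) * dt < 100.0:
        return TauMemFit(np.nan, False, "fewer than 100 ms of decay available")
    seg = v[i0:i1]
    t = dt * np.arange(seg.size)
    c0 = float(seg[-1])
    a0 = float(seg[0] - c0)
    if a0 <= 0:
        return TauMemFit(np.nan, False, "recovery EPSP decay is non-decaying")
    try:
        (a, tau, c), _ = optimize.curve_fit(
            lambda t, a, tau, c: a * np.exp(-t / tau) + c,
            t,
            seg,
            p0=[a0, 30.0, c0],
            bounds=([0.0, dt, -np.inf], [np.inf, 10 * fit_span_ms, np.inf]),
            maxfev=5000,
        )
    except RuntimeError:
        return TauMemFit(np.nan, False, "exponential fit did not converge")
    return TauMemFit(float(tau), True, "", float(a), float(c))


def deconvolve(trace: SweepTrace, tau_mem_ms: float) -> SweepTrace:
    """Apply the inverse membrane operator ``tau_mem dV/dt + V``.

    The derivative uses central differences (one-sided at the ends).
    On a baseline-subtracted trace the output is proportional to the
    unfiltered synaptic current.
    """
    dv = np.gradient(trace.v_mv, trace.dt_ms)
    return SweepTrace(trace.dt_ms, tau_mem_ms * dv + trace.v_mv)


def extract_peaks(
    deconvolved: SweepTrace,
    protocol: StimulusProtocol,
    baseline: float | None = None,
) -> PeakVector:
    """Per-pulse maxima of the deconvolved trace, from a common baseline.

    The search window for each pulse runs to the next pulse (300 ms for
    the recovery pulse).  ``baseline`` defaults to the mean deconvolved
    level over the pre-train segment, so all peaks are measured from
    the same voltage level.
    """
    dt = deconvolved.dt_ms
    x = deconvolved.v_mv
    if baseline is None:
        i_base = max(int(round((protocol.onset_ms - 10.0) / dt)), 1)
        baseline = float(x[:i_base].mean())
    times = protocol.pulse_times_ms
    peaks = np.empty(times.size)
    for n, t in enumerate(times):
        end = times[n + 1] if n + 1 < times.size else t + protocol.post_window_cap_ms
        i0, i1 = int(round(t / dt)), int(round(end / dt))
        if i1 <= i0 or i1 > x.size:
            raise ValueError(f"peak search window for pulse {n + 1} is empty")
        peaks[n] = x[i0:i1].max() - baseline
    return PeakVector(values=peaks, times_ms=times.copy())


def _tm_peaks_batch(
    u0: np.ndarray, d: np.ndarray, f: np.ndarray, intervals_ms: np.ndarray
) -> np.ndarray:
    """Normalized deterministic peak sequences for arrays of candidates.

    Returns shape (*candidate_shape, n_spikes); each sequence is divided
    by its maximum, matching the normalization of the measured peaks.
    """
    u = u0.copy()
    r = np.ones_like(u0)
    out = np.empty((*u0.shape, intervals_ms.size + 1))
    out[..., 0] = u * r
    for i, dt in enumerate(intervals_ms):
        r = 1.0 + (r - r * u - 1.0) * np.exp(-dt / d)
        u = u0 + u * (1.0 - u0) * np.exp(-dt / f)
        out[..., i + 1] = u * r
    peak = out.max(axis=-1)
    return out / np.maximum(peak[..., None], 1e-300)


def fit_tm_ga(
    peaks: PeakVector,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    return_history: bool = False,
):
    """Fit U, D, F to measured peaks with a restarted genetic algorithm.

    The objective is the mean squared distance between the normalized
    measured peaks and the normalized deterministic model peaks (A = 1).
    All restarts evolve in parallel (vectorized); the best individual
    across restarts is returned as ``(TMParams, mse)`` or, with
    ``return_history``, ``(TMParams, mse, history)`` where ``history``
    is the (restarts, generations + 1) matrix of best-so-far errors.
    """
    if config is None:
        config = GAConfig()
    if rng is None:
        rng = np.random.default_rng()
    target = peaks.values / np.max(np.abs(peaks.values))
    intervals = np.diff(peaks.times_ms)
    lo, hi = config.bounds
    eps = 1e-9
    nr, npop = config.restarts, config.population

    def objective(pop: np.ndarray) -> np.ndarray:
        model = _tm_peaks_batch(pop[..., 0], pop[..., 1], pop[..., 2], intervals)
        return ((model - target) ** 2).mean(axis=-1)

    pop = rng.uniform(lo + eps, hi, size=(nr, npop, 3))
    fit = objective(pop)
    history = np.empty((nr, config.generations + 1))
    best_idx = fit.argmin(axis=1)
    rows = np.arange(nr)
    best_x = pop[rows, best_idx].copy()
    best_f = fit[rows, best_idx].copy()
    history[:, 0] = best_f

    r_idx = rows[:, None, None]
    sigma = config.mutation_sigma_frac * (hi - lo)
    for gen in range(config.generations):
        # tournament selection
        cand = rng.integers(0, npop, size=(nr, npop, config.tournament))
        f_cand = fit[r_idx, cand]
        winners = np.take_along_axis(
            cand, f_cand.argmin(axis=2)[..., None], axis=2
        )[..., 0]
        parents = pop[rows[:, None], winners]
        # uniform crossover with a random mate
        mates = pop[rows[:, None], rng.integers(0, npop, size=(nr, npop))]
        do_cx = rng.random((nr, npop, 1)) < config.crossover_rate
        gene_mask = rng.random((nr, npop, 3)) < 0.5
        children = np.where(do_cx & gene_mask, mates, parents)
        # Gaussian mutation
        mut = rng.random((nr, npop, 3)) < config.mutation_rate
        children = children + mut * rng.normal(0.0, 1.0, (nr, npop, 3)) * sigma
        children = np.clip(children, lo + eps, hi)
        cfit = objective(children)
        # elitism: the best-so-far individual replaces the worst child
        worst = cfit.argmax(axis=1)
        children[rows, worst] = best_x
        cfit[rows, worst] = best_f
        pop, fit = children, cfit
        idx = fit.argmin(axis=1)
        improved = fit[rows, idx] < best_f
        best_x = np.where(improved[:, None], pop[rows, idx], best_x)
        best_f = np.where(improved, fit[rows, idx], best_f)
        history[:, gen + 1] = best_f

    k = int(best_f.argmin())
    u, d, f = best_x[k]
    params = TMParams(U=float(u), D=float(d), F=float(f))
    if return_history:
        return params, float(best_f[k]), history
    return params, float(best_f[k])


@dataclass
class DistributionFit:
    """Best-fitting family for a population of parameter values."""

    family: str
    params: tuple
    p_value: float
    ks_distance: float
    candidates: dict = field(default_factory=dict)

    def frozen(self):
        return getattr(stats, self.family)(*self.params)


def fit_param_distributions(values: np.ndarray, name: str = "") -> DistributionFit:
    """Select among beta, gamma and normal by KS goodness of fit.

    Each family is fitted by maximum likelihood; the family with the
    highest KS p-value (ties broken by the smallest KS distance) wins.
    The beta family is fitted on its natural (0, 1) support (it models
    fraction parameters) and is skipped when values fall outside it;
    with free location/scale it degenerates into a superset of the
    gamma family and the selection loses its meaning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 values to fit a distribution")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values")
    candidates: dict[str, tuple] = {}
    results = []
    for family in ("beta", "gamma", "norm"):
        dist = getattr(stats, family)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if family == "beta":
                    if x.min() <= 0.0 or x.max() >= 1.0:
                        continue
                    params = dist.fit(x, floc=0.0, fscale=1.0)
                else:
                    params = dist.fit(x)
                ks = stats.kstest(x, dist(*params).cdf)
        except Exception:  # a family can be unfittable for some samples
            continue
        candidates[family] = (params, ks.pvalue, ks.statistic)
        results.append((ks.pvalue, -ks.statistic, family, params))
    if not results:
        raise ValueError(f"no candidate distribution could be fitted to {name!r}")
    results.sort(reverse=True)
    p, neg_d, family, params = results[0]
    return DistributionFit(
        family=family,
        params=tuple(params),
        p_value=float(p),
        ks_distance=float(-neg_d),
        candidates=candidates,
    )


@dataclass
class ConnectionFit:
    """Full per-connection fit: membrane time constant and TM parameters."""

    tau_mem: TauMemFit
    params: TMParams
    mse: float
    peaks: PeakVector
    first_epsp_mv: float


def fit_connection(
    sweeps_mv: np.ndarray,
    dt_ms: float,
    protocol: StimulusProtocol,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectionFit:
    """Run the whole fitting pipeline on one connection's sweep set."""
    mean = np.atleast_2d(np.asarray(sweeps_mv, dtype=float)).mean(axis=0)
    trace = SweepTrace(dt_ms, mean)
    tau_fit = fit_tau_mem(trace, protocol)
    if not tau_fit.ok:
        raise ValueError(f"membrane time constant fit failed: {tau_fit.message}")
    i_base = max(int(round((protocol.onset_ms - 10.0) / dt_ms)), 1)
    rel = mean - mean[:i_base].mean()
    first_epsp = float(epsp_amplitudes(mean, dt_ms, protocol)[0])
    norm = rel / rel.max() if rel.max() > 0 else rel
    dec = deconvolve(SweepTrace(dt_ms, norm), tau_fit.tau_mem_ms)
    peaks = extract_peaks(dec, protocol)
    params, mse = fit_tm_ga(peaks, config, rng)
    return ConnectionFit(
        tau_mem=tau_fit, params=params, mse=mse, peaks=peaks,
        first_epsp_mv=first_epsp,
    )
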