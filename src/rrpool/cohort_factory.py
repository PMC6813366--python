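"""Synthetic cohorts of synaptic connections with known ground truth.

A cohort emulates a set of paired-recording experiments on one
connection type: each connection gets a contact count (uniform 4-8 for
L5 thick-tufted pyramidal pairs), per-contact pool sizes drawn from a
shifted Poisson ``1 + Poisson(lambda)`` (at least one vesicle per
contact), connection-level short-term-plasticity parameters drawn from
the population distributions fitted in vitro (U truncated-normal
0.38 +/- 0.1; D gamma 365.6 +/- 100.15 ms; F gamma 25.71 +/- 45.87 ms),
a per-connection maximal conductance, and OU membrane noise
(sigma 0.22 mV, tau 28.2 ms).  Every sweep is traceable to the exact
parameters that generated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .protocol import StimulusProtocol
from .synapse_model import SpikeTrain, TMParams, simulate_release_conductances
from .trace_engine import MembraneModel, NoiseParams, synthesize_sweep_matrix

__all__ = [
    "ParamDistributions",
    "CohortSpec",
    "Connection",
    "SweepSet",
    "sample_connection",
    "generate_cohort",
    "simulate_connection_sweeps",
]

MAX_POISSON_MEAN = 13.0  # pool means above 14 vesicles/contact are not modelled


@dataclass(frozen=True)
class ParamDistributions:
    """Population distributions for per-connection synapse parameters.

    Gamma distributions are parameterized by (mean, sd) and converted
    internally via shape = (mean/sd)^2, scale = sd^2/mean.  The U
    normal is truncated to [0, 1].  ``gmax_ns`` is a single scale
    shared by all connections of a cohort; calibration rescales it so
    the simulated mean first-EPSP amplitude matches a target.
    """

    u_mean: float = 0.38
    u_sd: float = 0.1
    d_mean_ms: float = 365.6
    d_sd_ms: float = 100.15
    f_mean_ms: float = 25.71
    f_sd_ms: float = 45.87
    contacts_min: int = 4
    contacts_max: int = 8
    gmax_ns: float = 1.54

    def __post_init__(self) -> None:
        for name in ("u_sd", "d_mean_ms", "d_sd_ms", "f_mean_ms", "f_sd_ms",
                     "gmax_ns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 1 <= self.contacts_min <= self.contacts_max <= 20:
            raise ValueError("contact range must satisfy 1 <= min <= max <= 20")

    def with_gmax(self, gmax_ns: float) -> "ParamDistributions":
        """Copy with a new g_max scale."""
        return replace(self, gmax_ns=gmax_ns)

    def sample_u(self, rng: np.random.Generator, size=None) -> np.ndarray:
        a = (0.0 - self.u_mean) / self.u_sd
        b = (1.0 - self.u_mean) / self.u_sd
        return stats.truncnorm.rvs(
            a, b, loc=self.u_mean, scale=self.u_sd, size=size, random_state=rng
        )

    @staticmethod
    def _gamma(mean: float, sd: float, rng: np.random.Generator, size=None):
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=size)

    def sample_d(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self._gamma(self.d_mean_ms, self.d_sd_ms, rng, size)

    def sample_f(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self._gamma(self.f_mean_ms, self.f_sd_ms, rng, size)

    def sample_contacts(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.contacts_min, self.contacts_max + 1))

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "u_mean", "u_sd", "d_mean_ms", "d_sd_ms", "f_mean_ms",
                "f_sd_ms", "contacts_min", "contacts_max", "gmax_ns",
            )
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParamDistributions":
        return cls(**d)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort reproducibly.

    ``lam`` is the shifted-Poisson mean offset: per-contact pool size
    N_RRP = 1 + Poisson(lam), so the expected mean pool is 1 + lam.
    """

    lam: float = 0.0
    n_connections: int = 100
    n_sweeps: int = 20
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    membrane: MembraneModel = field(default_factory=MembraneModel)
    noise: NoiseParams = field(default_factory=NoiseParams)
    distributions: ParamDistributions = field(default_factory=ParamDistributions)
    dt_ms: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= MAX_POISSON_MEAN:
            raise ValueError(f"lam must lie in [0, {MAX_POISSON_MEAN}]")
        if self.n_connections < 0:
            raise ValueError("n_connections must be >= 0")
        if self.n_sweeps < 2:
            raise ValueError("n_sweeps must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class Connection:
    """Ground truth for one synthetic connection."""

    n_rrp: np.ndarray  # per-contact pool sizes
    params: TMParams  # shared across contacts; g_max is per connection
    noise: NoiseParams

    @property
    def n_contacts(self) -> int:
        return self.n_rrp.size

    @property
    def mean_n_rrp(self) -> float:
        return float(self.n_rrp.mean())

    def to_dict(self) -> dict:
        return {
            "n_rrp": self.n_rrp.tolist(),
            "U": self.params.U,
            "D_ms": self.params.D,
            "F_ms": self.params.F,
            "g_max_ns": self.params.g_max,
            "noise": self.noise.to_dict(),
        }


@dataclass
class SweepSet:
    """The voltage sweeps of one connection on a common grid."""

    sweeps_mv: np.ndarray  # (n_sweeps, n_samples)
    dt_ms: float
    protocol: StimulusProtocol
    ground_truth: Connection | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.sweeps_mv, dtype=float))
        if v.shape[0] < 2:
            raise ValueError("a sweep set needs at least 2 sweeps")
        self.sweeps_mv = v

    @property
    def n_sweeps(self) -> int:
        return self.sweeps_mv.shape[0]

    @property
    def mean_trace_mv(self) -> np.ndarray:
        return self.sweeps_mv.mean(axis=0)


def sample_connection(spec: CohortSpec, rng: np.random.Generator) -> Connection:
    """Draw one connection: contact count, per-contact pools, parameters."""
    dists = spec.distributions
    m = dists.sample_contacts(rng)
    n_rrp = 1 + rng.poisson(spec.lam, size=m)
    params = TMParams(
        U=float(dists.sample_u(rng)),
        D=float(dists.sample_d(rng)),
        F=float(dists.sample_f(rng)),
        g_max=dists.gmax_ns,
    )
    return Connection(n_rrp=n_rrp, params=params, noise=spec.noise)


def simulate_connection_sweeps(
    connection: Connection,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """All sweeps of one connection: stochastic release, passive membrane,
    OU noise.  Returns the (n_sweeps, n_samples) voltage matrix in mV."""
    train = SpikeTrain(spec.protocol.pulse_times_ms)
    g = simulate_release_conductances(
        connection.n_rrp, connection.params, train, spec.n_sweeps, rng
    )
    noise = connection.noise if connection.noise.sigma_mv > 0 else None
    return synthesize_sweep_matrix(
        spec.membrane,
        g,
        train.times_ms,
        spec.protocol.sweep_duration_ms(),
        spec.dt_ms,
        noise,
        rng,
    )


def generate_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[SweepSet]:
    """Generate a full cohort of sweep sets with ground truth attached.

    Identical spec and seed yield a bit-identical cohort.
    """
    if rng is None:
        rng = spec.rng()
    cohort = []
    for _ in range(spec.n_connections):
        conn = sample_connection(spec, rng)
        v = simulate_connection_sweeps(conn, spec, rng)
        cohort.append(
            SweepSet(sweeps_mv=v, dt_ms=spec.dt_ms, protocol=spec.protocol,
                     ground_truth=conn)
        )
    return cohort
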