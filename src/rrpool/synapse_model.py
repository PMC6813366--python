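"""Tsodyks-Markram short-term plasticity and its stochastic multivesicular form.

The deterministic model predicts the relative EPSP amplitude sequence
``A_n = A * u_n * R_n`` for an arbitrary presynaptic spike train, where
``u_n`` tracks facilitation (release fraction, recovering to ``U`` with
time constant ``F``) and ``R_n`` tracks the available synaptic resources
(recovering with time constant ``D``).

The stochastic generalisation replaces the continuous resource variable
by a finite readily-releasable pool of ``n_rrp`` vesicles per synaptic
contact.  At each spike every ready vesicle releases independently with
probability ``u``; every empty slot refills independently with
probability ``1 - exp(-dt/D)`` since the previous spike.  A released
vesicle contributes a quantal conductance ``g_max / n_rrp``, so the
expected response is independent of the pool size while its trial-to-
trial variability shrinks as the pool grows -- the effect the pool-size
estimator exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TMParams",
    "SpikeTrain",
    "SynapticContact",
    "ReleaseEventSeries",
    "tm_deterministic_train",
    "advance_contact",
    "simulate_connection_events",
    "simulate_release_conductances",
]


@dataclass(frozen=True)
class TMParams:
    """Synaptic dynamics parameters of one contact or connection.

    U is the fraction of resources used by a single spike, D and F the
    depression and facilitation recovery time constants in ms, A the
    absolute synaptic efficacy (fixed to 1 for normalized fitting) and
    g_max the maximal conductance per contact in nS.
    """

    U: float
    D: float
    F: float
    A: float = 1.0
    g_max: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.U <= 1.0:
            raise ValueError(f"U must be in [0, 1], got {self.U}")
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.F <= 0:
            raise ValueError(f"F must be positive, got {self.F}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing presynaptic spike times in ms."""

    times_ms: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("spike train must contain at least one spike")
        if np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times_ms", times)

    @property
    def intervals_ms(self) -> np.ndarray:
        """Inter-spike intervals dt_n (length n_spikes - 1)."""
        return np.diff(self.times_ms)

    def __len__(self) -> int:
        return self.times_ms.size


def tm_deterministic_train(params: TMParams, train: SpikeTrain) -> np.ndarray:
    """Deterministic amplitude sequence A_n = A * u_n * R_n.

    Initial conditions u_1 = U, R_1 = 1; recursions

        u_{n+1} = U + u_n (1 - U) exp(-dt_n / F)
        R_{n+1} = 1 + (R_n - R_n u_n - 1) exp(-dt_n / D)
    """
    u = params.U
    r = 1.0
    amps = np.empty(len(train))
    amps[0] = params.A * u * r
    for i, dt in enumerate(train.intervals_ms):
        r = 1.0 + (r - r * u - 1.0) * np.exp(-dt / params.D)
        u = params.U + u * (1.0 - params.U) * np.exp(-dt / params.F)
        amps[i + 1] = params.A * u * r
    return amps


@dataclass
class SynapticContact:
    """One synaptic contact with a finite vesicle pool.

    ``ready`` counts vesicles currently available for release and ``u``
    is the running facilitation variable (0 before the first spike; the
    first spike takes it to U).
    """

    n_rrp: int
    params: TMParams
    ready: int = field(default=-1)
    u: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rrp < 1:
            raise ValueError("n_rrp must be >= 1")
        if self.ready < 0:
            self.ready = self.n_rrp
        if not 0 <= self.ready <= self.n_rrp:
            raise ValueError("ready must be within [0, n_rrp]")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("u must be within [0, 1]")

    def reset(self) -> None:
        self.ready = self.n_rrp
        self.u = 0.0


def advance_contact(
    contact: SynapticContact, dt_ms: float, rng: np.random.Generator
) -> int:
    """Advance one contact across one spike; return vesicles released.

    ``dt_ms`` is the time since the previous spike; pass ``np.inf`` for
    the first spike (full recovery, u jumps to U).  Empty slots refill
    before release accounting; each ready vesicle then releases
    independently with probability u.
    """
    if dt_ms < 0:
        raise ValueError("dt_ms must be >= 0")
    p = contact.params
    p_rec = -np.expm1(-dt_ms / p.D)
    empty = contact.n_rrp - contact.ready
    if empty:
        contact.ready += int(rng.binomial(empty, p_rec))
    contact.u = p.U + contact.u * (1.0 - p.U) * np.exp(-dt_ms / p.F)
    released = int(rng.binomial(contact.ready, contact.u))
    contact.ready -= released
    return released


@dataclass
class ReleaseEventSeries:
    """Per-spike release counts and total quantal conductance.

    ``counts`` has shape (n_spikes, n_contacts); ``conductances_ns``
    holds the per-spike summed conductance, each released vesicle of
    contact c contributing g_max_c / n_rrp_c.
    """

    spike_times_ms: np.ndarray
    counts: np.ndarray
    conductances_ns: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "spike_times_ms": self.spike_times_ms.tolist(),
                "counts": self.counts.tolist(),
                "conductances_ns": self.conductances_ns.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ReleaseEventSeries":
        d = json.loads(s)
        return cls(
            spike_times_ms=np.asarray(d["spike_times_ms"], dtype=float),
            counts=np.asarray(d["counts"], dtype=int),
            conductances_ns=np.asarray(d["conductances_ns"], dtype=float),
        )


def simulate_connection_events(
    contacts: list[SynapticContact],
    train: SpikeTrain,
    rng: np.random.Generator,
) -> ReleaseEventSeries:
    """Simulate stochastic release of all contacts across one sweep.

    Contacts evolve independently; state is reset to the fully recovered
    condition (ready = n_rrp, u = 0) before the first spike.
    """
    for c in contacts:
        c.reset()
    n_spikes = len(train)
    counts = np.zeros((n_spikes, len(contacts)), dtype=int)
    cond = np.zeros(n_spikes)
    dts = np.concatenate(([np.inf], train.intervals_ms))
    for k, dt in enumerate(dts):
        for j, c in enumerate(contacts):
            rel = advance_contact(c, dt, rng)
            counts[k, j] = rel
            cond[k] += rel * c.params.g_max / c.n_rrp
    return ReleaseEventSeries(train.times_ms.copy(), counts, cond)


def simulate_release_conductances(
    n_rrp: np.ndarray,
    params: TMParams,
    train: SpikeTrain,
    n_sweeps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized release simulation for repeated sweeps of one connection.

    All contacts share the connection-level TMParams (the fitting
    pipeline recovers one U/D/F per connection); ``n_rrp`` gives the
    per-contact pool sizes.  Returns the (n_sweeps, n_spikes) matrix of
    summed quantal conductances in nS.  Statistically equivalent to
    calling :func:`simulate_connection_events` per sweep, but draws the
    binomial variates for all sweeps at once.
    """
    n_rrp = np.asarray(n_rrp, dtype=np.int64)
    if n_rrp.ndim != 1:
        raise ValueError("n_rrp must be a 1-D array of per-contact pool sizes")
    n_contacts = n_rrp.size
    n_spikes = len(train)
    out = np.zeros((n_sweeps, n_spikes))
    if n_contacts == 0 or n_sweeps == 0:
        return out
    quantal = params.g_max / n_rrp  # (C,)
    ready = np.broadcast_to(n_rrp, (n_sweeps, n_contacts)).copy()
    u = 0.0
    dts = np.concatenate(([np.inf], train.intervals_ms))
    for k, dt in enumerate(dts):
        p_rec = -np.expm1(-dt / params.D)
        empty = n_rrp[None, :] - ready
        ready = ready + rng.binomial(empty, p_rec)
        u = params.U + u * (1.0 - params.U) * np.exp(-dt / params.F)
        rel = rng.binomial(ready, u)
        ready = ready - rel
        out[:, k] = rel @ quantal
    return out
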