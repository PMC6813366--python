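# rrpool

Estimation of the readily-releasable vesicle pool size (N_RRP) at
neocortical synaptic contacts from the trial-to-trial variability of
evoked EPSP trains.

## The problem

Paired whole-cell recordings of connected neurons (e.g. layer-5
thick-tufted pyramidal cells) yield trains of EPSPs — here 8 pulses at
20 Hz plus a recovery pulse 500 ms later, repeated 20–60 times.  The
mean amplitudes constrain the synapse's short-term plasticity, but the
*variability* across repetitions carries extra information: a contact
that can release several vesicles per spike (multivesicular release)
produces less variable responses than a univesicular one of the same
strength, because each vesicle contributes a smaller quantum
g_max/N_RRP.  The coefficient of variation (CV = SD/mean) of the EPSP
amplitudes therefore decreases with pool size, approximately as a power
law, and matching simulated CV profiles against a measured one
identifies the mean N_RRP of a cohort of connections.

## The model

Short-term dynamics follow the Tsodyks–Markram recursion

    A_n = A u_n R_n,   u_1 = U,  R_1 = 1
    u_{n+1} = U + u_n (1 − U) e^{−Δt_n/F}
    R_{n+1} = 1 + (R_n − R_n u_n − 1) e^{−Δt_n/D}

with release fraction U, depression recovery D and facilitation
recovery F.  Its stochastic counterpart gives every contact a finite
pool of N_RRP vesicles: at each spike every ready vesicle releases
independently with probability u_n, empty slots refill with probability
1 − e^{−Δt/D}, and each released vesicle injects a quantal conductance
g_max/N_RRP.  In expectation this reproduces the deterministic
recursion exactly; the pool size only controls the variance.

Release events drive a linear passive membrane (current-based synaptic
drive, exponential decay τ_syn = 1.7 ms, membrane time constant
τ_mem = 28.2 ms, R_input = 59.7 MΩ, V_rest = −65.3 mV), and stationary
Ornstein–Uhlenbeck noise (σ = 0.22 mV, τ = 28.2 ms) models membrane
fluctuations.  Per-pulse amplitudes are measured on leave-one-out
(jackknife) average traces, with the per-observation SD reconstructed
as std_n = sqrt((N−1) Σ_i (A_in − Ā_n)²).

The estimator simulates cohorts of connections with per-contact pools
N_RRP = 1 + Poisson(λ) for λ = 0…13, U/D/F drawn from the population
distributions fitted in vitro (U ~ N(0.38, 0.1) truncated to [0,1],
D ~ Γ(365.6, 100.15) ms, F ~ Γ(25.71, 45.87) ms), 4–8 contacts per
connection, g_max calibrated so the simulated mean first EPSP matches
the reference, and picks the λ whose mean jackknife CV profile is
closest (mean squared distance) to the reference profile.

The package also contains the fitting pipeline that produces those
population distributions from sweep data (membrane time-constant fit,
voltage deconvolution τ_mem·dV/dt + V, peak extraction, genetic-
algorithm fit of U/D/F) and a linear CV → CV_JKK transformation that
makes literature CV values, reported without the jackknife, usable as
references.

## Worked example

```python
import numpy as np
from rrpool import (CohortSpec, EstimatorConfig, ParamDistributions,
                    estimate_nrrp_profile, simulate_cv_cohort)

# reference cohort with known ground truth: per-contact pools 1 + Poisson(3)
dists = ParamDistributions(gmax_ns=3.2)
reference = simulate_cv_cohort(CohortSpec(lam=3.0, n_connections=30,
                                          distributions=dists, seed=11))
print(f"reference: realized mean pool = {reference.mean_nrrp.mean():.2f}, "
      f"mean first EPSP = {reference.amp_first_mv.mean():.2f} mV, "
      f"first-pulse CV_JKK = {np.nanmean(reference.cv_jkk[:, 0]):.2f}")

config = EstimatorConfig(iterations=10, n_connections=30,
                         target_amp_mv=float(reference.amp_first_mv.mean()),
                         amp_sd_mv=float(reference.amp_first_mv.std()))
result = estimate_nrrp_profile(np.nanmean(reference.cv_jkk, axis=0),
                               config, np.random.default_rng(0))
print(f"estimated N_RRP = {result.nrrp_mean:.2f} +/- {result.nrrp_sd:.2f}")
```

prints

```
reference: realized mean pool = 4.02, mean first EPSP = 1.36 mV, first-pulse CV_JKK = 0.37
estimated N_RRP = 4.29 +/- 0.41
```

The reference cohort of 30 connections was generated with a true mean
pool of 4.02 vesicles per contact; scanning λ = 0…13 with ten
independent repetitions recovers 4.29 ± 0.41.  The error-versus-λ
curve (`result.mean_error`) has its minimum at λ = 3.

A CLI wraps the pipeline stages: `rrpool generate` (synthetic
cohorts), `rrpool fit-noise`, `rrpool fit-tm`, `rrpool cv`,
`rrpool estimate`, `rrpool transform-cv` and `rrpool validate` (the
1/4/10 pool-size recovery experiment).  Run `rrpool --help` for
options.

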