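# Methods

This note records the model, the numerical choices and the limits of
what the synthetic experiments can show.

## Stochastic synapse model

Each connection consists of M synaptic contacts (M uniform on 4–8 by
default, the anatomical range for L5 thick-tufted pyramidal pairs).
Each contact holds a readily-releasable pool of `n_rrp` vesicles, drawn
per contact as 1 + Poisson(λ) — at least one vesicle per release site,
with λ ∈ [0, 13] so mean pools range from 1 to 14.

Dynamics follow the Tsodyks–Markram recursion.  The facilitation
variable u is deterministic and shared within a contact (only release
and recovery are stochastic), matching the stochastic-TM convention in
the microcircuit-modelling literature; the first spike takes u from 0
to U.  At each spike, empty vesicle slots first refill independently
with probability 1 − e^{−Δt/D} (event-driven recovery, applied once per
inter-spike interval), then every ready vesicle releases independently
with probability u.  This choice makes the expected ready fraction
follow the deterministic R_n recursion exactly, which the tests verify
at Monte-Carlo precision.  Released vesicles contribute a quantal
conductance g_max/n_rrp, so the expected response amplitude is
independent of the pool size while its variance scales as 1/n_rrp —
the signal the estimator uses.

Receptor saturation, desensitization, calcium dynamics and recycling
pools beyond the RRP are out of scope.

## Membrane and noise

The postsynaptic membrane is a single linear RC compartment
(τ_mem = 28.2 ms, R_input = 59.7 MΩ, V_rest = −65.3 mV).  Synaptic
drive is current-based with a fixed driving force E_rev − V_rest and
instantaneous-rise, exponential-decay kinetics (τ_syn = 1.7 ms,
AMPA-like).  Current-based drive keeps the membrane exactly linear, so
sweep synthesis commutes with event superposition and the deconvolution
operator τ_mem·dV/dt + V is its exact inverse; a conductance-based
synapse would break that identity at large amplitudes.  Sweeps are
synthesized at dt = 0.1 ms (10 kHz, the experimental sampling ceiling).

Background noise is a stationary Ornstein–Uhlenbeck process,

    X(t+dt) = X(t) − X(t)/τ·dt + σ·sqrt(2·dt/τ)·W_t,

with σ = 0.22 mV and τ = 28.2 ms by default (the values fitted to the
in vitro recordings; τ doubles as the membrane time constant).  The
AR(1) discretization has stationary variance σ²/(1 − dt/2τ), within
0.2% of σ² at the default resolution.

## Noise estimation

σ and τ are estimated per connection from the stimulus-free 400 ms
stretch between one inter-stimulus interval plus a 50 ms settling guard
after the 8th pulse and the recovery pulse (only the 400 ms total is
prescribed by the protocol; the guard split is ours).  Each sweep is
fitted separately and the fitted values averaged.  Two finite-segment
corrections matter at T ≈ 14τ: the empirical autocorrelation of a
mean-subtracted segment is biased down by roughly 2τ/T, so the
exponential is fitted with a free offset, (1−c)e^{−lag/τ} + c, over
lags up to 80 ms; and the segment variance underestimates the
stationary variance by the factor (1 − 2τ/T), which is divided out.
Even so, a single 400 ms segment determines τ only to ~±40% (near the
information limit), so per-connection values should always average 20+
sweeps; the round-trip tests use 30.  Degenerate inputs (constant
segment, non-decaying autocorrelation) are flagged, not raised;
white-noise-like segments (fitted τ ≤ 2·dt) produce a warning.

## Fitting pipeline

τ_mem is fitted per connection as a single exponential (with offset) on
the decay of the recovery EPSP of the averaged trace, starting 5 ms
after the recovery peak to skip the fast synaptic component.  The
averaged trace is baseline-subtracted, normalized to its maximum and
deconvolved with central differences (one-sided at the ends).  Peaks
are taken as per-pulse window maxima measured from the common pre-train
baseline; each window runs to the next pulse (300 ms for the recovery
pulse).

U, D, F are fitted to the nine peaks with a genetic algorithm on the
ranges U ∈ [0, 1], D ∈ [0, 1000] ms, F ∈ [0, 2000] ms: population 100,
tournament selection (size 3), uniform crossover (rate 0.7), Gaussian
mutation (SD 5% of each range, rate 0.2), one elite, 500 generations,
best of 50 restarts (all restarts evolve in parallel as one vectorized
array).  Elitism makes the best-of-generation error non-increasing,
which is asserted as an invariant.  Because the data are normalized to
their maximum while the model fixes A = 1 (first model peak U), the
objective compares max-normalized model peaks with max-normalized
measured peaks; U is then identified by the shape of depression rather
than the absolute scale.  On noiseless peaks the GA recovers U to ±0.05
(typically ±0.001); D and F carry the wide identifiability bands their
population spread (F: 25.71 ± 45.87 ms) implies.

Population distributions are selected among beta, gamma and normal by
Kolmogorov–Smirnov goodness of fit (highest p, then smallest D).  Beta
is fitted on its natural (0, 1) support and skipped for unbounded
parameters; with a free location and scale it degenerates into a
near-superset of the gamma family and the selection loses its meaning.

## Jackknife CV

Amplitudes are measured per pulse as max(post-window) − min(50 ms
pre-window); post windows are capped at the next stimulus (the 300 ms
cap binds only for the recovery pulse — a literal 300 ms window would
span six train pulses).  The jackknife profile measures amplitudes on
the N leave-one-out average traces and reconstructs the spread as
std_n = sqrt((N−1)·Σ_i (A_in − Ā_n)²), which equals the plain sample
SD exactly whenever the amplitude is linear in the single sweeps
(asserted on linear fixtures).  Its advantage over the per-sweep
("analytical") CV is bias, not variance: window extremes on raw noisy
sweeps inflate the mean amplitude and therefore deflate the CV, which
is why literature CV values need the linear CV → CV_JKK map before
matching.

## Estimator

For each λ on the grid (integers 0–13 by default) a cohort is simulated
(100 connections × 20 sweeps by default), g_max having been calibrated
once so the simulated cohort mean first-EPSP amplitude matches the
reference (the mean amplitude is independent of λ because quantal
scaling cancels, so one calibration serves the whole scan; the measured
amplitude is affine in g_max under fixed seeds, making the two-point
secant exact).  Connections whose mean first-EPSP amplitude falls
outside the reference range — by default [mean − 2 SD, mean + 2 SD],
since the raw experimental min–max is unavailable — are excluded.  The
error at λ is the mean squared distance between the cohort mean
jackknife CV profile and the reference profile (or, in the first-EPSP
variant, the absolute difference of first-pulse CVs).  The scan is
repeated (50 iterations by default) and the recovered pool size is
reported as mean ± SD over iterations of the realized cohort-mean
n_rrp at each iteration's argmin — realized means rather than 1 + λ,
since those are what validation cohorts report.  References outside
the simulated CV range pin the argmin to a grid edge and are flagged.

g_max is a single scalar per cohort.  The population of fitted g_max
values in vitro is broad, but modelling that spread injects
low-amplitude connections whose measured CV is dominated by noise and
inflates the cohort mean CV; the generator therefore keeps conductance
a calibration scalar and draws only U, D, F and the contact count per
connection.  Per-contact (rather than per-connection) U/D/F variation
is available behind the sampling API but off by default, because the
fitting pipeline recovers one U/D/F per connection.

## Problem sizes

Default study conditions are 100 connections × 20 sweeps per cohort and
50 scan iterations.  The validation experiments and tests run 30–50
connection cohorts with 10 iterations — cohort sizes at the lower end
of what the wet-lab protocol yields, which is the regime the method is
meant for — and the acceptance script uses the full 100-connection
cohorts with a single scan per λ.

## What the synthetic data do and do not show

The generator emulates pool-size statistics, short-term plasticity
heterogeneity, passive filtering and stationary membrane noise.  It
does not emulate dendritic filtering and morphology-dependent EPSP
shape diversity, active conductances, electrode artifacts, receptor
saturation or quantal-size variability.  Passing recovery tests
therefore show that the estimator inverts *this* generative family
reliably; on real recordings the CV additionally reflects mechanisms
the model folds into its noise and quantal terms.  Two consequences are
visible in the numbers: the univesicular-release cohort CV under the
fitted parameter distributions has a binomial floor near
E[sqrt((1−U)/(M·U))] ≈ 0.52 before noise, so reduced-model UVR CVs run
~0.1 above the value a morphologically detailed tissue model produces;
and cohort-level estimates say nothing about individual connections
(the method is cohort-level by construction).
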