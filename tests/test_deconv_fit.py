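"""Membrane-time-constant fit, deconvolution, peak extraction, GA fitting."""

import numpy as np
import pytest
from scipy import signal

from rrpool import (
    CohortSpec,
    MembraneModel,
    NoiseParams,
    SpikeTrain,
    SweepTrace,
    TMParams,
    deconvolve,
    extract_peaks,
    fit_connection,
    fit_param_distributions,
    fit_tau_mem,
    fit_tm_ga,
    generate_cohort,
    tm_deterministic_train,
)
from rrpool.deconv_fit import GAConfig, PeakVector

from conftest import make_spec


def _noiseless_sweepset(membrane=None, tau_mem=None, lam=1.0, seed=5, n_sweeps=30):
    mem = membrane or (
        MembraneModel(tau_mem_ms=tau_mem) if tau_mem else MembraneModel()
    )
    spec = make_spec(
        lam=lam,
        n_connections=1,
        n_sweeps=n_sweeps,
        seed=seed,
        membrane=mem,
        noise=NoiseParams(1e-9, 28.2),
    )
    return generate_cohort(spec)[0]


class TestTauMemFit:
    @pytest.mark.parametrize("tau", [28.0, 15.0])
    def test_round_trip_with_synthesized_sweeps(self, tau):
        """Recovery-EPSP decay of a synthesized sweep returns the membrane
        time constant within 5%."""
        ss = _noiseless_sweepset(tau_mem=tau)
        fit = fit_tau_mem(SweepTrace(ss.dt_ms, ss.mean_trace_mv), ss.protocol)
        assert fit.ok
        assert fit.tau_mem_ms == pytest.approx(tau, rel=0.05)

    def test_pure_exponential_decay(self, protocol):
        """An exact exponential tail after the recovery peak is fitted
        exactly."""
        dt = 0.1
        n = int(protocol.sweep_duration_ms() / dt)
        t = dt * np.arange(n)
        t_rec = protocol.pulse_times_ms[-1]
        v = np.where(t >= t_rec, 2.0 * np.exp(-(t - t_rec) / 20.0), 0.0)
        fit = fit_tau_mem(SweepTrace(dt, v), protocol)
        assert fit.ok
        assert fit.tau_mem_ms == pytest.approx(20.0, rel=0.01)

    def test_non_decaying_segment_flagged(self, protocol):
        dt = 0.1
        n = int(protocol.sweep_duration_ms() / dt)
        v = np.linspace(0.0, 1.0, n)  # monotone ramp: no decay anywhere
        fit = fit_tau_mem(SweepTrace(dt, v), protocol)
        assert not fit.ok


class TestDeconvolve:
    def test_constant_trace_is_fixed_point(self):
        tr = SweepTrace(0.1, np.full(500, 3.5))
        out = deconvolve(tr, 25.0)
        np.testing.assert_allclose(out.v_mv, 3.5, atol=1e-9)

    def test_membrane_exponential_is_annihilated(self):
        """exp(-t/tau_mem) is the homogeneous solution: the operator sends
        it to ~0 (interior points; boundaries use one-sided derivatives)."""
        tau, dt = 20.0, 0.01
        t = dt * np.arange(5000)
        out = deconvolve(SweepTrace(dt, np.exp(-t / tau)), tau)
        assert np.abs(out.v_mv[1:-1]).max() < 2e-4

    def test_refiltering_recovers_the_trace(self, membrane, protocol):
        """Integrating the deconvolved output through the RC membrane
        (exact exponential-integrator discretization) returns the
        original sweep up to O(dt) error."""
        ss = _noiseless_sweepset()
        v = ss.mean_trace_mv - ss.mean_trace_mv[0]
        out = deconvolve(SweepTrace(ss.dt_ms, v), membrane.tau_mem_ms)
        a = np.exp(-ss.dt_ms / membrane.tau_mem_ms)
        v_rec = signal.lfilter([1 - a], [1, -a], out.v_mv)
        err = np.abs(v_rec - v).max() / np.abs(v).max()
        assert err < 0.05


class TestExtractPeaks:
    def test_flat_trace_zero_peaks(self, protocol):
        tr = SweepTrace(0.1, np.zeros(int(protocol.sweep_duration_ms() / 0.1)))
        pk = extract_peaks(tr, protocol)
        np.testing.assert_allclose(pk.values, 0.0, atol=1e-12)

    def test_peaks_proportional_to_per_pulse_conductance(self, membrane, protocol):
        """Noiseless events with known quanta: deconvolved peaks scale
        with the per-pulse conductance within 1%."""
        from rrpool import synthesize_sweep_matrix

        g = np.array([[3.0, 1.5, 0.75, 0.6, 0.5, 0.45, 0.42, 0.4, 2.0]])
        v = synthesize_sweep_matrix(
            membrane, g, protocol.pulse_times_ms,
            protocol.sweep_duration_ms(), 0.1, None, None,
        )[0] - membrane.v_rest_mv
        dec = deconvolve(SweepTrace(0.1, v), membrane.tau_mem_ms)
        pk = extract_peaks(dec, protocol)
        ratios = pk.values / g[0]
        np.testing.assert_allclose(ratios, ratios[0], rtol=0.01)

    def test_peaks_additive_over_superposed_trains(self, membrane, protocol):
        from rrpool import synthesize_sweep_matrix

        g1 = np.linspace(2.0, 0.4, 9)[None, :]
        g2 = np.linspace(1.0, 0.2, 9)[None, :]
        mk = lambda g: deconvolve(
            SweepTrace(
                0.1,
                synthesize_sweep_matrix(
                    membrane, g, protocol.pulse_times_ms,
                    protocol.sweep_duration_ms(), 0.1, None, None,
                )[0] - membrane.v_rest_mv,
            ),
            membrane.tau_mem_ms,
        )
        p1 = extract_peaks(mk(g1), protocol).values
        p12 = extract_peaks(mk(g1 + g2), protocol).values
        p2 = extract_peaks(mk(g2), protocol).values
        np.testing.assert_allclose(p12, p1 + p2, rtol=0.02)


class TestGAFit:
    def _peaks(self, protocol, U=0.38, D=365.6, F=25.71):
        amps = tm_deterministic_train(
            TMParams(U=U, D=D, F=F), SpikeTrain(protocol.pulse_times_ms)
        )
        return PeakVector(values=amps / amps.max(), times_ms=protocol.pulse_times_ms)

    def test_forward_model_inversion_recovers_u(self, protocol):
        """Noiseless peaks from the population-mean parameters invert to
        U within 0.05 at near-zero MSE."""
        params, mse = fit_tm_ga(
            self._peaks(protocol), GAConfig(), np.random.default_rng(0)
        )
        assert mse < 1e-4
        assert params.U == pytest.approx(0.38, abs=0.05)

    def test_solutions_respect_printed_ranges(self, protocol):
        cfg = GAConfig(restarts=6, generations=80)
        params, _ = fit_tm_ga(self._peaks(protocol), cfg, np.random.default_rng(1))
        assert 0 <= params.U <= 1
        assert 0 < params.D <= 1000
        assert 0 < params.F <= 2000

    def test_constant_peaks_fit_with_near_zero_error(self, protocol):
        pk = PeakVector(values=np.ones(9), times_ms=protocol.pulse_times_ms)
        cfg = GAConfig(restarts=10, generations=200)
        params, mse = fit_tm_ga(pk, cfg, np.random.default_rng(2))
        assert mse < 1e-3
        assert 0 <= params.U <= 1

    def test_best_error_non_increasing_with_elitism(self, protocol):
        cfg = GAConfig(restarts=4, generations=60)
        _, _, hist = fit_tm_ga(
            self._peaks(protocol), cfg, np.random.default_rng(3), return_history=True
        )
        assert np.all(np.diff(hist, axis=1) <= 1e-15)

    def test_non_finite_peaks_rejected(self, protocol):
        with pytest.raises(ValueError):
            PeakVector(
                values=np.array([1.0] * 8 + [np.nan]),
                times_ms=protocol.pulse_times_ms,
            )


class TestDistributionSelection:
    def test_normal_sample_selects_normal(self):
        rng = np.random.default_rng(4)
        fit = fit_param_distributions(rng.normal(0.38, 0.1, 500), "U")
        assert fit.family == "norm"
        assert fit.params[0] == pytest.approx(0.38, abs=0.02)

    def test_gamma_sample_selects_gamma(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 150.0, 500)
        fit = fit_param_distributions(x, "D")
        assert fit.family == "gamma"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_param_distributions(np.arange(5.0))

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            fit_param_distributions(np.ones(20))


class TestFullPipeline:
    def test_pipeline_recovers_population_u(self):
        """Fitting noiseless synthetic connections end-to-end returns U
        values consistent with the generating population mean."""
        spec = make_spec(
            lam=2.0, n_connections=6, n_sweeps=40, seed=17,
            noise=NoiseParams(1e-9, 28.2),
        )
        cohort = generate_cohort(spec)
        cfg = GAConfig(restarts=8, generations=200)
        rng = np.random.default_rng(6)
        errs = []
        for ss in cohort:
            cf = fit_connection(ss.sweeps_mv, ss.dt_ms, ss.protocol, cfg, rng)
            errs.append(cf.params.U - ss.ground_truth.params.U)
        # finite-sweep binomial sampling limits per-connection accuracy
        assert np.abs(np.mean(errs)) < 0.08
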