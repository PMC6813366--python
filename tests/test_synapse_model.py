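"""Deterministic TM recursion and its stochastic vesicle-pool counterpart."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrpool import (
    ReleaseEventSeries,
    SpikeTrain,
    SynapticContact,
    TMParams,
    advance_contact,
    simulate_connection_events,
    simulate_release_conductances,
    tm_deterministic_train,
)


class TestDeterministicTrain:
    def test_two_spike_depression_example(self):
        # U=0.5, D=100, negligible F, spikes at 0 and 50 ms:
        # A1 = 0.5, R2 = 1 - 0.5 e^{-0.5}, A2 = 0.5 * R2
        params = TMParams(U=0.5, D=100.0, F=1e-6)
        amps = tm_deterministic_train(params, SpikeTrain(np.array([0.0, 50.0])))
        assert amps[0] == pytest.approx(0.5)
        assert amps[1] == pytest.approx(0.5 * (1 - 0.5 * np.exp(-0.5)), rel=1e-12)
        assert amps[1] == pytest.approx(0.34837, abs=5e-6)

    def test_single_spike_is_au(self):
        params = TMParams(U=0.3, D=200.0, F=20.0, A=0.8)
        amps = tm_deterministic_train(params, SpikeTrain(np.array([10.0])))
        assert amps == pytest.approx([0.8 * 0.3])

    def test_full_recovery_limit(self):
        params = TMParams(U=0.4, D=300.0, F=30.0)
        train = SpikeTrain(np.arange(5) * 1e6)
        amps = tm_deterministic_train(params, train)
        np.testing.assert_allclose(amps, 0.4, rtol=1e-12)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeTrain(np.array([0.0, 50.0, 50.0]))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        u=st.floats(0.01, 1.0),
        d=st.floats(1.0, 1000.0),
        f=st.floats(1e-3, 2000.0),
        dts=st.lists(st.floats(0.5, 1000.0), min_size=1, max_size=12),
    )
    def test_amplitudes_stay_in_unit_interval(self, u, d, f, dts):
        """u_n, R_n in [0, 1] implies 0 <= A_n <= 1 for any spike train."""
        train = SpikeTrain(np.concatenate(([0.0], np.cumsum(dts))))
        amps = tm_deterministic_train(TMParams(U=u, D=d, F=f), train)
        assert np.all(amps >= 0.0) and np.all(amps <= 1.0)


class TestStochasticContact:
    def test_zero_release_probability(self, rng):
        c = SynapticContact(n_rrp=5, params=TMParams(U=0.0, D=100.0, F=10.0))
        assert advance_contact(c, np.inf, rng) == 0

    def test_certain_release_empties_pool(self, rng):
        c = SynapticContact(n_rrp=5, params=TMParams(U=1.0, D=100.0, F=10.0))
        assert advance_contact(c, np.inf, rng) == 5
        assert c.ready == 0

    def test_vesicle_conservation_across_train(self, rng):
        c = SynapticContact(n_rrp=7, params=TMParams(U=0.5, D=120.0, F=15.0))
        for dt in [np.inf, 50.0, 50.0, 50.0, 500.0]:
            before_ready = c.ready
            released = advance_contact(c, dt, rng)
            assert 0 <= released <= c.n_rrp
            # ready + released + empty accounts for every vesicle
            empty = c.n_rrp - c.ready - released
            assert empty >= 0
            assert c.ready + released <= c.n_rrp
            assert c.ready >= 0
            del before_ready

    def test_first_spike_binomial_mean(self):
        """Mean released at the first spike equals n_rrp * U."""
        rng = np.random.default_rng(7)
        params = TMParams(U=0.5, D=100.0, F=10.0, g_max=1.0)
        g = simulate_release_conductances(
            np.array([4]), params, SpikeTrain(np.array([0.0])), 100_000, rng
        )
        # conductance = released * g_max / n_rrp; mean = U * g_max
        se = np.sqrt(0.5 * 0.5 / 4) / np.sqrt(100_000)
        assert g[:, 0].mean() == pytest.approx(0.5, abs=4 * se)


class TestConnectionEvents:
    def test_zero_contacts_all_zero(self, rng):
        train = SpikeTrain(np.arange(9) * 50.0)
        ev = simulate_connection_events([], train, rng)
        assert ev.counts.shape == (9, 0)
        np.testing.assert_array_equal(ev.conductances_ns, 0.0)

    def test_mean_first_conductance_independent_of_pool_size(self):
        """E[first response] = M * U * g_max regardless of n_rrp; its
        variance strictly decreases as the pool grows."""
        params = TMParams(U=0.4, D=200.0, F=20.0, g_max=2.0)
        train = SpikeTrain(np.array([0.0]))
        means, variances = [], []
        for n_rrp, seed in [(1, 1), (5, 2)]:
            rng = np.random.default_rng(seed)
            g = simulate_release_conductances(
                np.full(3, n_rrp), params, train, 100_000, rng
            )[:, 0]
            means.append(g.mean())
            variances.append(g.var())
        expected = 3 * 0.4 * 2.0
        for m in means:
            assert m == pytest.approx(expected, rel=0.02)
        assert variances[1] < 0.5 * variances[0]

    def test_expected_release_matches_deterministic_recursion(self):
        """E[conductance_n] = g_max * u_n * R_n at every spike (n_rrp=3)."""
        params = TMParams(U=0.45, D=300.0, F=25.0, g_max=1.0)
        protocol_times = np.append(np.arange(8) * 50.0, 850.0)
        train = SpikeTrain(protocol_times)
        rng = np.random.default_rng(11)
        g = simulate_release_conductances(np.array([3]), params, train, 60_000, rng)
        expected = tm_deterministic_train(params, train)  # A=1, g_max factors out
        mc_se = g.std(axis=0) / np.sqrt(g.shape[0])
        assert np.all(np.abs(g.mean(axis=0) - expected) < 5 * mc_se + 1e-4)

    def test_first_response_cv_closed_form(self):
        """CV of the summed first response = sqrt((1-U)/(M n U))."""
        params = TMParams(U=0.3, D=200.0, F=20.0, g_max=1.0)
        train = SpikeTrain(np.array([0.0]))
        rng = np.random.default_rng(13)
        m, n = 4, 2
        g = simulate_release_conductances(
            np.full(m, n), params, train, 200_000, rng
        )[:, 0]
        cv = g.std() / g.mean()
        assert cv == pytest.approx(np.sqrt((1 - 0.3) / (m * n * 0.3)), rel=0.02)

    def test_object_and_vectorized_paths_agree_in_mean(self):
        params = TMParams(U=0.5, D=150.0, F=10.0, g_max=1.0)
        train = SpikeTrain(np.array([0.0, 50.0, 100.0]))
        rng = np.random.default_rng(3)
        totals = np.zeros(3)
        n_trials = 4000
        for _ in range(n_trials):
            contacts = [
                SynapticContact(n_rrp=2, params=params),
                SynapticContact(n_rrp=3, params=params),
            ]
            totals += simulate_connection_events(contacts, train, rng).conductances_ns
        rng2 = np.random.default_rng(4)
        g = simulate_release_conductances(np.array([2, 3]), params, train, 20_000, rng2)
        np.testing.assert_allclose(totals / n_trials, g.mean(axis=0), atol=0.05)

    def test_event_series_json_round_trip(self, rng):
        params = TMParams(U=0.5, D=150.0, F=10.0, g_max=1.5)
        contacts = [SynapticContact(n_rrp=3, params=params)]
        ev = simulate_connection_events(
            contacts, SpikeTrain(np.array([0.0, 50.0])), rng
        )
        back = ReleaseEventSeries.from_json(ev.to_json())
        np.testing.assert_array_equal(back.counts, ev.counts)
        np.testing.assert_allclose(back.conductances_ns, ev.conductances_ns)
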