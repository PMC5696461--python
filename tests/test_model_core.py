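"""State space, rate matrices, equilibria and relaxation spectra of the
allosteric gating model, checked against independent oracles (null-space
stationary solve, full-generator eigendecomposition, brute-force cycle
enumeration)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hcgate as hg
from hcgate.errors import (
    DegenerateSolutionError,
    InvalidArgumentError,
    NoRootError,
)


def test_thermal_voltage_room_temperature(ctx):
    # RT/F at 295 K, to four significant figures
    assert ctx.thermal_voltage == pytest.approx(25.42, abs=5e-3)
    with pytest.raises(InvalidArgumentError):
        hg.ThermoContext(-1.0)


class TestStateSpace:
    @pytest.mark.parametrize("m,size", [(6, 22), (2, 10), (1, 7)])
    def test_size(self, m, size):
        assert len(hg.build_state_space(m)) == size

    def test_ordering(self):
        states = hg.build_state_space(2)
        assert [(s.tier, s.n_bound) for s in states[:4]] == [
            ("O", 0), ("C1", 0), ("C1", 1), ("C1", 2)
        ]
        assert states[-1].tier == "C3" and states[-1].n_bound == 2

    @pytest.mark.parametrize("bad", [0, -1, 2.5, "6"])
    def test_invalid_site_count(self, bad):
        with pytest.raises(InvalidArgumentError):
            hg.build_state_space(bad)

    def test_open_tier_carries_no_calcium(self):
        with pytest.raises(InvalidArgumentError):
            hg.MicroState("O", 1)


class TestTierRates:
    def test_prefactors_are_zero_millivolt_rates(self, mlv, ctx):
        g = hg.tier_transition_rates(mlv, 0.0, ctx)
        assert g.alpha[0] == pytest.approx(7.12)
        assert g.beta[0] == pytest.approx(0.92)

    def test_deep_tier_binding_constant_ratio(self, mlv, ctx):
        # Ka3/Ka1 = C^2 = (c_b/c_f)^2, about 1.6 for the published values
        g = hg.tier_transition_rates(mlv, 0.0, ctx)
        assert g.Ka3 / g.Ka1 == pytest.approx((1.11 / 0.87) ** 2, rel=1e-12)
        assert g.Ka3 / g.Ka1 == pytest.approx(1.63, abs=0.01)

    def test_no_coupling_means_occupancy_independent_rates(self, mlv, ctx):
        g = hg.tier_transition_rates(mlv.replace(c_b=1.0, c_f=1.0), -40.0, ctx)
        for arr in (g.alpha, g.beta, g.chi, g.delta):
            assert np.ptp(arr) == 0.0


class TestGenerator:
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, mlv):
        Q, _ = hg.build_generator(mlv, -30.0, 1.0)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
        assert np.abs(Q.sum(axis=1)).max() <= 1e-10 * np.abs(Q).max()

    def test_detailed_balance_every_edge(self, mlv):
        Q, _ = hg.build_generator(mlv, -30.0, 1.0)
        p = hg.stationary_occupancy(Q)
        for i in range(Q.shape[0]):
            for j in range(i + 1, Q.shape[0]):
                if Q[i, j] > 0 or Q[j, i] > 0:
                    fl, bl = p[i] * Q[i, j], p[j] * Q[j, i]
                    assert fl == pytest.approx(bl, rel=1e-8)

    def test_ladder_cycles_balance(self, mlv):
        # product of forward rates equals product of backward rates on
        # every C1_n -> C2_n -> C2_{n+1} -> C1_{n+1} -> C1_n cycle
        V, Ca, kon0 = -25.0, 0.7, 1e4
        g = hg.tier_transition_rates(mlv, V)
        m = mlv.m
        for n in range(m):
            fwd = g.alpha[n] * (m - n) * kon0 * Ca * g.beta[n + 1] * (n + 1) * kon0 / g.Ka1
            bwd = (m - n) * kon0 * Ca * g.alpha[n + 1] * (n + 1) * kon0 / g.Ka2 * g.beta[n]
            assert fwd == pytest.approx(bwd, rel=1e-12)

    def test_zero_calcium_confines_mass_to_unbound_column(self, mlv):
        Q, states = hg.build_generator(mlv, -20.0, 0.0)
        p = hg.stationary_occupancy(Q)
        bound = sum(pi for pi, s in zip(p, states) if s.n_bound > 0)
        assert bound == pytest.approx(0.0, abs=1e-12)

    def test_rapid_equilibrium_insensitive_to_on_rate(self, mlv):
        taus = {}
        for kon0 in (1e4, 1e5):
            Q, _ = hg.build_generator(mlv, -60.0, 1.0, kon0)
            taus[kon0] = hg.generator_time_constants(Q, 2)
        assert np.allclose(taus[1e4], taus[1e5], rtol=1e-2)

    def test_negative_calcium_rejected(self, mlv):
        with pytest.raises(InvalidArgumentError):
            hg.build_generator(mlv, 0.0, -1.0)


class TestStationary:
    def test_two_state_closed_form(self):
        Q = np.array([[-1.0, 1.0], [3.0, -3.0]])
        assert hg.stationary_occupancy(Q) == pytest.approx([0.75, 0.25])

    def test_probability_simplex(self, mlv):
        Q, _ = hg.build_generator(mlv, 10.0, 2.0)
        p = hg.stationary_occupancy(Q)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_strong_depolarization_opens_channel(self, mlv):
        Q, _ = hg.build_generator(mlv, 80.0, 0.0)
        assert hg.stationary_occupancy(Q)[0] > 0.99

    def test_disconnected_chain_raises(self):
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = 1.0
        Q[2, 3] = Q[3, 2] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with pytest.raises(DegenerateSolutionError):
            hg.stationary_occupancy(Q)


class TestOpenProbability:
    def test_half_activation_matches_published_boltzmann(self, mlv):
        # zero-Ca Po crosses half-maximum near -18 mV
        assert hg.open_probability(mlv, -18.0, 0.0) == pytest.approx(0.5, abs=0.02)
        assert hg.half_activation_voltage(mlv) == pytest.approx(-18.0, abs=1.5)

    def test_saturating_calcium_closes_channel(self, mlv):
        assert hg.open_probability(mlv, 0.0, 1e6) < 1e-10

    def test_closed_form_equals_nullspace_solve(self, mlv):
        rng = np.random.default_rng(7)
        for _ in range(20):
            V = rng.uniform(-100, 60)
            Ca = rng.uniform(0, 5)
            Q, _ = hg.build_generator(mlv, V, Ca)
            assert hg.open_probability(mlv, V, Ca) == pytest.approx(
                hg.stationary_occupancy(Q)[0], abs=1e-8
            )

    @given(
        V=st.floats(-120, 80),
        Ca=st.floats(0, 10),
        dV=st.floats(0.1, 40),
        dCa=st.floats(0.01, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_voltage_and_calcium(self, V, Ca, dV, dCa):
        p = hg.reference.CX46_MLV
        assert hg.open_probability(p, V + dV, Ca) >= hg.open_probability(p, V, Ca)
        assert hg.open_probability(p, V, Ca + dCa) <= hg.open_probability(p, V, Ca)


class TestReducedChain:
    def test_zero_calcium_aggregate_entry_rate(self, mlv, ctx):
        V = -35.0
        f1, b1, f2, b2 = hg.reduced_rates(mlv, V, 0.0, ctx)
        g = hg.tier_transition_rates(mlv, V, ctx)
        L1 = hg.fast_equilibrium_constant(mlv, V, ctx)
        assert f1 == pytest.approx(g.alpha[0] * L1 / (1 + L1), rel=1e-12)
        assert b1 == pytest.approx(g.beta[0], rel=1e-12)

    def test_aggregate_stationary_reproduces_tier_masses(self, mlv):
        V, Ca = -40.0, 1.5
        G = hg.reduced_generator(mlv, V, Ca)
        agg = hg.stationary_occupancy(G)
        Q, states = hg.build_generator(mlv, V, Ca)
        p = hg.stationary_occupancy(Q)
        masses = {
            "S1": sum(pi for pi, s in zip(p, states) if s.tier in ("O", "C1")),
            "S2": sum(pi for pi, s in zip(p, states) if s.tier == "C2"),
            "S3": sum(pi for pi, s in zip(p, states) if s.tier == "C3"),
        }
        assert agg == pytest.approx([masses["S1"], masses["S2"], masses["S3"]], abs=1e-8)

    def test_no_coupling_rates_calcium_free_except_entry_weight(self, mlv):
        p = mlv.replace(c_b=1.0, c_f=1.0)
        out0 = hg.reduced_rates(p, -30.0, 0.0)
        out5 = hg.reduced_rates(p, -30.0, 5.0)
        # b1, f2, b2 lose all Ca dependence; f1 keeps the (1+x)^m weight
        for a, b in zip(out0[1:], out5[1:]):
            assert a == pytest.approx(b, rel=1e-12)
        # Ca shifts aggregate mass from O into C1, raising the exit rate
        assert out5[0] > out0[0]

    def test_symmetric_three_state_chain_spectrum(self):
        Q = np.array([[-1.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, -1.0]])
        taus = hg.generator_time_constants(Q, 2)
        assert taus == pytest.approx([1.0 / 3.0, 1.0], rel=1e-10)

    def test_time_constants_accelerate_and_saturate_with_calcium(self, mlv):
        cas = [0.0, 1.0, 2.0, 5.0, 10.0]
        tf, ts = zip(*(hg.slow_time_constants(mlv, -100.0, ca) for ca in cas))
        assert all(np.diff(tf) < 0) and all(np.diff(ts) < 0)
        # plateau: the 5 -> 10 mM decrement is small and much smaller
        # than the initial 0 -> 1 mM drop (saturation is gradual,
        # ~1/(c_b x) convergence toward the c_b^m-scaled limit)
        for tau in (tf, ts):
            last = abs(tau[-1] - tau[-2]) / tau[-2]
            first = abs(tau[1] - tau[0]) / tau[0]
            assert last < 0.05 and last < 0.1 * first

    @pytest.mark.parametrize("V,Ca", [(-100.0, 1.0), (-60.0, 0.3), (-30.0, 3.0)])
    def test_matches_full_generator_spectrum(self, mlv, V, Ca):
        tf, ts = hg.slow_time_constants(mlv, V, Ca)
        Q, _ = hg.build_generator(mlv, V, Ca, kon0=1e4)
        full = hg.generator_time_constants(Q, 2)
        assert tf == pytest.approx(full[0], rel=0.02)
        assert ts == pytest.approx(full[1], rel=0.02)

    def test_aggregation_error_shrinks_as_binding_speeds_up(self, mlv):
        tf_red, _ = hg.slow_time_constants(mlv, -60.0, 1.0)
        errs = []
        for kon0 in (1e3, 1e4, 1e5):
            Q, _ = hg.build_generator(mlv, -60.0, 1.0, kon0)
            errs.append(abs(hg.generator_time_constants(Q, 2)[0] - tf_red))
        assert errs[0] > errs[1] > errs[2]


class TestPulseSimulation:
    def test_constant_voltage_gives_constant_occupancy(self, mlv):
        proto = hg.PulseProtocol(-20.0, -20.0, -20.0, (0.5, 0.2), 5e-3)
        tr = hg.simulate_pulse(mlv, proto, 1.0)
        assert np.ptp(tr.open_probability) < 1e-9

    def test_long_pulse_converges_to_stationary(self, mlv):
        _, ts = hg.slow_time_constants(mlv, -60.0, 0.0)
        proto = hg.PulseProtocol(20.0, -60.0, -60.0, (25 * ts, 0.01), 5e-3)
        tr = hg.simulate_pulse(mlv, proto, 0.0)
        assert tr.open_probability[-1] == pytest.approx(
            hg.open_probability(mlv, -60.0, 0.0), abs=1e-6
        )

    def test_deactivation_trace_carries_the_eigen_time_constants(self, mlv):
        proto = hg.PulseProtocol(0.0, -80.0, -70.0, (3.0, 0.1), 2e-3)
        tr = hg.simulate_pulse(mlv, proto, 0.0)
        t, y = tr.segment(0.0, 3.0)
        fit = hg.fit_exponentials(t[t >= 0.005], y[t >= 0.005], 2)
        tf, ts = hg.slow_time_constants(mlv, -80.0, 0.0)
        assert fit.taus[0] == pytest.approx(tf, rel=0.05)
        assert fit.taus[1] == pytest.approx(ts, rel=0.05)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hg.PulseProtocol(0.0, -80.0, -70.0, (0.0, 0.1), 1e-3)


class TestInhibitionCurves:
    def test_zero_calcium_reference_is_unity(self, mlv):
        rel = hg.model_inhibition(mlv, -20.0, [0.0, 0.1, 1.0])
        assert rel[0] == pytest.approx(1.0, rel=1e-12)

    def test_ic50_grows_with_test_voltage(self, mlv):
        ic = [hg.model_ic50(mlv, v) for v in np.arange(-60.0, 21.0, 10.0)]
        assert np.all(np.diff(ic) >= 0)

    def test_ic50_saturates_at_deep_hyperpolarization(self, mlv):
        lic = [np.log10(hg.model_ic50(mlv, v)) for v in (-60.0, -70.0, -80.0, -90.0)]
        assert np.all(np.abs(np.diff(lic)) < 0.01)

    def test_ic50_scales_with_dissociation_constant(self, mlv):
        # at voltages that keep the channel closed, IC50 ~ Kd
        v = -80.0
        assert hg.model_ic50(mlv.replace(Kd=2 * mlv.Kd), v) == pytest.approx(
            2 * hg.model_ic50(mlv, v), rel=0.01
        )

    def test_no_root_when_inhibition_never_reaches_half(self, mlv):
        with pytest.raises(NoRootError):
            hg.model_ic50(mlv.replace(Kd=1e9), -50.0, log_bracket=(-6.0, 1.0))


def test_params_json_round_trip(tmp_path, mlv, ctx):
    path = tmp_path / "params.json"
    mlv.to_json(path, ctx)
    back, ctx2 = hg.AllostericParams.from_json(path)
    assert back == mlv and ctx2.temperature == ctx.temperature
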