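"""Exchange-model construction, rate matrices and equilibrium solvers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from m6akin import (
    ExchangeModel,
    HybridizationSystem,
    RateSet,
    SpectroState,
    build_rate_matrix,
    equilibrium_populations,
    es_population_from_shift,
    load_model,
    pseudo_first_order,
    save_model,
    stationary_distribution,
    two_state_model,
)
from m6akin.exchange_models import CS_IF_STATE_ORDER


class TestRateMatrix:
    def test_two_state_stationary_ratio(self):
        # kf=1, kb=9 partitions populations 0.9 GS / 0.1 ES
        m = ExchangeModel.from_rates(
            [SpectroState("GS", 0.5), SpectroState("ES", 0.5)],
            {("GS", "ES"): 1.0, ("ES", "GS"): 9.0},
            "two_state",
        )
        assert np.allclose(m.populations, [0.9, 0.1])

    def test_zero_rate_limit_reduces_to_linear_cs_chain(self, cs_if_rates):
        """Shutting the syn pathway block-reduces the four-state matrix."""
        rates = {
            ("ss_syn", "ss_anti"): 54.0,
            ("ss_anti", "ss_syn"): 546.0,
            ("ss_anti", "ds_anti"): 100.0,
            ("ds_anti", "ss_anti"): 20.0,
        }
        states = [SpectroState(n, 0.25) for n in CS_IF_STATE_ORDER]
        m = ExchangeModel.from_rates(states, rates, "four_state_cs_if")
        K = build_rate_matrix(m)
        # ds_syn (index 1) fully decoupled
        assert np.all(K[1, :] == 0) and np.all(K[:, 1] == 0)
        assert m.populations[1] == 0

    def test_stationary_matches_long_time_integration(self):
        rng = np.random.default_rng(42)
        states = [SpectroState(n, 0.25) for n in CS_IF_STATE_ORDER]
        for _ in range(3):
            vals = 10 ** rng.uniform(0, 2, size=8)
            rates = {
                ("ds_anti", "ds_syn"): vals[0],
                ("ds_syn", "ds_anti"): vals[1],
                ("ds_syn", "ss_syn"): vals[2],
                ("ss_syn", "ds_syn"): vals[3],
                ("ss_syn", "ss_anti"): vals[4],
                ("ss_anti", "ss_syn"): vals[5],
                ("ss_anti", "ds_anti"): vals[6],
                ("ds_anti", "ss_anti"): vals[7],
            }
            m = ExchangeModel.from_rates(states, rates, "four_state_cs_if")
            K = build_rate_matrix(m)
            t_end = 50.0 / vals.min()
            sol = solve_ivp(
                lambda t, y: K @ y, (0, t_end),
                [1.0, 0, 0, 0], method="LSODA", rtol=1e-12, atol=1e-14,
            )
            assert np.max(np.abs(sol.y[:, -1] - m.populations)) < 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 1e3), min_size=8, max_size=8))
    def test_columns_sum_to_zero(self, vals):
        states = [SpectroState(n, 0.25) for n in CS_IF_STATE_ORDER]
        pairs = [
            ("ds_anti", "ds_syn"), ("ds_syn", "ds_anti"),
            ("ds_syn", "ss_syn"), ("ss_syn", "ds_syn"),
            ("ss_syn", "ss_anti"), ("ss_anti", "ss_syn"),
            ("ss_anti", "ds_anti"), ("ds_anti", "ss_anti"),
        ]
        m = ExchangeModel.from_rates(states, dict(zip(pairs, vals)),
                                     "four_state_cs_if")
        K = build_rate_matrix(m)
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-10)

    def test_disconnected_topology_names_states(self):
        states = [SpectroState(n, 0.25) for n in CS_IF_STATE_ORDER]
        rates = {
            ("ds_anti", "ds_syn"): 1.0, ("ds_syn", "ds_anti"): 1.0,
            ("ss_syn", "ss_anti"): 1.0, ("ss_anti", "ss_syn"): 1.0,
        }
        with pytest.raises(ValueError, match="ss_syn"):
            ExchangeModel.from_rates(states, rates, "four_state_cs_if")

    def test_inconsistent_populations_rejected(self):
        states = [SpectroState("GS", 0.5), SpectroState("ES", 0.5)]
        with pytest.raises(ValueError, match="stationary"):
            ExchangeModel(states, {("GS", "ES"): 1.0, ("ES", "GS"): 9.0},
                          "two_state")

    def test_detailed_balance_flag_enforces_cycle(self):
        states = [SpectroState(n, 0.25) for n in CS_IF_STATE_ORDER]
        rates = {
            ("ds_anti", "ds_syn"): 1.0, ("ds_syn", "ds_anti"): 1.0,
            ("ds_syn", "ss_syn"): 1.0, ("ss_syn", "ds_syn"): 1.0,
            ("ss_syn", "ss_anti"): 1.0, ("ss_anti", "ss_syn"): 1.0,
            ("ss_anti", "ds_anti"): 5.0, ("ds_anti", "ss_anti"): 1.0,
        }
        with pytest.raises(ValueError, match="detailed balance"):
            ExchangeModel.from_rates(states, rates, "four_state_cs_if",
                                     detailed_balance=True)


class TestEquilibriumPopulations:
    def test_unimolecular_isomer_ratio(self):
        rates = RateSet(k1=10.0, k_m1=90.0)
        system = HybridizationSystem(Ct=1e-4, bimolecular=False)
        eq = equilibrium_populations(rates, system)
        assert eq.populations["ss_syn"] == pytest.approx(0.9, abs=1e-9)
        assert eq.populations["ss_anti"] == pytest.approx(0.1, abs=1e-9)
        assert eq.populations["ds_anti"] == 0.0

    def test_symmetric_rates_give_equal_syn_anti_duplex(self):
        r = 50.0
        rates = RateSet(k1=r, k_m1=r, k2=r, k_m2=r,
                        kon_anti=1e5, koff_anti=r, kon_syn=1e5, koff_syn=r)
        system = HybridizationSystem(Ct=1e-3, ss2_total=1e-3, temperature=310.0)
        eq = equilibrium_populations(rates, system)
        assert eq.populations["ds_syn"] == pytest.approx(
            eq.populations["ds_anti"], rel=1e-9
        )

    def test_matches_nonlinear_steady_state_oracle(self):
        """Root-finding on the full mass-action equations agrees."""
        K1, K_anneal, K2 = 0.1, 1e6, 0.01
        k_m1, koff_anti, k_m2 = 500.0, 20.0, 300.0
        rates = RateSet(
            k1=K1 * k_m1, k_m1=k_m1,
            kon_anti=K_anneal * koff_anti, koff_anti=koff_anti,
            k2=K2 * k_m2, k_m2=k_m2,
            kon_syn=0.0, koff_syn=0.0,
        )
        Ct = 1e-3
        system = HybridizationSystem(Ct=Ct, ss2_total=Ct, temperature=310.0)
        eq = equilibrium_populations(rates, system)

        def residuals(x):
            ss_syn, ss_anti, ds_syn, ds_anti, ss2 = x
            return [
                rates.k1 * ss_syn - rates.k_m1 * ss_anti,
                rates.kon_anti * ss_anti * ss2 - rates.koff_anti * ds_anti,
                rates.k2 * ds_anti - rates.k_m2 * ds_syn,
                ss_syn + ss_anti + ds_syn + ds_anti - Ct,
                ss2 + ds_syn + ds_anti - Ct,
            ]

        x0 = [Ct / 4] * 5
        sol = fsolve(residuals, x0, full_output=False, xtol=1e-13)
        names = ["ss_syn", "ss_anti", "ds_syn", "ds_anti", "ss2"]
        for name, val in zip(names, sol):
            assert eq.concentrations[name] == pytest.approx(val, rel=1e-6)

    def test_all_zero_rates_error(self):
        with pytest.raises(ValueError, match="no equilibration"):
            equilibrium_populations(
                RateSet(), HybridizationSystem(Ct=1e-4, bimolecular=False)
            )

    def test_mass_conservation(self, cs_if_rates, duplex_system):
        eq = equilibrium_populations(cs_if_rates, duplex_system)
        c = eq.concentrations
        strand1 = c["ss_syn"] + c["ss_anti"] + c["ds_syn"] + c["ds_anti"]
        assert strand1 == pytest.approx(duplex_system.Ct, abs=1e-9 * duplex_system.Ct)
        strand2 = c["ss2"] + c["ds_syn"] + c["ds_anti"]
        assert strand2 == pytest.approx(
            duplex_system.ss2_total, abs=1e-9 * duplex_system.Ct
        )

    def test_detailed_balance_on_every_edge_for_closed_cycle(
        self, cs_if_rates, duplex_system
    ):
        cs_if_rates.check_cycle_closure()
        eq = equilibrium_populations(cs_if_rates, duplex_system)
        c = eq.concentrations
        # each edge flux balances at equilibrium
        assert cs_if_rates.k1 * c["ss_syn"] == pytest.approx(
            cs_if_rates.k_m1 * c["ss_anti"], rel=1e-6
        )
        assert cs_if_rates.kon_anti * c["ss_anti"] * c["ss2"] == pytest.approx(
            cs_if_rates.koff_anti * c["ds_anti"], rel=1e-6
        )
        assert cs_if_rates.k2 * c["ds_anti"] == pytest.approx(
            cs_if_rates.k_m2 * c["ds_syn"], rel=1e-6
        )


class TestPseudoFirstOrder:
    def test_annealing_rate_is_kon_times_ss2(self):
        rates = RateSet(k1=54.0, k_m1=546.0, kon_anti=1e6, koff_anti=368.5)
        # choose concentrations so equilibrium [ss2] is easy to verify
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=310.0)
        eq = equilibrium_populations(rates, system)
        model = pseudo_first_order(rates, system)
        assert model.rate("ss_anti", "ds_anti") == pytest.approx(
            1e6 * eq.ss2_free, rel=1e-9
        )

    def test_unimolecular_rates_pass_through(self):
        rates = RateSet(k1=10.0, k_m1=90.0, kon_anti=5.0, koff_anti=50.0)
        system = HybridizationSystem(Ct=1e-4, bimolecular=False)
        model = pseudo_first_order(rates, system)
        assert model.rate("ss_anti", "ds_anti") == 5.0
        assert model.rate("ds_anti", "ss_anti") == 50.0

    def test_round_trip_stationary_populations(self, cs_if_rates, duplex_system):
        eq = equilibrium_populations(cs_if_rates, duplex_system)
        model = pseudo_first_order(cs_if_rates, duplex_system)
        pi = stationary_distribution(build_rate_matrix(model))
        for i, name in enumerate(CS_IF_STATE_ORDER):
            assert pi[i] == pytest.approx(eq.populations[name], rel=1e-6, abs=1e-12)

    def test_two_state_collapse_reproduces_exchange_relation(self):
        """Apparent kon from k_ex and p_ss matches the pseudo-first-order model."""
        from m6akin import duplex_rates_from_exchange

        # pure two-state hybridization: no isomer split of the single strand
        rates = RateSet(kon_anti=1e6, koff_anti=30.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=338.0)
        eq = equilibrium_populations(rates, system)
        p_ss = eq.populations["ss_syn"] + eq.populations["ss_anti"]
        k_ex = rates.koff_anti + rates.kon_anti * eq.ss2_free
        kon, koff = duplex_rates_from_exchange(k_ex, p_ss, system.Ct)
        assert kon == pytest.approx(rates.kon_anti, rel=1e-6)
        assert koff == pytest.approx(rates.koff_anti, rel=1e-6)


class TestEsPopulationFromShift:
    def test_linear_interpolation(self):
        est = es_population_from_shift(1.01, 1.0, 2.0)
        assert est.population == pytest.approx(0.01)
        assert not est.out_of_range

    def test_observed_at_ground_state_gives_zero(self):
        assert es_population_from_shift(1.0, 1.0, 2.0).population == 0.0

    def test_tar_like_one_percent(self):
        # a 1% shift toward the excited state reports a ~1% population
        w_gs, w_es = 136.0, 139.0
        w_obs = w_gs + 0.01 * (w_es - w_gs)
        est = es_population_from_shift(w_obs, w_gs, w_es)
        assert est.population == pytest.approx(0.01, abs=1e-12)

    def test_out_of_range_flagged_and_clipped(self):
        est = es_population_from_shift(2.5, 1.0, 2.0)
        assert est.out_of_range and est.population == 1.0 and est.raw == 1.5

    def test_degenerate_shifts_error(self):
        with pytest.raises(ValueError):
            es_population_from_shift(1.0, 2.0, 2.0)


def test_serialization_round_trip(tmp_path, ss_iso_model):
    for ext in ("yaml", "json"):
        path = tmp_path / f"model.{ext}"
        save_model(ss_iso_model, path)
        loaded = load_model(path)
        assert loaded.topology == ss_iso_model.topology
        assert np.allclose(loaded.populations, ss_iso_model.populations)
        assert loaded.rates == dict(ss_iso_model.rates)
        for a, b in zip(loaded.states, ss_iso_model.states):
            assert a.dw_ppm("C10") == b.dw_ppm("C10")
            assert a.R2 == b.R2
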