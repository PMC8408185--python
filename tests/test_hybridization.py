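"""CS / IF / CS+IF kinetics, apparent rates, flux and the predictor."""

import math

import numpy as np
import pytest

from m6akin import (
    HybridizationSystem,
    RateSet,
    apparent_rates,
    equilibrium_populations,
    flux,
    integrate_cs,
    integrate_cs_if,
    integrate_if,
    predict_m6a_impact,
    predict_table,
)
from m6akin.constants import R_KCAL
from m6akin.hybridization_kinetics import (
    build_predicted_rateset,
    default_time_grid,
)


class TestIntegrateCS:
    def test_decoupled_isomerization_relaxes_at_k1_plus_km1(self):
        rates = RateSet(k1=30.0, k_m1=70.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=0.0, temperature=310.0)
        t = np.linspace(0, 0.2, 200)
        tc = integrate_cs(rates, system, times=t)
        anti = tc.concentrations["ss_anti"]
        anti_eq = anti[-1]
        # ln deviation decays at k1 + k_m1
        dev = anti_eq - anti[1:150]
        slope = np.polyfit(t[1:150], np.log(dev), 1)[0]
        assert -slope == pytest.approx(100.0, rel=1e-3)

    def test_long_time_limit_matches_equilibrium(self, cs_if_rates, duplex_system):
        tc = integrate_cs_if(cs_if_rates, duplex_system)
        eq = equilibrium_populations(cs_if_rates, duplex_system)
        for name in ("ss_syn", "ss_anti", "ds_syn", "ds_anti", "ss2"):
            assert tc.concentrations[name][-1] == pytest.approx(
                eq.concentrations[name], rel=1e-6, abs=1e-12
            )

    def test_mass_conserved_along_trajectory(self, cs_if_rates, duplex_system):
        tc = integrate_cs_if(cs_if_rates, duplex_system)
        assert tc.conservation_residual < 1e-9 * duplex_system.Ct


class TestIntegrateIF:
    def test_absorbing_two_state_recovers_generating_rates(self):
        rates = RateSet(kon_syn=5e5, koff_syn=40.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=328.0)
        tc = integrate_if(rates, system)
        ar = apparent_rates(tc, system)
        assert ar.kon_app == pytest.approx(5e5, rel=1e-4)
        assert ar.koff_app == pytest.approx(40.0, rel=1e-4)

    def test_equilibrium_duplex_ratio_matches_isomer_equilibrium(self):
        rates = RateSet(kon_syn=5e5, koff_syn=40.0, k2=8.0, k_m2=160.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=328.0)
        tc = integrate_if(rates, system)
        ratio = tc.concentrations["ds_anti"][-1] / tc.concentrations["ds_syn"][-1]
        assert ratio == pytest.approx(160.0 / 8.0, rel=1e-5)


class TestIntegrateCSIF:
    def test_syn_shutoff_reduces_to_cs(self, cs_if_rates, duplex_system):
        rates = RateSet(**{**cs_if_rates.__dict__, "kon_syn": 0.0,
                           "koff_syn": 0.0, "k2": 0.0, "k_m2": 0.0})
        t = default_time_grid(rates, duplex_system)
        full = integrate_cs_if(rates, duplex_system, times=t)
        cs = integrate_cs(rates, duplex_system, times=t)
        for name in ("ss_syn", "ss_anti", "ds_anti", "ss2"):
            assert np.max(np.abs(full.concentrations[name]
                                 - cs.concentrations[name])) < 1e-8 * duplex_system.Ct

    def test_anti_shutoff_reduces_to_if(self, cs_if_rates, duplex_system):
        rates = RateSet(**{**cs_if_rates.__dict__, "kon_anti": 0.0,
                           "koff_anti": 0.0, "k1": 0.0, "k_m1": 0.0})
        t = default_time_grid(rates, duplex_system)
        full = integrate_cs_if(rates, duplex_system, times=t)
        if_tc = integrate_if(rates, duplex_system, times=t)
        for name in ("ss_syn", "ds_syn", "ds_anti", "ss2"):
            assert np.max(np.abs(full.concentrations[name]
                                 - if_tc.concentrations[name])) < 1e-8 * duplex_system.Ct

    def test_agrees_with_fixed_step_rk4(self, cs_if_rates):
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=328.15)
        r = cs_if_rates
        t_end = 5e-3
        n_steps = 20000
        dt = t_end / n_steps

        def rhs(y):
            ss_syn, ss_anti, ds_syn, ds_anti, ss2 = y
            a_syn = r.kon_syn * ss_syn * ss2
            m_syn = r.koff_syn * ds_syn
            a_anti = r.kon_anti * ss_anti * ss2
            m_anti = r.koff_anti * ds_anti
            i_ss = r.k1 * ss_syn - r.k_m1 * ss_anti
            i_ds = r.k2 * ds_anti - r.k_m2 * ds_syn
            return np.array([
                -i_ss - a_syn + m_syn,
                i_ss - a_anti + m_anti,
                a_syn - m_syn + i_ds,
                a_anti - m_anti - i_ds,
                -a_syn + m_syn - a_anti + m_anti,
            ])

        y = np.array([system.Ct, 0, 0, 0, system.ss2_total])
        for _ in range(n_steps):
            k1_ = rhs(y)
            k2_ = rhs(y + 0.5 * dt * k1_)
            k3_ = rhs(y + 0.5 * dt * k2_)
            k4_ = rhs(y + dt * k3_)
            y = y + dt / 6.0 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)

        tc = integrate_cs_if(cs_if_rates, system,
                             times=np.array([0.0, t_end / 2, t_end]))
        names = ("ss_syn", "ss_anti", "ds_syn", "ds_anti", "ss2")
        for i, name in enumerate(names):
            assert tc.concentrations[name][-1] == pytest.approx(
                y[i], rel=1e-6, abs=1e-12 * system.Ct
            )

    def test_insensitive_to_preequilibrated_start(self, cs_if_rates,
                                                  duplex_system):
        """Starting from equilibrated single-strand isomers changes little."""
        t = default_time_grid(cs_if_rates, duplex_system)
        from_syn = integrate_cs_if(cs_if_rates, duplex_system, times=t)
        p_anti = cs_if_rates.k1 / (cs_if_rates.k1 + cs_if_rates.k_m1)
        Ct = duplex_system.Ct
        init = [Ct * (1 - p_anti), Ct * p_anti, 0.0, 0.0,
                duplex_system.ss2_total]
        from_eq = integrate_cs_if(cs_if_rates, duplex_system, init=init, times=t)
        a1 = apparent_rates(from_syn, duplex_system)
        a2 = apparent_rates(from_eq, duplex_system)
        assert a1.kon_app == pytest.approx(a2.kon_app, rel=0.01)


class TestApparentRates:
    def test_grid_shape_robustness(self, cs_if_rates, duplex_system):
        t_log = default_time_grid(cs_if_rates, duplex_system)
        tau = 1.0 / (cs_if_rates.koff_anti
                     + cs_if_rates.kon_anti * duplex_system.ss2_total)
        t_lin = np.linspace(0, 400 * tau, 4001)
        a_log = apparent_rates(integrate_cs_if(cs_if_rates, duplex_system,
                                               times=t_log), duplex_system)
        a_lin = apparent_rates(integrate_cs_if(cs_if_rates, duplex_system,
                                               times=t_lin), duplex_system)
        assert a_log.kon_app == pytest.approx(a_lin.kon_app, rel=0.005)
        assert a_log.koff_app == pytest.approx(a_lin.koff_app, rel=0.005)

    def test_warns_when_syn_duplex_accumulates(self):
        # an ultra-fast syn pathway piles up the intermediate
        rates = RateSet(k1=500.0, k_m1=500.0, kon_syn=1e7, koff_syn=10.0,
                        k2=50.0, k_m2=50.0, kon_anti=1e5, koff_anti=10.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=328.0)
        tc = integrate_cs_if(rates, system)
        ar = apparent_rates(tc, system)
        assert ar.warning is not None and "two-state" in ar.warning

    def test_unimolecular_kex_splits_by_equilibrium(self):
        # conformational transition: GS (ss_syn) <-> ES (ds_anti-like)
        rates = RateSet(k1=200.0, k_m1=800.0, kon_anti=3000.0, koff_anti=600.0)
        system = HybridizationSystem(Ct=1e-3, bimolecular=False,
                                     temperature=310.0)
        tc = integrate_cs_if(rates, system)
        ar = apparent_rates(tc, system)
        assert ar.k_ex == pytest.approx(ar.k_forward + ar.k_backward, abs=1e-9)
        # absolute Ct does not matter in the unimolecular mode
        system2 = HybridizationSystem(Ct=5e-5, bimolecular=False,
                                      temperature=310.0)
        tc2 = integrate_cs_if(rates, system2)
        ar2 = apparent_rates(tc2, system2)
        assert ar2.k_forward == pytest.approx(ar.k_forward, rel=1e-6)


class TestFlux:
    def test_equal_forward_rates_halve(self):
        # both CS steps with identical forward throughput r -> flux r/2
        rates = RateSet(k1=10.0, k_m1=10.0, kon_anti=1e5,
                        koff_anti=1e9, kon_syn=0.0, koff_syn=0.0)
        # koff huge keeps almost everything single-stranded, so
        # [ss_syn] ~ [ss_anti] and [ss2] ~ ss2_total: with
        # kon_anti * [ss2] = k1, both step throughputs equal r
        system = HybridizationSystem(Ct=2e-4, ss2_total=1e-4,
                                     temperature=310.0)
        fr = flux(rates, system)
        eq = equilibrium_populations(rates, system)
        step = 10.0 * eq.concentrations["ss_syn"]
        assert fr.F_CS == pytest.approx(step / 2.0, rel=0.02)

    def test_syn_shutoff_zeroes_if_fraction(self, cs_if_rates, duplex_system):
        rates = RateSet(**{**cs_if_rates.__dict__, "kon_syn": 0.0,
                           "koff_syn": 0.0, "k2": 0.0, "k_m2": 0.0})
        fr = flux(rates, duplex_system)
        assert fr.fraction_IF == 0.0 and fr.fraction_CS == 1.0

    def test_constructed_fifty_fifty_split(self, duplex_system):
        """Rates built so both pathway harmonic means coincide split 50:50."""
        base = RateSet(k1=54.0, k_m1=546.0, k2=5.0, k_m2=495.0,
                       kon_anti=2e5, koff_anti=20.0, kon_syn=5e3,
                       koff_syn=23.208342391461482)
        eq = equilibrium_populations(base, duplex_system)
        c = eq.concentrations
        f_cs = 1.0 / (1.0 / (base.k1 * c["ss_syn"])
                      + 1.0 / (base.kon_anti * c["ss_anti"] * c["ss2"]))
        f_if = 1.0 / (1.0 / (base.kon_syn * c["ss_syn"] * c["ss2"])
                      + 1.0 / (base.k_m2 * c["ds_syn"]))
        # rescale every IF-pathway rate by the same factor: equilibrium
        # and cycle closure are preserved while F_IF scales linearly
        scale = f_cs / f_if
        rates = RateSet(**{**base.__dict__,
                           "kon_syn": base.kon_syn * scale,
                           "koff_syn": base.koff_syn * scale,
                           "k2": base.k2 * scale,
                           "k_m2": base.k_m2 * scale})
        fr = flux(rates, duplex_system)
        assert fr.fraction_CS == pytest.approx(0.5, abs=0.02)
        assert fr.fraction_IF == pytest.approx(0.5, abs=0.02)

    def test_no_flux_errors(self):
        rates = RateSet(k1=1.0, k_m1=1.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=310.0)
        with pytest.raises(ValueError, match="zero"):
            flux(rates, system)


class TestPredictor:
    ISO_SS = (54.0, 546.0)
    ISO_DS = (5.0, 495.0)

    def test_unmethylated_limit_fold_is_one(self):
        """No destabilization, no isomer bias, no mismatch penalty: fold 1."""
        T = 328.15
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4, temperature=T)
        fast = 5e4
        kon_ref, dG_ref = 1e5, -6.0
        koff_ref = kon_ref * math.exp(dG_ref / (R_KCAL * T))
        rates = build_predicted_rateset(
            kon_ref=kon_ref, koff_ref=koff_ref, dG_anneal_ref=dG_ref,
            iso_ss=(fast, fast), iso_ds=(fast, fast), temperature=T,
            ddG_m6A=0.0, syn_kon_penalty=1.0, syn_koff_acceleration=1.0,
        )
        tc = integrate_cs_if(rates, system)
        ar = apparent_rates(tc, system, kon_ref=kon_ref, koff_ref=koff_ref)
        assert ar.fold_kon == pytest.approx(1.0, rel=0.02)
        assert ar.fold_koff == pytest.approx(1.0, rel=0.02)

    def test_cs_limit_analytic_fold(self):
        """Hybridization-limited CS: kon_app -> p_anti * kon_anti."""
        kon_ref = 1e5
        rates = RateSet(k1=5000.0, k_m1=45000.0, kon_anti=2 * kon_ref,
                        koff_anti=20.0)
        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4,
                                     temperature=328.15)
        tc = integrate_cs(rates, system)
        ar = apparent_rates(tc, system, kon_ref=kon_ref)
        p_anti = 0.1
        assert ar.fold_kon == pytest.approx(
            kon_ref / (p_anti * rates.kon_anti), rel=0.02
        )

    def test_closure_variants_agree_on_seeded_sweep(self):
        """Near-consistent thermodynamics: both closures within 20%."""
        rng = np.random.default_rng(17)
        for _ in range(6):
            T = rng.uniform(320.0, 340.0)
            RT = R_KCAL * T
            dG = rng.uniform(-7.5, -5.5)
            kon_ref = 10 ** rng.uniform(4.5, 5.5)
            Ct = 10 ** rng.uniform(-4.5, -3.8)
            ddG = 1.0
            pen = RT * math.log(20 * 80) - ddG + rng.uniform(-0.3, 0.3)
            kex_ds = rng.uniform(300.0, 800.0)
            p_syn = math.exp(-pen / RT) / (1 + math.exp(-pen / RT))
            iso_ds = (kex_ds * p_syn, kex_ds * (1 - p_syn))
            kex_ss = rng.uniform(500.0, 3000.0)
            p_anti = rng.uniform(0.05, 0.2)
            iso_ss = (kex_ss * p_anti, kex_ss * (1 - p_anti))
            system = HybridizationSystem(Ct=Ct, ss2_total=Ct, temperature=T)
            p1 = predict_m6a_impact(kon_ref, None, dG, iso_ss, iso_ds, system,
                                    ddG_m6A=ddG, closure="kon_syn_ratio")
            p2 = predict_m6a_impact(kon_ref, None, dG, iso_ss, iso_ds, system,
                                    ddG_m6A=ddG, closure="koff_syn_ratio")
            assert p1.fold_kon == pytest.approx(p2.fold_kon, rel=0.2)
            assert p1.fold_koff == pytest.approx(p2.fold_koff, rel=0.2)

    def test_unimolecular_transition_exceeds_equilibrium_deficit(self):
        """Fast transitions: isomerization becomes rate-limiting and the
        forward-rate slowdown far exceeds the anti-isomer deficit."""
        T = 298.15
        RT = R_KCAL * T
        kf_ref, kb_ref = 500.0, 5000.0
        dG_ref = -RT * math.log(kf_ref / kb_ref)
        system = HybridizationSystem(Ct=1e-3, bimolecular=False, temperature=T)
        pred = predict_m6a_impact(kf_ref, kb_ref, dG_ref,
                                  (1000.0, 10000.0), (50.0, 4950.0), system,
                                  ddG_m6A=2.0)
        anti_deficit = 10000.0 / 1000.0  # 10:1 syn preference
        fold_forward = kf_ref / pred.k_forward
        assert fold_forward > 3.0 * anti_deficit
        # backward rate is much less affected
        assert kb_ref / pred.k_backward < 3.0

    def test_table_matches_direct_call_and_is_deterministic(self):
        import pandas as pd

        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4,
                                     temperature=328.15)
        records = pd.DataFrame(
            {"id": ["a", "a2"], "kon_ref": [1e5, 1e5],
             "dG_anneal_ref": [-6.5, -6.5]}
        )
        table = predict_table(records, self.ISO_SS, self.ISO_DS, system)
        direct = predict_m6a_impact(1e5, None, -6.5, self.ISO_SS, self.ISO_DS,
                                    system)
        assert table.loc[0, "fold_kon"] == pytest.approx(direct.fold_kon,
                                                         rel=1e-9)
        # duplicated record, identical output
        assert table.loc[0, "fold_kon"] == table.loc[1, "fold_kon"]
        assert table.loc[0, "koff_app"] == table.loc[1, "koff_app"]

    def test_missing_columns_listed(self):
        import pandas as pd

        system = HybridizationSystem(Ct=1e-4, ss2_total=1e-4,
                                     temperature=328.15)
        with pytest.raises(ValueError, match="dG_anneal_ref"):
            predict_table(pd.DataFrame({"id": ["x"], "kon_ref": [1.0]}),
                          self.ISO_SS, self.ISO_DS, system)

    def test_slowdown_grows_as_isomerization_becomes_rate_limiting(self):
        """Faster hybridization pushes isomerization toward rate limitation
        and the annealing slowdown beyond the anti-population deficit."""
        system = HybridizationSystem(Ct=1e-3, ss2_total=1e-3,
                                     temperature=310.15)
        folds = []
        for kon_ref in (3e4, 1e5, 3e5, 1e6, 3e6):
            pred = predict_m6a_impact(kon_ref, None, -12.0, self.ISO_SS,
                                      self.ISO_DS, system)
            folds.append(pred.fold_kon)
        assert all(b > a for a, b in zip(folds, folds[1:]))
        assert folds[-1] > 2.0 * folds[0]

    def test_fold_band_across_duplex_stability(self):
        """At genome-table conditions the predicted annealing slowdown stays
        in the several-fold band across a wide duplex-stability span."""
        system = HybridizationSystem(Ct=1e-3, ss2_total=1e-3,
                                     temperature=310.15)
        folds = []
        for dG in (-8.0, -11.0, -14.0, -17.0, -20.0):
            pred = predict_m6a_impact(1e6, None, dG, self.ISO_SS, self.ISO_DS,
                                      system)
            folds.append(pred.fold_kon)
        assert all(3.0 < f < 25.0 for f in folds)
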