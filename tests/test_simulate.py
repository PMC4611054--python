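"""Protocol simulation and observables."""

import numpy as np
import pytest

from proteokin.models import build_model, make_engine
from proteokin.simulate import (dose_response, observable_product,
                                reaction_velocity, running_velocity,
                                simulate_cosubstrate, simulate_open_gate_mutant,
                                simulate_time_course, simulate_with_rpt,
                                species_product)
from proteokin.studies import mm_limit_setup


class TestTimeCourse:
    def test_no_substrate_no_product(self, m9, llvy):
        traj = simulate_time_course(m9, llvy, 0.0, [30.0, 60.0])
        assert np.allclose(observable_product(traj), 0.0)

    def test_no_catalysis_no_product(self, m9, llvy):
        traj = simulate_time_course(m9, llvy.with_(kp=0.0), 320.0,
                                    [30.0, 60.0])
        assert np.allclose(observable_product(traj), 0.0, atol=1e-12)
        # all peptide moiety stays in substrate-containing species
        s_moiety = (traj.series("Sout") + traj.series("G1Sout")
                    + traj.series("S") + traj.series("G2S")
                    + traj.series("EregS") + llvy.h * traj.series("IS"))
        assert np.allclose(s_moiety, 320.0, rtol=1e-8)

    def test_product_equals_integrated_hydrolysis_flux(self, m9, llvy):
        times = np.arange(1.0, 121.0, 1.0)
        traj = simulate_time_course(m9, llvy, 320.0, times)
        eng = traj.engine
        names = eng.state_names()
        cols = np.array([names.index(nm) for nm in traj.names])
        vh = np.empty(times.size)
        for i in range(times.size):
            y = np.zeros(eng.dim)
            y[cols] = traj.states[i]
            vh[i] = eng.hydrolysis_fluxes(y).sum()
        integral = np.concatenate(
            [[0], np.cumsum((vh[1:] + vh[:-1]) / 2 * np.diff(times))])
        prod = observable_product(traj)
        # compare increments past the fast initial transient (trapezoid
        # error on the 1-min grid dominates there)
        inc_prod = prod[20:] - prod[20]
        inc_int = integral[20:] - integral[20]
        assert np.allclose(inc_prod[1:], inc_int[1:], rtol=2e-3)

    def test_product_series_is_monotone(self, m9, llvy, kinetics_times):
        prod = observable_product(
            simulate_time_course(m9, llvy, 320.0, kinetics_times))
        assert np.all(np.diff(prod) > -1e-12)

    def test_solver_refinement_stability(self, m9, llvy):
        times = [15.0, 60.0, 180.0, 360.0]
        a = observable_product(simulate_time_course(
            m9, llvy, 320.0, times, rtol=1e-8, atol=1e-10))
        b = observable_product(simulate_time_course(
            m9, llvy, 320.0, times, rtol=1e-9, atol=1e-11))
        assert np.all(np.abs(a - b) / b < 1e-4)

    def test_outer_product_mode_is_smaller(self, m9, llvy):
        traj = simulate_time_course(m9, llvy, 320.0, [60.0, 240.0])
        total = observable_product(traj, "total")
        outer = observable_product(traj, "outer")
        assert np.all(outer <= total) and outer[-1] > 0


class TestVelocity:
    def test_exact_linear_series(self):
        t = np.array([15.0, 30.0, 45.0, 60.0])
        assert reaction_velocity(t, 0.7 * t + 3.0) == pytest.approx(0.7)
        assert reaction_velocity(t, np.full(4, 2.0)) == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        t = np.array([15.0, 30.0, 45.0, 60.0])
        y = 0.05 * t + rng.normal(0, 0.3, 4)
        # closed-form least squares: slope = cov(t, y) / var(t)
        slope = (np.mean(t * y) - t.mean() * y.mean()) / (np.mean(t * t)
                                                          - t.mean()**2)
        assert reaction_velocity(t, y) == pytest.approx(slope, rel=1e-10)

    def test_window_must_contain_points(self):
        with pytest.raises(ValueError):
            reaction_velocity(np.array([5.0, 10.0]), np.array([1.0, 2.0]))

    def test_running_velocity_of_linear_series(self):
        t = np.linspace(0, 10, 21)
        assert np.allclose(running_velocity(t, 2.0 * t), 2.0)


class TestDoseResponse:
    def test_monotone_without_regulation(self):
        # Michaelis-Menten limit: product at t_end rises with S0 on a
        # 20-point grid
        m9p, _ = mm_limit_setup()
        m9 = build_model("M9")
        grid = np.linspace(20, 640, 20)
        prod = dose_response(m9, m9p, grid, 60.0, rtol=1e-8, atol=1e-12)
        assert np.all(np.diff(prod) > 0)

    def test_zero_time_returns_zeros(self, m9, llvy):
        assert np.allclose(dose_response(m9, llvy, [20.0, 40.0], 0.0), 0.0)

    def test_empty_grid_rejected(self, m9, llvy):
        with pytest.raises(ValueError):
            dose_response(m9, llvy, [], 60.0)


class TestPerturbations:
    def test_mutant_factor_one_is_wildtype(self, m9, llvy):
        t = [30.0, 60.0]
        wt = simulate_time_course(m9, llvy, 200.0, t)
        mut = simulate_open_gate_mutant(m9, llvy, 200.0, t, factor=1.0)
        assert np.allclose(wt.states, mut.states)

    def test_open_gate_speeds_transport_limited_digestion(self, m9, llvy):
        t = [60.0]
        wt = observable_product(simulate_time_course(m9, llvy, 200.0, t))[-1]
        mut = observable_product(
            simulate_open_gate_mutant(m9, llvy, 200.0, t, factor=10.0))[-1]
        assert mut > wt

    def test_mutant_requires_compartmental_model(self, llvy):
        with pytest.raises(ValueError):
            simulate_open_gate_mutant(build_model("M1"), llvy, 100.0, [60.0])

    def test_rpt_factor_one_is_unity(self, m9, llvy):
        fold = simulate_with_rpt(m9, llvy, 200.0, [30.0, 120.0], rpt_factor=1.0)
        assert np.allclose(fold, 1.0, rtol=1e-7)

    def test_rpt_factor_zero_rejected(self, m9, llvy):
        with pytest.raises(ValueError):
            simulate_with_rpt(m9, llvy, 200.0, [30.0], rpt_factor=0.0)


class TestCosubstrate:
    def test_reduces_to_single_substrate_without_a(self, m9, llvy, lle):
        # topology-level constants (Hill, alpha/beta, regulation factors)
        # are shared from species A, so the single-substrate reference for
        # B must carry the same shared values
        times = np.array([30.0, 60.0, 120.0])
        pB = lle.with_(Xenh=llvy.Xenh, Yinh=llvy.Yinh, beta=llvy.beta)
        joint = simulate_cosubstrate(m9, llvy, pB, 0.0, 200.0, times)
        prod_b = species_product(joint, "PB")
        single = observable_product(
            simulate_time_course(m9, pB, 200.0, times))
        assert np.allclose(prod_b, single, rtol=1e-6)

    def test_identical_split_equals_single_run(self, m9, llvy):
        # inhibitor off: its h-th order binding sees each species
        # separately and would legitimately break the split identity
        p = llvy.with_(Ion=0.0, Yinh=0.0)
        times = np.array([30.0, 60.0, 120.0])
        joint = simulate_cosubstrate(m9, p, p, 160.0, 160.0, times)
        tot = species_product(joint, "PA") + species_product(joint, "PB")
        single = observable_product(
            simulate_time_course(m9, p, 320.0, times))
        assert np.allclose(tot, single, rtol=1e-5)

    def test_pre_incubation_starts_faster(self, m9, llvy):
        # after pre-filling the chamber with A, the enhancer is already
        # occupied, so B's early product formation is quicker
        times = np.array([10.0, 20.0, 30.0])
        cold = simulate_cosubstrate(m9, llvy, llvy, 200.0, 200.0, times)
        warm = simulate_cosubstrate(m9, llvy, llvy, 200.0, 200.0, times,
                                    pre_incubation_min=120.0)
        assert species_product(warm, "PB")[-1] > species_product(
            cold, "PB")[-1]

    def test_enhancer_occupying_cosubstrate_boosts_partner(self, m9, llvy,
                                                           lle):
        # species A binds the internal enhancer strongly while staying a
        # weak competitor (no inhibitor contact, slow gate association)
        times = np.array([60.0])
        pA = llvy.with_(Ion=0.0, Yinh=0.0, Xenh=10.0, Ron=0.05, Roff=1e-4,
                        kon=0.01, vin=20.0, kp=50.0)
        pB = lle.with_(Ron=0.0, Ion=0.0, Yinh=0.0, Xenh=10.0)
        joint = simulate_cosubstrate(m9, pA, pB, 320.0, 200.0, times)
        with_a = species_product(joint, "PB")[-1]
        alone = observable_product(
            simulate_time_course(m9, pB, 200.0, times))[-1]
        assert with_a > 1.2 * alone

    def test_requires_compartmental_model(self, llvy, lle):
        with pytest.raises(ValueError):
            simulate_cosubstrate(build_model("M2"), llvy, lle, 10.0, 10.0,
                                 [30.0])
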