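"""Model family definitions and the ODE right-hand sides."""

import math

import numpy as np
import pytest

from proteokin.models import (MODEL_IDS, build_model, initial_state, make_engine,
                              ode_rhs)
from proteokin.params import ParameterSet
from proteokin.ratelaws import rate_hydrolysis
from proteokin.synthetic import fixture_parameters


class TestBuildModel:
    def test_all_nine_ids_build(self):
        for mid in MODEL_IDS:
            m = build_model(mid)
            assert m.model_id == mid

    def test_unknown_id_names_valid_ones(self):
        with pytest.raises(ValueError, match="M1.*M9"):
            build_model("M0")

    def test_m1_species_and_parameters(self):
        m = build_model("M1")
        assert m.species == ("Sout", "Pout")
        assert set(m.parameters) == {"vmax", "KM", "E0"}

    def test_m9_topology(self):
        m = build_model("M9")
        assert m.enhancer_location == "inside"
        assert m.inhibitor_location == "outside"
        assert len(m.species) == 16

    def test_family_structure(self):
        for mid in ("M1", "M2", "M3", "M4"):
            assert not build_model(mid).compartmentalised
        for mid in ("M5", "M6", "M7", "M8", "M9"):
            assert build_model(mid).compartmentalised
        assert build_model("M3").feedback == "binding"
        assert build_model("M4").feedback == "hydrolysis"
        assert build_model("M8").inhibitor_location == "inside"

    def test_species_parameter_consistency(self):
        # regulation species appear exactly when the regulation parameters do
        for mid in ("M5", "M6", "M7", "M8", "M9"):
            m = build_model(mid)
            assert ("Ereg" in m.species) == ("Xenh" in m.parameters)
            assert ("Ifree" in m.species) == ("Yinh" in m.parameters)

    def test_diffusion_variant_only_m5(self):
        assert build_model("M5", diffusion=True).diffusion
        with pytest.raises(ValueError):
            build_model("M9", diffusion=True)


def _m9_rhs_oracle(y: dict, p: ParameterSet) -> dict:
    """Line-by-line transcription of the printed system (conservation-fixed
    signs), independent of the engine implementation."""
    enh = 1 + p.Xenh * (y["EregS"] + y["EregP"]) / p.E0
    inh = 1 + p.Yinh * (y["IS"] + y["IP"]) / p.I0
    tin = p.vin * enh / inh * math.tanh(max(0.0, p.E0 * p.C - y["S"] - y["P"]))
    tout = p.vout * enh / inh
    vh = rate_hydrolysis(y["S"], y["P"], p)
    h = p.h
    d = {}
    d["Sout"] = (-y["Sout"] * y["G1"] * p.kon + y["G1Sout"] * p.koff
                 + y["G2S"] * tout - h * y["Sout"]**h * y["Ifree"] * p.Ion
                 + h * y["IS"] * p.Ioff)
    d["Pout"] = (-y["Pout"] * y["G1"] * p.kon + y["G1Pout"] * p.koff
                 + y["G2P"] * tout - h * y["Pout"]**h * y["Ifree"] * p.Ion
                 + h * y["IP"] * p.Ioff)
    d["G1"] = (-(y["Sout"] + y["Pout"]) * y["G1"] * p.kon
               + (y["G1Sout"] + y["G1Pout"]) * (p.koff + tin))
    d["G1Sout"] = y["Sout"] * y["G1"] * p.kon - y["G1Sout"] * (p.koff + tin)
    d["G1Pout"] = y["Pout"] * y["G1"] * p.kon - y["G1Pout"] * (p.koff + tin)
    d["S"] = (y["G1Sout"] * tin - p.tau * y["S"] * y["G2"] / p.E0 - vh
              - p.Ron * y["S"] * y["Ereg"] / p.E0 + p.Roff * y["EregS"])
    d["P"] = (y["G1Pout"] * tin - p.tau * y["P"] * y["G2"] / p.E0 + vh
              - p.Ron * y["P"] * y["Ereg"] / p.E0 + p.Roff * y["EregP"])
    d["G2S"] = p.tau * y["G2"] * y["S"] / p.E0 - y["G2S"] * tout
    d["G2P"] = p.tau * y["G2"] * y["P"] / p.E0 - y["G2P"] * tout
    d["G2"] = (-p.tau * y["G2"] * (y["S"] + y["P"]) / p.E0
               + (y["G2S"] + y["G2P"]) * tout)
    d["Ereg"] = (-p.Ron * y["Ereg"] * (y["S"] + y["P"]) / p.E0
                 + p.Roff * (y["EregS"] + y["EregP"]))
    d["EregS"] = p.Ron * y["Ereg"] * y["S"] / p.E0 - p.Roff * y["EregS"]
    d["EregP"] = p.Ron * y["Ereg"] * y["P"] / p.E0 - p.Roff * y["EregP"]
    d["Ifree"] = (-(y["Sout"]**h + y["Pout"]**h) * y["Ifree"] * p.Ion
                  + p.Ioff * (y["IS"] + y["IP"]))
    d["IS"] = y["Sout"]**h * y["Ifree"] * p.Ion - p.Ioff * y["IS"]
    d["IP"] = y["Pout"]**h * y["Ifree"] * p.Ion - p.Ioff * y["IP"]
    return d


def _random_m9_state(model, p, rng):
    y = initial_state(model, 0.0, p)
    names = list(model.species)
    state = dict(zip(names, y))
    state["Sout"] = rng.uniform(0, 400)
    state["Pout"] = rng.uniform(0, 40)
    state["S"] = rng.uniform(0, p.E0 * p.C / 2)
    state["P"] = rng.uniform(0, p.E0 * p.C / 2)
    for tot, free, bound in ((p.G1_tot, "G1", ("G1Sout", "G1Pout")),
                             (p.G2_tot, "G2", ("G2S", "G2P")),
                             (p.Ereg_tot, "Ereg", ("EregS", "EregP")),
                             (p.I0, "Ifree", ("IS", "IP"))):
        split = rng.dirichlet(np.ones(3)) * tot
        state[free] = split[0]
        state[bound[0]], state[bound[1]] = split[1], split[2]
    return state


class TestOdeRhs:
    def test_m9_matches_line_by_line_oracle(self, m9, llvy):
        rng = np.random.default_rng(42)
        for _ in range(10):
            state = _random_m9_state(m9, llvy, rng)
            vec = np.array([state[nm] for nm in m9.species])
            got = dict(zip(m9.species, ode_rhs(m9, vec, llvy)))
            want = _m9_rhs_oracle(state, llvy)
            for nm in m9.species:
                assert got[nm] == pytest.approx(want[nm], rel=1e-10,
                                                abs=1e-14), nm

    def test_conserved_totals_have_zero_derivative(self, m9, llvy):
        rng = np.random.default_rng(7)
        state = _random_m9_state(m9, llvy, rng)
        d = dict(zip(m9.species, ode_rhs(
            m9, np.array([state[nm] for nm in m9.species]), llvy)))
        h = llvy.h
        moiety = (d["Sout"] + d["Pout"] + d["G1Sout"] + d["G1Pout"] + d["S"]
                  + d["P"] + d["G2S"] + d["G2P"] + d["EregS"] + d["EregP"]
                  + h * (d["IS"] + d["IP"]))
        assert abs(moiety) < 1e-12
        for grp in (("G1", "G1Sout", "G1Pout"), ("G2", "G2S", "G2P"),
                    ("Ereg", "EregS", "EregP"), ("Ifree", "IS", "IP")):
            assert abs(sum(d[g] for g in grp)) < 1e-12

    def test_hydrolysis_converts_one_to_one(self, llvy):
        # with transport and regulation frozen, dS = -vh and dP = +vh
        m9 = build_model("M9")
        p = llvy.with_(kon=0.0, koff=0.0, vin=0.0, vout=0.0, tau=0.0,
                       Ron=0.0, Roff=0.0, Ion=0.0, Ioff=0.0)
        y = initial_state(m9, 0.0, p)
        vec = dict(zip(m9.species, y))
        vec["S"], vec["P"] = 0.1, 0.05
        arr = np.array([vec[nm] for nm in m9.species])
        d = dict(zip(m9.species, ode_rhs(m9, arr, p)))
        vh = rate_hydrolysis(0.1, 0.05, p)
        assert d["S"] == pytest.approx(-vh, rel=1e-12)
        assert d["P"] == pytest.approx(vh, rel=1e-12)

    def test_all_zero_peptide_is_fixed_point(self, llvy):
        for mid in MODEL_IDS:
            m = build_model(mid)
            y = initial_state(m, 0.0, llvy)
            assert np.allclose(ode_rhs(m, y, llvy), 0.0, atol=1e-15)

    def test_m2_rate_law(self, llvy):
        m2 = build_model("M2")
        d = ode_rhs(m2, np.array([50.0, 10.0]), llvy)
        vh = rate_hydrolysis(50.0, 10.0, llvy)
        assert d[0] == pytest.approx(-vh) and d[1] == pytest.approx(vh)

    def test_feedback_models_accelerate_with_product(self, llvy):
        # product affinities pushed out so the feedback term acts alone,
        # substrate below KaS so stronger binding raises the rate
        p = llvy.with_(eps_bind=5.0, eps_hyd=5.0, KaP=1e9, KiP=1e9)
        for mid in ("M3", "M4"):
            m = build_model(mid)
            v0 = ode_rhs(m, np.array([0.5, 0.0]), p)[1]
            v1 = ode_rhs(m, np.array([0.5, 50.0]), p)[1]
            assert v1 > v0

    def test_negative_state_rejected(self, m9, llvy):
        y = initial_state(m9, 100.0, llvy)
        y[0] = -1.0
        with pytest.raises(ValueError):
            ode_rhs(m9, y, llvy)

    def test_state_dimension_checked(self, m9, llvy):
        with pytest.raises(ValueError):
            ode_rhs(m9, np.zeros(4), llvy)


class TestInitialState:
    def test_totals(self, m9, llvy):
        y = dict(zip(m9.species, initial_state(m9, 480.0, llvy)))
        assert y["Sout"] == 480.0
        assert y["G1"] == llvy.G1_tot and y["G2"] == llvy.G2_tot
        assert y["Ereg"] == llvy.Ereg_tot and y["Ifree"] == llvy.I0
        assert sum(v for k, v in y.items()
                   if k in ("Pout", "S", "P", "G1Sout", "G2S")) == 0.0

    def test_moiety_total_equals_s0(self, m9, llvy):
        eng = make_engine(m9, llvy)
        y = eng.initial_state({"S": 20.0})
        assert eng.conservation_totals(y)["moiety"] == pytest.approx(20.0)

    def test_negative_s0_rejected(self, m9, llvy):
        with pytest.raises(ValueError):
            initial_state(m9, -1.0, llvy)
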