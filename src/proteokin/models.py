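"""The nine-model family of proteasomal peptide hydrolysis.

M1   Michaelis-Menten (no transport, no inhibition)
M2   two-site-modifier law with substrate and product inhibition (SI)
M3   SI + positive feedback of product on catalytic binding
M4   SI + positive feedback of product on the hydrolysis rate
M5   compartmentalised gate/antechamber transport with capacity limit
M6   M5 + transport-enhancing regulatory site on the outer surface
M7   M5 + transport-enhancing regulatory site inside the chamber
M8   M7 + transport-inhibiting site inside the chamber
M9   M7 + transport-inhibiting site on the outer surface (selected model)

M1-M4 are non-compartmental (intermediate enzyme complexes treated in
quasi-steady state, so the observable substrate/product pool evolves under
the closed-form rate laws).  M5-M9 share the transport skeleton and differ
only in regulatory topology; they are instances of the generic
:class:`~proteokin.engine.EngineSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import LOC_INSIDE, LOC_NONE, LOC_OUTSIDE, EngineSpec
from .params import ParameterSet
from . import ratelaws

__all__ = ["MODEL_IDS", "ModelDefinition", "build_model", "ode_rhs",
           "initial_state"]

MODEL_IDS = tuple(f"M{i}" for i in range(1, 10))

_BASE_SPECIES = ["Sout", "Pout", "G1", "G1Sout", "G1Pout",
                 "S", "P", "G2", "G2S", "G2P"]
_ENH_SPECIES = ["Ereg", "EregS", "EregP"]
_INH_SPECIES = ["Ifree", "IS", "IP"]

_TRANSPORT_PARAMS = ["kon", "koff", "vin", "vout", "tau", "C",
                     "G1_tot", "G2_tot"]
_ACTIVE_PARAMS = ["kp", "KaS", "KaP", "KiS", "KiP", "na", "ni",
                  "alpha", "beta", "E0"]


@dataclass(frozen=True)
class ModelDefinition:
    """Topology of one model variant: species and consumed parameters."""

    model_id: str
    compartmentalised: bool
    enhancer_location: str        # none | outside | inside
    inhibitor_location: str       # none | inside | outside
    feedback: str                 # none | binding | hydrolysis
    species: tuple
    parameters: tuple
    diffusion: bool = False

    @property
    def n_species(self) -> int:
        return len(self.species)


def build_model(model_id: str, diffusion: bool = False) -> ModelDefinition:
    """Return the definition of one of the nine model variants.

    ``diffusion=True`` (M5 only) replaces gate binding by symmetric
    first-order exchange; this variant is not part of the default
    selection ladder.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(
            f"unknown model id {model_id!r}; valid ids are {', '.join(MODEL_IDS)}")
    if diffusion and model_id != "M5":
        raise ValueError("the diffusion variant exists only for M5")
    if model_id == "M1":
        return ModelDefinition("M1", False, "none", "none", "none",
                               ("Sout", "Pout"), ("vmax", "KM", "E0"))
    if model_id in ("M2", "M3", "M4"):
        pars = list(_ACTIVE_PARAMS)
        fb = "none"
        if model_id == "M3":
            pars += ["eps_bind", "Kf"]
            fb = "binding"
        elif model_id == "M4":
            pars += ["eps_hyd", "Kf"]
            fb = "hydrolysis"
        return ModelDefinition(model_id, False, "none", "none", fb,
                               ("Sout", "Pout"), tuple(pars))
    enh = {"M5": "none", "M6": "outside", "M7": "inside",
           "M8": "inside", "M9": "inside"}[model_id]
    inh = {"M5": "none", "M6": "none", "M7": "none",
           "M8": "inside", "M9": "outside"}[model_id]
    species = list(_BASE_SPECIES)
    pars = _TRANSPORT_PARAMS + _ACTIVE_PARAMS
    if enh != "none":
        species += _ENH_SPECIES
        pars += ["Ron", "Roff", "Xenh", "Ereg_tot"]
    if inh != "none":
        species += _INH_SPECIES
        pars += ["Ion", "Ioff", "Yinh", "h", "I0"]
    return ModelDefinition(model_id, True, enh, inh, "none",
                           tuple(species), tuple(pars), diffusion=diffusion)


# --------------------------------------------------------------------- engine
_LOC = {"none": LOC_NONE, "inside": LOC_INSIDE, "outside": LOC_OUTSIDE}


def make_engine(model: ModelDefinition, p: ParameterSet) -> EngineSpec:
    """Engine instance for a compartmental model (species S and P)."""
    if not model.compartmentalised:
        raise ValueError(f"{model.model_id} is not compartmentalised")
    two = np.ones(2)
    return EngineSpec(
        species=["S", "P"],
        kon=p.kon * two, koff=p.koff * two, vin=p.vin * two,
        vout=p.vout * two, tau=p.tau * two, cap=p.C * two,
        Ka=np.array([p.KaS, p.KaP]), Ki=np.array([p.KiS, p.KiP]),
        channels=[(0, 1, -1, 1.0, 1)],
        E0=p.E0, kp=p.kp, na=p.na, ni=p.ni, alpha=p.alpha, beta=p.beta,
        Xenh=p.Xenh if model.enhancer_location != "none" else 0.0,
        Yinh=p.Yinh if model.inhibitor_location != "none" else 0.0,
        h=p.h,
        Ron=p.Ron if model.enhancer_location != "none" else 0.0,
        Roff=p.Roff, Ion=p.Ion if model.inhibitor_location != "none" else 0.0,
        Ioff=p.Ioff, I0=p.I0, G1_tot=p.G1_tot, G2_tot=p.G2_tot,
        Ereg_tot=p.Ereg_tot,
        enh_loc=_LOC[model.enhancer_location],
        inh_loc=_LOC[model.inhibitor_location],
        diffusion=model.diffusion,
        is_product=np.array([False, True]),
    )


def _engine_permutation(model: ModelDefinition, eng: EngineSpec) -> np.ndarray:
    names = eng.state_names()
    return np.array([names.index(nm) for nm in model.species])


# ------------------------------------------------- non-compartmental rate laws
def _noncompartmental_rate(model: ModelDefinition, S: float, P: float,
                           p: ParameterSet) -> float:
    S = max(S, 0.0)
    P = max(P, 0.0)
    if model.model_id == "M1":
        return p.vmax * S / (p.KM + S)
    q = p
    if model.feedback == "binding":
        # product enhances catalytic binding: KaS^-1 * (1 + eps*P/(Kf+P))
        q = p.with_(KaS=p.KaS / (1.0 + p.eps_bind * P / (p.Kf + P)))
    elif model.feedback == "hydrolysis":
        q = p.with_(kp=p.kp * (1.0 + p.eps_hyd * P / (p.Kf + P)))
    return ratelaws.rate_hydrolysis(S, P, q)


# ------------------------------------------------------------------ public API
def ode_rhs(model: ModelDefinition, state: np.ndarray,
            p: ParameterSet) -> np.ndarray:
    """Time derivative of the canonical state vector (µM/min).

    States more negative than -1e-6 µM are rejected; smaller negative
    excursions (integrator noise) are clamped inside the rate evaluation.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError(
            f"state must have {model.n_species} entries for {model.model_id}")
    if np.min(state) < -1e-6:
        raise ValueError("state has negative entries beyond tolerance")
    if not model.compartmentalised:
        v = _noncompartmental_rate(model, state[0], state[1], p)
        return np.array([-v, v])
    eng = make_engine(model, p)
    perm = _engine_permutation(model, eng)
    y = np.zeros(eng.dim)
    y[perm] = state
    return eng.rhs(0.0, y)[perm]


def initial_state(model: ModelDefinition, S0: float,
                  p: ParameterSet) -> np.ndarray:
    """Canonical initial state: all substrate outside, free sites at totals."""
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    if not model.compartmentalised:
        return np.array([S0, 0.0])
    eng = make_engine(model, p)
    perm = _engine_permutation(model, eng)
    return eng.initial_state({"S": S0})[perm]
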