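"""Simulation of digestion protocols and mapping of states to observables.

The measured quantity of the fluorogenic assay is released fluorophore,
which tracks every peptide bond the proteasome has hydrolysed regardless
of where the cleaved peptide currently resides.  The default product
observable is therefore the total product moiety
``Pout + G1Pout + P + G2P + EregP + h*IP`` (identically equal to the
time-integral of the hydrolysis flux); ``mode="outer"`` restricts it to
the outer product pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import odeint

from .engine import EngineSpec, LOC_NONE
from .models import ModelDefinition, _engine_permutation, make_engine
from .params import ParameterSet
from . import models as _models

__all__ = ["Trajectory", "simulate_time_course", "simulate_engine",
           "observable_product", "reaction_velocity", "running_velocity",
           "dose_response", "simulate_open_gate_mutant", "simulate_with_rpt",
           "simulate_cosubstrate"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
VELOCITY_WINDOW = (15.0, 30.0, 45.0, 60.0)


@dataclass
class Trajectory:
    """Time grid (min) and state matrix (µM), one row per time point."""

    times: np.ndarray
    states: np.ndarray
    names: list
    engine: Optional[EngineSpec] = None
    model: Optional[ModelDefinition] = None
    params: Optional[ParameterSet] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.states.shape != (self.times.size, len(self.names)):
            raise ValueError("state matrix shape does not match grid/species")

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]


def _integrate(rhs, y0, times, rtol, atol):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(times < 0):
        raise ValueError("times must be non-negative and one-dimensional")
    grid = times
    prepend = times[0] > 0
    if prepend:
        grid = np.concatenate(([0.0], times))
    sol, info = odeint(rhs, y0, grid, tfirst=True, rtol=rtol, atol=atol,
                       mxstep=200000, full_output=True)
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"ODE integration failed: {info['message']}")
    return sol[1:] if prepend else sol


def simulate_engine(eng: EngineSpec, y0: np.ndarray, times: Sequence[float],
                    rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                    conservation_tol: float = 1e-4,
                    positivity_tol: float = 1e-6) -> Trajectory:
    """Integrate an engine instance, with conservation/positivity checks."""
    sol = _integrate(eng.rhs, y0, times, rtol, atol)
    ref = eng.conservation_totals(np.asarray(y0, dtype=float))
    end = eng.conservation_totals(sol[-1])
    for key, v0 in ref.items():
        scale = max(abs(v0), atol)
        if abs(end[key] - v0) > conservation_tol * scale:
            raise RuntimeError(
                f"conservation breach in total {key}: {v0} -> {end[key]}")
    if sol.min() < -positivity_tol:
        raise RuntimeError(f"negative species beyond tolerance: {sol.min()}")
    return Trajectory(np.asarray(times, dtype=float), sol,
                      eng.state_names(), engine=eng)


def simulate_time_course(model: ModelDefinition, p: ParameterSet, S0: float,
                         times: Sequence[float],
                         rtol: float = DEFAULT_RTOL,
                         atol: float = DEFAULT_ATOL) -> Trajectory:
    """Simulate one digestion at initial substrate concentration S0 (µM)."""
    if S0 < 0:
        raise ValueError("S0 must be >= 0")
    if not model.compartmentalised:
        def rhs(t, y):
            v = _models._noncompartmental_rate(model, y[0], y[1], p)
            return np.array([-v, v])
        sol = _integrate(rhs, np.array([S0, 0.0]), times, rtol, atol)
        return Trajectory(np.asarray(times, dtype=float), sol,
                          list(model.species), model=model, params=p)
    eng = make_engine(model, p)
    traj = simulate_engine(eng, eng.initial_state({"S": S0}), times,
                           rtol=rtol, atol=atol)
    perm = _engine_permutation(model, eng)
    return Trajectory(traj.times, traj.states[:, perm], list(model.species),
                      engine=eng, model=model, params=p)


def observable_product(traj: Trajectory, mode: str = "total") -> np.ndarray:
    """Product time series (µM) for a trajectory.

    ``total``: total product moiety (cumulative hydrolysis).
    ``outer``: product outside the proteasome only.
    """
    if traj.engine is not None:
        eng = traj.engine
        w = eng.product_weights()
        names = eng.state_names()
        cols = np.array([names.index(nm) for nm in traj.names])
        wt = np.zeros(len(traj.names))
        # trajectory may be a canonical-order view of the engine state
        for i, c in enumerate(cols):
            wt[i] = w[c]
        if mode == "outer":
            for i, nm in enumerate(traj.names):
                if not any(nm == f"{sp}out" for sp in eng.species):
                    wt[i] = 0.0
        elif mode != "total":
            raise ValueError("mode must be 'total' or 'outer'")
        return traj.states @ wt
    # non-compartmental: the product pool is the observable
    return traj.series("Pout")


def reaction_velocity(times: np.ndarray, product: np.ndarray,
                      window: Sequence[float] = VELOCITY_WINDOW) -> float:
    """Initial velocity (µM/min): least-squares slope over the window points.

    The default window regresses product concentration on time at the
    15/30/45/60 min samples.
    """
    times = np.asarray(times, dtype=float)
    product = np.asarray(product, dtype=float)
    mask = np.isin(times, np.asarray(window, dtype=float))
    if mask.sum() < 2:
        raise ValueError("need at least two samples inside the window")
    slope, _ = np.polyfit(times[mask], product[mask], 1)
    return float(slope)


def running_velocity(times: np.ndarray, product: np.ndarray) -> np.ndarray:
    """Centered finite-difference velocity series (µM/min)."""
    return np.gradient(np.asarray(product, float), np.asarray(times, float))


def dose_response(model: ModelDefinition, p: ParameterSet,
                  S0_list: Sequence[float], t_end: float,
                  mode: str = "total", **solver) -> np.ndarray:
    """Product at ``t_end`` for each initial substrate concentration."""
    if len(S0_list) == 0:
        raise ValueError("S0_list must be non-empty")
    if t_end == 0:
        return np.zeros(len(S0_list))
    out = np.empty(len(S0_list))
    for i, s0 in enumerate(S0_list):
        traj = simulate_time_course(model, p, s0, [t_end], **solver)
        out[i] = observable_product(traj, mode=mode)[-1]
    return out


def simulate_open_gate_mutant(model: ModelDefinition, p: ParameterSet,
                              S0: float, times: Sequence[float],
                              factor: float = 10.0, **solver) -> Trajectory:
    """Open-gate mutant: influx and efflux scaled ``factor``-fold."""
    if not model.compartmentalised:
        raise ValueError("the open-gate mutant requires a compartmental model")
    return simulate_time_course(
        model, p.with_(vin=p.vin * factor, vout=p.vout * factor),
        S0, times, **solver)


def simulate_with_rpt(model: ModelDefinition, p: ParameterSet, S0: float,
                      times: Sequence[float], rpt_factor: float = 5.0,
                      **solver) -> np.ndarray:
    """Fold stimulation of product formation by gate-opening Rpt peptides.

    Rpt binding is modelled as a constant multiplicative increase of the
    influx rate ``vin``.  Returns product_with / product_without per time
    point; NaN where the baseline product is still zero.
    """
    if rpt_factor <= 0:
        raise ValueError("rpt_factor must be > 0")
    base = observable_product(simulate_time_course(model, p, S0, times, **solver))
    with_ = observable_product(simulate_time_course(
        model, p.with_(vin=p.vin * rpt_factor), S0, times, **solver))
    out = np.full(base.shape, np.nan)
    ok = base > 0
    out[ok] = with_[ok] / base[ok]
    return out


def cosubstrate_engine(model: ModelDefinition, pA: ParameterSet,
                       pB: ParameterSet) -> EngineSpec:
    """Two fluorogenic peptides sharing gates, capacity, sites and catalysis.

    Active sites are competitive through the joint partition denominator;
    the capacity term weights the inner load by molecular volume via the
    per-species capacities.  Topology-level constants (Hill coefficients,
    alpha/beta, enhancement/inhibition factors, h) are taken from
    ``pA``; species-level constants are per species.
    """
    if not model.compartmentalised:
        raise ValueError("co-substrate simulation requires a compartmental model")
    loc = {"none": 0, "inside": 1, "outside": 2}
    return EngineSpec(
        species=["SA", "PA", "SB", "PB"],
        kon=[pA.kon, pA.kon, pB.kon, pB.kon],
        koff=[pA.koff, pA.koff, pB.koff, pB.koff],
        vin=[pA.vin, pA.vin, pB.vin, pB.vin],
        vout=[pA.vout, pA.vout, pB.vout, pB.vout],
        tau=[pA.tau, pA.tau, pB.tau, pB.tau],
        cap=[pA.C, pA.C, pB.C, pB.C],
        Ka=[pA.KaS, pA.KaP, pB.KaS, pB.KaP],
        Ki=[pA.KiS, pA.KiP, pB.KiS, pB.KiP],
        channels=[(0, 1, -1, pA.kp, 1), (2, 3, -1, pB.kp, 2)],
        E0=pA.E0, kp=1.0, na=pA.na, ni=pA.ni, alpha=pA.alpha, beta=pA.beta,
        Xenh=pA.Xenh if model.enhancer_location != "none" else 0.0,
        Yinh=pA.Yinh if model.inhibitor_location != "none" else 0.0,
        h=pA.h,
        Ron=[pA.Ron, pA.Ron, pB.Ron, pB.Ron],
        Roff=[pA.Roff, pA.Roff, pB.Roff, pB.Roff],
        Ion=[pA.Ion, pA.Ion, pB.Ion, pB.Ion],
        Ioff=[pA.Ioff, pA.Ioff, pB.Ioff, pB.Ioff],
        I0=pA.I0, G1_tot=pA.G1_tot, G2_tot=pA.G2_tot, Ereg_tot=pA.Ereg_tot,
        enh_loc=loc[model.enhancer_location],
        inh_loc=loc[model.inhibitor_location],
        is_product=np.array([False, True, False, True]),
    )


def simulate_cosubstrate(model: ModelDefinition, pA: ParameterSet,
                         pB: ParameterSet, S0_A: float, S0_B: float,
                         times: Sequence[float],
                         pre_incubation_min: float = 0.0,
                         rtol: float = DEFAULT_RTOL,
                         atol: float = DEFAULT_ATOL) -> Trajectory:
    """Joint digestion of peptides A and B; optional pre-incubation of A.

    With pre-incubation, species A is digested alone for
    ``pre_incubation_min`` before B is added; the returned time axis
    starts at the moment B is added.
    """
    eng = cosubstrate_engine(model, pA, pB)
    y0 = eng.initial_state({"SA": S0_A})
    if pre_incubation_min > 0:
        pre = _integrate(eng.rhs, y0, [pre_incubation_min], rtol, atol)
        y0 = pre[-1].copy()
    y0[eng.index("SBout")] += S0_B
    return simulate_engine(eng, y0, times, rtol=rtol, atol=atol)


def species_product(traj: Trajectory, species: str) -> np.ndarray:
    """Total product moiety of one product species of an engine trajectory."""
    eng = traj.engine
    if eng is None:
        raise ValueError("trajectory has no engine attached")
    k = eng.species.index(species)
    cols = [f"{species}out", f"G1{species}out", species, f"G2{species}"]
    if eng.enh_loc != LOC_NONE:
        cols.append(f"Ereg{species}")
    w = {c: 1.0 for c in cols}
    if eng.inh_loc != LOC_NONE:
        w[f"I{species}"] = eng.h
    out = np.zeros(traj.times.size)
    for c, wt in w.items():
        out += wt * traj.series(c)
    return out * eng.moiety[k]
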