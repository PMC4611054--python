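"""Two-cleavage-site polypeptide degradation and cleavage-site usage.

A hypothetical substrate S carries two cleavage sites; cutting site 1
yields fragments A + BC, cutting site 2 yields AB + C.  The single-site
fragments BC (site 2 intact) and AB (site 1 intact) can be cut again,
yielding the terminal fragments A, B and C:

    S --1--> A + BC        BC --2--> B + C
    S --2--> AB + C        AB --1--> A + B

All six species share the proteasome chamber (volume-weighted capacity),
gates and regulatory sites, each with its own transport parameters.
Active-site regulation is simplified: one shared two-site-modifier
denominator over summed occupancies with common parameters
(KaS, KiS, KiP, na, ni, alpha, beta, kp) and per-site relative rates.

The model analogue of the experimental site-specific cleavage strength
is the per-site cleavage flux; its time evolution classifies into four
behaviour classes (flat / both decreasing / both increasing /
divergent) on the per-site normalised usage measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .engine import LOC_INSIDE, LOC_OUTSIDE, EngineSpec
from .inference import Prior, PriorSet
from .simulate import Trajectory, simulate_engine

__all__ = ["FragmentSet", "UsageTrajectory", "build_polypeptide_model",
           "simulate_polypeptide", "cleavage_site_usage",
           "classify_usage_behavior", "search_behaviors",
           "mean_fragment_length", "default_behavior_prior"]

SPECIES = ("S", "A", "B", "Cfrag", "AB", "BC")
LABELS = ("flat", "both_decrease", "both_increase", "divergent")


@dataclass
class FragmentSet:
    """Species roster and parameters of the two-cleavage-site model."""

    lengths: Dict[str, int] = field(default_factory=lambda: {
        "S": 23, "A": 8, "B": 7, "Cfrag": 8, "AB": 15, "BC": 15})
    #: per-species transport scale, multiplying the shared base rates
    transport_scale: Dict[str, float] = field(default_factory=lambda: {
        s: 1.0 for s in SPECIES})
    kon: float = 0.05
    koff: float = 2.0
    vin: float = 50.0
    vout: float = 2.0
    tau: float = 0.3
    C: float = 100.0              # capacity for the full-length substrate
    E0: float = 0.00179
    # shared simplified active-site parameters; affinities sit at the
    # inner-concentration scale (~E0*C) so modifier occupancy can engage
    kp: float = 5000.0
    KaS: float = 0.05
    KiS: float = 0.5
    KiP: float = 0.1
    na: float = 1.0
    ni: float = 1.0
    alpha: float = 0.3
    beta: float = 0.1
    site_rates: tuple = (1.0, 1.0)   # relative hydrolysis rate of sites 1, 2
    # optional regulation (enhancer inside, inhibitor outside, as selected)
    Ron: float = 0.0
    Roff: float = 1e-3
    Xenh: float = 0.0
    Ion: float = 0.0
    Ioff: float = 0.5
    Yinh: float = 0.0
    product_reentry: bool = True

    def __post_init__(self):
        L = self.lengths
        if set(L) != set(SPECIES):
            raise ValueError(f"lengths must cover exactly {SPECIES}")
        if L["S"] != L["A"] + L["B"] + L["Cfrag"]:
            raise ValueError("length(S) must equal len(A)+len(B)+len(C)")
        if L["AB"] != L["A"] + L["B"] or L["BC"] != L["B"] + L["Cfrag"]:
            raise ValueError("AB/BC lengths inconsistent with A, B, C")

    def with_(self, **kw) -> "FragmentSet":
        return replace(self, **kw)


def build_polypeptide_model(fs: FragmentSet) -> EngineSpec:
    """Compartmental engine for the fragment roster of ``fs``."""
    n = len(SPECIES)
    scale = np.array([fs.transport_scale[s] for s in SPECIES])
    lengths = np.array([fs.lengths[s] for s in SPECIES], dtype=float)
    kon = fs.kon * scale
    if not fs.product_reentry:
        kon = kon * np.array([1.0] + [0.0] * (n - 1))
    cleavable = {"S": fs.KaS, "AB": fs.KaS, "BC": fs.KaS}
    Ka = np.array([cleavable.get(s, np.inf) for s in SPECIES])
    Ki = np.array([fs.KiS if s in cleavable else fs.KiP for s in SPECIES])
    idx = {s: i for i, s in enumerate(SPECIES)}
    r1, r2 = fs.site_rates
    channels = [
        (idx["S"], idx["A"], idx["BC"], r1, 1),
        (idx["S"], idx["AB"], idx["Cfrag"], r2, 2),
        (idx["BC"], idx["B"], idx["Cfrag"], r2, 2),
        (idx["AB"], idx["A"], idx["B"], r1, 1),
    ]
    return EngineSpec(
        species=list(SPECIES),
        kon=kon, koff=fs.koff * scale, vin=fs.vin * scale,
        vout=fs.vout * scale, tau=fs.tau * scale,
        cap=fs.C * fs.lengths["S"] / lengths,  # volume ~ residue count
        Ka=Ka, Ki=Ki, channels=channels,
        E0=fs.E0, kp=fs.kp, na=fs.na, ni=fs.ni, alpha=fs.alpha, beta=fs.beta,
        Xenh=fs.Xenh, Yinh=fs.Yinh, h=1.0,
        Ron=fs.Ron, Roff=fs.Roff, Ion=fs.Ion, Ioff=fs.Ioff, I0=fs.E0,
        G1_tot=fs.E0, G2_tot=fs.E0, Ereg_tot=fs.E0,
        enh_loc=LOC_INSIDE if fs.Xenh > 0 else 0,
        inh_loc=LOC_OUTSIDE if fs.Yinh > 0 else 0,
        moiety=lengths,
        is_product=np.array([s != "S" for s in SPECIES]),
    )


def simulate_polypeptide(fs: FragmentSet, S0: float, times,
                         **solver) -> Trajectory:
    eng = build_polypeptide_model(fs)
    return simulate_engine(eng, eng.initial_state({"S": S0}), times, **solver)


# ---------------------------------------------------------------------- usage
@dataclass
class UsageTrajectory:
    """Per-site cleavage fluxes, cumulative counts and usage measures."""

    times: np.ndarray
    flux: np.ndarray          # (2, T) instantaneous cleavage flux per site
    cumulative: np.ndarray    # (2, T) time-integrated flux
    relative: np.ndarray      # (2, T) share of total cleavages (sums to 1)
    fold: np.ndarray          # (2, T) flux normalised to its first sample

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in (0, 1):
            for i, t in enumerate(self.times):
                rows.append((t, s + 1, self.flux[s, i], self.cumulative[s, i],
                             self.relative[s, i], self.fold[s, i]))
        return pd.DataFrame(rows, columns=["time_min", "site", "flux",
                                           "cumulative", "relative", "fold"])


def cleavage_site_usage(traj: Trajectory) -> UsageTrajectory:
    """Site-resolved cleavage fluxes of a polypeptide trajectory."""
    eng = traj.engine
    if eng is None or not eng.channels:
        raise ValueError("trajectory is not a polypeptide simulation")
    sites = np.array([ch[4] for ch in eng.channels])
    flux = np.zeros((2, traj.times.size))
    for i, y in enumerate(traj.states):
        f = eng.hydrolysis_fluxes(y)
        for s in (1, 2):
            flux[s - 1, i] = f[sites == s].sum()
    cum = np.concatenate([np.zeros((2, 1)),
                          cumulative_trapezoid(flux, traj.times, axis=1)],
                         axis=1)
    tot = cum.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(tot > 0, cum / np.maximum(tot, 1e-300), np.nan)
        f0 = flux[:, [0]]
        fold = np.where(f0 > 0, flux / np.maximum(f0, 1e-300), np.nan)
    return UsageTrajectory(traj.times, flux, cum, rel, fold)


def classify_usage_behavior(usage: UsageTrajectory,
                            deadband: float = 0.15) -> str:
    """Label the drift of the per-site normalised usage measures.

    Each site's flux, normalised to its first sample, is given a trend
    (-1/0/+1) from the sign of its fitted slope, with trends whose total
    relative change stays inside ``deadband`` set to zero.  Opposite
    trends are ``divergent``; same-sign trends ``both_increase`` /
    ``both_decrease``; otherwise ``flat``.
    """
    if usage.times.size < 3:
        raise ValueError("need usage at >= 3 time points")
    trends = []
    for s in (0, 1):
        u = usage.fold[s]
        ok = np.isfinite(u)
        if ok.sum() < 3:
            trends.append(0)
            continue
        res = linregress(usage.times[ok], u[ok])
        change = res.slope * (usage.times[ok][-1] - usage.times[ok][0])
        trends.append(0 if abs(change) < deadband else int(np.sign(res.slope)))
    t1, t2 = trends
    if t1 * t2 == -1:
        return "divergent"
    if t1 + t2 > 0:
        return "both_increase"
    if t1 + t2 < 0:
        return "both_decrease"
    return "flat"


# --------------------------------------------------------------------- search
def default_behavior_prior() -> PriorSet:
    """Prior over transport/regulation parameters for the behaviour search."""
    ps = PriorSet()
    ps["vin"] = Prior("loguniform", 10.0, 300.0)
    ps["vout"] = Prior("loguniform", 0.5, 30.0)
    ps["tau"] = Prior("loguniform", 0.03, 3.0)
    ps["kon"] = Prior("loguniform", 0.01, 0.3)
    for s in ("A", "B", "Cfrag", "AB", "BC"):
        ps[f"scale_{s}"] = Prior("loguniform", 0.05, 20.0)
    ps["Xenh"] = Prior("loguniform", 0.01, 30.0)
    ps["Ron"] = Prior("loguniform", 1e-5, 1e-2)
    ps["Yinh"] = Prior("loguniform", 0.01, 30.0)
    ps["Ion"] = Prior("loguniform", 1e-5, 1e-2)
    ps["site_rate_2"] = Prior("loguniform", 0.1, 10.0)
    ps["KaS"] = Prior("loguniform", 0.005, 5.0)
    ps["KiP"] = Prior("loguniform", 0.005, 5.0)
    # recleave-vs-escape competition window: kp*E0/(KaS*x) ~ efflux rates
    ps["kp"] = Prior("loguniform", 10.0, 3000.0)
    return ps


def _fragment_set_from_theta(theta: dict, base: FragmentSet) -> FragmentSet:
    scale = {"S": 1.0}
    for s in ("A", "B", "Cfrag", "AB", "BC"):
        scale[s] = theta.get(f"scale_{s}", 1.0)
    kw = {k: theta[k] for k in ("vin", "vout", "tau", "kon", "KaS", "KiP",
                                "kp") if k in theta}
    for k in ("Xenh", "Ron", "Yinh", "Ion"):
        if k in theta:
            kw[k] = theta[k]
    if "site_rate_2" in theta:
        kw["site_rates"] = (1.0, theta["site_rate_2"])
    return base.with_(transport_scale=scale, **kw)


def search_behaviors(prior: Optional[PriorSet] = None, n_samples: int = 1000,
                     seed: int = 0, base: Optional[FragmentSet] = None,
                     S0: float = 40.0, times=None, stop_when_complete: bool = True,
                     solver_opts: Optional[dict] = None):
    """Sample the prior, simulate and classify cleavage-site behaviour.

    Returns ``(exemplars, counts, n_evaluated)`` where exemplars maps each
    attained label to one sampled parameter dict and counts is the label
    frequency table (failed simulations count under ``"failed"``).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    prior = prior or default_behavior_prior()
    base = base or FragmentSet()
    times = np.asarray(times if times is not None
                       else np.linspace(15.0, 360.0, 24))
    solver_opts = solver_opts or {"rtol": 1e-6, "atol": 1e-9}
    rng = np.random.default_rng(seed)
    exemplars: dict = {}
    counts = {lab: 0 for lab in LABELS}
    counts["failed"] = 0
    n_eval = 0
    for _ in range(n_samples):
        theta = prior.sample(rng)
        n_eval += 1
        try:
            fs = _fragment_set_from_theta(theta, base)
            traj = simulate_polypeptide(fs, S0, times, **solver_opts)
            label = classify_usage_behavior(cleavage_site_usage(traj))
        except (RuntimeError, ValueError, FloatingPointError):
            counts["failed"] += 1
            continue
        counts[label] += 1
        exemplars.setdefault(label, theta)
        if stop_when_complete and all(l in exemplars for l in LABELS):
            break
    return exemplars, counts, n_eval


def mean_fragment_length(traj: Trajectory) -> np.ndarray:
    """Molar-abundance-weighted mean residue length of the products.

    Intact substrate is excluded; NaN before any product exists.
    """
    eng = traj.engine
    if eng is None or not eng.channels:
        raise ValueError("trajectory is not a polypeptide simulation")
    out = np.full(traj.times.size, np.nan)
    names = eng.state_names()
    for i, y in enumerate(traj.states):
        tot = 0.0
        wsum = 0.0
        for k, sp in enumerate(eng.species):
            if not eng.is_product[k]:
                continue
            slots = [f"{sp}out", f"G1{sp}out", sp, f"G2{sp}"]
            if eng.enh_loc:
                slots.append(f"Ereg{sp}")
            if eng.inh_loc:
                slots.append(f"I{sp}")
            amount = sum(y[names.index(s)] for s in slots)
            tot += amount
            wsum += amount * eng.moiety[k]
        if tot > 1e-12:
            out[i] = wsum / tot
    return out
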