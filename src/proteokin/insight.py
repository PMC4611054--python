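"""Rate-limiting-step analysis, chamber-filling diagnostics, capacity checks.

The rate-limiting step of the proteolytic cascade is probed by scaling
one reaction class at a time (gate affinity, influx, hydrolysis,
translocation, efflux, or gate size = influx+efflux jointly) and
measuring the fold change of product formation after a fixed reaction
time; the class with the strongest fold change is rate limiting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .inference import Posterior
from .models import ModelDefinition
from .params import ParameterSet
from .simulate import Trajectory, observable_product, simulate_time_course

__all__ = ["REACTION_CLASSES", "SensitivityResult", "ChamberReport",
           "rate_limiting_analysis", "chamber_occupancy",
           "capacity_consistency"]

REACTION_CLASSES = ("gate_affinity", "influx", "hydrolysis",
                    "translocation", "efflux", "gate_size")


def _scaled(p: ParameterSet, reaction_class: str, factor: float,
            gate_affinity_mode: str = "kon") -> ParameterSet:
    if reaction_class == "gate_affinity":
        if gate_affinity_mode == "kon":
            return p.with_(kon=p.kon * factor)
        if gate_affinity_mode == "koff":
            return p.with_(koff=p.koff / factor)
        raise ValueError("gate_affinity_mode must be 'kon' or 'koff'")
    if reaction_class == "influx":
        return p.with_(vin=p.vin * factor)
    if reaction_class == "hydrolysis":
        return p.with_(kp=p.kp * factor)
    if reaction_class == "translocation":
        return p.with_(tau=p.tau * factor)
    if reaction_class == "efflux":
        return p.with_(vout=p.vout * factor)
    if reaction_class == "gate_size":
        return p.with_(vin=p.vin * factor, vout=p.vout * factor)
    raise ValueError(f"unknown reaction class {reaction_class!r}; "
                     f"valid classes: {REACTION_CLASSES}")


@dataclass
class SensitivityResult:
    """Fold changes of product formation per perturbed reaction class."""

    table: pd.DataFrame        # reaction_class, particle_id, fold_change
    S0: float
    t_end: float
    factor: float

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("reaction_class")["fold_change"]
        out = g.agg(["mean", "median"]).reset_index()
        out["S0"] = self.S0
        out["t_end"] = self.t_end
        out["factor"] = self.factor
        return out

    def ranking(self, stat: str = "median") -> list:
        return list(self.summary().sort_values(stat, ascending=False)
                    ["reaction_class"])


def rate_limiting_analysis(model: ModelDefinition,
                           params: Union[ParameterSet, Posterior],
                           S0: float = 320.0, t_end: float = 60.0,
                           factor: float = 2.0,
                           classes: Sequence[str] = REACTION_CLASSES,
                           gate_affinity_mode: str = "kon",
                           base_params: Optional[ParameterSet] = None,
                           max_particles: int = 50,
                           **solver) -> SensitivityResult:
    """Product fold change at ``t_end`` when scaling each reaction class.

    With a :class:`Posterior`, the analysis runs over (up to
    ``max_particles`` of) the weighted particles and the result table
    carries one row per particle and class; with a single
    :class:`ParameterSet` there is one row per class.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    for c in classes:
        if c not in REACTION_CLASSES:
            raise ValueError(f"unknown reaction class {c!r}")
    if isinstance(params, Posterior):
        if base_params is None:
            raise ValueError("base_params needed to complete posterior particles")
        idx = np.argsort(params.weights)[::-1][:max_particles]
        plist = [(int(i), base_params.with_(
            **{nm: params.particles.iloc[i][nm] for nm in params.names}))
            for i in idx]
    else:
        plist = [(0, params)]
    rows = []
    for pid, p in plist:
        base = observable_product(
            simulate_time_course(model, p, S0, [t_end], **solver))[-1]
        for c in classes:
            scaled = observable_product(simulate_time_course(
                model, _scaled(p, c, factor, gate_affinity_mode),
                S0, [t_end], **solver))[-1]
            rows.append((c, pid, scaled / base if base > 0 else np.nan))
    return SensitivityResult(
        pd.DataFrame(rows, columns=["reaction_class", "particle_id",
                                    "fold_change"]),
        S0, t_end, factor)


@dataclass
class ChamberReport:
    """Chamber filling diagnostics of one trajectory."""

    times: np.ndarray
    molecules_inside: np.ndarray      # S+P load per proteasome (molecules)
    product_fraction: np.ndarray      # NaN while the chamber is empty
    capacity: float

    def time_to_fill(self, level: float = 0.9) -> float:
        """First time the load reaches ``level`` of its final value (NaN if never)."""
        target = level * self.molecules_inside[-1]
        hit = np.nonzero(self.molecules_inside >= target)[0]
        return float(self.times[hit[0]]) if hit.size else float("nan")


def chamber_occupancy(traj: Trajectory, p: ParameterSet) -> ChamberReport:
    """Molecules inside the chambers per proteasome and the product share.

    Load counts free inner peptide, inner-gate-bound and (for an
    inside-located enhancer) enhancer-bound peptide.
    """
    if traj.model is None or not traj.model.compartmentalised:
        raise ValueError("chamber occupancy requires a compartmental trajectory")
    inside_s = traj.series("S") + traj.series("G2S")
    inside_p = traj.series("P") + traj.series("G2P")
    if traj.model.enhancer_location == "inside":
        inside_s = inside_s + traj.series("EregS")
        inside_p = inside_p + traj.series("EregP")
    if traj.model.inhibitor_location == "inside":
        inside_s = inside_s + p.h * traj.series("IS")
        inside_p = inside_p + p.h * traj.series("IP")
    load = (inside_s + inside_p) / p.E0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(load > 0, inside_p / np.maximum(inside_s + inside_p,
                                                        1e-300), np.nan)
    frac = np.where(load <= 0, np.nan, frac)
    return ChamberReport(traj.times, load, frac, p.C)


def capacity_consistency(C_estimates: dict, molecular_volumes: dict
                         ) -> pd.DataFrame:
    """Pairwise capacity ratios against inverse molecular-volume ratios.

    The chamber capacity scales inversely with substrate volume, so for a
    pair (larger-volume substrate i, smaller-volume substrate j) the
    ratio ``C_j/C_i`` should match ``V_i/V_j``.  The agreement score is
    ``min(r1, r2)/max(r1, r2)``.
    """
    subs = [s for s in C_estimates if s in molecular_volumes]
    if len(subs) < 2:
        raise ValueError("need C estimates and volumes for >= 2 substrates")
    for s in subs:
        if molecular_volumes[s] <= 0:
            raise ValueError(f"non-positive molecular volume for {s}")
    rows = []
    for a in range(len(subs)):
        for b in range(a + 1, len(subs)):
            i, j = subs[a], subs[b]
            if molecular_volumes[i] < molecular_volumes[j]:
                i, j = j, i     # i = larger volume
            c_ratio = C_estimates[j] / C_estimates[i]
            v_ratio = molecular_volumes[i] / molecular_volumes[j]
            rows.append((i, j, c_ratio, v_ratio,
                         min(c_ratio, v_ratio) / max(c_ratio, v_ratio)))
    return pd.DataFrame(rows, columns=["larger_volume", "smaller_volume",
                                       "capacity_ratio",
                                       "inverse_volume_ratio", "agreement"])
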