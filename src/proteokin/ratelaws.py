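"""Scalar rate laws: two-site-modifier hydrolysis and regulated transport.

The hydrolysis law follows the two-site-modifier scheme: substrate and
product can each occupy the catalytic site (affinities KaS, KaP) and a
non-catalytic modifier site (KiS, KiP).  Modifier-site occupancy reduces
catalysis by the factor ``beta`` and interacts with catalytic binding via
``alpha``.  With all modifier and product affinities pushed to infinity
and ``na = 1`` the law collapses to Michaelis-Menten with
``vmax = na*kp*E0`` and ``KM = KaS``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ParameterSet

__all__ = ["partition_denominator", "rate_hydrolysis", "rate_transport"]


def partition_denominator(S: float, P: float, p: ParameterSet) -> float:
    """x, the partition function of the two-site-modifier scheme (>= 1).

    x = 1 + S^na/KaS + S^ni/KiS + P^na/KaP + P^ni/KiP
          + S^(na+ni)/(a*KaS*KiS) + P^(na+ni)/(a*KaP*KiP)
          + S^na*P^ni/(a*KaS*KiP) + S^ni*P^na/(a*KiS*KaP)

    which factors as 1 + A + B + A*B/alpha with
    A = S^na/KaS + P^na/KaP (catalytic-site occupancies) and
    B = S^ni/KiS + P^ni/KiP (modifier-site occupancies).
    """
    _check_conc(S, P)
    _check_affinities(p)
    A = S**p.na / p.KaS + P**p.na / p.KaP
    B = S**p.ni / p.KiS + P**p.ni / p.KiP
    return 1.0 + A + B + A * B / p.alpha


def rate_hydrolysis(S: float, P: float, p: ParameterSet) -> float:
    """Hydrolysis flux v_hydr (µM/min) at inner substrate/product levels.

    v_hydr = na*kp*E0 * (S^na/KaS) * (1 + b*S^ni/(a*KiS) + b*P^ni/(a*KiP)) / x
    """
    _check_conc(S, P)
    _check_affinities(p)
    x = partition_denominator(S, P, p)
    mod = 1.0 + p.beta * (S**p.ni / p.KiS + P**p.ni / p.KiP) / p.alpha
    return p.na * p.kp * p.E0 * (S**p.na / p.KaS) * mod / x


def rate_transport(state: dict, p: ParameterSet, direction: str) -> float:
    """Regulated transport rate constant (1/min) for a state snapshot.

    ``state`` needs the regulatory occupancies (EregS, EregP, IS, IP; absent
    keys default to 0) and, for the inward direction, the inner free load
    S + P.  The inward rate carries the capacity term
    ``tanh(max(0, E0*C - S - P))`` (argument clamped at zero: no reverse
    over-capacity flux); the outward rate does not.
    """
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    ereg = state.get("EregS", 0.0) + state.get("EregP", 0.0)
    iocc = state.get("IS", 0.0) + state.get("IP", 0.0)
    if p.Xenh > 0 and p.E0 == 0:
        raise ValueError("E0 = 0 with active enhancer regulation")
    if p.Yinh > 0 and p.I0 == 0:
        raise ValueError("I0 = 0 with active inhibitor regulation")
    enh = 1.0 + (p.Xenh * ereg / p.E0 if p.Xenh > 0 else 0.0)
    inh = 1.0 + (p.Yinh * iocc / p.I0 if p.Yinh > 0 else 0.0)
    reg = enh / inh
    if direction == "out":
        return p.vout * reg
    load = state.get("S", 0.0) + state.get("P", 0.0)
    return p.vin * reg * math.tanh(max(0.0, p.E0 * p.C - load))


def _check_conc(S: float, P: float) -> None:
    if not (np.isfinite(S) and np.isfinite(P)):
        raise ValueError("non-finite concentration input")
    if S < 0 or P < 0:
        raise ValueError("concentrations must be >= 0")


def _check_affinities(p: ParameterSet) -> None:
    for name in ("KaS", "KaP", "KiS", "KiP"):
        if getattr(p, name) == 0:
            raise ValueError(f"affinity constant {name} must be non-zero")
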