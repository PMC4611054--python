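"""Synthetic fluorogenic-assay data: designs, fixture parameters, noise.

The generator emulates the standard in-vitro digestion setup: purified
20S proteasome in 100 µl buffer, duplicate measurements of released
fluorophore (reported directly in concentration units, nM) over
minutes-to-hours, for several initial substrate concentrations.

The parameter sets returned by :func:`fixture_parameters` are synthetic
fixtures: order-of-magnitude-plausible values chosen so that each
substrate class displays its characteristic kinetic signature
(LLVY-like: strong transport enhancement and rising velocity; LLE-like:
rapid chamber filling, strong substrate inhibition, inefficient
catalysis; VGR-like: intermediate).  They are not experimental
estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelDefinition, build_model
from .params import ParameterSet, enzyme_concentration_um
from .simulate import observable_product, simulate_time_course

__all__ = ["AssayDesign", "TimeCourseDataset", "default_designs",
           "fixture_parameters", "generate_assay_dataset", "SUBSTRATES",
           "ISOFORMS"]

SUBSTRATES = ("LLVY", "VGR", "LLE")
ISOFORMS = ("mouse", "human-s", "human-i")

#: Standard sampling grids (min)
KINETICS_TIMES = (15.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 360.0)
VELOCITY_TIMES = (15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class AssayDesign:
    """Experimental design of one digestion series."""

    substrate: str
    isoform: str
    concentrations_uM: tuple
    times_min: tuple
    replicates: int = 2
    enzyme_ug: float = 0.125
    volume_ul: float = 100.0

    def __post_init__(self):
        if len(self.concentrations_uM) == 0 or min(self.concentrations_uM) <= 0:
            raise ValueError("concentrations must be positive and non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def E0_uM(self) -> float:
        return enzyme_concentration_um(self.enzyme_ug, self.volume_ul)


def default_designs() -> dict:
    """The named assay designs used throughout the analyses."""
    human = {s: AssayDesign(s, "human-s", (20.0, 40.0, 80.0, 160.0, 320.0, 640.0),
                            KINETICS_TIMES, enzyme_ug=0.5) for s in SUBSTRATES}
    return {
        "mouse-LLVY": AssayDesign("LLVY", "mouse",
                                  (80.0, 160.0, 240.0, 320.0, 480.0),
                                  KINETICS_TIMES),
        "mouse-LLE": AssayDesign("LLE", "mouse",
                                 (160.0, 240.0, 320.0, 480.0, 640.0),
                                 KINETICS_TIMES),
        "human-LLVY": human["LLVY"],
        "human-VGR": human["VGR"],
        "human-LLE": human["LLE"],
        "velocity": AssayDesign("LLVY", "mouse",
                                (20.0, 40.0, 80.0, 160.0, 320.0, 640.0),
                                VELOCITY_TIMES),
        "long-kinetics": AssayDesign("LLVY", "mouse", (320.0,),
                                     tuple(np.arange(5.0, 365.0, 5.0))),
    }


# ------------------------------------------------------------------- fixtures
_MOUSE_FIXTURES = {
    # Enhancer-dominated: velocity rises over the first ~90 min as inner
    # product accumulates on the enhancer site; mild substrate inhibition.
    "LLVY": dict(kon=0.05, koff=2.0, vin=50.0, vout=2.0, tau=0.3, C=200.0,
                 kp=5000.0, KaS=2.0, KaP=5.0, KiS=150.0, KiP=100.0,
                 na=1.0, ni=1.0, alpha=0.3, beta=0.1,
                 Ron=4e-4, Roff=1e-3, Xenh=15.0,
                 Ion=5.5e-6, Ioff=0.5, h=2.0, Yinh=4.0),
    # Fast transport, rapid chamber filling, strong external substrate
    # inhibition and inefficient catalysis (small beta).
    "LLE": dict(kon=0.1, koff=0.5, vin=150.0, vout=5.0, tau=0.1, C=250.0,
                kp=5000.0, KaS=1.0, KaP=5.0, KiS=20.0, KiP=10.0,
                na=1.0, ni=1.0, alpha=0.3, beta=0.01,
                Ron=5e-4, Roff=2e-3, Xenh=3.0,
                Ion=2.2e-5, Ioff=0.5, h=2.0, Yinh=10.0),
    # Intermediate behaviour.
    "VGR": dict(kon=0.03, koff=2.0, vin=80.0, vout=3.0, tau=0.4, C=290.0,
                kp=5000.0, KaS=3.0, KaP=8.0, KiS=200.0, KiP=150.0,
                na=1.0, ni=1.0, alpha=0.3, beta=0.2,
                Ron=2e-4, Roff=1e-3, Xenh=8.0,
                Ion=2e-6, Ioff=0.5, h=2.0, Yinh=2.0),
}

# Multiplicative immuno-vs-standard differences (qualitative signatures:
# altered gate affinity, transport and active-site constants; identical C).
_IMMUNO_SCALE = {
    "LLVY": dict(vin=1.5, vout=1.5, kp=1.3, KaS=0.7, koff=0.7, Roff=1.5),
    "LLE": dict(vin=0.7, vout=0.7, KaS=1.4, koff=0.7, Roff=1.5),
    "VGR": dict(vin=1.5, vout=1.5, kon=0.7, Roff=1.5),
}


def fixture_parameters(substrate: str, isoform: str = "mouse") -> ParameterSet:
    """Synthetic fixture ParameterSet for a substrate/isoform combination."""
    if substrate not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; choose from {SUBSTRATES}")
    if isoform not in ISOFORMS:
        raise ValueError(f"unknown isoform {isoform!r}; choose from {ISOFORMS}")
    vals = dict(_MOUSE_FIXTURES[substrate])
    enzyme_ug = 0.125 if isoform == "mouse" else 0.5
    vals["E0"] = enzyme_concentration_um(enzyme_ug)
    if isoform == "human-i":
        for key, fac in _IMMUNO_SCALE[substrate].items():
            vals[key] = vals[key] * fac
    return ParameterSet(**vals)


# -------------------------------------------------------------------- dataset
@dataclass
class TimeCourseDataset:
    """Tidy product measurements plus generation provenance.

    ``data`` columns: substrate, concentration_uM, time_min, replicate,
    product_nM.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    REQUIRED = ("substrate", "concentration_uM", "time_min", "replicate",
                "product_nM")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        if (self.data["product_nM"] < 0).any():
            raise ValueError("negative product concentrations in dataset")

    def design_cells(self) -> pd.DataFrame:
        return self.data[["concentration_uM", "time_min"]].drop_duplicates()

    def mean_over_replicates(self) -> pd.DataFrame:
        """Fitting target: the replicate mean per design cell."""
        return (self.data
                .groupby(["substrate", "concentration_uM", "time_min"],
                         as_index=False)["product_nM"].mean())

    def pivot(self) -> pd.DataFrame:
        """Replicate-mean table, concentrations as rows, times as columns."""
        m = self.mean_over_replicates()
        return m.pivot(index="concentration_uM", columns="time_min",
                       values="product_nM")


def generate_assay_dataset(model: ModelDefinition, params: ParameterSet,
                           design: AssayDesign, noise_sd: float = 0.05,
                           seed: int = 0, noise: str = "lognormal",
                           **solver) -> TimeCourseDataset:
    """Simulate a design and add per-cell measurement noise.

    ``lognormal`` noise multiplies each measurement by
    ``exp(noise_sd * Z)`` (errors scale with signal, CV ~ noise_sd);
    ``additive`` adds ``noise_sd`` µM of Gaussian noise, clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise not in ("lognormal", "additive"):
        raise ValueError("noise must be 'lognormal' or 'additive'")
    rng = np.random.default_rng(seed)
    rows = []
    for s0 in design.concentrations_uM:
        traj = simulate_time_course(model, params, s0,
                                    list(design.times_min), **solver)
        prod_nM = observable_product(traj) * 1e3
        for rep in range(1, design.replicates + 1):
            if noise_sd == 0:
                noisy = prod_nM.copy()
            elif noise == "lognormal":
                noisy = prod_nM * np.exp(noise_sd * rng.standard_normal(prod_nM.size))
            else:
                noisy = np.clip(
                    prod_nM + 1e3 * noise_sd * rng.standard_normal(prod_nM.size),
                    0.0, None)
            for t, v in zip(design.times_min, noisy):
                rows.append((design.substrate, s0, t, rep, v))
    df = pd.DataFrame(rows, columns=list(TimeCourseDataset.REQUIRED))
    prov = {"kind": "synthetic", "model": model.model_id,
            "params": params.as_dict(), "seed": seed, "noise": noise,
            "noise_sd": noise_sd,
            "design": {"substrate": design.substrate,
                       "isoform": design.isoform,
                       "concentrations_uM": list(design.concentrations_uM),
                       "times_min": list(design.times_min),
                       "replicates": design.replicates}}
    return TimeCourseDataset(df, prov)
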