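"""Kinetic parameters of the proteasome hydrolysis models.

All concentrations are in µM and all times in minutes.  Rate constants
therefore carry units of 1/min (first order), 1/(µM·min) (second order,
e.g. ``kon``) or 1/(µM^h·min) for the h-th order inhibitor binding step.
The chamber capacity ``C`` is a dimensionless molecule count per
proteasome; the product ``E0*C`` is the maximal bulk concentration of
peptide that can reside inside the chambers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = ["ParameterSet", "enzyme_concentration_um"]

#: Avogadro-free conversion: µg of enzyme in µl of buffer to µM.
def enzyme_concentration_um(mass_ug: float, volume_ul: float = 100.0,
                            molar_mass_kda: float = 700.0) -> float:
    """Bulk concentration (µM) of proteasome from assay mass and volume.

    Default molar mass is 700 kDa for the 20S particle; default reaction
    volume 100 µl, matching the standard fluorogenic digestion setup.
    """
    if mass_ug < 0 or volume_ul <= 0 or molar_mass_kda <= 0:
        raise ValueError("mass must be >= 0 and volume/molar mass > 0")
    # µg / (g/mol) -> µmol; / µl -> µmol/µl = mol/l... careful:
    # mol = mass_ug * 1e-6 / (molar_mass_kda * 1e3)  [g / (g/mol)]
    # conc_M = mol / (volume_ul * 1e-6)  -> µM = conc_M * 1e6
    mol = mass_ug * 1e-6 / (molar_mass_kda * 1e3)
    return mol / (volume_ul * 1e-6) * 1e6


@dataclass
class ParameterSet:
    """All kinetic constants of the model family.

    Each model variant consumes only the subset of fields relevant to its
    topology; ``validate`` enforces the global sign/shape constraints.
    Fields left as ``None`` (site totals) default to one effective site per
    proteasome, i.e. ``E0``.
    """

    # gate / transport
    kon: float = 0.02      # gate association, 1/(µM·min)
    koff: float = 2.0      # gate dissociation, 1/min
    vin: float = 50.0      # influx through the gate, 1/min
    vout: float = 10.0     # efflux through the gate, 1/min
    tau: float = 30.0      # translocation to the inner gate site, 1/min
    C: float = 200.0       # chamber capacity, molecules per proteasome
    # enhancer site (inside the chamber in the selected topology)
    Ron: float = 0.0       # enhancer binding, 1/(µM·min)
    Roff: float = 0.0      # enhancer unbinding, 1/min
    Xenh: float = 0.0      # transport enhancement factor, dimensionless
    # inhibitor site (outer surface in the selected topology)
    Ion: float = 0.0       # inhibitor binding, 1/(µM^h·min)
    Ioff: float = 0.0      # inhibitor unbinding, 1/min
    h: float = 1.0         # inhibitor binding stoichiometry (Hill exponent)
    Yinh: float = 0.0      # transport inhibition factor, dimensionless
    # active site (two-site-modifier scheme)
    kp: float = 5000.0     # hydrolysis rate constant, 1/min
    KaS: float = 2.0       # catalytic-site affinity constant for substrate, µM^na
    KaP: float = 5.0       # catalytic-site affinity constant for product, µM^na
    KiS: float = 150.0     # modifier-site affinity constant for substrate, µM^ni
    KiP: float = 100.0     # modifier-site affinity constant for product, µM^ni
    na: float = 1.0        # Hill coefficient, catalytic binding
    ni: float = 1.0        # Hill coefficient, modifier binding
    alpha: float = 0.3     # site-interaction factor
    beta: float = 0.1      # catalysis modulation by modifier occupancy (<= 1)
    # Michaelis-Menten variant (M1) only
    vmax: float = 1.0      # µM/min
    KM: float = 100.0      # µM
    # positive-feedback variants (M3/M4) only
    eps_bind: float = 0.0  # feedback strength on catalytic binding
    eps_hyd: float = 0.0   # feedback strength on the hydrolysis rate
    Kf: float = 50.0       # feedback half-saturation, µM
    # totals
    E0: float = 0.00179    # proteasome concentration, µM (0.125 µg / 100 µl)
    I0: Optional[float] = None       # total external inhibitory sites, µM
    G1_tot: Optional[float] = None   # total outer gate sites, µM
    G2_tot: Optional[float] = None   # total inner gate sites, µM
    Ereg_tot: Optional[float] = None  # total enhancer sites, µM

    def __post_init__(self) -> None:
        if self.I0 is None:
            self.I0 = self.E0
        if self.G1_tot is None:
            self.G1_tot = self.E0
        if self.G2_tot is None:
            self.G2_tot = self.E0
        if self.Ereg_tot is None:
            self.Ereg_tot = self.E0
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or v != v:
                raise ValueError(f"parameter {f.name} is not set/finite")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.C < 1:
            raise ValueError("capacity C must be >= 1 molecule")
        if self.na < 1 or self.ni < 1 or self.h < 1:
            raise ValueError("Hill coefficients na, ni, h must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")

    def with_(self, **overrides) -> "ParameterSet":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
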