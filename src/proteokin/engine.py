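"""Generic compartmentalised transport/hydrolysis engine.

A single right-hand side serves every compartmental model in the family:
``n`` peptide species share one outer gate site (G1), one inner gate site
(G2), optionally one transport-enhancing regulatory site (inside or
outside the chamber) and one transport-inhibiting site (outside or
inside).  Substrate and product of the single-substrate models are simply
two engine species linked by a cleavage channel; the co-substrate and
two-cleavage-site polypeptide models add more species and channels.

State layout (length ``4n + 2 + (1+n if enhancer) + (1+n if inhibitor)``)::

    [f_out, G1f, f_in, G2f] * n,  G1, G2,  [Ereg, Eregf*n],  [Ifree, If*n]

The two-site-modifier hydrolysis law couples all inner species through
the shared partition denominator ``x = 1 + A + B + A*B/alpha`` with
``A = sum_k f_in^na/Ka_k`` and ``B = sum_k f_in^ni/Ki_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["EngineSpec", "LOC_NONE", "LOC_INSIDE", "LOC_OUTSIDE"]

LOC_NONE, LOC_INSIDE, LOC_OUTSIDE = 0, 1, 2


@njit(cache=True)
def _rhs_kernel(y, dy, n, kon, koff, vin, vout, tau, cap, loadw, Ka, Ki,
                ch_sub, ch_p1, ch_p2, ch_rate,
                E0, kp, na, ni, alpha, beta, Xenh, Yinh, h,
                Ron, Roff, Ion, Ioff, I0,
                enh_loc, inh_loc, diffusion):  # pragma: no cover - jitted
    for i in range(y.shape[0]):
        dy[i] = 0.0
    base = 4 * n
    iG1 = base
    iG2 = base + 1
    pos = base + 2
    iEreg = -1
    if enh_loc != 0:
        iEreg = pos
        pos += 1 + n
    iI = -1
    if inh_loc != 0:
        iI = pos

    # regulation factor on transport (shared by all species)
    enh = 1.0
    if enh_loc != 0:
        occ = 0.0
        for k in range(n):
            occ += max(y[iEreg + 1 + k], 0.0)
        enh = 1.0 + Xenh * occ / E0
    inh = 1.0
    if inh_loc != 0:
        occ = 0.0
        for k in range(n):
            occ += max(y[iI + 1 + k], 0.0)
        inh = 1.0 + Yinh * occ / I0
    reg = enh / inh

    G1 = max(y[iG1], 0.0)
    G2 = max(y[iG2], 0.0)

    # transport
    for k in range(n):
        fout = max(y[4 * k], 0.0)
        g1f = max(y[4 * k + 1], 0.0)
        fin = max(y[4 * k + 2], 0.0)
        g2f = max(y[4 * k + 3], 0.0)
        load = 0.0
        for j in range(n):
            load += loadw[k, j] * max(y[4 * j + 2], 0.0)
        arg = E0 * cap[k] - load
        if arg < 0.0:
            arg = 0.0
        tin = vin[k] * reg * np.tanh(arg)
        tout = vout[k] * reg
        if diffusion != 0:
            # first-order exchange through an unmodelled gate
            influx = tin * fout
            efflux = tout * fin
            dy[4 * k] += -influx + efflux
            dy[4 * k + 2] += influx - efflux
        else:
            b1 = kon[k] * fout * G1
            dy[4 * k] += -b1 + koff[k] * g1f + tout * g2f
            dy[4 * k + 1] += b1 - g1f * (koff[k] + tin)
            dy[iG1] += -b1 + g1f * (koff[k] + tin)
            trans = tau[k] * fin * G2 / E0
            dy[4 * k + 2] += g1f * tin - trans
            dy[4 * k + 3] += trans - g2f * tout
            dy[iG2] += -trans + g2f * tout

    # hydrolysis through the shared two-site-modifier denominator
    A = 0.0
    B = 0.0
    for k in range(n):
        fin = max(y[4 * k + 2], 0.0)
        if Ka[k] > 0.0:
            A += fin**na / Ka[k]
        if Ki[k] > 0.0:
            B += fin**ni / Ki[k]
    x = 1.0 + A + B + A * B / alpha
    mod = 1.0 + beta * B / alpha
    for c in range(ch_sub.shape[0]):
        s = ch_sub[c]
        fin = max(y[4 * s + 2], 0.0)
        v = na * kp * ch_rate[c] * E0 * (fin**na / Ka[s]) * mod / x
        dy[4 * s + 2] -= v
        dy[4 * ch_p1[c] + 2] += v
        if ch_p2[c] >= 0:
            dy[4 * ch_p2[c] + 2] += v

    # enhancer site
    if enh_loc != 0:
        Ereg = max(y[iEreg], 0.0)
        for k in range(n):
            if enh_loc == 1:  # inside: printed 1/E0 scaling
                conc = max(y[4 * k + 2], 0.0)
                b = Ron[k] * conc * Ereg / E0
            else:             # outside: plain bimolecular binding
                conc = max(y[4 * k], 0.0)
                b = Ron[k] * conc * Ereg
            u = Roff[k] * max(y[iEreg + 1 + k], 0.0)
            tgt = 4 * k + 2 if enh_loc == 1 else 4 * k
            dy[tgt] += -b + u
            dy[iEreg + 1 + k] += b - u
            dy[iEreg] += -b + u

    # inhibitor site (binds/releases h peptide molecules per site)
    if inh_loc != 0:
        Ifree = max(y[iI], 0.0)
        for k in range(n):
            src = 4 * k if inh_loc == 2 else 4 * k + 2
            conc = max(y[src], 0.0)
            b = Ion[k] * conc**h * Ifree
            u = Ioff[k] * max(y[iI + 1 + k], 0.0)
            dy[src] += -h * b + h * u
            dy[iI + 1 + k] += b - u
            dy[iI] += -b + u
    return dy


@dataclass
class EngineSpec:
    """A fully specified compartmental model instance (species + rates)."""

    species: list                     # peptide species names
    kon: np.ndarray
    koff: np.ndarray
    vin: np.ndarray
    vout: np.ndarray
    tau: np.ndarray
    cap: np.ndarray                   # per-species chamber capacity C_k
    Ka: np.ndarray                    # catalytic-site affinities (inf = no binding)
    Ki: np.ndarray                    # modifier-site affinities
    channels: list                    # (sub_idx, prod_idx..., rel_rate, site_label)
    E0: float
    kp: float
    na: float = 1.0
    ni: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    Xenh: float = 0.0
    Yinh: float = 0.0
    h: float = 1.0
    Ron: np.ndarray = None    # per-species enhancer binding constants
    Roff: np.ndarray = None
    Ion: np.ndarray = None    # per-species inhibitor binding constants
    Ioff: np.ndarray = None
    I0: float = 1.0
    G1_tot: float = 1.0
    G2_tot: float = 1.0
    Ereg_tot: float = 1.0
    enh_loc: int = LOC_NONE
    inh_loc: int = LOC_NONE
    diffusion: bool = False
    moiety: np.ndarray = None         # peptide-moiety weight per species (residues)
    is_product: np.ndarray = None     # which species count as product moiety

    def __post_init__(self):
        n = len(self.species)
        for name in ("Ron", "Roff", "Ion", "Ioff"):
            v = getattr(self, name)
            if v is None:
                v = 0.0
            setattr(self, name, np.broadcast_to(
                np.asarray(v, dtype=float), (n,)).copy())
        for name in ("kon", "koff", "vin", "vout", "tau", "cap", "Ka", "Ki"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per species")
        if self.moiety is None:
            self.moiety = np.ones(n)
        self.moiety = np.asarray(self.moiety, dtype=float)
        if self.is_product is None:
            self.is_product = np.zeros(n, dtype=bool)
        self.is_product = np.asarray(self.is_product, dtype=bool)
        for ch in self.channels:
            s, p1, p2 = ch[0], ch[1], ch[2]
            w = self.moiety[p1] + (self.moiety[p2] if p2 >= 0 else 0.0)
            if abs(self.moiety[s] - w) > 1e-9:
                raise ValueError("cleavage channel does not conserve residues")
        if (self.Xenh > 0 or self.enh_loc != LOC_NONE) and self.E0 == 0:
            raise ValueError("E0 = 0 with enhancer regulation present")
        if self.inh_loc != LOC_NONE and self.Yinh > 0 and self.I0 == 0:
            raise ValueError("I0 = 0 with active inhibitor regulation")
        self._loadw = self.cap[:, None] / self.cap[None, :]
        m = len(self.channels)
        self._ch_sub = np.array([c[0] for c in self.channels], dtype=np.int64)
        self._ch_p1 = np.array([c[1] for c in self.channels], dtype=np.int64)
        self._ch_p2 = np.array([c[2] for c in self.channels], dtype=np.int64)
        self._ch_rate = np.array([c[3] for c in self.channels], dtype=float)
        if m == 0:
            self._ch_sub = np.zeros(0, dtype=np.int64)
            self._ch_p1 = np.zeros(0, dtype=np.int64)
            self._ch_p2 = np.zeros(0, dtype=np.int64)
            self._ch_rate = np.zeros(0)

    # ------------------------------------------------------------------ layout
    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def dim(self) -> int:
        d = 4 * self.n + 2
        if self.enh_loc != LOC_NONE:
            d += 1 + self.n
        if self.inh_loc != LOC_NONE:
            d += 1 + self.n
        return d

    def state_names(self) -> list:
        names = []
        for nm in self.species:
            names += [f"{nm}out", f"G1{nm}out", nm, f"G2{nm}"]
        names += ["G1", "G2"]
        if self.enh_loc != LOC_NONE:
            names += ["Ereg"] + [f"Ereg{nm}" for nm in self.species]
        if self.inh_loc != LOC_NONE:
            names += ["Ifree"] + [f"I{nm}" for nm in self.species]
        return names

    def index(self, name: str) -> int:
        return self.state_names().index(name)

    # ------------------------------------------------------------- evaluation
    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        _rhs_kernel(y, dy, self.n, self.kon, self.koff, self.vin, self.vout,
                    self.tau, self.cap, self._loadw, self.Ka, self.Ki,
                    self._ch_sub, self._ch_p1, self._ch_p2, self._ch_rate,
                    self.E0, self.kp, self.na, self.ni, self.alpha, self.beta,
                    self.Xenh, self.Yinh, self.h,
                    self.Ron, self.Roff, self.Ion, self.Ioff, self.I0,
                    self.enh_loc, self.inh_loc, 1 if self.diffusion else 0)
        return dy

    def initial_state(self, outer: dict) -> np.ndarray:
        """State with the given outer concentrations, free sites at totals."""
        y = np.zeros(self.dim)
        for nm, c in outer.items():
            if c < 0:
                raise ValueError("initial concentrations must be >= 0")
            y[4 * self.species.index(nm)] = c
        y[4 * self.n] = self.G1_tot
        y[4 * self.n + 1] = self.G2_tot
        pos = 4 * self.n + 2
        if self.enh_loc != LOC_NONE:
            y[pos] = self.Ereg_tot
            pos += 1 + self.n
        if self.inh_loc != LOC_NONE:
            y[pos] = self.I0
        return y

    # ------------------------------------------------------------ observables
    def moiety_weights(self) -> np.ndarray:
        """Peptide-moiety weight of every state slot (site slots weigh 0)."""
        w = np.zeros(self.dim)
        for k in range(self.n):
            w[4 * k:4 * k + 4] = self.moiety[k]
        pos = 4 * self.n + 2
        if self.enh_loc != LOC_NONE:
            for k in range(self.n):
                w[pos + 1 + k] = self.moiety[k]
            pos += 1 + self.n
        if self.inh_loc != LOC_NONE:
            for k in range(self.n):
                w[pos + 1 + k] = self.h * self.moiety[k]
        return w

    def product_weights(self) -> np.ndarray:
        """Like :meth:`moiety_weights`, restricted to product species."""
        w = self.moiety_weights().copy()
        mask = np.zeros(self.dim, dtype=bool)
        for k in range(self.n):
            if self.is_product[k]:
                mask[4 * k:4 * k + 4] = True
        pos = 4 * self.n + 2
        if self.enh_loc != LOC_NONE:
            for k in range(self.n):
                mask[pos + 1 + k] = self.is_product[k]
            pos += 1 + self.n
        if self.inh_loc != LOC_NONE:
            for k in range(self.n):
                mask[pos + 1 + k] = self.is_product[k]
        w[~mask] = 0.0
        return w

    def conservation_totals(self, y: np.ndarray) -> dict:
        """Site totals and the peptide-moiety total of a state."""
        out = {"G1": y[4 * self.n] + sum(y[4 * k + 1] for k in range(self.n)),
               "G2": y[4 * self.n + 1] + sum(y[4 * k + 3] for k in range(self.n)),
               "moiety": float(self.moiety_weights() @ y)}
        pos = 4 * self.n + 2
        if self.enh_loc != LOC_NONE:
            out["Ereg"] = float(y[pos] + y[pos + 1:pos + 1 + self.n].sum())
            pos += 1 + self.n
        if self.inh_loc != LOC_NONE:
            out["I"] = float(y[pos] + y[pos + 1:pos + 1 + self.n].sum())
        return out

    def hydrolysis_fluxes(self, y: np.ndarray) -> np.ndarray:
        """Per-channel hydrolysis flux (µM/min) at a state snapshot."""
        fin = np.maximum(y[2:4 * self.n:4], 0.0)
        A = float(np.sum(fin**self.na / self.Ka))
        B = float(np.sum(fin**self.ni / self.Ki))
        x = 1.0 + A + B + A * B / self.alpha
        mod = 1.0 + self.beta * B / self.alpha
        out = np.empty(len(self.channels))
        for c, (s, _, _, r, *_rest) in enumerate(self.channels):
            out[c] = (self.na * self.kp * r * self.E0
                      * (fin[s]**self.na / self.Ka[s]) * mod / x)
        return out
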