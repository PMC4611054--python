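"""SBML Level 3 export/import of the compartmental models (M5-M9).

Each model is exported as one compartment, its species with initial
amounts, the full parameter list, and one rate rule per species whose
MathML (including ``tanh`` and ``max``, both in the Level 3 operator
set) is generated from a symbolic reconstruction of the rate equations.
Import reads the species, parameters and the embedded model id back and
rebuilds the model definition, which makes write -> read an exact
parameter round trip.
"""

from __future__ import annotations

from pathlib import Path

import sympy as sp
from lxml import etree
from sympy.printing.mathml import MathMLContentPrinter

from .models import ModelDefinition, build_model
from .params import ParameterSet

__all__ = ["write_sbml", "read_sbml", "validate_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://proteokin.invalid/sbml-annotations"

_PARAM_NAMES = ["kon", "koff", "vin", "vout", "tau", "C", "Ron", "Roff",
                "Xenh", "Ion", "Ioff", "h", "Yinh", "kp", "KaS", "KaP",
                "KiS", "KiP", "na", "ni", "alpha", "beta", "E0", "I0",
                "G1_tot", "G2_tot", "Ereg_tot"]


def _sbml_id(name: str) -> str:
    # underscores would be typeset as subscripts by the MathML printer
    return name.replace("_", "")


def _symbolic_rhs(model: ModelDefinition) -> dict:
    """Symbolic reconstruction of the ODE system, canonical species order."""
    sym = {nm: sp.Symbol(nm, nonnegative=True) for nm in model.species}
    p = {nm: sp.Symbol(_sbml_id(nm), positive=True) for nm in _PARAM_NAMES}
    S, P = sym["S"], sym["P"]
    enh = sp.Integer(1)
    inh = sp.Integer(1)
    if model.enhancer_location != "none":
        enh = 1 + p["Xenh"] * (sym["EregS"] + sym["EregP"]) / p["E0"]
    if model.inhibitor_location != "none":
        inh = 1 + p["Yinh"] * (sym["IS"] + sym["IP"]) / p["I0"]
    reg = enh / inh
    tin = p["vin"] * reg * sp.tanh(sp.Max(0, p["E0"] * p["C"] - S - P))
    tout = p["vout"] * reg
    A = S**p["na"] / p["KaS"] + P**p["na"] / p["KaP"]
    B = S**p["ni"] / p["KiS"] + P**p["ni"] / p["KiP"]
    x = 1 + A + B + A * B / p["alpha"]
    vhydr = (p["na"] * p["kp"] * p["E0"] * (S**p["na"] / p["KaS"])
             * (1 + p["beta"] * B / p["alpha"]) / x)

    d = {nm: sp.Integer(0) for nm in model.species}
    Sout, Pout = sym["Sout"], sym["Pout"]
    G1, G1S, G1P = sym["G1"], sym["G1Sout"], sym["G1Pout"]
    G2, G2S, G2P = sym["G2"], sym["G2S"], sym["G2P"]
    kon, koff, tau, E0 = p["kon"], p["koff"], p["tau"], p["E0"]
    d["Sout"] = -Sout * G1 * kon + G1S * koff + G2S * tout
    d["Pout"] = -Pout * G1 * kon + G1P * koff + G2P * tout
    d["G1"] = -(Sout + Pout) * G1 * kon + (G1S + G1P) * (koff + tin)
    d["G1Sout"] = Sout * G1 * kon - G1S * (koff + tin)
    d["G1Pout"] = Pout * G1 * kon - G1P * (koff + tin)
    d["S"] = G1S * tin - tau * S * G2 / E0 - vhydr
    d["P"] = G1P * tin - tau * P * G2 / E0 + vhydr
    d["G2"] = -tau * G2 * (S + P) / E0 + (G2S + G2P) * tout
    d["G2S"] = tau * G2 * S / E0 - G2S * tout
    d["G2P"] = tau * G2 * P / E0 - G2P * tout
    if model.enhancer_location != "none":
        Ereg, EregS, EregP = sym["Ereg"], sym["EregS"], sym["EregP"]
        Ron, Roff = p["Ron"], p["Roff"]
        if model.enhancer_location == "inside":
            bS, bP = Ron * S * Ereg / E0, Ron * P * Ereg / E0
        else:
            bS, bP = Ron * Sout * Ereg, Ron * Pout * Ereg
        d["Ereg"] = -(bS + bP) + Roff * (EregS + EregP)
        d["EregS"] = bS - Roff * EregS
        d["EregP"] = bP - Roff * EregP
        tgtS, tgtP = (("S", "P") if model.enhancer_location == "inside"
                      else ("Sout", "Pout"))
        d[tgtS] = d[tgtS] - bS + Roff * EregS
        d[tgtP] = d[tgtP] - bP + Roff * EregP
    if model.inhibitor_location != "none":
        Ifree, IS, IP = sym["Ifree"], sym["IS"], sym["IP"]
        Ion, Ioff, h = p["Ion"], p["Ioff"], p["h"]
        srcS, srcP = (("Sout", "Pout") if model.inhibitor_location == "outside"
                      else ("S", "P"))
        bS = Ion * sym[srcS]**h * Ifree
        bP = Ion * sym[srcP]**h * Ifree
        d["Ifree"] = -(bS + bP) + Ioff * (IS + IP)
        d["IS"] = bS - Ioff * IS
        d["IP"] = bP - Ioff * IP
        d[srcS] = d[srcS] - h * bS + h * Ioff * IS
        d[srcP] = d[srcP] - h * bP + h * Ioff * IP
    return d


class _ContentPrinter(MathMLContentPrinter):
    """Content MathML with plain <ci> symbols (no subscript typesetting)."""

    def _print_Symbol(self, sym):
        ci = self.dom.createElement("ci")
        ci.appendChild(self.dom.createTextNode(sym.name))
        return ci


def _mathml(expr) -> etree._Element:
    body = _ContentPrinter().doprint(expr)
    xml = f'<math xmlns="{MATHML_NS}">{body}</math>'
    return etree.fromstring(xml.encode())


def write_sbml(model: ModelDefinition, params: ParameterSet, path,
               S0: float = 0.0, force: bool = False) -> None:
    """Write a compartmental model as an SBML Level 3 document."""
    if not model.compartmentalised and not force:
        raise ValueError("SBML export covers the compartmental models M5-M9")
    nsmap = {None: SBML_NS, "pk": ANNOT_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(root, "model", id=f"proteasome_{model.model_id}",
                           name=f"20S proteasome hydrolysis model "
                                f"{model.model_id}")
    annot = etree.SubElement(mdl, "annotation")
    info = etree.SubElement(annot, f"{{{ANNOT_NS}}}modelInfo")
    info.set("modelId", model.model_id)
    info.set("diffusion", str(model.diffusion).lower())

    comps = etree.SubElement(mdl, "listOfCompartments")
    etree.SubElement(comps, "compartment", id="assay", spatialDimensions="3",
                     size="1", constant="true")
    species = etree.SubElement(mdl, "listOfSpecies")
    init = {"Sout": S0, "G1": params.G1_tot, "G2": params.G2_tot,
            "Ereg": params.Ereg_tot, "Ifree": params.I0}
    for nm in model.species:
        etree.SubElement(
            species, "species", id=nm, compartment="assay",
            initialConcentration=repr(float(init.get(nm, 0.0))),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")
    plist = etree.SubElement(mdl, "listOfParameters")
    for nm in _PARAM_NAMES:
        etree.SubElement(plist, "parameter", id=_sbml_id(nm),
                         value=repr(float(getattr(params, nm))),
                         constant="true")
    rules = etree.SubElement(mdl, "listOfRules")
    for nm, expr in _symbolic_rhs(model).items():
        rule = etree.SubElement(rules, "rateRule", variable=nm)
        rule.append(_mathml(expr))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True,
                                          encoding="UTF-8"))


def read_sbml(path):
    """Read an exported document back: (ModelDefinition, ParameterSet, S0)."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    info = root.find(f".//{{{ANNOT_NS}}}modelInfo")
    if info is None:
        raise ValueError("not a recognised export: missing model annotation")
    model = build_model(info.get("modelId"),
                        diffusion=info.get("diffusion") == "true")
    back = {_sbml_id(nm): nm for nm in _PARAM_NAMES}
    vals = {}
    for el in root.findall(f".//{{{SBML_NS}}}parameter"):
        vals[back[el.get("id")]] = float(el.get("value"))
    params = ParameterSet(**vals)
    S0 = 0.0
    for el in root.findall(f".//{{{SBML_NS}}}species"):
        if el.get("id") == "Sout":
            S0 = float(el.get("initialConcentration"))
    ids = [el.get("id") for el in root.findall(f".//{{{SBML_NS}}}species")]
    if set(ids) != set(model.species):
        raise ValueError("species list inconsistent with the declared model id")
    return model, params, S0


def validate_sbml(path) -> list:
    """Structural validation; returns a list of problems (empty = valid)."""
    problems = []
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as e:
        return [f"unreadable document: {e}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append("root element is not sbml (level 3 namespace)")
    if root.get("level") != "3":
        problems.append("missing/incorrect level attribute")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        return problems + ["no model element"]
    sp_ids = set()
    for el in model.findall(f".//{{{SBML_NS}}}species"):
        if not el.get("id"):
            problems.append("species without id")
        sp_ids.add(el.get("id"))
        if not el.get("compartment"):
            problems.append(f"species {el.get('id')} lacks a compartment")
    for el in model.findall(f".//{{{SBML_NS}}}parameter"):
        if el.get("value") is None:
            problems.append(f"parameter {el.get('id')} lacks a value")
    for rule in model.findall(f".//{{{SBML_NS}}}rateRule"):
        var = rule.get("variable")
        if var not in sp_ids:
            problems.append(f"rateRule targets unknown species {var}")
        math = rule.find(f"{{{MATHML_NS}}}math")
        if math is None:
            problems.append(f"rateRule for {var} lacks MathML")
    return problems
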