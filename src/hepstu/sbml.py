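"""SBML Level 3 export/import of the cellular metabolic model.

The document is written directly as SBML L3v2 XML (lxml).  Kinetic laws
are the rate-law registry expressions rendered as content MathML; all
rates are on the cytosolic-volume basis (mM/min), and ER/mitochondrial
species derivatives carry the cytosol-to-compartment volume ratio, which
the importer reconstructs from the compartment sizes.

The importer parses species, parameters, stoichiometry and the kinetic-law
MathML back into sympy expressions, so a round trip can be checked by
re-evaluating the right-hand side against the numerical kernel.
"""

from __future__ import annotations

import sympy as sp
from lxml import etree

from .metabolic import EnzymeParameterSet, ExternalMilieu, MetabolicState
from .rate_laws import FIXED_COFACTORS, IRREVERSIBLE, RATE_LAWS
from .species import (COMPARTMENT_OF, INTERCONVERTIBLE, REACTIONS, SPECIES,
                      VOLUME_FRACTIONS, _STOICH)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

GAMMA_PARAM = {"GS": "g_gs", "GP": "g_gp", "PK": "g_pk",
               "PFK2": "g_pfk2", "FBP2": "g_fbp2"}
EXTERNAL_SPECIES = {"glc_x": "glucose (plasma)", "lac_x": "lactate (plasma)"}

_SYMBOLS = {}


def _sym(name: str) -> sp.Symbol:
    if name not in _SYMBOLS:
        _SYMBOLS[name] = sp.Symbol(name, positive=True)
    return _SYMBOLS[name]


def parse_rate_law(reaction: str) -> sp.Expr:
    """The registry rate law of one reaction as a sympy expression."""
    law = RATE_LAWS[reaction]
    names = set()
    for token in sp.sympify(law, evaluate=False).atoms(sp.Symbol):
        names.add(str(token))
    return sp.sympify(law, locals={n: _sym(n) for n in names})


# ---- content MathML rendering -------------------------------------------

def _ml(tag, *children, text=None):
    el = etree.Element(f"{{{MATHML_NS}}}{tag}")
    if text is not None:
        el.text = text
    for c in children:
        el.append(c)
    return el


def _expr_to_mathml(expr: sp.Expr):
    if isinstance(expr, sp.Symbol):
        return _ml("ci", text=str(expr))
    if isinstance(expr, (sp.Integer, sp.Float)):
        return _ml("cn", text=repr(float(expr)))
    if isinstance(expr, sp.Rational):
        return _ml("apply", _ml("divide"),
                   _ml("cn", text=str(expr.p)), _ml("cn", text=str(expr.q)))
    if isinstance(expr, sp.Add):
        return _ml("apply", _ml("plus"), *[_expr_to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Mul):
        num, den = [], []
        for f in expr.args:
            if isinstance(f, sp.Pow) and f.exp.is_number and f.exp < 0:
                den.append(sp.Pow(f.base, -f.exp))
            elif isinstance(f, sp.Rational) and not isinstance(f, sp.Integer):
                num.append(sp.Integer(f.p))
                den.append(sp.Integer(f.q))
            else:
                num.append(f)
        num_ml = (_expr_to_mathml(num[0]) if len(num) == 1 else
                  _ml("apply", _ml("times"), *[_expr_to_mathml(a) for a in num])
                  if num else _ml("cn", text="1.0"))
        if not den:
            return num_ml
        den_expr = den[0] if len(den) == 1 else sp.Mul(*den, evaluate=False)
        return _ml("apply", _ml("divide"), num_ml, _expr_to_mathml(den_expr))
    if isinstance(expr, sp.Pow):
        if expr.exp.is_number and expr.exp < 0:
            return _ml("apply", _ml("divide"), _ml("cn", text="1.0"),
                       _expr_to_mathml(sp.Pow(expr.base, -expr.exp)))
        return _ml("apply", _ml("power"), _expr_to_mathml(expr.base),
                   _expr_to_mathml(expr.exp))
    raise ValueError(f"cannot render expression node {expr!r}")


def _mathml_to_expr(node) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        return _mathml_to_expr(node[0])
    if tag == "ci":
        return _sym(node.text.strip())
    if tag == "cn":
        return sp.Float(node.text.strip())
    if tag == "apply":
        op = etree.QName(node[0]).localname
        args = [_mathml_to_expr(c) for c in node[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            return args[0] - args[1] if len(args) == 2 else -args[0]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return sp.Pow(args[0], args[1])
        raise ValueError(f"unsupported MathML operator {op!r}")
    raise ValueError(f"unsupported MathML element {tag!r}")


# ---- export --------------------------------------------------------------

def export_sbml(params: EnzymeParameterSet,
                milieu: ExternalMilieu | None = None,
                state: MetabolicState | None = None) -> bytes:
    """Serialise the single-hepatocyte model as an SBML L3v2 document."""
    milieu = milieu or ExternalMilieu()
    state = state or MetabolicState.physiological(milieu.glucose)

    E = lambda tag, **attrs: etree.Element(f"{{{SBML_NS}}}{tag}", **attrs)

    sbml = E("sbml", level="3", version="2")
    model = E("model", id="hepatocyte_carbohydrate_metabolism",
              name="Hepatocyte glycolysis, gluconeogenesis and glycogen turnover",
              substanceUnits="millimole", timeUnits="minute",
              volumeUnits="litre", extentUnits="millimole")
    sbml.append(model)

    comps = E("listOfCompartments")
    for cid, size in [("cytosol", VOLUME_FRACTIONS["cytosol"]),
                      ("er", VOLUME_FRACTIONS["er"]),
                      ("mito", VOLUME_FRACTIONS["mito"]),
                      ("external", 1.0)]:
        comps.append(E("compartment", id=cid, size=repr(size),
                       constant="true", spatialDimensions="3"))
    model.append(comps)

    species_el = E("listOfSpecies")
    for sp_name in SPECIES:
        species_el.append(E(
            "species", id=sp_name, compartment=COMPARTMENT_OF[sp_name],
            initialConcentration=repr(state[sp_name]),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false"))
    for sp_name, label in EXTERNAL_SPECIES.items():
        value = milieu.glucose if sp_name == "glc_x" else milieu.lactate
        species_el.append(E(
            "species", id=sp_name, name=label, compartment="external",
            initialConcentration=repr(float(value)),
            hasOnlySubstanceUnits="false", boundaryCondition="true",
            constant="true"))
    for cof, value in FIXED_COFACTORS.items():
        species_el.append(E(
            "species", id=cof, compartment="cytosol",
            initialConcentration=repr(float(value)),
            hasOnlySubstanceUnits="false", boundaryCondition="true",
            constant="true"))
    model.append(species_el)

    pars = E("listOfParameters")
    for rxn in REACTIONS:
        pars.append(E("parameter", id=f"{rxn}_Vmax",
                      value=repr(params.vmax_of(rxn)), constant="true"))
    for key, value in sorted(params.constants.items()):
        pars.append(E("parameter", id=key, value=repr(float(value)),
                      constant="true"))
    for enz in INTERCONVERTIBLE:
        pars.append(E("parameter", id=GAMMA_PARAM[enz],
                      value=repr(float(milieu.gamma[enz])), constant="true"))
    model.append(pars)

    rxns = E("listOfReactions")
    cof_and_ext = set(FIXED_COFACTORS) | set(EXTERNAL_SPECIES)
    for rxn in REACTIONS:
        r = E("reaction", id=rxn,
              reversible="false" if rxn in IRREVERSIBLE else "true")
        stoich = _STOICH[rxn]
        reactants = E("listOfReactants")
        products = E("listOfProducts")
        for sp_name, coeff in stoich.items():
            ref = E("speciesReference", species=sp_name,
                    stoichiometry=repr(float(abs(coeff))), constant="true")
            (reactants if coeff < 0 else products).append(ref)
        if len(reactants):
            r.append(reactants)
        if len(products):
            r.append(products)
        expr = parse_rate_law(rxn)
        modifiers = sorted(
            str(s) for s in expr.atoms(sp.Symbol)
            if str(s) in SPECIES and str(s) not in stoich)
        mod_el = E("listOfModifiers")
        for m in modifiers:
            mod_el.append(E("modifierSpeciesReference", species=m))
        for m in sorted(str(s) for s in expr.atoms(sp.Symbol)
                        if str(s) in cof_and_ext):
            mod_el.append(E("modifierSpeciesReference", species=m))
        if len(mod_el):
            r.append(mod_el)
        kl = E("kineticLaw")
        math = etree.Element(f"{{{MATHML_NS}}}math")
        math.append(_expr_to_mathml(expr))
        kl.append(math)
        r.append(kl)
        rxns.append(r)
    model.append(rxns)

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


# ---- import --------------------------------------------------------------

class ImportedModel:
    """Parsed SBML model: enough structure to re-evaluate the RHS."""

    def __init__(self, species, boundary, parameters, compartments,
                 species_compartment, reactions):
        self.species = species                  # dynamic: id -> initial conc
        self.boundary = boundary                # boundary: id -> value
        self.parameters = parameters            # id -> value
        self.compartments = compartments        # id -> size
        self.species_compartment = species_compartment
        self.reactions = reactions              # id -> (stoich, sympy expr)

    def rates(self, state: dict | None = None) -> dict:
        values = dict(self.boundary)
        values.update(self.parameters)
        values.update(self.species)
        if state:
            values.update(state)
        subs = {_sym(k): float(v) for k, v in values.items()}
        return {rid: float(expr.evalf(subs=subs))
                for rid, (stoich, expr) in self.reactions.items()}

    def rhs(self, state: dict | None = None) -> dict:
        """Concentration derivatives with compartment-volume scaling
        (kinetic laws are on the cytosolic-volume basis)."""
        v = self.rates(state)
        v_cyt = self.compartments["cytosol"]
        out = {s: 0.0 for s in self.species}
        for rid, (stoich, _) in self.reactions.items():
            for sp_name, coeff in stoich.items():
                if sp_name in out:
                    scale = v_cyt / self.compartments[
                        self.species_compartment[sp_name]]
                    out[sp_name] += coeff * v[rid] * scale
        return out


def import_sbml(document: bytes) -> ImportedModel:
    root = etree.fromstring(document)
    ns = {"s": SBML_NS, "m": MATHML_NS}
    model = root.find("s:model", ns)
    compartments = {c.get("id"): float(c.get("size"))
                    for c in model.findall(".//s:compartment", ns)}
    species, boundary, species_comp = {}, {}, {}
    for s_el in model.findall(".//s:species", ns):
        sid = s_el.get("id")
        conc = float(s_el.get("initialConcentration"))
        species_comp[sid] = s_el.get("compartment")
        if s_el.get("boundaryCondition") == "true":
            boundary[sid] = conc
        else:
            species[sid] = conc
    parameters = {p.get("id"): float(p.get("value"))
                  for p in model.findall(".//s:parameter", ns)}
    reactions = {}
    for r_el in model.findall(".//s:reaction", ns):
        rid = r_el.get("id")
        stoich = {}
        for ref in r_el.findall("s:listOfReactants/s:speciesReference", ns):
            stoich[ref.get("species")] = -float(ref.get("stoichiometry"))
        for ref in r_el.findall("s:listOfProducts/s:speciesReference", ns):
            stoich[ref.get("species")] = float(ref.get("stoichiometry"))
        math = r_el.find("s:kineticLaw/m:math", ns)
        reactions[rid] = (stoich, _mathml_to_expr(math))
    return ImportedModel(species, boundary, parameters, compartments,
                         species_comp, reactions)


def validate_sbml(document: bytes) -> list:
    """Structural consistency checks; returns a list of problems (empty =
    valid)."""
    issues = []
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    ns = {"s": SBML_NS, "m": MATHML_NS}
    model = root.find("s:model", ns)
    if model is None:
        return ["missing <model>"]
    comp_ids = {c.get("id") for c in model.findall(".//s:compartment", ns)}
    sp_ids = set()
    for s_el in model.findall(".//s:species", ns):
        sid = s_el.get("id")
        if sid in sp_ids:
            issues.append(f"duplicate species id {sid}")
        sp_ids.add(sid)
        if s_el.get("compartment") not in comp_ids:
            issues.append(f"species {sid} references unknown compartment")
    par_ids = {p.get("id") for p in model.findall(".//s:parameter", ns)}
    known = sp_ids | par_ids
    for r_el in model.findall(".//s:reaction", ns):
        rid = r_el.get("id")
        math = r_el.find("s:kineticLaw/m:math", ns)
        if math is None:
            issues.append(f"reaction {rid} lacks a kinetic law")
            continue
        try:
            expr = _mathml_to_expr(math)
        except ValueError as exc:
            issues.append(f"reaction {rid}: {exc}")
            continue
        for sym in expr.atoms(sp.Symbol):
            if str(sym) not in known:
                issues.append(f"reaction {rid} references unknown id {sym}")
        for ref in r_el.findall(".//s:speciesReference", ns):
            if ref.get("species") not in sp_ids:
                issues.append(f"reaction {rid} references unknown species "
                              f"{ref.get('species')}")
    return issues
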