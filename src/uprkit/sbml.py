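"""SBML Level 2 Version 4 export/import of assembled models.

The writer emits the subset of SBML the model assembly produces —
compartments, species with initial concentrations, global parameters, and
irreversible reactions whose kinetic laws are closed-form expressions —
with rate laws serialised as content MathML.  The reader inverts exactly
that subset and refuses anything else (rules, events, function
definitions) with an explicit error naming the construct, rather than
silently mis-importing a model.

The MathML bridge covers the operator set our rate laws use: arithmetic,
powers and roots, and the clamped-discriminant guard of the extended
Michaelis–Menten law, which is emitted as a piecewise maximum (SBML has
no ``max`` operator).
"""

from __future__ import annotations

from typing import Mapping

import sympy as sp
from lxml import etree

from .network import AssemblyError, ModelSpec, ReactionDef, SpeciesDef

__all__ = ["export_sbml", "import_sbml", "SbmlError"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


class SbmlError(ValueError):
    """Unsupported or malformed SBML content."""


# ---------------------------------------------------------------------------
# sympy <-> content MathML
# ---------------------------------------------------------------------------


def _mathml_number(parent, value) -> None:
    if isinstance(value, sp.Rational) and not isinstance(value, sp.Integer):
        cn = etree.SubElement(parent, _q("cn", MATHML_NS), type="rational")
        cn.text = str(value.p)
        etree.SubElement(cn, _q("sep", MATHML_NS)).tail = str(value.q)
    elif isinstance(value, sp.Integer):
        cn = etree.SubElement(parent, _q("cn", MATHML_NS), type="integer")
        cn.text = str(int(value))
    else:
        cn = etree.SubElement(parent, _q("cn", MATHML_NS))
        cn.text = repr(float(value))


def _emit(parent, expr: sp.Expr) -> None:
    """Append the content-MathML rendering of ``expr`` to ``parent``."""
    if isinstance(expr, sp.Symbol):
        ci = etree.SubElement(parent, _q("ci", MATHML_NS))
        ci.text = str(expr)
    elif expr.is_Number:
        _mathml_number(parent, expr)
    elif isinstance(expr, sp.Add):
        ap = etree.SubElement(parent, _q("apply", MATHML_NS))
        etree.SubElement(ap, _q("plus", MATHML_NS))
        for a in expr.args:
            _emit(ap, a)
    elif isinstance(expr, sp.Mul):
        num, den = expr.as_numer_denom()
        if den != 1:
            ap = etree.SubElement(parent, _q("apply", MATHML_NS))
            etree.SubElement(ap, _q("divide", MATHML_NS))
            _emit(ap, num)
            _emit(ap, den)
        else:
            ap = etree.SubElement(parent, _q("apply", MATHML_NS))
            etree.SubElement(ap, _q("times", MATHML_NS))
            for a in expr.args:
                _emit(ap, a)
    elif isinstance(expr, sp.Pow):
        ap = etree.SubElement(parent, _q("apply", MATHML_NS))
        etree.SubElement(ap, _q("power", MATHML_NS))
        _emit(ap, expr.base)
        _emit(ap, expr.exp)
    elif isinstance(expr, sp.Max):
        # SBML has no max operator: piecewise(a if a >= b, else b), folded
        # pairwise for more than two arguments
        args = list(expr.args)
        a, rest = args[0], args[1:]
        b = rest[0] if len(rest) == 1 else sp.Max(*rest)
        pw = etree.SubElement(parent, _q("piecewise", MATHML_NS))
        piece = etree.SubElement(pw, _q("piece", MATHML_NS))
        _emit(piece, a)
        cond = etree.SubElement(piece, _q("apply", MATHML_NS))
        etree.SubElement(cond, _q("geq", MATHML_NS))
        _emit(cond, a)
        _emit(cond, b)
        other = etree.SubElement(pw, _q("otherwise", MATHML_NS))
        _emit(other, b)
    elif isinstance(expr, sp.Piecewise):
        pw = etree.SubElement(parent, _q("piecewise", MATHML_NS))
        for val, cond in expr.args:
            if cond is sp.true:
                other = etree.SubElement(pw, _q("otherwise", MATHML_NS))
                _emit(other, val)
            else:
                piece = etree.SubElement(pw, _q("piece", MATHML_NS))
                _emit(piece, val)
                _emit_condition(piece, cond)
    else:
        raise SbmlError(f"cannot serialise expression node {type(expr).__name__}: {expr}")


_REL_TAGS = {sp.StrictGreaterThan: "gt", sp.GreaterThan: "geq",
             sp.StrictLessThan: "lt", sp.LessThan: "leq", sp.Equality: "eq"}


def _emit_condition(parent, cond) -> None:
    for cls, tag in _REL_TAGS.items():
        if isinstance(cond, cls):
            ap = etree.SubElement(parent, _q("apply", MATHML_NS))
            etree.SubElement(ap, _q(tag, MATHML_NS))
            _emit(ap, cond.lhs)
            _emit(ap, cond.rhs)
            return
    raise SbmlError(f"cannot serialise condition {cond}")


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse(elem) -> sp.Expr:
    tag = _strip(elem.tag)
    if tag == "ci":
        return sp.Symbol(elem.text.strip())
    if tag == "cn":
        kind = elem.get("type", "real")
        if kind == "rational":
            sep = elem.find(_q("sep", MATHML_NS))
            return sp.Rational(int(elem.text.strip()), int(sep.tail.strip()))
        if kind == "integer":
            return sp.Integer(int(elem.text.strip()))
        return sp.Float(elem.text.strip())
    if tag == "piecewise":
        pieces = []
        for child in elem:
            ctag = _strip(child.tag)
            kids = list(child)
            if ctag == "piece":
                val, cond = _parse(kids[0]), _parse_condition(kids[1])
                pieces.append((val, cond))
            elif ctag == "otherwise":
                pieces.append((_parse(kids[0]), sp.true))
        # recognise the emitted max pattern: piece(a, a >= b) / otherwise(b)
        if (len(pieces) == 2 and pieces[1][1] is sp.true
                and isinstance(pieces[0][1], sp.GreaterThan)
                and pieces[0][1].lhs == pieces[0][0]
                and pieces[0][1].rhs == pieces[1][0]):
            return sp.Max(pieces[0][0], pieces[1][0])
        return sp.Piecewise(*pieces)
    if tag == "apply":
        kids = list(elem)
        op = _strip(kids[0].tag)
        args = [_parse(k) for k in kids[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "times":
            return sp.Mul(*args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "root":
            # optional <degree>; default square root
            return sp.sqrt(args[0]) if len(args) == 1 else args[1] ** (1 / args[0])
        raise SbmlError(f"unsupported MathML operator <{op}>")
    raise SbmlError(f"unsupported MathML element <{tag}>")


def _parse_condition(elem):
    kids = list(elem)
    op = _strip(kids[0].tag)
    lhs, rhs = _parse(kids[1]), _parse(kids[2])
    rel = {"gt": sp.StrictGreaterThan, "geq": sp.GreaterThan,
           "lt": sp.StrictLessThan, "leq": sp.LessThan, "eq": sp.Equality}
    if op not in rel:
        raise SbmlError(f"unsupported relational operator <{op}>")
    return rel[op](lhs, rhs)


# ---------------------------------------------------------------------------
# document level
# ---------------------------------------------------------------------------


def export_sbml(model: ModelSpec, path: str | None = None) -> bytes:
    """Serialise a model as an SBML Level 2 Version 4 document.

    Returns the document bytes; if ``path`` is given the document is also
    written there.  Species/reaction/parameter identity and simulated
    trajectories are preserved to round-trip precision.
    """
    nsmap = {None: SBML_NS}
    root = etree.Element(_q("sbml"), nsmap=nsmap, level="2", version="4")
    mdl = etree.SubElement(root, _q("model"), id=model.name.replace("-", "_"))

    comps = etree.SubElement(mdl, _q("listOfCompartments"))
    for cname in sorted({s.compartment for s in model.species}):
        etree.SubElement(comps, _q("compartment"), id=cname, size="1")

    sps = etree.SubElement(mdl, _q("listOfSpecies"))
    for s in model.species:
        attrs = {"id": s.id, "compartment": s.compartment,
                 "initialConcentration": repr(float(s.initial))}
        if s.role:
            attrs["name"] = s.role
        etree.SubElement(sps, _q("species"), **attrs)

    pars = etree.SubElement(mdl, _q("listOfParameters"))
    for name, value in model.parameters.items():
        etree.SubElement(pars, _q("parameter"), id=name, value=repr(float(value)),
                         constant="true")

    rxns = etree.SubElement(mdl, _q("listOfReactions"))
    for r in model.reactions:
        rx = etree.SubElement(rxns, _q("reaction"), id=r.id, reversible="false")
        if r.note:
            rx.set("name", r.note[:80])
        if r.reactants:
            lst = etree.SubElement(rx, _q("listOfReactants"))
            for spid, nu in r.reactants.items():
                etree.SubElement(lst, _q("speciesReference"), species=spid,
                                 stoichiometry=str(int(nu)))
        if r.products:
            lst = etree.SubElement(rx, _q("listOfProducts"))
            for spid, nu in r.products.items():
                etree.SubElement(lst, _q("speciesReference"), species=spid,
                                 stoichiometry=str(int(nu)))
        kl = etree.SubElement(rx, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS),
                                nsmap={None: MATHML_NS})
        _emit(math, sp.sympify(r.rate))

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data


_UNSUPPORTED = ("listOfRules", "listOfEvents", "listOfFunctionDefinitions",
                "listOfConstraints", "listOfInitialAssignments")


def import_sbml(source: str | bytes) -> ModelSpec:
    """Parse an SBML L2V4 document (path or bytes) into a :class:`ModelSpec`.

    Only the constructs the exporter emits are accepted; an unsupported
    element raises :class:`SbmlError` naming it.
    """
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()
    mdl = root.find(_q("model"))
    if mdl is None:
        raise SbmlError("document has no <model> element")
    for bad in _UNSUPPORTED:
        if mdl.find(_q(bad)) is not None:
            raise SbmlError(f"unsupported SBML construct <{bad}>")

    species = []
    for s in mdl.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        species.append(SpeciesDef(
            id=s.get("id"),
            compartment=s.get("compartment"),
            initial=float(s.get("initialConcentration", "0")),
            role=s.get("name", ""),
        ))

    parameters: dict[str, float] = {}
    for p in mdl.findall(f"{_q('listOfParameters')}/{_q('parameter')}"):
        parameters[p.get("id")] = float(p.get("value"))

    reactions = []
    for rx in mdl.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        def refs(tag):
            out = {}
            for ref in rx.findall(f"{_q(tag)}/{_q('speciesReference')}"):
                out[ref.get("species")] = int(float(ref.get("stoichiometry", "1")))
            return out
        math = rx.find(f"{_q('kineticLaw')}/{_q('math', MATHML_NS)}")
        if math is None or len(math) != 1:
            raise SbmlError(f"reaction {rx.get('id')!r} has no kinetic law")
        rate = _parse(math[0])
        reactions.append(ReactionDef(rx.get("id"), refs("listOfReactants"),
                                     refs("listOfProducts"), rate,
                                     note=rx.get("name", "")))

    name = mdl.get("id", "model")
    try:
        return ModelSpec(species, reactions, parameters, name=name)
    except AssemblyError as err:
        raise SbmlError(f"inconsistent SBML model: {err}") from err
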