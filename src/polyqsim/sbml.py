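"""SBML Level 2 export/import for reaction-network models.

The exchange format is SBML Level 2 Version 4: species with initial
amounts, global parameters, reactions with MathML kinetic laws (ROS enters
ROS-modulated laws as a modifier, keeping them pseudo-second-order), and
one-shot events with trigger/assignment pairs — including the event that
zeroes ``k_alive`` on death.

Export writes genuine MathML for every kinetic law and additionally tags
each element with a small annotation (law kind, rate parameter, trigger)
in a private namespace so that import can reconstruct the exact ModelDef
without a symbolic-math round trip.  Import accepts this package's exports
and plain mass-action SBML; constructs outside the supported subset
(rules, function definitions, event delays) are rejected with a
descriptive error rather than silently dropped.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from lxml import etree

from .core import (
    ALIVE_PARAM,
    PI_EXPONENT_PARAM,
    PI_THRESHOLD_PARAM,
    PROT_TOTAL_PARAM,
    ROS_ALPHA_PARAM,
    ROS_BASAL_PARAM,
    EventDef,
    ModelDef,
    ReactionDef,
    SpeciesDef,
    validate_model,
)

__all__ = ["export_sbml", "import_sbml", "UnsupportedSBMLError", "SBML_NS"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:polyqsim:annotations"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"

_S = "{%s}" % SBML_NS
_M = "{%s}" % MATHML_NS
_A = "{%s}" % ANNOT_NS


class UnsupportedSBMLError(ValueError):
    """Raised when a document uses constructs outside the supported subset."""


def _m(tag: str, *children, text: Optional[str] = None, **attrs):
    el = etree.Element(_M + tag, nsmap={None: MATHML_NS})
    if text is not None:
        el.text = text
    for k, v in attrs.items():
        el.set(k, v)
    for c in children:
        el.append(c)
    return el


def _ci(name: str):
    return _m("ci", text=f" {name} ")


def _cn(value: float):
    v = float(value)
    if v == int(v) and abs(v) < 1e15:
        return _m("cn", text=f" {int(v)} ", type="integer")
    return _m("cn", text=f" {v!r} ")


def _apply(op: str, *args):
    return _m("apply", _m(op), *args)


def _times(*factors):
    factors = [f for f in factors if f is not None]
    if len(factors) == 1:
        return factors[0]
    return _apply("times", *factors)


def _mass_action_math(reaction: ReactionDef):
    """k_alive * k * f(reactant counts) as MathML."""
    factors = [_ci(ALIVE_PARAM), _ci(reaction.rate_param)]
    for s, n in reaction.reactants:
        if n == 1:
            factors.append(_ci(s))
        else:  # homodimer: X*(X-1)/2 unordered pairs
            factors.append(
                _apply(
                    "divide",
                    _times(_ci(s), _apply("minus", _ci(s), _cn(1))),
                    _cn(2),
                )
            )
    return factors


def _kinetic_math(reaction: ReactionDef):
    kind = reaction.law_kind
    if kind == "mass_action":
        return _times(*_mass_action_math(reaction))
    if kind == "ros_modulated_mass_action":
        ros = reaction.modifiers[0]
        enhancement = _m(
            "piecewise",
            _m(
                "piece",
                _apply(
                    "plus",
                    _cn(1),
                    _times(
                        _ci(ROS_ALPHA_PARAM),
                        _apply(
                            "divide",
                            _apply("minus", _ci(ros), _ci(ROS_BASAL_PARAM)),
                            _ci(ROS_BASAL_PARAM),
                        ),
                    ),
                ),
                _apply("gt", _ci(ros), _ci(ROS_BASAL_PARAM)),
            ),
            _m("otherwise", _cn(1)),
        )
        return _times(*_mass_action_math(reaction), enhancement)
    if kind == "ros_excess_mass_action":
        ros = reaction.modifiers[0]
        excess = _m(
            "piecewise",
            _m(
                "piece",
                _apply("minus", _ci(ros), _ci(ROS_BASAL_PARAM)),
                _apply("gt", _ci(ros), _ci(ROS_BASAL_PARAM)),
            ),
            _m("otherwise", _cn(0)),
        )
        return _times(*_mass_action_math(reaction), excess)
    if kind == "p38_death_hazard":
        return _times(_ci(ALIVE_PARAM), _ci(reaction.rate_param), _ci(reaction.modifiers[0]))
    if kind == "proteasome_death_hazard":
        frac = _apply(
            "divide",
            _apply("divide", _ci(reaction.modifiers[0]), _ci(PROT_TOTAL_PARAM)),
            _ci(PI_THRESHOLD_PARAM),
        )
        return _times(
            _ci(ALIVE_PARAM),
            _ci(reaction.rate_param),
            _apply("power", frac, _ci(PI_EXPONENT_PARAM)),
        )
    raise UnsupportedSBMLError(f"no kinetic-law encoding for {kind!r}")


def export_sbml(model: ModelDef) -> bytes:
    """Serialise a validated ModelDef as an SBML Level 2 document."""
    errors = validate_model(model)
    if errors:
        raise ValueError("refusing to export invalid model: " + "; ".join(errors))

    root = etree.Element(
        _S + "sbml", nsmap={None: SBML_NS, "pq": ANNOT_NS}, level="2", version="4"
    )
    mdl = etree.SubElement(root, _S + "model", id=model.name)

    comp_list = etree.SubElement(mdl, _S + "listOfCompartments")
    etree.SubElement(comp_list, _S + "compartment", id="cell", size="1")

    sp_list = etree.SubElement(mdl, _S + "listOfSpecies")
    for sp in model.species:
        el = etree.SubElement(
            sp_list,
            _S + "species",
            id=sp.name,
            compartment="cell",
            initialAmount=str(sp.initial_count),
            hasOnlySubstanceUnits="true",
        )
        annot = etree.SubElement(el, _S + "annotation")
        etree.SubElement(annot, _A + "speciesInfo", role=sp.role)

    par_list = etree.SubElement(mdl, _S + "listOfParameters")
    for name, value in model.parameters.items():
        etree.SubElement(
            par_list, _S + "parameter", id=name, value=repr(float(value)), constant="false"
        )

    rx_list = etree.SubElement(mdl, _S + "listOfReactions")
    for r in model.reactions:
        el = etree.SubElement(rx_list, _S + "reaction", id=r.id, reversible="false")
        annot = etree.SubElement(el, _S + "annotation")
        etree.SubElement(annot, _A + "law", kind=r.law_kind, rateParam=r.rate_param)
        if r.reactants:
            lo = etree.SubElement(el, _S + "listOfReactants")
            for s, n in r.reactants:
                etree.SubElement(lo, _S + "speciesReference", species=s, stoichiometry=str(n))
        if r.products:
            lo = etree.SubElement(el, _S + "listOfProducts")
            for s, n in r.products:
                etree.SubElement(lo, _S + "speciesReference", species=s, stoichiometry=str(n))
        if r.modifiers:
            lo = etree.SubElement(el, _S + "listOfModifiers")
            for s in r.modifiers:
                etree.SubElement(lo, _S + "modifierSpeciesReference", species=s)
        kl = etree.SubElement(el, _S + "kineticLaw")
        math = etree.SubElement(kl, _M + "math", nsmap={None: MATHML_NS})
        math.append(_kinetic_math(r))

    if model.events:
        ev_list = etree.SubElement(mdl, _S + "listOfEvents")
        for ev in model.events:
            el = etree.SubElement(ev_list, _S + "event", id=ev.id)
            annot = etree.SubElement(el, _S + "annotation")
            if ev.trigger[0] == "time":
                etree.SubElement(
                    annot, _A + "trigger", kind="time", time=repr(float(ev.trigger[1]))
                )
            else:
                etree.SubElement(
                    annot,
                    _A + "trigger",
                    kind="species_ge",
                    species=ev.trigger[1],
                    value=repr(float(ev.trigger[2])),
                )
            trig = etree.SubElement(el, _S + "trigger")
            math = etree.SubElement(trig, _M + "math", nsmap={None: MATHML_NS})
            if ev.trigger[0] == "time":
                t_sym = _m("csymbol", text=" t ", encoding="text")
                t_sym.set("definitionURL", TIME_CSYMBOL)
                math.append(_apply("geq", t_sym, _cn(ev.trigger[1])))
            else:
                math.append(_apply("geq", _ci(ev.trigger[1]), _cn(ev.trigger[2])))
            lo = etree.SubElement(el, _S + "listOfEventAssignments")
            for target, value in ev.assignments:
                ea = etree.SubElement(lo, _S + "eventAssignment", variable=target)
                math = etree.SubElement(ea, _M + "math", nsmap={None: MATHML_NS})
                math.append(_cn(value))

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _parse_math_ci_product(math_el) -> List[str]:
    """Flatten a pure product-of-identifiers MathML expression."""
    names: List[str] = []

    def walk(el):
        tag = etree.QName(el).localname
        if tag == "ci":
            names.append(el.text.strip())
        elif tag == "math":
            for c in el:
                walk(c)
        elif tag == "apply":
            children = list(el)
            op = etree.QName(children[0]).localname
            if op != "times":
                raise UnsupportedSBMLError(
                    f"unsupported kinetic law operator <{op}> (only plain "
                    "mass-action products are recognised without annotations)"
                )
            for c in children[1:]:
                walk(c)
        else:
            raise UnsupportedSBMLError(f"unsupported kinetic-law element <{tag}>")

    walk(math_el)
    return names


def import_sbml(document: bytes | str) -> ModelDef:
    """Parse an SBML Level 2 document into a validated ModelDef.

    Supports the subset written by :func:`export_sbml` plus foreign
    documents whose kinetic laws are plain mass-action products.  Rules,
    function definitions, and event delays are explicitly rejected.
    """
    if isinstance(document, str):
        document = document.encode()
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"not well-formed XML: {exc}") from exc
    if etree.QName(root).localname != "sbml":
        raise ValueError("not an SBML document (missing <sbml> root)")
    mdl = root.find(_S + "model")
    if mdl is None:
        raise ValueError("SBML document has no <model> element")

    for bad, label in (
        ("listOfRules", "rules"),
        ("listOfFunctionDefinitions", "function definitions"),
        ("listOfConstraints", "constraints"),
        ("listOfInitialAssignments", "initial assignments"),
    ):
        found = mdl.find(_S + bad)
        if found is not None and len(found):
            raise UnsupportedSBMLError(f"SBML {label} are not supported")

    species: List[SpeciesDef] = []
    for el in mdl.findall(f"{_S}listOfSpecies/{_S}species"):
        role_el = el.find(f"{_S}annotation/{_A}speciesInfo")
        role = role_el.get("role") if role_el is not None else "protein"
        amount = float(el.get("initialAmount", "0"))
        if amount != int(amount):
            raise ValueError(f"species {el.get('id')}: non-integer initial amount")
        species.append(SpeciesDef(el.get("id"), int(amount), role))

    parameters: Dict[str, float] = {}
    for el in mdl.findall(f"{_S}listOfParameters/{_S}parameter"):
        parameters[el.get("id")] = float(el.get("value", "0"))

    reactions: List[ReactionDef] = []
    for el in mdl.findall(f"{_S}listOfReactions/{_S}reaction"):
        rid = el.get("id")
        reactants = tuple(
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall(f"{_S}listOfReactants/{_S}speciesReference")
        )
        products = tuple(
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.findall(f"{_S}listOfProducts/{_S}speciesReference")
        )
        modifiers = tuple(
            sr.get("species")
            for sr in el.findall(f"{_S}listOfModifiers/{_S}modifierSpeciesReference")
        )
        law = el.find(f"{_S}annotation/{_A}law")
        if law is not None:
            kind, rate_param = law.get("kind"), law.get("rateParam")
        else:
            kl = el.find(f"{_S}kineticLaw")
            if kl is None:
                raise UnsupportedSBMLError(f"reaction {rid}: missing kinetic law")
            math = kl.find(_M + "math")
            names = _parse_math_ci_product(math)
            sp_names = {s.name for s in species}
            candidates = [n for n in names if n not in sp_names and n != ALIVE_PARAM]
            if len(candidates) != 1:
                raise UnsupportedSBMLError(
                    f"reaction {rid}: cannot identify a unique rate parameter"
                )
            kind, rate_param = "mass_action", candidates[0]
            # local kinetic-law parameters become global
            for pel in kl.findall(f"{_S}listOfParameters/{_S}parameter"):
                parameters.setdefault(pel.get("id"), float(pel.get("value", "0")))
        if rate_param not in parameters:
            raise ValueError(
                f"reaction {rid}: kinetic law references undefined parameter {rate_param!r}"
            )
        reactions.append(
            ReactionDef(rid, reactants, products, rate_param, kind, modifiers)
        )

    events: List[EventDef] = []
    for el in mdl.findall(f"{_S}listOfEvents/{_S}event"):
        eid = el.get("id")
        if el.find(_S + "delay") is not None:
            raise UnsupportedSBMLError(f"event {eid}: delays are not supported")
        trig_annot = el.find(f"{_S}annotation/{_A}trigger")
        if trig_annot is not None:
            if trig_annot.get("kind") == "time":
                trigger: Tuple = ("time", float(trig_annot.get("time")))
            else:
                trigger = (
                    "species_ge",
                    trig_annot.get("species"),
                    float(trig_annot.get("value")),
                )
        else:
            trigger = _parse_trigger_math(el.find(f"{_S}trigger/{_M}math"), eid)
        assignments = []
        for ea in el.findall(f"{_S}listOfEventAssignments/{_S}eventAssignment"):
            math = ea.find(_M + "math")
            cn = math.find(_M + "cn") if math is not None else None
            if cn is None:
                raise UnsupportedSBMLError(
                    f"event {eid}: only constant event assignments are supported"
                )
            assignments.append((ea.get("variable"), float(cn.text)))
        events.append(EventDef(eid, trigger, tuple(assignments)))

    model = ModelDef(
        species=species,
        reactions=reactions,
        parameters=parameters,
        events=events,
        name=mdl.get("id", "model"),
    )
    errors = validate_model(model)
    if errors:
        raise ValueError("imported model is invalid: " + "; ".join(errors))
    return model


def _parse_trigger_math(math, eid: str) -> Tuple:
    if math is None:
        raise UnsupportedSBMLError(f"event {eid}: missing trigger")
    apply_el = math.find(_M + "apply")
    children = list(apply_el) if apply_el is not None else []
    if not children or etree.QName(children[0]).localname != "geq":
        raise UnsupportedSBMLError(f"event {eid}: only geq triggers are supported")
    lhs, rhs = children[1], children[2]
    value = float(rhs.text)
    if etree.QName(lhs).localname == "csymbol":
        return ("time", value)
    return ("species_ge", lhs.text.strip(), value)
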