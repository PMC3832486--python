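"""SBML Level 2 subset import/export.

The supported subset covers discrete stochastic reaction networks: species
with integer-interpretable initial amounts, global parameters, and
reactions whose kinetic laws are closed-form arithmetic expressions
(including mass-action products).  Kinetic laws are interpreted directly as
propensity functions over copy numbers; substance units are copy numbers.

Deliberately unsupported constructs raise :class:`UnsupportedConstructError`
naming the construct: events, assignment/algebraic/rate rules, function
definitions, and compartments with size ≠ 1 (no unit conversion semantics
are defined for volumes unless ``allow_volume=True`` requests copy-number
reinterpretation, which ignores the volume).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

from .expressions import RateExpression
from .model import Model, ModelError, Reaction, Species

__all__ = ["SbmlError", "UnsupportedConstructError", "import_sbml_subset", "export_sbml_subset"]

_MATHML = "{http://www.w3.org/1998/Math/MathML}"


class SbmlError(ValueError):
    pass


class UnsupportedConstructError(SbmlError):
    def __init__(self, construct: str):
        self.construct = construct
        super().__init__(f"unsupported SBML construct: {construct}")


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find(parent, name):
    for child in parent:
        if _strip(child.tag) == name:
            return child
    return None


def _findall(parent, name):
    return [c for c in parent if _strip(c.tag) == name]


# -- MathML → expression text ------------------------------------------------

_MATHML_OPS = {
    "plus": "+",
    "minus": "-",
    "times": "*",
    "divide": "/",
    "power": "^",
}


def _mathml_to_text(node) -> str:
    tag = _strip(node.tag)
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise SbmlError("math element must contain one expression")
        return _mathml_to_text(children[0])
    if tag == "ci":
        return node.text.strip()
    if tag == "cn":
        cn_type = node.get("type", "real")
        if cn_type in ("e-notation",):
            parts = [t.strip() for t in node.itertext() if t.strip()]
            return f"({parts[0]}e{parts[1]})"
        return node.text.strip()
    if tag == "apply":
        children = list(node)
        op = _strip(children[0].tag)
        args = [_mathml_to_text(c) for c in children[1:]]
        if op in _MATHML_OPS:
            if op == "minus" and len(args) == 1:
                return f"(-{args[0]})"
            return "(" + f" {_MATHML_OPS[op]} ".join(args) + ")"
        if op in ("exp", "ln"):
            fname = "log" if op == "ln" else op
            return f"{fname}({args[0]})"
        raise UnsupportedConstructError(f"MathML operator {op!r}")
    raise UnsupportedConstructError(f"MathML element {tag!r}")


def import_sbml_subset(document: str, allow_volume: bool = False,
                       round_amounts: bool = False) -> Model:
    """Parse an SBML Level 2 document (text) into a :class:`Model`.

    ``round_amounts`` rounds non-integer initial amounts to the nearest
    integer instead of raising; ``allow_volume`` accepts compartments with
    size ≠ 1, reinterpreting amounts as copy numbers.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SbmlError(f"not well-formed XML: {exc}") from exc
    if _strip(root.tag) != "sbml":
        raise SbmlError("root element is not <sbml>")
    if root.get("level") not in (None, "2"):
        raise UnsupportedConstructError(f"SBML level {root.get('level')}")
    sbml_model = _find(root, "model")
    if sbml_model is None:
        raise SbmlError("document has no <model>")

    for list_name, construct in [
        ("listOfEvents", "event"),
        ("listOfRules", "rule"),
        ("listOfFunctionDefinitions", "functionDefinition"),
        ("listOfConstraints", "constraint"),
        ("listOfInitialAssignments", "initialAssignment"),
    ]:
        lst = _find(sbml_model, list_name)
        if lst is not None and len(list(lst)):
            raise UnsupportedConstructError(construct)

    compartments = _find(sbml_model, "listOfCompartments")
    if compartments is not None:
        for comp in _findall(compartments, "compartment"):
            size = float(comp.get("size", comp.get("volume", "1")))
            if size != 1.0 and not allow_volume:
                raise UnsupportedConstructError(
                    f"compartment {comp.get('id')!r} with volume {size} != 1"
                )

    species: list[Species] = []
    lst = _find(sbml_model, "listOfSpecies")
    boundary: set[str] = set()
    if lst is not None:
        for sp in _findall(lst, "species"):
            sid = sp.get("id") or sp.get("name")
            amount_s = sp.get("initialAmount")
            if amount_s is None:
                if sp.get("initialConcentration") is not None:
                    raise UnsupportedConstructError(
                        f"species {sid!r} defined by initialConcentration"
                    )
                amount = 0.0
            else:
                amount = float(amount_s)
            if amount != int(amount):
                if round_amounts:
                    amount = round(amount)
                else:
                    raise ModelError(
                        f"species {sid!r} has non-integer initial amount {amount}; "
                        "pass round_amounts=True to round"
                    )
            fixed = sp.get("boundaryCondition") == "true" or sp.get("constant") == "true"
            if fixed:
                boundary.add(sid)
            species.append(Species(sid, int(amount), fixed=fixed))

    parameters: dict[str, float] = {}
    lst = _find(sbml_model, "listOfParameters")
    if lst is not None:
        for par in _findall(lst, "parameter"):
            parameters[par.get("id")] = float(par.get("value", "0"))

    reactions: list[Reaction] = []
    lst = _find(sbml_model, "listOfReactions")
    if lst is not None:
        for rxn in _findall(lst, "reaction"):
            rid = rxn.get("id")
            if rxn.get("reversible") == "true":
                raise UnsupportedConstructError(f"reversible reaction {rid!r}")

            def _side(container_name):
                out: dict[str, int] = {}
                container = _find(rxn, container_name)
                if container is None:
                    return out
                for ref in _findall(container, "speciesReference"):
                    st = float(ref.get("stoichiometry", "1"))
                    if st != int(st) or st <= 0:
                        raise SbmlError(
                            f"reaction {rid!r}: non-integer stoichiometry {st}"
                        )
                    name = ref.get("species")
                    out[name] = out.get(name, 0) + int(st)
                return out

            kl = _find(rxn, "kineticLaw")
            if kl is None:
                raise SbmlError(f"reaction {rid!r} has no kineticLaw")
            for local in _findall(kl, "listOfParameters") + _findall(kl, "listOfLocalParameters"):
                for par in list(local):
                    pid = par.get("id")
                    if pid in parameters:
                        raise SbmlError(f"local parameter {pid!r} shadows a global")
                    parameters[pid] = float(par.get("value", "0"))
            math_el = _find(kl, "math")
            if math_el is None:
                raise SbmlError(f"reaction {rid!r}: kineticLaw has no math")
            text = _mathml_to_text(math_el)
            reactions.append(
                Reaction(rid, _side("listOfReactants"), _side("listOfProducts"),
                         RateExpression(text))
            )

    name = sbml_model.get("id") or sbml_model.get("name") or "sbml_model"
    return Model(species, reactions, parameters, name=name)


# -- export ------------------------------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level2/version4"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _expr_to_mathml(text: str) -> ET.Element:
    """Convert a rate expression to MathML via its (validated) Python AST."""
    import ast

    def build(node):
        if isinstance(node, ast.Expression):
            return build(node.body)
        if isinstance(node, ast.Constant):
            el = ET.Element(f"{{{_MATHML_NS}}}cn")
            el.text = repr(node.value)
            return el
        if isinstance(node, ast.Name):
            el = ET.Element(f"{{{_MATHML_NS}}}ci")
            el.text = node.id
            return el
        if isinstance(node, ast.UnaryOp):
            apply_el = ET.Element(f"{{{_MATHML_NS}}}apply")
            apply_el.append(ET.Element(f"{{{_MATHML_NS}}}minus"))
            apply_el.append(build(node.operand))
            return apply_el
        if isinstance(node, ast.BinOp):
            ops = {ast.Add: "plus", ast.Sub: "minus", ast.Mult: "times",
                   ast.Div: "divide", ast.Pow: "power"}
            apply_el = ET.Element(f"{{{_MATHML_NS}}}apply")
            apply_el.append(ET.Element(f"{{{_MATHML_NS}}}{ops[type(node.op)]}"))
            apply_el.append(build(node.left))
            apply_el.append(build(node.right))
            return apply_el
        if isinstance(node, ast.Call):
            fname = {"exp": "exp", "log": "ln"}.get(node.func.id)
            if fname is None:
                raise SbmlError(f"cannot export call to {node.func.id!r} as MathML")
            apply_el = ET.Element(f"{{{_MATHML_NS}}}apply")
            apply_el.append(ET.Element(f"{{{_MATHML_NS}}}{fname}"))
            for arg in node.args:
                apply_el.append(build(arg))
            return apply_el
        raise SbmlError(f"cannot export AST node {type(node).__name__}")

    math_el = ET.Element(f"{{{_MATHML_NS}}}math")
    math_el.append(build(ast.parse(text.replace("^", "**"), mode="eval")))
    return math_el


def export_sbml_subset(model: Model) -> str:
    """Serialize a model to the same SBML Level 2 subset.

    Mass-action rate laws are written as explicit propensity expressions
    (including the n(n−1)/2 dimerization factor), so a round trip through
    :func:`import_sbml_subset` preserves the propensity function.
    """
    from .model import MassAction

    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "2", "version": "4"})
    m = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": model.name})
    lc = ET.SubElement(m, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{_SBML_NS}}}compartment", {"id": "cell", "size": "1"})
    ls = ET.SubElement(m, f"{{{_SBML_NS}}}listOfSpecies")
    for sp in model.species:
        attrs = {
            "id": sp.name,
            "compartment": "cell",
            "initialAmount": str(sp.initial_copies),
            "hasOnlySubstanceUnits": "true",
        }
        if sp.fixed:
            attrs["boundaryCondition"] = "true"
        ET.SubElement(ls, f"{{{_SBML_NS}}}species", attrs)
    if model.parameters:
        lp = ET.SubElement(m, f"{{{_SBML_NS}}}listOfParameters")
        for pname, val in model.parameters.items():
            ET.SubElement(lp, f"{{{_SBML_NS}}}parameter",
                          {"id": pname, "value": repr(float(val))})
    lr = ET.SubElement(m, f"{{{_SBML_NS}}}listOfReactions")
    for r in model.reactions:
        rx = ET.SubElement(lr, f"{{{_SBML_NS}}}reaction",
                           {"id": r.name, "reversible": "false"})
        for container, side in (("listOfReactants", r.reactants),
                                ("listOfProducts", r.products)):
            if side:
                el = ET.SubElement(rx, f"{{{_SBML_NS}}}{container}")
                for sp, mult in side.items():
                    ET.SubElement(el, f"{{{_SBML_NS}}}speciesReference",
                                  {"species": sp, "stoichiometry": str(mult)})
        kl = ET.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        if isinstance(r.rate_law, MassAction):
            terms = [repr(r.rate_law.constant)]
            for sp, mult in sorted(r.reactants.items()):
                if mult == 1:
                    terms.append(sp)
                elif mult == 2:
                    terms.append(f"{sp}*({sp}-1)/2")
                else:
                    for k in range(mult):
                        terms.append(f"({sp}-{k})" if k else sp)
                    terms.append(f"(1/{__import__('math').factorial(mult)})")
            text = "*".join(terms)
        else:
            text = r.rate_law.text
        kl.append(_expr_to_mathml(text))
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
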