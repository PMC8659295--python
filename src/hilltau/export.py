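"""Export HillTau models as ODE rate rules, SBML L3 documents and DOT graphs.

The event-driven relaxation update has a small-timestep ODE limit

    dY/dt = (Yinf + baseline - Y) / tau

with Yinf the reaction's Hill-form steady state.  ODE solvers cannot
switch time constants between rising and falling phases, so the export
uses tau throughout and attaches a warning to every reaction where
tau2 != tau (the exported model is then only approximate).  Equation
nodes become assignment rules.  SBML is emitted as Level 3 Version 2
with rate rules rather than kinetic-law reactions, since HillTau outputs
are not conserved-mass reactions.
"""

from __future__ import annotations

import ast
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import sympy as sp
from sympy.printing.mathml import mathml

from .model import ModelSpec, ReactionSpec

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


@dataclass(frozen=True)
class RateRule:
    """One exported rule: dY/dt = expr (rate) or Y = expr (assignment)."""

    variable: str
    expr: sp.Expr
    is_assignment: bool = False
    warning: str | None = None


def _order(x: float) -> sp.Expr:
    """Exponents: integers where integral, for cleaner (and comparable) math."""
    return sp.Integer(int(x)) if float(x).is_integer() else sp.Float(x)


def steady_state_expr(r: ReactionSpec, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    """Symbolic Yinf for a reaction (mirrors engine.steady_state_output)."""
    y_in = symbols[r.input]
    if r.ligand is None:
        return sp.Float(r.gain) * y_in**_order(r.n) / sp.Float(r.KA)
    L = symbols[r.ligand]
    ka_n = sp.Float(r.KA) ** _order(r.n)
    if r.modifier is not None:
        x = (symbols[r.modifier] / sp.Float(r.Kmod)) ** _order(r.Nmod)
        ka_n = ka_n * (1 + x) / (1 + sp.Float(r.Amod) * x)
    theta = L**_order(r.n) / (ka_n + L**_order(r.n))
    if r.inhibit:
        theta = 1 - theta
    return sp.Float(r.gain) * y_in * theta


def _expr_to_sympy(tree: ast.AST, symbols: dict[str, sp.Symbol]) -> sp.Expr:
    if isinstance(tree, ast.Expression):
        return _expr_to_sympy(tree.body, symbols)
    if isinstance(tree, ast.Constant):
        return sp.Float(tree.value)
    if isinstance(tree, ast.Name):
        return symbols[tree.id]
    if isinstance(tree, ast.BinOp):
        a = _expr_to_sympy(tree.left, symbols)
        b = _expr_to_sympy(tree.right, symbols)
        ops = {ast.Add: lambda: a + b, ast.Sub: lambda: a - b,
               ast.Mult: lambda: a * b, ast.Div: lambda: a / b,
               ast.Pow: lambda: a**b}
        return ops[type(tree.op)]()
    if isinstance(tree, ast.UnaryOp):
        v = _expr_to_sympy(tree.operand, symbols)
        return -v if isinstance(tree.op, ast.USub) else v
    if isinstance(tree, ast.Call):
        fns = {"exp": sp.exp, "log": sp.log, "pow": sp.Pow,
               "min": sp.Min, "max": sp.Max}
        args = [_expr_to_sympy(a, symbols) for a in tree.args]
        return fns[tree.func.id](*args)  # type: ignore[union-attr]
    raise ValueError(f"unsupported expression construct {type(tree).__name__}")


def to_ode_rates(m: ModelSpec) -> list[RateRule]:
    """Convert a model to symbolic rate/assignment rules (tau only)."""
    m.validate()
    symbols = {name: sp.Symbol(name) for name in m.molecule_names()}
    rules: list[RateRule] = []
    for name, r in m.reactions.items():
        y_inf = steady_state_expr(r, symbols)
        rate = (y_inf + sp.Float(r.baseline) - symbols[name]) / sp.Float(r.tau)
        warning = None
        if r.tau_fall != r.tau:
            warning = (f"reaction {name!r} uses tau2={r.tau_fall} != tau="
                       f"{r.tau}; exported ODE uses tau only and is "
                       "approximate for falling phases")
        rules.append(RateRule(variable=name, expr=rate, warning=warning))
    for name, eq in m.equations.items():
        expr = _expr_to_sympy(eq.expr.tree, symbols)
        rules.append(RateRule(variable=name, expr=expr, is_assignment=True))
    return rules


# ---------------------------------------------------------------------------
# SBML

def _mathml_element(expr: sp.Expr) -> ET.Element:
    content = mathml(expr)
    root = ET.fromstring(f'<math xmlns="{MATHML_NS}">{content}</math>')
    return root


def to_sbml(m: ModelSpec, model_id: str = "hilltau_model") -> str:
    """Emit an SBML Level 3 Version 2 document with rate rules.

    Boundary (plain) species are marked constant; computed outputs carry a
    rate rule (reactions) or an assignment rule (equations).  Reactions
    with tau2 != tau trigger a notes annotation flagging the approximation.
    """
    from .engine import initialize  # local import to avoid cycle

    rules = to_ode_rates(m)
    state = initialize(m)

    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml",
                      attrib={"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", attrib={"id": model_id})

    warnings = [r.warning for r in rules if r.warning]
    if warnings:
        notes = ET.SubElement(model, f"{{{SBML_NS}}}notes")
        body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
        for w in warnings:
            p = ET.SubElement(body, "{http://www.w3.org/1999/xhtml}p")
            p.text = w

    units = ET.SubElement(model, f"{{{SBML_NS}}}listOfUnitDefinitions")
    udef = ET.SubElement(units, f"{{{SBML_NS}}}unitDefinition",
                         attrib={"id": "conc"})
    ulist = ET.SubElement(udef, f"{{{SBML_NS}}}listOfUnits")
    scale = {"M": 0, "mM": -3, "uM": -6, "nM": -9}[m.units]
    ET.SubElement(ulist, f"{{{SBML_NS}}}unit",
                  attrib={"kind": "mole", "exponent": "1",
                          "scale": str(scale), "multiplier": "1"})
    ET.SubElement(ulist, f"{{{SBML_NS}}}unit",
                  attrib={"kind": "litre", "exponent": "-1",
                          "scale": "0", "multiplier": "1"})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  attrib={"id": "cell", "size": "1", "constant": "true",
                          "spatialDimensions": "3"})

    species_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for name in m.molecule_names():
        is_input = name in m.species
        ET.SubElement(species_el, f"{{{SBML_NS}}}species", attrib={
            "id": name, "compartment": "cell",
            "initialConcentration": repr(float(state.conc[name])),
            "substanceUnits": "conc",
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if is_input else "false",
            "constant": "true" if is_input else "false",
        })

    rules_el = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")
    for rule in rules:
        tag = "assignmentRule" if rule.is_assignment else "rateRule"
        rel = ET.SubElement(rules_el, f"{{{SBML_NS}}}{tag}",
                            attrib={"variable": rule.variable})
        rel.append(_mathml_element(rule.expr))

    ET.indent(sbml)
    return ('<?xml version="1.0" encoding="UTF-8"?>\n'
            + ET.tostring(sbml, encoding="unicode"))


# ---------------------------------------------------------------------------
# DOT

_EDGE_STYLES = {
    "input": 'arrowhead=vee, style=solid, color=black',
    "activator": 'arrowhead=normal, style=solid, color="#2166ac"',
    "inhibitor": 'arrowhead=tee, style=solid, color="#b2182b"',
    "modifier": 'arrowhead=odot, style=dashed, color="#7b3294"',
    "equation_arg": 'arrowhead=none, style=dotted, color=gray40',
}


def to_dot(m: ModelSpec, name: str = "hilltau") -> str:
    """Emit a Graphviz DOT diagram of the model topology.

    One node per molecule; edge roles (reagent, activator, inhibitor,
    modifier, equation argument) are distinguished by style and carry an
    explicit ``role`` attribute so the topology is machine-recoverable
    from the emitted text.
    """
    m.validate()
    lines = [f"digraph {name} {{"]
    for sp_name in m.species:
        lines.append(f'  "{sp_name}" [shape=box, role=species];')
    for rname in m.reactions:
        lines.append(f'  "{rname}" [shape=ellipse, role=reaction];')
    for ename in m.equations:
        lines.append(
            f'  "{ename}" [shape=doublecircle, label="Σ {ename}", '
            "role=equation];")
    for rname, r in m.reactions.items():
        lines.append(f'  "{r.input}" -> "{rname}" '
                     f'[{_EDGE_STYLES["input"]}, role=input];')
        if r.ligand is not None:
            role = "inhibitor" if r.inhibit else "activator"
            lines.append(f'  "{r.ligand}" -> "{rname}" '
                         f'[{_EDGE_STYLES[role]}, role={role}];')
        if r.modifier is not None:
            lines.append(f'  "{r.modifier}" -> "{rname}" '
                         f'[{_EDGE_STYLES["modifier"]}, role=modifier];')
    for ename, eq in m.equations.items():
        for dep in eq.dependencies():
            lines.append(f'  "{dep}" -> "{ename}" '
                         f'[{_EDGE_STYLES["equation_arg"]}, role=equation_arg];')
    lines.append("}")
    return "\n".join(lines) + "\n"
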