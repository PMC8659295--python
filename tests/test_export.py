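"""SBML/ODE/DOT export: algebraic fidelity, cross-simulation, round-trips."""

import re
import xml.etree.ElementTree as ET

import numpy as np
import pytest
import sympy as sp

import hilltau as ht
from hilltau.export import SBML_NS, steady_state_expr, to_dot, to_ode_rates, to_sbml
from conftest import build_model


class TestRateRules:
    def test_activation_rule_matches_hand_built_form(self):
        doc = {"species": {"inp": 1.0, "L": 0.5},
               "reactions": {"out": {"input": "inp", "ligand": "L", "KA": 0.4,
                                     "n": 2.0, "tau": 3.0, "gain": 1.5,
                                     "baseline": 0.1}}}
        rules = to_ode_rates(build_model(doc))
        assert len(rules) == 1
        inp, L, out = sp.symbols("inp L out")
        expected = (sp.Float(1.5) * inp * L**2 / (sp.Float(0.4)**2 + L**2)
                    + sp.Float(0.1) - out) / sp.Float(3.0)
        assert sp.simplify(rules[0].expr - expected) == 0

    def test_rule_zero_at_asymptote(self):
        doc = {"species": {"inp": 2.0, "L": 1.0},
               "reactions": {"out": {"input": "inp", "ligand": "L", "KA": 1.0,
                                     "tau": 2.0, "baseline": 0.5}}}
        m = build_model(doc)
        rules = to_ode_rates(m)
        env = {sp.Symbol("inp"): 2.0, sp.Symbol("L"): 1.0,
               sp.Symbol("out"): 2.0 * 0.5 + 0.5}  # Yinf + baseline
        assert float(rules[0].expr.subs(env)) == pytest.approx(0.0, abs=1e-12)

    def test_random_models_match_engine_steady_state(self):
        """Symbolic Yinf equals the engine's numeric Yinf on random draws."""
        from hilltau.engine import steady_state_output
        from hilltau.model import ReactionSpec
        rng = np.random.default_rng(11)
        for _ in range(50):
            r = ReactionSpec(
                output="y", input="a", ligand="b",
                modifier="c" if rng.random() < 0.5 else None,
                KA=float(rng.uniform(0.1, 3)), n=float(rng.uniform(0.3, 4)),
                tau=1.0, gain=float(rng.uniform(0.2, 4)),
                Kmod=float(rng.uniform(0.1, 2)),
                Amod=float(rng.uniform(0.1, 8)),
                Nmod=float(rng.uniform(0.3, 3)),
                inhibit=bool(rng.integers(0, 2)))
            if r.modifier is None:
                r.Kmod = None
            syms = {n: sp.Symbol(n) for n in ("a", "b", "c")}
            env = {n: float(rng.uniform(0.01, 3)) for n in ("a", "b", "c")}
            symbolic = float(steady_state_expr(r, syms).subs(
                {syms[k]: v for k, v in env.items()}))
            numeric = steady_state_output(r, env)
            assert symbolic == pytest.approx(numeric, rel=1e-9)

    def test_tau2_warning_attached(self):
        m = ht.example_model("baseline_tau2")
        rules = to_ode_rates(m)
        assert rules[0].warning is not None and "tau2" in rules[0].warning

    def test_equation_becomes_assignment_rule(self):
        doc = {"species": {"a": 1.0, "b": 2.0},
               "equations": {"tot": "0.5*a + 2*b"}}
        rules = to_ode_rates(build_model(doc))
        assert rules[0].is_assignment
        a, b = sp.symbols("a b")
        assert sp.simplify(rules[0].expr - (0.5 * a + 2 * b)) == 0

    def test_cross_simulation_oscillator(self, oscillator_model):
        """Integrating the exported rules reproduces the finely-stepped
        HillTau trajectory of a tau-only model within <1% normalized RMS."""
        from scipy.integrate import solve_ivp
        m = oscillator_model
        rules = to_ode_rates(m)
        assert all(r.warning is None for r in rules)
        names = [r.variable for r in rules]
        syms = [sp.Symbol(n) for n in names + list(m.species)]
        fns = [sp.lambdify(syms, r.expr, "numpy") for r in rules]
        consts = [m.species[n].conc_init for n in m.species]
        s0 = ht.initialize(m)
        y0 = [s0.conc[n] for n in names]
        runtime = 150.0

        def rhs(_t, y):
            return [f(*y, *consts) for f in fns]

        sol = solve_ivp(rhs, (0, runtime), y0, method="LSODA", rtol=1e-10,
                        atol=1e-12, t_eval=np.arange(0, runtime + 0.5, 0.5))
        ode = ht.Trace(axis=sol.t,
                       series={n: sol.y[i] for i, n in enumerate(names)})
        hillt = ht.run_program(m, ht.StimulusProgram(runtime=runtime,
                                                     sample_dt=0.5),
                               record=names, dt_internal=0.002)
        score = ht.nrms_score(ode, hillt, [("output", "output")])
        assert score < 0.01


class TestSbml:
    def test_document_structure(self, bcm_model):
        text = to_sbml(bcm_model)
        root = ET.fromstring(text)
        assert root.tag == f"{{{SBML_NS}}}sbml"
        assert root.get("level") == "3" and root.get("version") == "2"
        model = root.find(f"{{{SBML_NS}}}model")
        species = model.find(f"{{{SBML_NS}}}listOfSpecies")
        names = {s.get("id") for s in species}
        assert names == set(bcm_model.molecule_names())
        # boundary species constant, outputs not
        for s in species:
            is_input = s.get("id") in bcm_model.species
            assert s.get("constant") == ("true" if is_input else "false")
            assert s.get("boundaryCondition") == ("true" if is_input else "false")
        rules = model.find(f"{{{SBML_NS}}}listOfRules")
        rate_rules = rules.findall(f"{{{SBML_NS}}}rateRule")
        assert len(rate_rules) == len(bcm_model.reactions)
        for rr in rate_rules:
            math_el = rr.find("{http://www.w3.org/1998/Math/MathML}math")
            assert math_el is not None and len(math_el) == 1

    def test_tau2_model_exports_with_note(self, feedback_model):
        text = to_sbml(feedback_model)
        assert "tau2" in text  # warning carried in the notes block
        ET.fromstring(text)    # well-formed

    def test_equation_assignment_rule(self):
        doc = {"species": {"a": 1.0}, "equations": {"e": "2*a"}}
        text = to_sbml(build_model(doc))
        root = ET.fromstring(text)
        assert root.find(f".//{{{SBML_NS}}}assignmentRule") is not None

    def test_sbml_ode_reproduces_hilltau(self, oscillator_model):
        """Simulating the exported document's rate rules (parsed back from
        the SBML text, not from the model object) matches HillTau."""
        from scipy.integrate import solve_ivp
        text = to_sbml(oscillator_model)
        root = ET.fromstring(text)
        mathns = "{http://www.w3.org/1998/Math/MathML}"

        def math_to_expr(el):
            tag = el.tag.replace(mathns, "")
            if tag == "ci":
                return sp.Symbol(el.text.strip())
            if tag == "cn":
                if el.get("type") == "e-notation":
                    mant = float(el.text.strip())
                    expo = float(el.find(f"{mathns}sep").tail.strip())
                    return sp.Float(mant * 10**expo)
                return sp.Float(float(el.text.strip()))
            if tag == "apply":
                children = list(el)
                op = children[0].tag.replace(mathns, "")
                args = [math_to_expr(c) for c in children[1:]]
                ops = {"plus": lambda *a: sp.Add(*a),
                       "times": lambda *a: sp.Mul(*a),
                       "minus": lambda *a: a[0] - a[1] if len(a) > 1 else -a[0],
                       "divide": lambda a, b: a / b,
                       "power": lambda a, b: a**b,
                       "exp": sp.exp, "ln": sp.log}
                return ops[op](*args)
            raise AssertionError(f"unhandled MathML element {tag}")

        sns = f"{{{SBML_NS}}}"
        rate = {}
        for rr in root.iter(f"{sns}rateRule"):
            math_el = rr.find(f"{mathns}math")
            rate[rr.get("variable")] = math_to_expr(math_el[0])
        init = {s.get("id"): float(s.get("initialConcentration"))
                for s in root.iter(f"{sns}species")}
        names = list(rate)
        consts = {k: v for k, v in init.items() if k not in rate}
        syms = [sp.Symbol(n) for n in names]
        fns = {n: sp.lambdify(syms, rate[n].subs(
            {sp.Symbol(k): v for k, v in consts.items()}), "numpy")
            for n in names}

        def rhs(_t, y):
            return [fns[n](*y) for n in names]

        runtime = 120.0
        sol = solve_ivp(rhs, (0, runtime), [init[n] for n in names],
                        method="LSODA", rtol=1e-10, atol=1e-12,
                        t_eval=np.arange(0, runtime + 0.5, 0.5))
        ode = ht.Trace(axis=sol.t,
                       series={n: sol.y[i] for i, n in enumerate(names)})
        hillt = ht.run_program(oscillator_model,
                               ht.StimulusProgram(runtime=runtime, sample_dt=0.5),
                               record=names, dt_internal=0.002)
        assert ht.nrms_score(ode, hillt, [("output", "output")]) < 0.01


def parse_dot(text: str):
    """Tiny parser for the constrained DOT dialect the exporter emits."""
    nodes, edges = {}, set()
    for line in text.splitlines():
        mn = re.match(r'\s*"([^"]+)" \[.*role=(\w+)\];', line)
        me = re.match(r'\s*"([^"]+)" -> "([^"]+)" \[.*role=(\w+)\];', line)
        if me:
            edges.add((me.group(1), me.group(2), me.group(3)))
        elif mn:
            nodes[mn.group(1)] = mn.group(2)
    return nodes, edges


class TestDot:
    def test_feedback_topology(self, feedback_model):
        nodes, edges = parse_dot(to_dot(feedback_model))
        assert len(nodes) == 3  # input, fb, output
        assert nodes["input"] == "species"
        assert nodes["fb"] == nodes["output"] == "reaction"
        assert ("input", "output", "input") in edges
        assert ("fb", "output", "inhibitor") in edges
        assert ("output", "fb", "input") in edges

    def test_empty_model(self):
        text = to_dot(ht.load_model("{}"))
        assert text.strip().startswith("digraph") and text.strip().endswith("}")
        nodes, edges = parse_dot(text)
        assert nodes == {} and edges == set()

    @pytest.mark.parametrize("name", ["bcm", "bistable", "oscillator",
                                      "modifier", "feedback_inhibition"])
    def test_topology_recoverable_from_dot(self, name):
        """Inverse-parsing the DOT text reconstructs the model topology."""
        m = ht.example_model(name)
        nodes, edges = parse_dot(to_dot(m))
        assert set(nodes) == set(m.molecule_names())
        expected = set()
        for rn, r in m.reactions.items():
            expected.add((r.input, rn, "input"))
            if r.ligand:
                expected.add((r.ligand, rn,
                              "inhibitor" if r.inhibit else "activator"))
            if r.modifier:
                expected.add((r.modifier, rn, "modifier"))
        for en, eq in m.equations.items():
            for d in eq.dependencies():
                expected.add((d, en, "equation_arg"))
        assert edges == expected

    def test_equation_node_rendered_distinctly(self):
        doc = {"species": {"a": 1.0, "b": 1.0}, "equations": {"tot": "a+b"}}
        text = to_dot(build_model(doc))
        assert "doublecircle" in text and "Σ" in text
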