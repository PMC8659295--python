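"""HillTau model definition, JSON serialization and unit handling.

A HillTau model is a feed-forward network of "reactions", each of which
lumps one or more chemical steps into a single Hill-form steady state
(association constant ``KA``, order ``n``, optional modifier) relaxed
exponentially with time constants ``tau`` (rising) and ``tau2`` (falling).
Models are authored as JSON with four top-level keys::

    {
      "units": "uM",
      "species":   {"input": 1.0, "stim": {"concInit": 0.0}},
      "reactions": {"output": {"input": "input", "ligand": "stim",
                               "KA": 0.5, "tau": 2.0}},
      "equations": {"total": "output + 0.5*input"}
    }

Reaction (and equation) definition order is semantically meaningful: the
scheduler uses it to break feedback loops deterministically, so ordered
mappings are preserved end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from . import expression

#: scale factor from each supported concentration unit to mM (the
#: canonical internal unit).
UNIT_TO_MM = {"M": 1e3, "mM": 1.0, "uM": 1e-3, "nM": 1e-6}

CANONICAL_UNIT = "mM"


class ModelError(ValueError):
    """Schema/validation error; the message names the offending element."""


@dataclass
class SpeciesSpec:
    """A plain (non-computed) molecular species.

    Plain species are boundary conditions: the engine never updates them
    except through explicit events or clamps.
    """

    conc_init: float = 0.0
    is_buffered: bool = True


@dataclass
class ReactionSpec:
    """One HillTau reaction defining the molecule named ``output``.

    ``input`` is the reagent (Y_input); ``ligand`` the activating or
    inhibiting molecule L (absent for conversion reactions); ``modifier``
    an optional molecule rescaling the effective KA per the
    Hofmeyr--Cornish-Bowden form (inhibitory when Amod < 1).
    """

    output: str
    input: str
    KA: float
    tau: float
    ligand: str | None = None
    modifier: str | None = None
    n: float = 1.0
    tau2: float | None = None  # filled with tau by load/validation
    gain: float = 1.0
    baseline: float = 0.0
    Kmod: float | None = None
    Amod: float = 4.0
    Nmod: float = 1.0
    inhibit: bool = False
    conc_init: float | None = None  # explicit initial value for the output

    @property
    def tau_fall(self) -> float:
        return self.tau if self.tau2 is None else self.tau2

    def dependencies(self) -> list[str]:
        deps = [self.input]
        if self.ligand is not None:
            deps.append(self.ligand)
        if self.modifier is not None:
            deps.append(self.modifier)
        return deps


@dataclass
class EquationSpec:
    """An algebraic molecule: output = f(other molecules), instantaneous."""

    output: str
    expr_text: str
    expr: expression.Expr | None = field(default=None, repr=False, compare=False)

    def dependencies(self) -> list[str]:
        assert self.expr is not None
        return sorted(self.expr.names)


@dataclass
class ModelSpec:
    """A complete HillTau model (species, reactions, equations, units)."""

    units: str = "mM"
    species: dict[str, SpeciesSpec] = field(default_factory=dict)
    reactions: dict[str, ReactionSpec] = field(default_factory=dict)
    equations: dict[str, EquationSpec] = field(default_factory=dict)

    # -- namespace helpers -------------------------------------------------
    def molecule_names(self) -> list[str]:
        """All molecule names: species, reaction outputs, equation outputs."""
        return (list(self.species) + list(self.reactions) + list(self.equations))

    def input_names(self) -> list[str]:
        """Species with no defining reaction/equation (layer-0 inputs)."""
        return list(self.species)

    def node_order(self) -> list[str]:
        """Computed nodes (reactions then equations) in authored order."""
        return list(self.reactions) + list(self.equations)

    def dependencies_of(self, name: str) -> list[str]:
        if name in self.reactions:
            return self.reactions[name].dependencies()
        return self.equations[name].dependencies()

    def copy(self) -> "ModelSpec":
        return ModelSpec(
            units=self.units,
            species={k: replace(v) for k, v in self.species.items()},
            reactions={k: replace(v) for k, v in self.reactions.items()},
            equations={k: replace(v) for k, v in self.equations.items()},
        )

    def validate(self) -> None:
        _validate(self)


# ---------------------------------------------------------------------------
# validation

def _require_positive(value: float, what: str) -> None:
    if not (value > 0) or value != value:
        raise ModelError(f"{what} must be > 0, got {value!r}")


def _require_nonneg(value: float, what: str) -> None:
    if not (value >= 0):
        raise ModelError(f"{what} must be >= 0, got {value!r}")


def _validate(m: ModelSpec) -> None:
    if m.units not in UNIT_TO_MM:
        raise ModelError(
            f"unknown concentration unit {m.units!r}; expected one of "
            f"{sorted(UNIT_TO_MM)}")

    names = m.molecule_names()
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ModelError(
                f"name {name!r} is defined more than once (species, reaction "
                "outputs and equation outputs must be disjoint)")
        seen.add(name)

    for name, sp in m.species.items():
        _require_nonneg(sp.conc_init, f"species {name!r}: concInit")

    for name, r in m.reactions.items():
        if r.output != name:
            raise ModelError(f"reaction {name!r}: output field mismatch")
        _require_positive(r.KA, f"reaction {name!r}: KA")
        _require_positive(r.tau, f"reaction {name!r}: tau")
        if r.tau2 is not None:
            _require_positive(r.tau2, f"reaction {name!r}: tau2")
        _require_positive(r.gain, f"reaction {name!r}: gain")
        _require_nonneg(r.baseline, f"reaction {name!r}: baseline")
        _require_nonneg(r.n, f"reaction {name!r}: n")
        _require_nonneg(r.Nmod, f"reaction {name!r}: Nmod")
        _require_positive(r.Amod, f"reaction {name!r}: Amod")
        if r.conc_init is not None:
            _require_nonneg(r.conc_init, f"reaction {name!r}: concInit")
        if (r.modifier is None) != (r.Kmod is None):
            raise ModelError(
                f"reaction {name!r}: Kmod must be given if and only if a "
                "modifier is given")
        if r.Kmod is not None:
            _require_positive(r.Kmod, f"reaction {name!r}: Kmod")
        if r.modifier is not None and r.ligand is None:
            raise ModelError(
                f"reaction {name!r}: a modifier requires a ligand")
        if r.ligand is None and r.inhibit:
            raise ModelError(
                f"reaction {name!r}: conversion form (no ligand) cannot be "
                "inhibitory")
        for dep in r.dependencies():
            if dep not in seen:
                raise ModelError(
                    f"reaction {name!r} references unknown molecule {dep!r}")

    namespace = frozenset(seen)
    for name, eq in m.equations.items():
        if eq.output != name:
            raise ModelError(f"equation {name!r}: output field mismatch")
        try:
            eq.expr = expression.parse(eq.expr_text, namespace - {name})
        except expression.ExpressionError as exc:
            raise ModelError(f"equation {name!r}: {exc}") from None


# ---------------------------------------------------------------------------
# JSON loading

_REACTION_KEYS = {
    "input", "ligand", "modifier", "KA", "n", "tau", "tau2", "gain",
    "baseline", "Kmod", "Amod", "Nmod", "inhibit", "concInit",
}
_SPECIES_KEYS = {"concInit", "buffered"}
_TOP_KEYS = {"units", "species", "reactions", "equations"}


def load_model(json_text: str) -> ModelSpec:
    """Parse and validate a HillTau model from JSON text.

    All defaulted fields are filled in (tau2 = tau, gain = 1, baseline = 0,
    Amod = 4, Nmod = 1, n = 1); unknown keys are rejected with a diagnostic
    that names the offending element.
    """
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise ModelError("top level of a HillTau model must be a JSON object")
    unknown = set(doc) - _TOP_KEYS - {"massaction"}
    if unknown:
        raise ModelError(f"unknown top-level keys: {sorted(unknown)}")

    m = ModelSpec(units=doc.get("units", "mM"))

    for name, sdef in (doc.get("species") or {}).items():
        if isinstance(sdef, (int, float)) and not isinstance(sdef, bool):
            m.species[name] = SpeciesSpec(conc_init=float(sdef))
        elif isinstance(sdef, dict):
            bad = set(sdef) - _SPECIES_KEYS
            if bad:
                raise ModelError(f"species {name!r}: unknown keys {sorted(bad)}")
            m.species[name] = SpeciesSpec(
                conc_init=float(sdef.get("concInit", 0.0)),
                is_buffered=bool(sdef.get("buffered", True)))
        else:
            raise ModelError(
                f"species {name!r}: expected a number or an object")

    for name, rdef in (doc.get("reactions") or {}).items():
        if not isinstance(rdef, dict):
            raise ModelError(f"reaction {name!r}: expected an object")
        bad = set(rdef) - _REACTION_KEYS
        if bad:
            raise ModelError(f"reaction {name!r}: unknown keys {sorted(bad)}")
        for req in ("input", "KA", "tau"):
            if req not in rdef:
                raise ModelError(f"reaction {name!r}: missing required key {req!r}")
        m.reactions[name] = ReactionSpec(
            output=name,
            input=str(rdef["input"]),
            ligand=rdef.get("ligand"),
            modifier=rdef.get("modifier"),
            KA=float(rdef["KA"]),
            n=float(rdef.get("n", 1.0)),
            tau=float(rdef["tau"]),
            tau2=float(rdef["tau2"]) if "tau2" in rdef else None,
            gain=float(rdef.get("gain", 1.0)),
            baseline=float(rdef.get("baseline", 0.0)),
            Kmod=float(rdef["Kmod"]) if "Kmod" in rdef else None,
            Amod=float(rdef.get("Amod", 4.0)),
            Nmod=float(rdef.get("Nmod", 1.0)),
            inhibit=bool(rdef.get("inhibit", False)),
            conc_init=float(rdef["concInit"]) if "concInit" in rdef else None,
        )

    for name, edef in (doc.get("equations") or {}).items():
        if not isinstance(edef, str):
            raise ModelError(f"equation {name!r}: expected an expression string")
        m.equations[name] = EquationSpec(output=name, expr_text=edef)

    _validate(m)
    # fill tau2 default so every field has a concrete value after load
    for r in m.reactions.values():
        if r.tau2 is None:
            r.tau2 = r.tau
    return m


def load_model_file(path) -> ModelSpec:
    with open(path, encoding="utf-8") as fh:
        return load_model(fh.read())


def write_model(m: ModelSpec) -> str:
    """Serialize a model to JSON; ``load_model(write_model(m))`` equals m."""
    m.validate()
    doc: dict = {"units": m.units}
    doc["species"] = {
        name: ({"concInit": sp.conc_init} if sp.is_buffered
               else {"concInit": sp.conc_init, "buffered": False})
        for name, sp in m.species.items()
    }
    reactions: dict = {}
    for name, r in m.reactions.items():
        rd: dict = {"input": r.input}
        if r.ligand is not None:
            rd["ligand"] = r.ligand
        if r.modifier is not None:
            rd["modifier"] = r.modifier
        rd["KA"] = r.KA
        rd["n"] = r.n
        rd["tau"] = r.tau
        rd["tau2"] = r.tau_fall
        rd["gain"] = r.gain
        rd["baseline"] = r.baseline
        if r.Kmod is not None:
            rd["Kmod"] = r.Kmod
            rd["Amod"] = r.Amod
            rd["Nmod"] = r.Nmod
        if r.inhibit:
            rd["inhibit"] = True
        if r.conc_init is not None:
            rd["concInit"] = r.conc_init
        reactions[name] = rd
    doc["reactions"] = reactions
    doc["equations"] = {name: eq.expr_text for name, eq in m.equations.items()}
    return json.dumps(doc, indent=2)


def write_model_file(m: ModelSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_model(m))
        fh.write("\n")


# ---------------------------------------------------------------------------
# units

def convert_units(m: ModelSpec, to: str) -> ModelSpec:
    """Return a copy of ``m`` with all concentrations expressed in ``to``.

    Concentration-typed fields (species concInit, KA, baseline, Kmod,
    reaction concInit) are scaled by the ratio of unit scale factors.
    Note that the conversion reaction form (Yinput**n / KA) is not
    dimensionally homogeneous, so for models containing conversion
    reactions with n != 1 a unit change rescales the dynamics; author
    such models in the unit they are simulated in.
    """
    if to not in UNIT_TO_MM:
        raise ModelError(f"unknown concentration unit {to!r}")
    factor = UNIT_TO_MM[m.units] / UNIT_TO_MM[to]
    out = m.copy()
    out.units = to
    for sp in out.species.values():
        sp.conc_init *= factor
    for r in out.reactions.values():
        r.KA *= factor
        r.baseline *= factor
        if r.Kmod is not None:
            r.Kmod *= factor
        if r.conc_init is not None:
            r.conc_init *= factor
    return out


def canonicalize_units(m: ModelSpec) -> ModelSpec:
    """Express all concentrations in the canonical internal unit (mM)."""
    return convert_units(m, CANONICAL_UNIT)
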