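"""Event-driven evaluation of HillTau models.

Each reaction has a closed-form steady state (a Hill function of its
ligand, scaled by the reagent and optionally rescaled by a modifier) and
relaxes toward it exponentially with time constant ``tau`` when rising and
``tau2`` when falling:

    Y(t + dt) = Y(t) + (Yinf - (Y(t) - baseline)) * (1 - exp(-dt / tau))

Because the update is closed-form, a step can in principle span the whole
simulation; sub-steps are only needed so that *cascaded* reactions see
fresh upstream values, so the engine subdivides long intervals into
internal steps no larger than ``dt_internal`` (default: smallest tau in
the model divided by 10).  Within a step, reactions are evaluated layer
by layer (see :mod:`hilltau.scheduler`); dependencies severed to break
feedback loops read the previous internal step's value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import expression
from .model import ModelSpec, ReactionSpec
from .scheduler import LayerAssignment, build_dependency_layers

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data types

@dataclass
class SimState:
    """Current concentrations of all molecules plus current time."""

    t: float
    conc: dict[str, float]

    def copy(self) -> "SimState":
        return SimState(t=self.t, conc=dict(self.conc))


@dataclass(frozen=True)
class Event:
    """Set ``species`` to ``value`` (model units) at ``time`` seconds."""

    time: float
    species: str
    value: float


@dataclass
class StimulusProgram:
    """A deterministic stimulus protocol.

    For time-series protocols (``kind == "time"``): ordered events, total
    runtime and a sampling interval.  For dose-response protocols
    (``kind == "dose"``): the clamped input, the doses to sweep and the
    settling time per dose.
    """

    events: list[Event] = field(default_factory=list)
    runtime: float = 0.0
    sample_dt: float = 1.0
    kind: str = "time"  # "time" | "dose"
    dose_input: str | None = None
    doses: list[float] = field(default_factory=list)
    settle_time: float | None = None

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time)
        if self.kind == "time":
            if self.sample_dt <= 0:
                raise ValueError("sample_dt must be > 0")
            if self.events and self.runtime < max(e.time for e in self.events):
                raise ValueError("runtime must cover all event times")


@dataclass
class Trace:
    """Sampled time- or dose-series of named concentrations."""

    axis: np.ndarray
    series: dict[str, np.ndarray]
    axis_kind: str = "time"  # "time" | "dose"

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, v in self.series.items():
            if v.shape != self.axis.shape:
                raise ValueError(f"series {name!r} length mismatch with axis")

    def resampled(self, axis: np.ndarray) -> "Trace":
        """Linear interpolation of every series onto a new axis."""
        axis = np.asarray(axis, dtype=float)
        return Trace(axis=axis, axis_kind=self.axis_kind, series={
            k: np.interp(axis, self.axis, v) for k, v in self.series.items()})

    def to_csv(self, fh) -> None:
        names = list(self.series)
        fh.write(",".join([self.axis_kind] + names) + "\n")
        cols = [self.axis] + [self.series[n] for n in names]
        for row in zip(*cols):
            fh.write(",".join(repr(float(x)) for x in row) + "\n")

    @classmethod
    def from_csv(cls, fh) -> "Trace":
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
        cols = [c.strip() for c in header.strip().split(",")]
        rows = [[float(x) for x in line.strip().split(",")]
                for line in fh if line.strip()]
        if not rows:
            raise ValueError("empty trace")
        data = np.asarray(rows, dtype=float)
        axis_kind = cols[0] if cols[0] in ("time", "dose") else "time"
        return cls(axis=data[:, 0], axis_kind=axis_kind,
                   series={name: data[:, i + 1] for i, name in enumerate(cols[1:])})


# ---------------------------------------------------------------------------
# elementary operations

def steady_state_output(r: ReactionSpec, env: dict[str, float]) -> float:
    """The reaction's target steady state Yinf given an environment.

    Activation:            gain * Yin * L**n / (KA**n + L**n)
    Inhibition:            gain * Yin * (1 - L**n / (KA**n + L**n))
    With modifier M:       KA**n is rescaled by
                           (1 + (M/Kmod)**h) / (1 + Amod*(M/Kmod)**h)
    Conversion (no L):     gain * Yin**n / KA
    """
    y_in = env[r.input]
    if r.ligand is None:
        return r.gain * y_in**r.n / r.KA
    L = env[r.ligand]
    ka_n = r.KA**r.n
    if r.modifier is not None:
        x = (env[r.modifier] / r.Kmod) ** r.Nmod
        ka_n *= (1.0 + x) / (1.0 + r.Amod * x)
    ln = L**r.n
    denom = ka_n + ln
    theta = ln / denom if denom > 0.0 else 0.0
    if r.inhibit:
        theta = 1.0 - theta
    return r.gain * y_in * theta


def relax(y_now: float, y_inf: float, baseline: float, dt: float,
          tau: float, tau2: float) -> float:
    """Advance one output by ``dt`` toward its asymptote Yinf + baseline.

    ``tau`` is used when the output is rising, ``tau2`` when falling
    (the asymptote Yinf + baseline is compared against the current value).
    Closed form: exact for any ``dt`` while inputs are constant.
    """
    target = y_inf + baseline
    tc = tau if target > y_now else tau2
    # -expm1(-x) = 1 - exp(-x), accurate for small dt/tau
    return y_now + (y_inf - (y_now - baseline)) * (-math.expm1(-dt / tc))


def default_dt(m: ModelSpec) -> float:
    """Default internal timestep: smallest tau in the model / 10."""
    taus = [r.tau for r in m.reactions.values()]
    taus += [r.tau_fall for r in m.reactions.values()]
    return min(taus) / 10.0 if taus else 1.0


def _eval_equation(name: str, eq, env: dict[str, float]) -> float:
    value = expression.evaluate(eq.expr, env)
    if value < 0.0:
        logger.warning("equation %r produced negative value %g; clamped to 0",
                       name, value)
        value = 0.0
    return value


# ---------------------------------------------------------------------------
# state initialization and advancing

def initialize(m: ModelSpec, layers: LayerAssignment | None = None) -> SimState:
    """Initial state: species use concInit; reaction outputs without an
    explicit concInit fall back to Yinf + baseline at the initial upstream
    values, filled layer by layer."""
    if layers is None:
        layers = build_dependency_layers(m)
    conc: dict[str, float] = {}
    for name, sp in m.species.items():
        conc[name] = sp.conc_init
    for name, r in m.reactions.items():
        conc[name] = r.conc_init if r.conc_init is not None else 0.0
    for name in m.equations:
        conc[name] = 0.0
    for layer in layers.schedule:
        for name in layer:
            if name in m.reactions:
                r = m.reactions[name]
                if r.conc_init is None:
                    conc[name] = steady_state_output(r, conc) + r.baseline
            else:
                conc[name] = _eval_equation(name, m.equations[name], conc)
    return SimState(t=0.0, conc=conc)


def advance(m: ModelSpec, layers: LayerAssignment, s: SimState, t_end: float,
            dt_internal: float, clamped: frozenset[str] = frozenset()) -> SimState:
    """Advance the state in place to ``t_end``.

    The interval is split into equal internal steps no longer than
    ``dt_internal``; within a step, layers are evaluated in ascending
    order so each reaction sees current-step upstream values, except for
    dependencies severed by feedback breaking, which read the previous
    step's value.  Molecules in ``clamped`` are never updated.
    """
    if t_end < s.t:
        raise ValueError("t_end precedes current state time")
    span = t_end - s.t
    if span == 0.0:
        return s
    if dt_internal <= 0:
        raise ValueError("dt_internal must be > 0")
    nsteps = max(1, math.ceil(span / dt_internal - 1e-12))
    dt = span / nsteps
    conc = s.conc
    for _ in range(nsteps):
        prev = dict(conc)
        for layer in layers.schedule:
            for name in layer:
                if name in clamped:
                    continue
                if name in m.reactions:
                    r = m.reactions[name]
                    broken = layers.broken_inputs_of(name)
                    if broken:
                        env = {d: (prev[d] if d in broken else conc[d])
                               for d in r.dependencies()}
                    else:
                        env = conc
                    y_inf = steady_state_output(r, env)
                    conc[name] = relax(conc[name], y_inf, r.baseline, dt,
                                       r.tau, r.tau_fall)
                else:
                    conc[name] = _eval_equation(name, m.equations[name], conc)
    s.t = t_end
    return s


def run_program(m: ModelSpec, p: StimulusProgram, record: list[str] | None = None,
                dt_internal: float | None = None) -> Trace:
    """Run a stimulus program and sample the requested molecules.

    Events set species concentrations at their times (applied before the
    sample at the same time).  ``record`` defaults to every molecule.
    """
    if p.kind == "dose":
        if p.dose_input is None or not p.doses:
            raise ValueError("dose program requires dose_input and doses")
        return dose_response(m, p.dose_input, p.doses,
                             record or m.molecule_names(),
                             settle_time=p.settle_time)
    layers = build_dependency_layers(m)
    if dt_internal is None:
        dt_internal = default_dt(m)
    names = record if record is not None else m.molecule_names()
    for e in p.events:
        if e.species not in m.molecule_names():
            raise ValueError(f"event references unknown species {e.species!r}")

    state = initialize(m, layers)
    n_samples = int(round(p.runtime / p.sample_dt)) + 1
    sample_times = np.arange(n_samples) * p.sample_dt

    breakpoints = sorted(set(float(t) for t in sample_times)
                         | set(e.time for e in p.events))
    events_at: dict[float, list[Event]] = {}
    for e in p.events:
        events_at.setdefault(e.time, []).append(e)

    out = {name: [] for name in names}
    axis = []
    sample_set = set(float(t) for t in sample_times)
    for t in breakpoints:
        advance(m, layers, state, t, dt_internal)
        for e in events_at.get(t, ()):
            state.conc[e.species] = e.value
        if t in sample_set:
            axis.append(t)
            for name in names:
                out[name].append(state.conc[name])
    return Trace(axis=np.asarray(axis),
                 series={k: np.asarray(v) for k, v in out.items()})


def solve_steady_state(m: ModelSpec, boundary: dict[str, float] | None = None,
                       settle_time: float | None = None,
                       state: SimState | None = None) -> dict[str, float]:
    """Settle the model and return its steady concentrations.

    The settling interval (default 100x the largest tau) is subdivided
    into exactly 10 equal steps so that feedback loops also settle; this
    is conservative, since for feed-forward models the first closed-form
    step would already land on the fixed point.
    """
    layers = build_dependency_layers(m)
    if settle_time is None:
        taus = [r.tau for r in m.reactions.values()]
        taus += [r.tau_fall for r in m.reactions.values()]
        settle_time = 100.0 * max(taus) if taus else 1.0
    if state is None:
        state = initialize(m, layers)
    else:
        state = state.copy()
    clamped = frozenset(boundary or ())
    if boundary:
        for name, value in boundary.items():
            if name not in state.conc:
                raise ValueError(f"boundary references unknown molecule {name!r}")
            state.conc[name] = value
    advance(m, layers, state, state.t + settle_time, settle_time / 10.0,
            clamped=clamped)
    return dict(state.conc)


def dose_response(m: ModelSpec, input_name: str, doses, readouts,
                  settle_time: float | None = None,
                  carry_over: bool = True) -> Trace:
    """Steady-state response of ``readouts`` as ``input_name`` is swept.

    With ``carry_over`` (default), the settled state of one dose seeds the
    next, which exposes hysteresis in bistable systems; pass False to
    re-initialize at every dose.
    """
    if isinstance(readouts, str):
        readouts = [readouts]
    for name in readouts:
        if name not in m.molecule_names():
            raise ValueError(f"readout references unknown molecule {name!r}")
    layers = build_dependency_layers(m)
    state: SimState | None = None
    out = {name: [] for name in readouts}
    for dose in doses:
        if carry_over and state is not None:
            start = state
        else:
            start = initialize(m, layers)
        start.conc[input_name] = float(dose)
        conc = solve_steady_state(m, boundary={input_name: float(dose)},
                                  settle_time=settle_time, state=start)
        state = SimState(t=0.0, conc=conc)
        for name in readouts:
            out[name].append(conc[name])
    return Trace(axis=np.asarray(list(doses), dtype=float), axis_kind="dose",
                 series={k: np.asarray(v) for k, v in out.items()})
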