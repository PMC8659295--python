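"""Minimal mass-action / Michaelis-Menten ODE integrator.

This module provides the ground truth that the HillTau abstraction
approximates: networks of reversible binding reactions (mass-action) and
enzymatic steps using the quasi-steady-state Michaelis-Menten rate law

    dP/dt = E * S * kcat / (Km + S) - Kr * P

with an optional first-order back reaction returning product to
substrate.  It serves two roles: verifying the closed-form cascade
approximations (a cascade of such stages is itself Hill-like), and
generating reference traces for the MASH model-reduction optimizer
without any external simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .engine import Event, Trace


@dataclass(frozen=True)
class BindingReaction:
    """Reversible mass-action reaction: substrates <-> products.

    ``substrates`` and ``products`` are lists of (name, stoichiometry).
    Forward rate Kf * prod(substrate**stoich); backward Kb * prod(product**stoich).
    """

    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    Kf: float
    Kb: float


@dataclass(frozen=True)
class EnzymeStep:
    """Quasi-steady-state enzymatic step with first-order back reaction.

    E + S -> E + P at rate E*S*kcat/(Km+S); P -> S at rate Kr*P.
    """

    enzyme: str
    substrate: str
    product: str
    kcat: float
    Km: float
    Kr: float = 0.0


@dataclass
class MassActionNetwork:
    species: dict[str, float] = field(default_factory=dict)
    bindings: list[BindingReaction] = field(default_factory=list)
    enzymes: list[EnzymeStep] = field(default_factory=list)
    #: species held fixed (boundary conditions); their derivatives are zeroed
    buffered: set[str] = field(default_factory=set)

    def validate(self) -> None:
        names = set(self.species)
        for i, b in enumerate(self.bindings):
            if b.Kf < 0 or b.Kb < 0:
                raise ValueError(f"binding {i}: rates must be >= 0")
            for name, _ in list(b.substrates) + list(b.products):
                if name not in names:
                    raise ValueError(f"binding {i}: unknown species {name!r}")
        for i, e in enumerate(self.enzymes):
            if e.kcat < 0 or e.Km <= 0 or e.Kr < 0:
                raise ValueError(f"enzyme step {i}: invalid rates")
            for name in (e.enzyme, e.substrate, e.product):
                if name not in names:
                    raise ValueError(f"enzyme step {i}: unknown species {name!r}")


def load_network(json_text: str) -> MassActionNetwork:
    """Load a network from the shared JSON envelope (key ``massaction``)."""
    doc = json.loads(json_text)
    body = doc.get("massaction", doc)
    net = MassActionNetwork(
        species={k: float(v) for k, v in body.get("species", {}).items()},
        buffered=set(body.get("buffered", [])),
    )
    for b in body.get("bindings", []):
        net.bindings.append(BindingReaction(
            substrates=tuple((str(n), int(s)) for n, s in b["substrates"]),
            products=tuple((str(n), int(s)) for n, s in b["products"]),
            Kf=float(b["Kf"]), Kb=float(b["Kb"])))
    for e in body.get("enzymes", []):
        net.enzymes.append(EnzymeStep(
            enzyme=str(e["enzyme"]), substrate=str(e["substrate"]),
            product=str(e["product"]), kcat=float(e["kcat"]),
            Km=float(e["Km"]), Kr=float(e.get("Kr", 0.0))))
    net.validate()
    return net


def _rhs_factory(net: MassActionNetwork, index: dict[str, int]):
    buffered_idx = [index[n] for n in net.buffered]

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for b in net.bindings:
            vf = b.Kf
            for name, st in b.substrates:
                vf *= y[index[name]] ** st
            vb = b.Kb
            for name, st in b.products:
                vb *= y[index[name]] ** st
            v = vf - vb
            for name, st in b.substrates:
                dy[index[name]] -= st * v
            for name, st in b.products:
                dy[index[name]] += st * v
        for e in net.enzymes:
            s = y[index[e.substrate]]
            v = y[index[e.enzyme]] * s * e.kcat / (e.Km + s)
            back = e.Kr * y[index[e.product]]
            dy[index[e.substrate]] -= v - back
            dy[index[e.product]] += v - back
        for i in buffered_idx:
            dy[i] = 0.0
        return dy

    return rhs


def simulate(net: MassActionNetwork, events: list[Event] | None = None,
             runtime: float = 1.0, sample_dt: float = 0.1,
             rtol: float = 1e-8) -> Trace:
    """Integrate the network with a stiff adaptive solver (LSODA).

    Events set species concentrations at their times; integration is
    piecewise between event times.  Deterministic given inputs.
    """
    net.validate()
    events = sorted(events or [], key=lambda e: e.time)
    names = list(net.species)
    index = {n: i for i, n in enumerate(names)}
    rhs = _rhs_factory(net, index)

    n_samples = int(round(runtime / sample_dt)) + 1
    sample_times = np.arange(n_samples) * sample_dt
    y = np.array([net.species[n] for n in names], dtype=float)
    out = np.empty((len(names), n_samples))

    segments: list[tuple[float, float, list[Event]]] = []
    t0 = 0.0
    for e in events:
        segments.append((t0, max(e.time, t0), [e]))
        t0 = max(e.time, t0)
    segments.append((t0, runtime, []))

    si = 0  # next sample to fill; samples at a boundary recorded pre-event
    atol = rtol * max(1e-9, float(np.max(np.abs(y))) or 1.0) * 1e-3
    for start, stop, evs in segments:
        ts = []
        while si < n_samples and sample_times[si] <= stop + 1e-9:
            ts.append(sample_times[si])
            si += 1
        if stop > start:
            sol = solve_ivp(rhs, (start, stop), y, method="LSODA",
                            rtol=rtol, atol=atol, dense_output=True)
            if not sol.success:
                raise RuntimeError(
                    f"integration failed in [{start}, {stop}]: {sol.message}")
            for k, t in enumerate(ts):
                out[:, si - len(ts) + k] = sol.sol(min(max(t, start), stop))
            y = sol.sol(stop).copy()
        else:
            for k, _ in enumerate(ts):
                out[:, si - len(ts) + k] = y
        for e in evs:
            y[index[e.species]] = e.value
    return Trace(axis=sample_times[:si],
                 series={n: out[i, :si] for i, n in enumerate(names)})


# ---------------------------------------------------------------------------
# Hill/exponential fitting of cascade responses

@dataclass(frozen=True)
class HillFit:
    """Composite Hill + exponential parameters fitted to a trace family."""

    KA: float
    n: float
    ymax: float          # plateau (effective R * gain of the cascade)
    tau: float           # rising-phase time constant (mean over traces)
    tau2: float          # falling-phase time constant, = tau if no decay data
    residual: float      # RMS of steady-state fit / max steady state


def _hill(L, ymax, KA, n):
    L = np.asarray(L, dtype=float)
    return ymax * L**n / (KA**n + L**n)


def _fit_tau(t: np.ndarray, y: np.ndarray) -> float:
    """Fit y(t) = yinf - (yinf - y0) * exp(-t/tau) on a monotone segment."""
    y0, yinf = y[0], y[-1]
    if abs(yinf - y0) < 1e-30:
        return float("nan")

    def f(t, tau):
        return yinf - (yinf - y0) * np.exp(-t / tau)

    p0 = max((t[-1] - t[0]) / 5.0, 1e-6)
    popt, _ = curve_fit(f, t - t[0], y, p0=[p0], maxfev=10000,
                        bounds=(1e-12, np.inf))
    return float(popt[0])


def fit_hill_to_cascade(trace_family: list[tuple[float, Trace]],
                        readout: str) -> HillFit:
    """Fit composite Hill + exponential parameters to step responses.

    ``trace_family`` pairs each input (ligand) level with the response
    trace it produced.  The steady-state curve across inputs is fitted by
    a Hill function; each rising phase by a single exponential.
    """
    if len(trace_family) < 3:
        raise ValueError("need at least 3 input levels to fit a Hill curve")
    levels = np.array([lvl for lvl, _ in trace_family], dtype=float)
    finals = np.array([tr.series[readout][-1] for _, tr in trace_family])
    if np.ptp(finals) <= 0:
        raise ValueError("degenerate (flat) trace family")
    p0 = [finals.max(), np.median(levels), 1.0]
    popt, _ = curve_fit(_hill, levels, finals, p0=p0, maxfev=20000,
                        bounds=([0, 0, 0.05], [np.inf, np.inf, 20.0]))
    ymax, KA, n = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((_hill(levels, *popt) - finals) ** 2))
                  / finals.max())
    taus = []
    for _, tr in trace_family:
        y = tr.series[readout]
        if np.ptp(y) > 1e-12 * max(1.0, abs(y[-1])):
            taus.append(_fit_tau(tr.axis, y))
    tau = float(np.nanmean(taus)) if taus else float("nan")
    return HillFit(KA=KA, n=n, ymax=ymax, tau=tau, tau2=tau, residual=resid)
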