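"""MASH: fit a HillTau model's parameters to reference traces.

Model reduction proceeds by running both the reference system (a
mass-action network, another HillTau model, or experimental CSV traces)
and the candidate HillTau model through the same stimulus protocols,
scoring the discrepancy as a normalized RMS difference, and minimizing
that score over a chosen set of reaction parameters with bounded
quasi-Newton optimization (L-BFGS-B, positive parameters in log space).
A score below 0.05 means the reference and reduced responses differ by
less than 5% of the response range on average.

Staged fitting (``staged_fit``) freezes already-fitted reactions while
later stages tune downstream ones, mirroring how one reduces a large
pathway one readout at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .engine import Event, StimulusProgram, Trace, dose_response, run_program
from .model import ModelSpec

#: reaction fields MASH may tune; positive ones are optimized in log space
TUNABLE_FIELDS = ("KA", "tau", "tau2", "gain", "baseline", "Kmod", "Amod",
                  "n", "Nmod")
_LOG_FIELDS = {"KA", "tau", "tau2", "gain", "Kmod", "Amod"}


@dataclass(frozen=True)
class FitParam:
    """One free parameter: a (reaction, field) pair with bounds."""

    reaction: str
    fieldname: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.fieldname not in TUNABLE_FIELDS:
            raise ValueError(f"field {self.fieldname!r} is not tunable")
        if not (self.lo <= self.hi):
            raise ValueError("lower bound exceeds upper bound")
        if self.fieldname in _LOG_FIELDS and self.lo <= 0:
            raise ValueError(
                f"{self.fieldname} bounds must be positive (log-space search)")


@dataclass
class FitSpec:
    """What to fit, over which protocols, scored on which readouts."""

    free_params: list[FitParam]
    protocols: list[StimulusProgram]
    #: (hilltau name, reference name) pairs
    readouts: list[tuple[str, str]]
    max_iterations: int = 200
    tolerance: float = 1e-9
    multistart: int = 0  # extra random restarts; 0 = deterministic single start
    seed: int | None = None
    dt_internal: float | None = None


@dataclass
class FitResult:
    model: ModelSpec
    score: float
    initial_score: float
    per_protocol: list[float]
    iterations: int
    converged: bool
    message: str = ""


def default_bounds(value: float, fieldname: str) -> tuple[float, float]:
    """Default search bounds: two decades either side of the initial value."""
    if fieldname in _LOG_FIELDS:
        return (value / 100.0, value * 100.0)
    if fieldname in ("n", "Nmod"):
        return (0.2, 8.0)
    return (0.0, max(1.0, value * 100.0))  # baseline


# ---------------------------------------------------------------------------
# scoring

def nrms_score(ref: Trace, test: Trace,
               readouts: list[tuple[str, str]]) -> float:
    """Normalized RMS difference between two traces, averaged over readouts.

    Per readout: sqrt(mean((ref - test)^2)) / (max(ref) - min(ref)); a flat
    reference falls back to max(|ref|) as denominator, and to absolute RMS
    if the reference is identically zero.  ``test`` is linearly resampled
    onto the reference axis if the grids differ.
    """
    if len(ref.axis) == 0:
        raise ValueError("empty reference trace")
    scores = []
    for ht_name, ref_name in readouts:
        if ref_name not in ref.series:
            raise ValueError(f"reference trace lacks readout {ref_name!r}")
        if ht_name not in test.series:
            raise ValueError(f"test trace lacks readout {ht_name!r}")
        r = ref.series[ref_name]
        t = test.series[ht_name]
        if len(t) != len(r) or not np.allclose(test.axis, ref.axis):
            t = np.interp(ref.axis, test.axis, t)
        rms = math.sqrt(float(np.mean((r - t) ** 2)))
        denom = float(np.max(r) - np.min(r))
        if denom == 0.0:
            denom = float(np.max(np.abs(r)))
        if denom == 0.0:
            denom = 1.0
        scores.append(rms / denom)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# protocol builders

def make_protocol(kind: str, **params) -> StimulusProgram:
    """Build a deterministic stimulus protocol.

    kind="step": ``species``, ``value``, ``onset``, optional ``offset`` and
    ``base`` (post-offset level, default 0), ``runtime``, ``sample_dt``.

    kind="pulse_train": ``species``, ``amplitude``, ``width``, ``interval``
    (onset-to-onset), ``count``, optional ``start`` and ``base``,
    ``runtime`` (default covers the train), ``sample_dt``.

    kind="dose_response": ``input_name``, ``doses``, ``settle_time``.
    """
    if kind == "step":
        onset = float(params["onset"])
        events = [Event(onset, params["species"], float(params["value"]))]
        if "offset" in params and params["offset"] is not None:
            off = float(params["offset"])
            if off <= onset:
                raise ValueError("offset must follow onset")
            events.append(Event(off, params["species"],
                                float(params.get("base", 0.0))))
        return StimulusProgram(events=events, runtime=float(params["runtime"]),
                               sample_dt=float(params.get("sample_dt", 1.0)))
    if kind == "pulse_train":
        width = float(params["width"])
        interval = float(params["interval"])
        count = int(params["count"])
        if width <= 0 or interval <= 0 or count < 1:
            raise ValueError("pulse width, interval and count must be positive")
        if width >= interval:
            raise ValueError("pulse width must be shorter than the interval")
        start = float(params.get("start", 0.0))
        base = float(params.get("base", 0.0))
        amp = float(params["amplitude"])
        sp = params["species"]
        events = []
        for k in range(count):
            onset = start + k * interval
            events.append(Event(onset, sp, amp))
            events.append(Event(onset + width, sp, base))
        runtime = float(params.get("runtime",
                                   start + (count - 1) * interval + 10 * width))
        return StimulusProgram(events=events, runtime=runtime,
                               sample_dt=float(params.get("sample_dt", 1.0)))
    if kind == "dose_response":
        doses = [float(d) for d in params["doses"]]
        if any(d <= 0 for d in doses):
            raise ValueError("doses must be positive")
        return StimulusProgram(kind="dose",
                               dose_input=params["input_name"], doses=doses,
                               settle_time=params.get("settle_time"))
    raise ValueError(f"unknown protocol kind {kind!r}")


# ---------------------------------------------------------------------------
# fitting

def _get_param(m: ModelSpec, p: FitParam) -> float:
    r = m.reactions[p.reaction]
    v = getattr(r, "tau_fall" if p.fieldname == "tau2" else p.fieldname)
    return float(v)


def _set_param(m: ModelSpec, p: FitParam, value: float) -> None:
    setattr(m.reactions[p.reaction], p.fieldname, float(value))


def simulate_protocols(m: ModelSpec, protocols: list[StimulusProgram],
                       readouts: list[str],
                       dt_internal: float | None = None) -> list[Trace]:
    """Run the HillTau model through each protocol, recording ``readouts``."""
    traces = []
    for p in protocols:
        if p.kind == "dose":
            traces.append(dose_response(m, p.dose_input, p.doses, readouts,
                                        settle_time=p.settle_time))
        else:
            traces.append(run_program(m, p, record=list(readouts),
                                      dt_internal=dt_internal))
    return traces


def _resolve_reference(reference, spec: FitSpec) -> list[Trace]:
    if callable(reference):
        return [reference(p) for p in spec.protocols]
    refs = list(reference)
    if len(refs) != len(spec.protocols):
        raise ValueError("need one reference trace per protocol")
    return refs


def fit(m: ModelSpec, spec: FitSpec, reference) -> FitResult:
    """Fit ``spec.free_params`` of model ``m`` to reference traces.

    ``reference`` is either a list of Traces (one per protocol, aligned)
    or a callable mapping a StimulusProgram to a Trace.  The returned
    model's pooled score is never worse than the initial model's; optimizer
    failures are reported through the result, not raised.
    """
    if not spec.free_params:
        raise ValueError("no free parameters to fit")
    refs = _resolve_reference(reference, spec)
    ht_names = [ht for ht, _ in spec.readouts]

    def pooled(model: ModelSpec) -> tuple[float, list[float]]:
        traces = simulate_protocols(model, spec.protocols, ht_names,
                                    spec.dt_internal)
        per = [nrms_score(ref, tr, spec.readouts)
               for ref, tr in zip(refs, traces)]
        return float(np.mean(per)), per

    params = spec.free_params
    x0, bounds = [], []
    for p in params:
        v = _get_param(m, p)
        v = min(max(v, p.lo), p.hi)
        if p.fieldname in _LOG_FIELDS:
            x0.append(math.log(v))
            bounds.append((math.log(p.lo), math.log(p.hi)))
        else:
            x0.append(v)
            bounds.append((p.lo, p.hi))

    def build(x) -> ModelSpec:
        model = m.copy()
        for p, xi in zip(params, x):
            v = math.exp(xi) if p.fieldname in _LOG_FIELDS else xi
            _set_param(model, p, v)
        return model

    best = {"x": np.array(x0), "score": None, "per": None}

    def objective(x):
        try:
            score, per = pooled(build(x))
        except (ValueError, ArithmeticError, OverflowError):
            return 1e6
        if best["score"] is None or score < best["score"]:
            best.update(x=np.array(x), score=score, per=per)
        return score

    initial_score, _ = pooled(build(x0))
    starts = [np.array(x0)]
    if spec.multistart > 0:
        rng = np.random.default_rng(spec.seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        for _ in range(spec.multistart):
            starts.append(rng.uniform(lo, hi))

    iterations = 0
    converged = False
    message = ""
    for start in starts:
        res = minimize(objective, start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": spec.max_iterations,
                                "ftol": spec.tolerance})
        iterations += int(res.nit)
        converged = converged or bool(res.success)
        message = str(res.message)

    if best["score"] is None or best["score"] > initial_score:
        best.update(x=np.array(x0), score=initial_score)
        _, per = pooled(build(x0))
        best["per"] = per
    fitted = build(best["x"])
    fitted.validate()
    return FitResult(model=fitted, score=float(best["score"]),
                     initial_score=float(initial_score),
                     per_protocol=list(best["per"]), iterations=iterations,
                     converged=converged, message=message)


def staged_fit(m: ModelSpec, stages: list[FitSpec], reference) -> FitResult:
    """Run ``fit`` stage by stage, carrying fitted parameters forward.

    Earlier-fitted reactions are frozen simply by not appearing in later
    stages' free parameter lists.  The final pooled score is reported over
    the union of all stages' protocols.
    """
    if not stages:
        raise ValueError("no stages given")
    model = m.copy()
    total_iter = 0
    converged = True
    for stage in stages:
        result = fit(model, stage, reference)
        model = result.model
        total_iter += result.iterations
        converged = converged and result.converged

    ht_names = sorted({ht for st in stages for ht, _ in st.readouts})
    per = []
    for stage in stages:
        traces = simulate_protocols(model, stage.protocols, ht_names,
                                    stage.dt_internal)
        refs = _resolve_reference(reference, stage)
        per.extend(nrms_score(ref, tr, stage.readouts)
                   for ref, tr in zip(refs, traces))
    pooled_score = float(np.mean(per))
    return FitResult(model=model, score=pooled_score,
                     initial_score=result.initial_score, per_protocol=per,
                     iterations=total_iter, converged=converged,
                     message="staged fit")
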