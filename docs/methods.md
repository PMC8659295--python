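# Methods

## The model form and its assumptions

A HillTau model is a feed-forward network of *reactions*, each defining
one output molecule. A reaction abstracts an arbitrary stretch of
chemistry into (i) a Hill-form steady state and (ii) an exponential
relaxation toward it. The steady-state forms are

- activation: `Yinf = gain * Yin * L^n / (KA^n + L^n)`
- inhibition: `Yinf = gain * Yin * (1 - L^n / (KA^n + L^n))`
- with a modifier M, `KA^n` is rescaled by
  `(1 + (M/Kmod)^h) / (1 + Amod * (M/Kmod)^h)` (inhibitory for Amod < 1,
  inert at Amod = 1),
- conversion (no ligand): `Yinf = gain * Yin^n / KA`.

Time evolution is the closed-form update

```
Y(t+dt) = Y(t) + (Yinf - (Y(t) - baseline)) * (1 - exp(-dt/tau))
```

so the asymptote is `Yinf + baseline` and the update is exact for any
`dt` while inputs are constant. Distinct rise (`tau`) and fall (`tau2`)
time constants are supported; the engine selects between them by
comparing `Yinf + baseline` against the current value. (The alternative
reading — comparing `Yinf` alone against `Y(t)` — differs when
`baseline > 0` and `Y` lies between `Yinf` and `Yinf + baseline`; the
chosen rule keeps the rise/fall decision consistent with the actual
asymptote.)

The form is justified by the algebra of common signaling motifs: a
Michaelis–Menten stage with a first-order back reaction has steady state
`E*S*kcat/((Km+S)*Kr)`, and a cascade of binding steps collapses to a
single Hill function with composite parameters
`KA_x = KA1*KA2/(R1+KA2)`, `R_x = R1*R2/(R1+KA2)`; a single binding step
settles exponentially with `tau = 1/(L*Kf + Kb)`. The package's
mass-action integrator (`hilltau.massaction`) exists to check exactly
these reductions and to generate reference traces for the reduction
optimizer. Key assumptions inherited from the form: the network is
feed-forward at the level of a single reaction (substrates are not
depleted by downstream consumers), one step of each lumped cascade is
rate-limiting, and `tau`/`tau2` are constants even though the underlying
binding time constant depends on ligand concentration.

Equation nodes (`Yinf = f(Y1, Y2, ...)`) cover non-chemical couplings
such as weighted summation. They are evaluated instantaneously (no
relaxation) each internal step, after the reactions of shallower layers:
the algebraic form defines a steady state only, and attaching a time
constant to it would duplicate what a reaction already provides.
Negative equation results are clamped to zero with a logged warning,
since all quantities are concentrations. The expression grammar is a
strict whitelist (literals, names, `+ - * / **`, unary minus,
`exp/log/pow/min/max`) parsed against the model's namespace; nothing is
ever evaluated as host code.

## Scheduling and feedback

Plain species are layer 0. Each reaction or equation is assigned the
layer one deeper than its deepest dependency (equal to the longest
dependency path on acyclic graphs), so within an update step every node
reads already-updated upstream values. Cycles are broken
deterministically: the earliest-defined unresolved node (model
definition order — the reason reaction order is part of the format's
semantics) is assigned the next layer after the current deepest, its
unresolved input edges are severed, and layering resumes, repeating for
further loops. Severed dependencies read the previous internal step's
value — an explicit one-step delay that vanishes as the internal step
shrinks. No attempt is made at minimum-feedback-arc optimality; the
definition-order heuristic is the contract.

## Time stepping, steady states, dose responses

The internal step defaults to `min(tau)/10` over all reactions (a
user-overridable choice; feedback loops need steps below the loop's
smallest tau, and a factor of 10 gives ~0.1% accuracy on the packaged
feedback fixture at a 1 s step). Because the per-reaction update is
closed-form, accuracy is limited only by cascade/feedback coupling, and
trajectories converge first-order in the internal step to the ODE limit
`dY/dt = (Yinf + baseline - Y)/tau`. For oscillators this convergence
is measured over the onset window: over many cycles a small phase drift
accumulates and dominates any pointwise norm even when amplitude and
period are accurate.

Steady states are computed by settling for `settle_time` (default
`100 * max(tau)`) subdivided into exactly 10 equal steps. For
feed-forward models the first step already lands on the fixed point; the
10 subdivisions give feedback loops 10 fixed-point iterations, so for
cyclic models the result is accurate to the loop's contraction rate to
the 10th power (typically <0.5% on the packaged fixtures) rather than to
machine precision. Dose responses clamp the input, settle per dose, and
by default carry the settled state from one dose to the next — this is
what exposes hysteresis in bistable systems; a `carry_over=False` flag
re-initializes per dose instead.

Initial conditions: plain species use `concInit`; reaction outputs
default to `Yinf + baseline` evaluated layer by layer at the initial
upstream values. An explicit per-reaction `concInit` overrides the
fallback (the format places `concInit` on the reaction because output
names may not appear in the species map).

## Units

Concentrations are authored in one of M/mM/uM/nM; mM is the canonical
internal unit and `canonicalize_units` rescales every
concentration-typed field uniformly. The conversion form
`Yin^n / KA` is not dimensionally homogeneous (it is inherited as-is
from the formalism), so models containing conversion reactions should be
authored in the unit they are simulated in; unit conversion of such
models rescales their dynamics.

## Model reduction (MASH)

`nrms_score` is root-mean-square difference divided by the reference
range (`max - min`), averaged over readouts and protocols; a flat
reference falls back to `max(|ref|)`, then to absolute RMS. Range
normalization was chosen over max- or mean-normalization so that "score
0.05 = 5% average deviation" reads directly against step-like responses;
other normalizations would shift printed percentages by tenths.

`fit` performs bounded L-BFGS-B over the selected (reaction, field)
parameters, with positive-definite fields (KA, tau, tau2, gain, Kmod,
Amod) searched in log space — the scales across realistic models span
orders of magnitude and log-transforming keeps the optimizer
conditioned. Default bounds are two decades either side of the initial
value. The best evaluation seen is tracked, so the returned score is
never worse than the initial model's even if the optimizer fails; a
seeded multistart is available for rugged landscapes (oscillators).
`staged_fit` runs stages in sequence, carrying fitted values forward;
freezing is expressed simply by which parameters later stages leave out.
Note that after loading, `tau2` always holds a concrete value (the
default fill is `tau2 = tau`), so freeing `tau` alone does not drag
`tau2` along — free both when they should track.

Initial parameter guesses follow the usual heuristics: KA near the
half-maximum of the activation curve, tau from the observed time course.

## Export

The ODE (rate-rule) interpretation uses `tau` only: SBML and general ODE
solvers cannot switch time constants on the sign of the derivative, so
every reaction with `tau2 != tau` exports with an attached warning (and
an SBML notes entry) and its falling phases are approximate. Baseline is
handled by shifting the relaxation target to `Yinf + baseline`. SBML is
emitted as Level 3 Version 2 with rate rules rather than kinetic-law
reactions, because HillTau outputs are not conserved-mass species;
boundary species are exported constant, equations as assignment rules,
and the rule math as content MathML. DOT output encodes each edge's role
(reagent, activator, inhibitor, modifier, equation argument) both as a
visual style and as an explicit `role` attribute, so the full topology
is machine-recoverable from the text.

## Packaged fixtures and what they do (and do not) show

The example models carry the package's own parameter choices, selected
once so each motif exhibits its defining behaviour, with concentrations
on the 0.1–1 uM scale and time constants of 0.5–20 s typical of
post-synaptic signaling:

- `feedback_inhibition` — 3 molecules, 2 reactions: output driven by the
  input reagent and inhibited by a feedback conversion of itself;
  produces the adapting transient. A companion 5-species mass-action
  network (3 enzyme steps) is packaged as the reduction reference.
- `bistable` — mutual activation of `fb` (baseline 0.1 uM, KA 0.4, n 2)
  and `output` (KA 0.9, n 2) with the buffered `stim` as a modifier
  (Kmod 0.5, Amod 20, h 2) on the output reaction. At the resting
  stim of 0.13 uM the effective KA sits mid-way inside the bistable
  window (analysis of the composed Hill map gives bistability for
  effective KA between ~0.45 and ~0.75 uM); saturating stim pushes it
  below the window (only the high state remains) and stim = 0 above it
  (only the low state), which is what makes transient switching in both
  directions possible.
- `oscillator` — a three-reaction negative-feedback relaxation
  oscillator (two fast stages, tau 2 s; one slow feedback stage, tau
  20 s; n = 6 throughout) with sustained ~11 s period oscillations.
- `bcm` — a high-affinity phosphatase (KA 0.1 uM, n 2) inhibiting the
  receptor readout and a low-affinity kinase (KA 2 uM, n 4) that
  weakens that inhibition via an Amod = 0.01 modifier; moderate calcium
  depresses the readout below its resting value, strong calcium
  potentiates it above. The kinase's slow falling time constant
  (tau2 = 20 s) makes brief strong stimuli potentiate transiently.

Passing tests on these fixtures demonstrate the formalism's mechanics —
layering, feedback breaking, closed-form accuracy, reduction — on
networks *designed* to be cleanly bistable/oscillatory/U-shaped. They do
not show that fitted reductions of arbitrary real pathways reach any
particular accuracy: real mass-action systems add implicit couplings
(enzyme sequestration, substrate depletion) that the feed-forward form
can only capture through explicit extra reactions.

## Numerical choices and limitations

- Internal step `min(tau)/10`; steady-state settling `100*max(tau)` in
  10 steps; ODE oracle: LSODA at rtol 1e-8 (1e-10 in cross-checks).
- Problem sizes in the shipped tests and the acceptance script are
  desk-scale by design: ≤10-node random graphs (500 draws) for the
  scheduler oracle, 1000 random draws for the Hill identities, 20
  recovery trials on a 2-reaction cascade, single-protocol reductions of
  the 5-species reference network.
- Rise/fall switching at `Yinf + baseline` (see above); negative
  equation outputs clamped at 0; events at a sample time are applied
  before the sample is recorded.
- Stochasticity and diffusion are out of scope, as is minimum-arc
  feedback breaking, SBML *import*, and automated topology search: the
  reduction optimizer tunes parameters of a user-supplied topology only.
- The conversion form applies `gain` as a plain multiplier (default 1
  reproduces the bare `Yin^n / KA` form); this is a package extension
  for symmetry with the other forms.
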