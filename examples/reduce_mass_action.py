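"""Model reduction (MASH): fit a 2-reaction HillTau model to a
mass-action feedback-inhibition network.

The reference is a 5-species / 3-enzyme-step mass-action model simulated
with the built-in stiff ODE integrator.  MASH tunes the HillTau
parameters (L-BFGS-B over log-transformed values) to minimize the
normalized RMS difference of the output trace; a score of 0.05 means 5%
average deviation relative to the response range.
"""

import hilltau as ht

net = ht.load_network(open(ht.example_model_path(
    "feedback_inhibition_massaction"), encoding="utf-8").read())
protocol = ht.make_protocol("step", species="input", value=1.0, onset=10.0,
                            offset=50.0, runtime=100.0, sample_dt=1.0)
reference = ht.simulate(net, events=list(protocol.events),
                        runtime=protocol.runtime,
                        sample_dt=protocol.sample_dt)

model = ht.example_model("feedback_inhibition")
free = [ht.FitParam(rxn, f, getattr(model.reactions[rxn], f) / 100,
                    getattr(model.reactions[rxn], f) * 100)
        for rxn in ("output", "fb") for f in ("KA", "tau", "gain")]
free += [ht.FitParam("output", "tau2", 0.1, 1000.0),
         ht.FitParam("output", "n", 0.2, 8.0)]
spec = ht.FitSpec(free_params=free, protocols=[protocol],
                  readouts=[("output", "output")])
result = ht.fit(model, spec, [reference])

print(f"initial score: {result.initial_score:.4f} "
      f"({100 * result.initial_score:.1f}% NRMS)")
print(f"final score:   {result.score:.6f} "
      f"({100 * result.score:.3f}% NRMS)")
print("\nfitted reactions:")
for name, r in result.model.reactions.items():
    print(f"  {name}: KA={r.KA:.3g} uM, tau={r.tau:.3g} s, "
          f"tau2={r.tau_fall:.3g} s, gain={r.gain:.3g}, n={r.n:.3g}")
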