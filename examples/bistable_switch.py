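"""Drive the bistable switch through its full stimulus protocol.

Two mutually activating reactions (fb and output) form the switch; the
buffered molecule stim modulates the output reaction's sensitivity.
Weak pulses leave the state unchanged; a strong excitatory pulse flips
it on, and a strong inhibitory pulse (stim pulled to zero) flips it off.
"""

import hilltau as ht

model = ht.example_model("bistable")
rest = 0.13  # resting stim level of the fixture
events = [
    ht.Event(20, "stim", 0.2),  ht.Event(25, "stim", rest),   # weak +
    ht.Event(40, "stim", 2.0),  ht.Event(48, "stim", rest),   # strong +
    ht.Event(60, "stim", 0.05), ht.Event(65, "stim", rest),   # weak -
    ht.Event(80, "stim", 0.0),  ht.Event(95, "stim", rest),   # strong -
]
trace = ht.run_program(model, ht.StimulusProgram(events=events, runtime=140,
                                                 sample_dt=1.0))
y = trace.series["output"]
print("output before any stimulus (t=18):   %.4f uM" % y[18])
print("after weak excitatory pulse (t=38):  %.4f uM  (no switch)" % y[38])
print("after strong excitatory pulse (t=55): %.4f uM  (switched ON)" % y[55])
print("after weak inhibitory pulse (t=78):  %.4f uM  (stays ON)" % y[78])
print("after strong inhibitory pulse (t=139): %.4f uM  (switched OFF)" % y[-1])

low = ht.solve_steady_state(model)
seed = ht.SimState(0.0, dict(low))
seed.conc.update(output=1.0, fb=1.0)
high = ht.solve_steady_state(model, state=seed)
print("\nstable states: low = %.4f uM, high = %.4f uM"
      % (low["output"], high["output"]))
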