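"""Simulate a single binding step under a two-level stimulus.

The model is one HillTau reaction: output relaxes toward
mol * L / (KA + L) with tau = 1 s.  The ligand L is stepped to 1 uM at
t = 0 and down to 0.2 uM at t = 10 s; the output approaches each Hill
steady state (0.667 then 0.286 uM) exponentially.
"""

import hilltau as ht

model = ht.example_model("binding")
program = ht.StimulusProgram(
    events=[ht.Event(0.0, "L", 1.0), ht.Event(10.0, "L", 0.2)],
    runtime=20.0, sample_dt=1.0)
trace = ht.run_program(model, program, record=["L", "output"])

print("time(s)  L(uM)   output(uM)")
for t, L, y in zip(trace.axis, trace.series["L"], trace.series["output"]):
    print(f"{t:6.1f}  {L:5.2f}  {y:9.4f}")
print()
print("plateau at L=1.0 uM should be 1/(0.5+1)   =", 1 / 1.5)
print("plateau at L=0.2 uM should be 0.2/(0.5+0.2) =", 0.2 / 0.7)
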