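"""Steady-state dose response of the bidirectional-plasticity (BCM) motif.

A high-affinity phosphatase and a low-affinity kinase compete for the
synaptic receptor readout: moderate calcium depresses it below the
resting level, strong calcium potentiates it above -- the classic
U-shaped plasticity curve.
"""

import numpy as np

import hilltau as ht

model = ht.example_model("bcm")
rest = ht.solve_steady_state(model)["synAMPAR"]
doses = np.logspace(-2, 1, 13)
trace = ht.dose_response(model, "Ca", doses, "synAMPAR", carry_over=False)

print(f"resting synAMPAR (Ca = 0.08 uM): {rest:.3f} uM\n")
print(" Ca (uM)   synAMPAR (uM)  vs rest")
for d, v in zip(trace.axis, trace.series["synAMPAR"]):
    tag = "depressed" if v < 0.9 * rest else (
        "potentiated" if v > 1.1 * rest else "~rest")
    print(f"{d:8.3f}   {v:10.3f}    {tag}")
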