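"""Relaxed linking-number densities of the alternative DNA forms.

Each structural state has its own helical repeat and handedness; relative to
B-DNA this shifts the torsionally relaxed linking number per base pair,
which is what couples the states to an applied torque.
"""

from twlc import ParamTable

table = ParamTable.default()
print("state   h (bp/turn)  handedness   dlk0 vs B (turns/bp)")
for state in "BLPS":
    s = table[state]
    print(f"  {state}        {s.h:5.1f}        {s.handedness:+d}        "
          f"{table.relaxed_linking_density(state):+.3f}")
print()
print("Large |dlk0| (L and P) means strong stabilisation by torque; the")
print("small value for S is why S-DNA only appears under high tension.")
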