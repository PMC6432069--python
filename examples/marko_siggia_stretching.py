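"""Worm-like-chain force-extension: closed form vs transfer matrix.

Computes the relative extension of torsionless B-DNA from the exact
discretised transfer matrix and compares it with the Marko-Siggia
interpolation formula at the same persistence length (50 nm).
"""

from twlc import ChainSpec, Constraint, ParamTable, TruncationOrder
from twlc import marko_siggia_extension
from twlc.tmatrix import single_state_observables

table = ParamTable.default()
chain = ChainSpec(n_bp=10000, q=1.5)
trunc = TruncationOrder(kmax=24)

print(" f (pN)   z/L transfer-matrix   z/L Marko-Siggia")
for f_pn in (0.25, 0.5, 1.0, 2.0, 5.0, 10.0):
    con = Constraint.from_pn(f_pn, 0.0)
    z = single_state_observables(table["B"], chain, con, trunc)["z"]
    print(f" {f_pn:5.2f}        {z / chain.contour_length_b:6.4f}            "
          f"{marko_siggia_extension(con.f, 50.0):6.4f}")
print()
print("The interpolation is excellent above ~0.5 pN; at lower forces it")
print("underestimates the extension by a few percent (a known property of")
print("the interpolation, not of the chain model).")
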