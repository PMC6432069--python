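"""Metropolis Monte-Carlo sampling of a stretched, twisted chain.

Samples a 600 bp B-DNA chain at 2 pN and +5 pN nm and prints the ensemble
averages with batch-means errors.  The torque couples to the exact Gauss
writhe, making this an independent check of the transfer-matrix model.
"""

from twlc import ChainSpec, Constraint, MCConfig, metropolis_sample

chain = ChainSpec(n_bp=600, q=1.5)
con = Constraint.from_pn(2.0, 5.0)
cfg = MCConfig(n_steps=60_000, burn_in=20_000, thin=20, seed=1)
stats = metropolis_sample(chain, con, config=cfg)

L = chain.contour_length_b
print(f"extension  <z>/L = {stats.mean_ext / L:.4f} +- {stats.stderr_ext / L:.4f}")
print(f"twist      <Tw>  = {stats.mean_tw:+.3f} +- {stats.stderr_tw:.3f} turns")
print(f"writhe     <Wr>  = {stats.mean_wr:+.3f} +- {stats.stderr_wr:.3f} turns")
print(f"linking    <DLk> = {stats.mean_dlk:+.3f} +- {stats.stderr_dlk:.3f} turns")
print(f"acceptance: {({k: round(v, 2) for k, v in stats.acceptance.items()})}")
print()
print("Positive torque overwinds the chain: <DLk> > 0, split between elastic")
print("twist and a small positive writhe. At -5 pN nm both change sign.")
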