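# Methods

## Model

`twlc` treats double-stranded DNA as an inextensible, twistable worm-like
chain discretised into N straight segments of length `b_u = q * rise_u`
(`q` base pairs per segment, default `q = 1.5`; B-form rise 0.33 nm/bp).
Each segment is a rigid body whose orientation is a z-y-z Euler rotation
`R = Rz(alpha) Ry(beta) Rz(gamma)` of the laboratory frame; the tangent is
`t = R z0` and the force acts along `+z0`.  Energies are in kBT; a force f
therefore carries units kBT/nm and a torque tau units of kBT (conversions to
pN and pN nm use kB T with T = 298.15 K by default — the model itself never
needs an absolute temperature).

The conformational energy of a chain is

    E = sum_n (a_u/2) |t_{n+1} - t_n|^2  +  sum_n (c_u/2) (2 pi DTw_n)^2
        - f d_z - 2 pi tau DLk + sum_n q mu_u ,

with `a_u = Lp(u)/b_u`, `c_u = Ltw(u)/b_u`, `DTw_n = ([u_n x u_{n+1}] .
t_n)/2pi` the local twist number, `d_z` the end-to-end extension and `DLk =
Tw + Wr + sum_n q dlk0(u_n)` the linking-number change relative to
torsionally relaxed B-DNA.  Four structural states are supported — B
(reference), L (left-handed), P (overwound) and S (overstretched) — each
with its own persistence lengths, contour ratio, helical repeat/handedness
(hence `dlk0(u) = handedness_u/h_u - 1/h_B`), base-pairing penalty `mu_u`
and torque-split weight `lambda_u`.  The packaged defaults give
`dlk0 = -0.159 (L), +0.237 (P), -0.068 (S)` turns/bp.

Two independent routes compute equilibrium observables:

1. **Metropolis Monte Carlo** (`twlc.mc`) samples single-state (B) chains
   from `exp(-E)` with the torque coupled to the *exact* Gauss double-sum
   writhe.  Moves: crankshaft (sub-chain rotation about a chord), tail and
   head pivots (rigid end-block rotations about a vertex — both ends are
   needed: with tail pivots alone the head orientations are quasi-frozen,
   which biases the extension), and local twist; all preserve segment
   lengths and orthonormality exactly.  Writhe updates are incremental: a rigid block move changes only
   moved-static segment-pair terms, evaluated with a jit-compiled exact
   two-segment solid-angle kernel (O(m(N-m)) per move).  At tau = 0 the
   writhe drops out of the Boltzmann weight and is only measured on
   snapshots.  Chains start straight, pre-twisted at the mean-field twist
   angle `asin(tau/c)`; runs are bit-reproducible given a seed.

2. **Transfer matrix** (`twlc.tmatrix` / `twlc.multistate`) evaluates
   `Z = Tr(S^{N-1} V)` in the basis of Wigner D-function harmonics.  Because
   the Gauss writhe is non-local, the torque coupling uses Fuller's
   single-sum linking form split by the per-state weight lambda:
   `-2 pi tau DLk -> -tau (2 pi - lambda) DLk_F - tau lambda DTw`,
   where `DLk_F^n = (d alpha~ + d gamma~)/2 pi` is the per-junction Fuller
   linking increment built from unwrapped Euler angles.  lambda is the knob
   the model's authors calibrated against the measured buckling boundary; it
   is a fixed per-state input here, not re-fitted.

## Topology

* Gauss writhe: double sum of exact mutual solid angles of straight segment
  pairs (validated against adaptive 2-D quadrature of the Gauss integrand to
  1e-6).  Adjacent pairs vanish identically and are skipped; coplanar pairs
  are detected and contribute exactly zero (their naive sign factor is
  ill-conditioned).  Open chains use the open double sum, no artificial
  closure.
* Fuller writhe: `Wr_F = DLk_F - Tw` from unwrapped angles; an error is
  raised when a tangent points along `-z0` (the Fuller integrand diverges
  there).  Test fixtures confirm the textbook behaviour: agreement with
  Gauss to <1% on solenoids embedded in an extended chain, qualitative
  failure (including sign) on interwound plectoneme braids.

## The transfer matrix in detail

The matrix elements combine squared Wigner 3-j symbols (exact integer
arithmetic via Racah's formula, cached per magnetic index), bilateral
Laplace transforms `L_r^k(s)` of diagonal Wigner-d elements (Gauss–Legendre
quadrature of the Jacobi-polynomial closed form), and modified Bessel
functions.  Numerically the `e^{-a}` / `e^{-c}` prefactors are folded into
the Laplace tables and scaled Bessel products (`ive`), so a ~ 100 and
c ~ 200 pose no dynamic-range problems; matrix powers run with per-squaring
rescaling and log accumulation.

The N=2 partition function was verified against direct quadrature of the
junction weight

    T = exp[ -a (1 - t.t') - c (1 - cos psi) + b f cos beta
             + (tau lambda / 2 pi) sin psi
             + tau (1 - lambda/2 pi) sin(d alpha + d gamma) ] ,

i.e. the cosine/sine small-angle forms of the discrete energies; this is
the precise discrete model the harmonic expansion implements (the chain
energy module keeps the quadratic/cross-product forms; the two
agree to O(angle^3), far below thermal accuracy at the default
discretisation where typical angles are ~ a^-1/2 ~ 0.1).

**Four-state block structure.**  Each state's matrix is weighted by
`exp(-q(mu_u - 2 pi tau dlk0(u)))`.  The block matrix with identical row
blocks collapses exactly onto the single k-space operator
`S_tot = sum_u w_u S_u` (proved by the block algebra, asserted against the
literal block trace in tests), which makes the four-state model as cheap as
one state.

**Observables.**  Extension is `d ln Z / d f` (central differences,
optional Richardson step).  Occupancies are `-(1/q) d ln Z / d mu_u`
(central differences that only re-weight cached matrices); they sum to one
identically.  The linking number is estimated as

    DLk = (1/2 pi) d ln Z / d eps |_{chi fixed}  +  n_bp sum_u phi_u dlk0(u) ,

where eps shifts the linking-channel Bessel argument `tau (1 -
lambda_u/2pi)` uniformly across states while the twist-channel quantities
(chi, omega, the `I_r(c sqrt(1+chi^2))` argument) stay fixed.  This is the
constant-chi derivative normalised per unit of the linking coefficient, so
the estimator equals the thermal mean of the Fuller linking increments plus
the structural (occupancy-weighted) helicity term.  Without the
normalisation the derivative returns `(1 - lambda/2pi) <DLk_F>` — about a
third of the physical linking change at lambda = 4.3 — which would
contradict the Monte-Carlo oracle; the normalised form agrees with MC
within statistical error below buckling.

**Truncation.**  All angular indices are bounded by `kmax`; the magnetic
index r is cut where the Bessel coefficient product falls below 1e-13 of
its r=0 value.  `kmax = 30` is converged (relative changes < 1e-7 under
near-doubling) for forces up to ~100 pN; the 120 pN / 60 pN nm corner of
the phase diagram needs `kmax = 40`.  Defaults: 10 kbp chains, `q = 1.5`;
by extensivity z/L, sigma and occupancies are insensitive to length once
L >> Lp, which the test suite checks via the linear growth of ln Z.

## Known limitations

* **Post-buckling winding branch.**  At fixed torque the Fuller-form
  coupling rewards conformations whose tangents wind tightly around the
  `-z0` pole (the `1/(1 + t.z0)` divergence of Fuller's integrand).  The
  lambda split tames this up to the buckling boundary — indeed the
  extension collapse it produces at, e.g., 0.3 pN sits at 10–12 pN nm,
  exactly where the calibrated model should buckle — but beyond the
  boundary the dominant configurations have strongly negative extension
  rather than the ~zero extension of physical plectonemes.  Boundary
  *locations* (50% occupancy, 50% extension drop) are meaningful;
  post-buckling extension *values* are not.  This is intrinsic to the
  single-writhe model, kmax-converged (checked to kmax = 60), and
  regularised only by the finite segment length.
* One consequence: the +-tau extension symmetry of torque-extension
  profiles at low force holds only while both signs stay in the achiral
  B/sc-B regime.  Because the L state takes over near -11 pN nm at
  essentially all forces, and the collapsed sc-branches of different states
  have different (negative) extensions, the computed profiles develop >5%
  asymmetry within |tau| <= 25 pN nm even at 0.1 pN, not only above
  ~0.5 pN as the visible B-to-L step on extension curves would suggest.
* The Marko–Siggia interpolation deviates from the exact worm-like chain by
  several percent in extension around f Lp ~ kBT; the transfer matrix
  (which is exact for the discrete chain) reproduces it to 2% only above
  ~0.3 pN.  This is a property of the interpolation formula, documented in
  the WLC literature, and shows up as an honest failure of the 2% check at
  0.1 pN.
* Monte Carlo treats the chain as a phantom chain by default (no excluded
  volume; strand passage allowed).  A hard-core diameter screen is
  available but off, since the torque-ensemble model itself does not forbid
  strand passage.
* Sequence dependence, DNA stretch modulus, protein binding and the
  fixed-linking-number ensemble are out of scope.

## Test and acceptance problem sizes

Monte-Carlo cross-checks run scaled-down by design: 250 bp for the
MC-vs-transfer-matrix comparison at f = 2 pN, tau = +-5 pN nm; 600 bp for
the torsionless Marko–Siggia check; 90–150 bp for symmetry and bookkeeping
tests.  Statistical errors are batch means over
autocorrelation-decimated series (>= 20 batches).  Transfer-matrix results
in tests and the acceptance script use 10 kbp chains at `kmax = 30`
(`kmax = 40` for the high-force S-transition scan).
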