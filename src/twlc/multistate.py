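"""Four-state (B/L/P/S) block transfer matrix: structural transitions of DNA.

Each segment of the discretised chain carries a structural state u with its
own stiffnesses (a_u, c_u), segment length b_u, torque split lambda_u, and a
statistical weight per segment

    w_u(tau) = exp( -q * (mu_u - 2 pi tau dlk0(u)) ) ,

where mu_u is the base-pairing free energy per bp relative to B and dlk0(u)
the relaxed linking-number density difference.  The partition function is

    Z(f, tau) = Tr( U Shat^{N-1} Vhat ) ,

with Shat the 4x4 block matrix whose row-u blocks all equal w_u S_u, Vhat
the block column of w_u V(b_u), and U a block row of identity matrices.
Because every block row of Shat is constant across block columns, the block
trace collapses exactly onto a single k-space operator

    S_tot = sum_u w_u S_u ,      Z = ( S_tot^{N-1} sum_u w_u V_u )[0] ,

which is how it is evaluated here (the literal block form is kept for
cross-checks).  Observables follow by numerical differentiation of ln Z:

* extension        z = d ln Z / d f                                  (nm)
* occupancy        N_u = -(1/q) d ln Z / d mu_u                      (segments)
* linking change   DLk = (1/2pi) d ln Z / d eps  +  n_bp * sum_u phi_u dlk0(u)

where eps uniformly shifts the linking-channel Bessel argument
tau (1 - lambda_u/2pi) of every state (the constant-chi prescription: the
twist-channel factors chi, omega and I_r(c sqrt(1+chi^2)) are held fixed),
normalised so the estimator equals the thermal mean of the per-junction
Fuller linking increments; phi_u are the occupancy fractions supplying the
structural part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .energy import marko_siggia_extension
from .model import ChainSpec, Constraint, ParamTable, kbt_pn_nm
from .special import TruncationOrder
from .tmatrix import (
    PartitionResult,
    TorqueParams,
    mat_power_vec,
    s_matrix,
    single_state_log_partition,
    spectral_gap,
    v_vector,
)

__all__ = [
    "PhasePoint",
    "MultistateEngine",
    "block_partition",
    "occupancy",
    "observables",
    "response_curves",
    "phase_diagram",
    "occupancy_boundary_tau",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhasePoint:
    """One (force, torque) point of a response curve or phase grid."""

    f_pn: float
    tau_pn_nm: float
    z_over_lb: float
    dlk: float
    sigma: float
    occupancy: Dict[str, float]
    dominant: str
    supercoiled: bool

    def row(self) -> dict:
        d = {
            "f_pN": self.f_pn,
            "tau_pNnm": self.tau_pn_nm,
            "z_over_L": self.z_over_lb,
            "dLk": self.dlk,
            "sigma": self.sigma,
            "dominant": self.dominant,
            "supercoiled": self.supercoiled,
        }
        for u, frac in self.occupancy.items():
            d[f"occ_{u}"] = frac
        return d


class MultistateEngine:
    """Caches the per-state transfer matrices at one (f, tau, eps) point.

    Base-pairing energy shifts only rescale the per-state weights, so
    occupancy derivatives reuse the cached matrices at no extra cost.
    """

    def __init__(
        self,
        table: ParamTable,
        chain: ChainSpec,
        constraint: Constraint,
        trunc: TruncationOrder,
        eps_link: float = 0.0,
    ):
        chain.validate_against(table)
        self.table = table
        self.chain = chain
        self.constraint = constraint
        self.trunc = trunc
        self.eps_link = eps_link
        self._S: Dict[str, np.ndarray] = {}
        self._v: Dict[str, np.ndarray] = {}
        self._log_w: Dict[str, float] = {}
        self.imag_residual = 0.0
        for u, st in table.items():
            a, c = chain.dimensionless_stiffness(st)
            b = chain.segment_length(st)
            tp = TorqueParams(tau=constraint.tau, lam=st.lam, c=c)
            S, res = s_matrix(
                a, b, c, st.lam, constraint.f, constraint.tau, trunc,
                tau_link=tp.tau_link + eps_link,
            )
            self._S[u] = S
            self._v[u] = v_vector(b, constraint.f, trunc)
            self._log_w[u] = -chain.q * (
                st.mu - TWO_PI * constraint.tau * table.relaxed_linking_density(u)
            )
            self.imag_residual = max(self.imag_residual, res)

    # ------------------------------------------------------------------
    def weights(self, dmu: Dict[str, float] | None = None) -> Dict[str, float]:
        dmu = dmu or {}
        return {
            u: math.exp(self._log_w[u] - self.chain.q * dmu.get(u, 0.0))
            for u in self._S
        }

    def log_z(self, dmu: Dict[str, float] | None = None, with_gap: bool = False) -> PartitionResult:
        w = self.weights(dmu)
        S_tot = sum(w[u] * self._S[u] for u in self._S)
        v_tot = sum(w[u] * self._v[u] for u in self._S)
        n = self.chain.n_segments
        vec, log_scale = mat_power_vec(S_tot, n - 1, v_tot)
        z0 = vec[0]
        if z0 <= 0:
            raise FloatingPointError("block partition trace non-positive; increase kmax")
        return PartitionResult(
            log_z=log_scale + math.log(z0),
            kmax=self.trunc.kmax,
            imag_residual=self.imag_residual,
            n_segments=n,
            spectral_gap=spectral_gap(S_tot) if with_gap else None,
        )

    def occupancies(self, h_mu: float = 1e-3) -> Dict[str, float]:
        """Fractions N_u / N via central differences in each mu_u.

        The derivative step only reweights cached matrices.  Fractions are
        clipped to [0, 1]; their sum equals 1 up to derivative error.
        """
        n = self.chain.n_segments
        frac = {}
        for u in self._S:
            lp = self.log_z({u: +h_mu}).log_z
            lm = self.log_z({u: -h_mu}).log_z
            nu = -(lp - lm) / (2.0 * h_mu * self.chain.q)
            frac[u] = min(max(nu / n, 0.0), 1.0)
        total = sum(frac.values())
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise FloatingPointError(f"occupancies sum to {total}, not 1")
        return {u: frac[u] / total for u in frac}


def block_partition(
    table: ParamTable,
    chain: ChainSpec,
    constraint: Constraint,
    trunc: TruncationOrder,
    *,
    eps_link: float = 0.0,
    with_gap: bool = False,
) -> PartitionResult:
    """ln Z of the four-state block transfer matrix (collapsed evaluation)."""
    return MultistateEngine(table, chain, constraint, trunc, eps_link).log_z(with_gap=with_gap)


def literal_block_partition(
    table: ParamTable,
    chain: ChainSpec,
    constraint: Constraint,
    trunc: TruncationOrder,
) -> PartitionResult:
    """ln Z evaluated from the literal block matrices (cross-check path).

    Builds the full (n_states*K) x (n_states*K) block matrix with repeated
    row blocks, the block boundary column and the block-row of identities,
    exactly as the formalism is written, and evaluates the trace.  Used to
    validate the collapsed evaluation on small problems.
    """
    eng = MultistateEngine(table, chain, constraint, trunc)
    w = eng.weights()
    states = list(eng._S)
    K = trunc.kmax + 1
    m = len(states)
    Shat = np.zeros((m * K, m * K))
    for i, u in enumerate(states):
        block = w[u] * eng._S[u]
        for j in range(m):
            Shat[i * K : (i + 1) * K, j * K : (j + 1) * K] = block
    Vhat = np.zeros((m * K, K))
    for i, u in enumerate(states):
        Vhat[i * K : (i + 1) * K, 0] = w[u] * eng._v[u]
    n = chain.n_segments
    # Tr(U Shat^{N-1} Vhat) with U the block row of identities
    cur = Vhat
    log_scale = 0.0
    power = n - 1
    base = Shat
    base_log = 0.0
    while power > 0:
        if power & 1:
            cur = base @ cur
            log_scale += base_log
            nrm = np.max(np.abs(cur))
            cur /= nrm
            log_scale += math.log(nrm)
        power >>= 1
        if power:
            base = base @ base
            base_log *= 2.0
            nrm = np.max(np.abs(base))
            base /= nrm
            base_log += math.log(nrm)
    tr = 0.0
    for i in range(m):
        tr += np.trace(cur[i * K : (i + 1) * K, :])
    return PartitionResult(
        log_z=log_scale + math.log(tr),
        kmax=trunc.kmax,
        imag_residual=eng.imag_residual,
        n_segments=n,
    )


def occupancy(
    table: ParamTable,
    chain: ChainSpec,
    constraint: Constraint,
    trunc: TruncationOrder,
) -> Dict[str, float]:
    """Per-state occupancy fractions N_u / N at one (f, tau) point."""
    return MultistateEngine(table, chain, constraint, trunc).occupancies()


def observables(
    table: ParamTable,
    chain: ChainSpec,
    constraint: Constraint,
    trunc: TruncationOrder,
    *,
    rel_step: float = 1e-3,
    need_dlk: bool = True,
    need_occupancy: bool = True,
) -> PhasePoint:
    """Extension, linking number, superhelical density and occupancies."""
    center = MultistateEngine(table, chain, constraint, trunc)
    occ = center.occupancies() if (need_occupancy or need_dlk) else {}

    hf = max(abs(constraint.f) * rel_step, 1e-4)
    f0 = constraint.f
    lzp = MultistateEngine(table, chain, dc_replace(constraint, f=f0 + hf), trunc).log_z().log_z
    lzm = MultistateEngine(
        table, chain, dc_replace(constraint, f=max(f0 - hf, 0.0)), trunc
    ).log_z().log_z
    z = (lzp - lzm) / (hf + min(hf, f0))

    dlk = float("nan")
    sigma = float("nan")
    if need_dlk:
        he = 1e-3
        lp = MultistateEngine(table, chain, constraint, trunc, eps_link=+he).log_z().log_z
        lm = MultistateEngine(table, chain, constraint, trunc, eps_link=-he).log_z().log_z
        dlk_elastic = (lp - lm) / (2.0 * he) / TWO_PI
        dlk_structural = chain.n_bp * sum(
            occ[u] * table.relaxed_linking_density(u) for u in occ
        )
        dlk = dlk_elastic + dlk_structural
        sigma = dlk / chain.lk0_b(table)

    dominant = max(occ, key=occ.get) if occ else "B"
    z_over_lb = z / chain.contour_length_b
    supercoiled = False
    if occ:
        st = table[dominant]
        z_wlc = marko_siggia_extension(constraint.f, st.Lp) * st.contour_ratio
        supercoiled = bool(z_over_lb < 0.5 * z_wlc)
    return PhasePoint(
        f_pn=constraint.f_pn,
        tau_pn_nm=constraint.tau_pn_nm,
        z_over_lb=z_over_lb,
        dlk=dlk,
        sigma=sigma,
        occupancy=occ,
        dominant=dominant,
        supercoiled=supercoiled,
    )


def response_curves(
    mode: str,
    fixed_value: float,
    sweep: Sequence[float],
    table: ParamTable | None = None,
    chain: ChainSpec | None = None,
    trunc: TruncationOrder | None = None,
    *,
    temperature_K: float | None = None,
) -> pd.DataFrame:
    """Sweep force or torque at a fixed conjugate constraint.

    ``mode`` is one of ``force_extension``, ``force_sigma`` (sweep force in
    pN at fixed torque in pN*nm) or ``torque_extension``, ``torque_sigma``
    (sweep torque at fixed force).  Extension is normalised to the B-form
    contour length.  A ``transition`` column flags sweep intervals where any
    occupancy crosses 0.5.
    """
    if table is None:
        table = ParamTable.default()
    if chain is None:
        chain = ChainSpec(n_bp=10000, q=1.5)
    if trunc is None:
        trunc = TruncationOrder(kmax=30)
    kwargs = {} if temperature_K is None else {"temperature_K": temperature_K}
    rows = []
    if mode.startswith("force"):
        points = [Constraint.from_pn(f_pn, fixed_value, **kwargs) for f_pn in sweep]
    elif mode.startswith("torque"):
        points = [Constraint.from_pn(fixed_value, tau_pn, **kwargs) for tau_pn in sweep]
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    need_sigma = mode.endswith("sigma")
    prev_occ = None
    for con in points:
        pp = observables(table, chain, con, trunc, need_dlk=need_sigma)
        row = pp.row()
        row["transition"] = bool(
            prev_occ is not None
            and any((prev_occ[u] - 0.5) * (pp.occupancy[u] - 0.5) < 0 for u in pp.occupancy)
        )
        prev_occ = pp.occupancy
        rows.append(row)
    return pd.DataFrame(rows)


def occupancy_boundary_tau(
    state: str,
    f_pn: float,
    tau_lo_pn_nm: float,
    tau_hi_pn_nm: float,
    table: ParamTable | None = None,
    chain: ChainSpec | None = None,
    trunc: TruncationOrder | None = None,
    *,
    tol_pn_nm: float = 0.1,
) -> float | None:
    """Torque (pN*nm) at which the occupancy of ``state`` crosses 50%.

    Bisects between ``tau_lo`` and ``tau_hi`` at fixed force; returns None
    when the crossing is not bracketed.
    """
    if table is None:
        table = ParamTable.default()
    if chain is None:
        chain = ChainSpec(n_bp=10000, q=1.5)
    if trunc is None:
        trunc = TruncationOrder(kmax=30)

    def occ_minus_half(tau_pn: float) -> float:
        con = Constraint.from_pn(f_pn, tau_pn)
        return occupancy(table, chain, con, trunc)[state] - 0.5

    lo, hi = float(tau_lo_pn_nm), float(tau_hi_pn_nm)
    flo, fhi = occ_minus_half(lo), occ_minus_half(hi)
    if flo * fhi > 0:
        return None
    while abs(hi - lo) > tol_pn_nm:
        mid = 0.5 * (lo + hi)
        fm = occ_minus_half(mid)
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def phase_diagram(
    f_grid_pn: Iterable[float] | None = None,
    tau_grid_pn_nm: Iterable[float] | None = None,
    table: ParamTable | None = None,
    chain: ChainSpec | None = None,
    trunc: TruncationOrder | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Grid of PhasePoints plus refined structural-boundary polylines.

    Structural boundaries (B-L, B-P, ... ) are the 50%-occupancy contours,
    refined by bisection in tau at each force.  Supercoiling boundaries are
    the points where the extension falls to 50% of the worm-like-chain
    prediction for the locally dominant structure (its Lp and contour
    length); they are reported per dominant state.
    """
    if f_grid_pn is None:
        f_grid_pn = np.geomspace(0.05, 120.0, 24)
    if tau_grid_pn_nm is None:
        tau_grid_pn_nm = np.linspace(-60.0, 60.0, 41)
    if table is None:
        table = ParamTable.default()
    if chain is None:
        chain = ChainSpec(n_bp=10000, q=1.5)
    if trunc is None:
        trunc = TruncationOrder(kmax=30)
    f_grid_pn = np.asarray(list(f_grid_pn), dtype=float)
    tau_grid_pn_nm = np.asarray(list(tau_grid_pn_nm), dtype=float)

    rows = []
    boundaries: dict[str, list] = {}
    for f_pn in f_grid_pn:
        col = []
        for tau_pn in tau_grid_pn_nm:
            pp = observables(
                table, chain, Constraint.from_pn(f_pn, tau_pn), trunc, need_dlk=False
            )
            col.append(pp)
            rows.append(pp.row())
        # refine 50%-occupancy crossings along tau
        for u in ("L", "P", "S"):
            occs = np.array([p.occupancy[u] for p in col]) - 0.5
            for i in range(len(occs) - 1):
                if occs[i] * occs[i + 1] < 0:
                    tau_star = occupancy_boundary_tau(
                        u, f_pn, tau_grid_pn_nm[i], tau_grid_pn_nm[i + 1],
                        table, chain, trunc,
                    )
                    if tau_star is not None:
                        boundaries.setdefault(f"B-{u}", []).append((f_pn, tau_star))
        # supercoiling boundary: z drops through 50% of the dominant state's WLC
        for i in range(len(col) - 1):
            for p_a, p_b in ((col[i], col[i + 1]),):
                if p_a.supercoiled != p_b.supercoiled and p_a.dominant == p_b.dominant:
                    boundaries.setdefault(f"sc-{p_a.dominant}", []).append(
                        (f_pn, 0.5 * (p_a.tau_pn_nm + p_b.tau_pn_nm))
                    )
    blist = [
        {"name": name, "points": sorted(pts)} for name, pts in sorted(boundaries.items())
    ]
    return pd.DataFrame(rows), blist
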