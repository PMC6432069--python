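"""Single-state transfer matrix against brute-force integration and
worm-like-chain physics."""

import math
from dataclasses import replace

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from twlc.energy import marko_siggia_extension
from twlc.model import ChainSpec, Constraint, ParamTable, StateParams
from twlc.special import TruncationOrder
from twlc.tmatrix import (
    mat_power_vec,
    s_matrix,
    single_state_log_partition,
    single_state_observables,
    v_vector,
)


# ---------------------------------------------------------------------------
# direct-quadrature oracles for the two-segment partition function
# ---------------------------------------------------------------------------

def direct_z2_torsionless(a, c, b, f, n_beta=48, n_per=48):
    """N=2 partition function at tau=0 by quadrature in smooth coordinates.

    Variables: beta_1 and the relative polar angle beta' (Gauss-Legendre in
    their cosines), the twist angle v = alpha'+gamma' and the azimuth
    u entering the second segment's polar angle (periodic trapezoid).  The
    integrand is smooth and periodic, so convergence is spectral.
    """
    x, wx = leggauss(n_beta)
    per = 2 * np.pi * np.arange(n_per) / n_per
    wper = 2 * np.pi / n_per
    c1 = x[:, None, None, None]
    s1 = np.sqrt(1 - x**2)[:, None, None, None]
    cb = x[None, :, None, None]
    sb = np.sqrt(1 - x**2)[None, :, None, None]
    u = per[None, None, :, None]
    v = per[None, None, None, :]
    cos_beta2 = c1 * cb - s1 * sb * np.cos(u)
    E = (
        -a * (1 - cb)
        - c * (1 - np.cos(v))
        + b * f * c1
        + b * f * cos_beta2
    )
    val = np.einsum("i,j,ijkl->", wx, wx, np.exp(E)) * wper**2
    return (2 * np.pi) ** 2 * val


def direct_z2_torque(a, c, b, f, tau, lam, n_beta=40, n_per=32):
    """N=2 partition function with torque, brute-force over the five
    non-trivial absolute Euler angles.  The Fuller linking angle makes the
    integrand discontinuous on a measure-zero set, so convergence is
    algebraic; tolerances are set accordingly."""
    x, wx = leggauss(n_beta)
    per = 2 * np.pi * np.arange(n_per) / n_per
    wper = 2 * np.pi / n_per
    total = 0.0
    g1 = per[None, None, :, None]
    g2 = per[None, None, None, :]
    cg1, sg1 = np.cos(g1), np.sin(g1)
    cg2, sg2 = np.cos(g2), np.sin(g2)
    for i in range(n_beta):
        c1, s1 = x[i], math.sqrt(1 - x[i] ** 2)
        da = per[:, None, None, None]
        c2 = x[None, :, None, None]
        s2 = np.sqrt(1 - x**2)[None, :, None, None]
        cda, sda = np.cos(da), np.sin(da)
        M02 = c1 * cda * s2 - s1 * c2
        M12 = sda * s2
        M20 = s1 * cda * c2 - c1 * s2
        M21 = -s1 * sda * np.ones_like(c2)
        M22 = s1 * cda * s2 + c1 * c2
        R12 = -sg1 * M02 + cg1 * M12
        R02 = cg1 * M02 + sg1 * M12
        R20 = M20 * cg2 + M21 * sg2
        R21 = -M20 * sg2 + M21 * cg2
        psi = np.arctan2(R12, R02) + np.arctan2(R21, -R20)
        theta = da + (g2 - g1)
        E = (
            -a * (1 - M22)
            - c * (1 - np.cos(psi))
            + b * f * c1
            + (tau * lam / (2 * np.pi)) * np.sin(psi)
            + tau * (1 - lam / (2 * np.pi)) * np.sin(theta)
        )
        total += wx[i] * np.einsum("j,ajlm->", wx, np.exp(E) * np.exp(b * f * c2))
    return 2 * np.pi * total * wper**3


def z2_transfer(a, c, b, f, tau, lam, kmax=16):
    trunc = TruncationOrder(kmax=kmax)
    S, _ = s_matrix(a, b, c, lam, f, tau, trunc)
    return float((S @ v_vector(b, f, trunc))[0])


@pytest.mark.parametrize("a,c,b,f", [(2.0, 2.0, 0.5, 1.0), (3.0, 1.5, 0.5, 0.6)])
def test_two_segment_partition_vs_quadrature_torsionless(a, c, b, f):
    want = direct_z2_torsionless(a, c, b, f)
    got = z2_transfer(a, c, b, f, 0.0, 1.0)
    assert got == pytest.approx(want, rel=1e-3)
    # at soft stiffness the agreement is far inside the tolerance
    assert got == pytest.approx(want, rel=1e-6)


@pytest.mark.parametrize(
    "a,c,b,f,tau,lam",
    [(2.0, 2.0, 0.5, 1.0, 0.8, 1.0), (2.0, 2.0, 0.5, 0.5, 1.2, 2.5),
     (2.0, 2.0, 0.5, 1.0, -0.9, 4.3)],
)
def test_two_segment_partition_vs_quadrature_torque(a, c, b, f, tau, lam):
    want = direct_z2_torque(a, c, b, f, tau, lam)
    got = z2_transfer(a, c, b, f, tau, lam)
    assert got == pytest.approx(want, rel=5e-3)


# ---------------------------------------------------------------------------
# boundary vector and assembly invariants
# ---------------------------------------------------------------------------

def test_v_vector_examples():
    trunc = TruncationOrder(kmax=8)
    v0 = v_vector(1.0, 0.0, trunc)
    assert v0[0] == pytest.approx(8 * math.pi**2, rel=1e-14)
    assert np.allclose(v0[1:], 0.0)
    v1 = v_vector(1.0, 1.0, trunc)
    assert v1[0] == pytest.approx(8 * math.pi**2 * math.sinh(1.0), rel=1e-12)
    assert np.all(v1 >= 0.0)  # i_k(x) >= 0 for x >= 0
    with pytest.raises(ValueError):
        v_vector(1.0, -1.0, trunc)


def test_s_matrix_real_assembly(table, chain_10kbp):
    st_b = table["B"]
    a, c = chain_10kbp.dimensionless_stiffness(st_b)
    b = chain_10kbp.segment_length(st_b)
    con = Constraint.from_pn(3.0, 7.0)
    _, res = s_matrix(a, b, c, st_b.lam, con.f, con.tau, TruncationOrder(kmax=20))
    assert res < 1e-8
    with pytest.raises(ValueError):
        s_matrix(-1.0, b, c, st_b.lam, con.f, con.tau, TruncationOrder(kmax=8))


def test_trace_collapse_equals_literal_trace():
    """Tr(S^{N-1} V) with the boundary matrix V_kk' = delta_k'0 v_k equals
    the matrix-power-times-vector contraction used for speed."""
    trunc = TruncationOrder(kmax=10)
    a, c, b, f, tau, lam = 5.0, 4.0, 0.5, 0.8, 0.6, 4.3
    S, _ = s_matrix(a, b, c, lam, f, tau, trunc)
    v = v_vector(b, f, trunc)
    V = np.zeros((11, 11))
    V[:, 0] = v
    n = 5
    literal = np.trace(np.linalg.matrix_power(S, n - 1) @ V)
    w, logs = mat_power_vec(S, n - 1, v)
    assert w[0] * math.exp(logs) == pytest.approx(literal, rel=1e-12)


def test_kmax_convergence(table, chain_10kbp):
    con = Constraint.from_pn(2.0, 5.0)
    vals = [
        single_state_log_partition(table["B"], chain_10kbp, con, TruncationOrder(kmax=k)).log_z
        for k in (20, 40)
    ]
    assert vals[1] == pytest.approx(vals[0], rel=5e-7)


def test_extensivity(table, trunc_fast):
    con = Constraint.from_pn(1.0, 0.0)
    logz = [
        single_state_log_partition(table["B"], ChainSpec(n_bp=n, q=1.5), con, trunc_fast).log_z
        for n in (1500, 3000, 6000)
    ]
    # bulk-dominated: ln Z grows linearly in chain length (the sign of the
    # per-segment term is a normalisation convention)
    d1 = logz[1] - logz[0]
    d2 = logz[2] - logz[1]
    assert d2 == pytest.approx(2 * d1, rel=1e-3)


# ---------------------------------------------------------------------------
# physics checks
# ---------------------------------------------------------------------------

def test_wlc_extension_vs_marko_siggia_moderate_force(table, chain_10kbp, trunc_fast):
    con = Constraint.from_pn(2.0, 0.0)
    obs = single_state_observables(table["B"], chain_10kbp, con, trunc_fast)
    ms = marko_siggia_extension(con.f, 50.0)
    assert obs["z"] / chain_10kbp.contour_length_b == pytest.approx(ms, rel=0.02)


def test_rigid_rod_limit(chain_10kbp):
    stiff = StateParams("B", 2000.0, 2000.0, 1.0, 10.4, +1, 0.0, 4.3)
    con = Constraint.from_pn(2.0, 0.0)
    obs = single_state_observables(stiff, chain_10kbp, con, TruncationOrder(kmax=24))
    # stiff limit: z/L -> 1 - (4 f Lp)^(-1/2) = 0.984 at Lp = 2 um, f = 2 pN
    zol = obs["z"] / chain_10kbp.contour_length_b
    assert zol > 0.98
    assert zol == pytest.approx(1.0 - 1.0 / math.sqrt(4 * con.f * 2000.0), abs=2e-3)


def test_no_spontaneous_extension_at_zero_force(table, chain_10kbp, trunc_fast):
    con = Constraint(f=1e-5, tau=0.0)
    obs = single_state_observables(table["B"], chain_10kbp, con, trunc_fast)
    assert abs(obs["z"]) / chain_10kbp.contour_length_b < 0.01


def test_single_state_torque_parity(table, chain_10kbp, trunc_fast):
    """B-DNA is achiral in this model: z is even and DLk odd in tau."""
    f = 3.0
    plus = single_state_observables(
        table["B"], chain_10kbp, Constraint.from_pn(f, 6.0), trunc_fast
    )
    minus = single_state_observables(
        table["B"], chain_10kbp, Constraint.from_pn(f, -6.0), trunc_fast
    )
    assert plus["z"] == pytest.approx(minus["z"], rel=1e-6)
    assert plus["dlk"] == pytest.approx(-minus["dlk"], rel=1e-6)
    zero = single_state_observables(
        table["B"], chain_10kbp, Constraint.from_pn(f, 0.0), trunc_fast
    )
    assert zero["dlk"] == pytest.approx(0.0, abs=1e-8)


def test_linking_linear_in_small_torque(table, chain_10kbp, trunc_fast):
    f = 3.0
    d1 = single_state_observables(
        table["B"], chain_10kbp, Constraint.from_pn(f, 1.0), trunc_fast
    )["dlk"]
    d2 = single_state_observables(
        table["B"], chain_10kbp, Constraint.from_pn(f, 2.0), trunc_fast
    )["dlk"]
    assert d2 == pytest.approx(2 * d1, rel=0.02)


def test_boundary_condition_insensitivity(table, trunc_fast):
    """For L >> Lp the boundary vector's force argument barely matters."""
    chain = ChainSpec(n_bp=10000, q=1.5)  # L = 3300 nm = 66 Lp
    con = Constraint.from_pn(1.0, 0.0)

    def z_with(boundary_f):
        h = 1e-4
        lp = single_state_log_partition(
            table["B"], chain, replace(con, f=con.f + h), trunc_fast,
            boundary_f=boundary_f,
        ).log_z
        lm = single_state_log_partition(
            table["B"], chain, replace(con, f=con.f - h), trunc_fast,
            boundary_f=boundary_f,
        ).log_z
        return (lp - lm) / (2 * h)

    z_native = z_with(None)
    z_zero = z_with(0.0)
    assert z_zero == pytest.approx(z_native, rel=0.005)
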