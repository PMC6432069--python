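"""Elastic energies, the constrained total energy and the Marko-Siggia form."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twlc.chain import ChainConformation, build_fixture, euler_to_matrix, matrix_to_euler
from twlc.energy import (
    bend_twist_energy,
    marko_siggia_extension,
    marko_siggia_force,
    total_energy,
)
from twlc.model import ChainSpec, Constraint


# ---------------------------------------------------------------------------
# Marko-Siggia interpolation
# ---------------------------------------------------------------------------

def test_ms_force_examples():
    assert marko_siggia_force(0.0, 50.0) == 0.0
    assert marko_siggia_force(0.5, 50.0) == pytest.approx(1.25 / 50.0, rel=1e-12)
    with pytest.raises(ValueError):
        marko_siggia_force(1.0, 50.0)
    with pytest.raises(ValueError):
        marko_siggia_force(0.5, -1.0)


def test_ms_low_force_slope():
    x = 1e-7
    assert marko_siggia_force(x, 50.0) * 50.0 / x == pytest.approx(1.5, rel=1e-4)


def test_ms_high_force_law():
    x = 1.0 - 1e-5
    f = marko_siggia_force(x, 50.0)
    assert f * 50.0 * 4 * (1 - x) ** 2 == pytest.approx(1.0, rel=1e-4)


@given(f=st.floats(1e-6, 10.0))
@settings(max_examples=80, deadline=None)
def test_ms_inversion_round_trip(f):
    x = marko_siggia_extension(f, 50.0)
    assert 0.0 <= x < 1.0
    assert marko_siggia_force(x, 50.0) == pytest.approx(f, rel=1e-9, abs=1e-10)


def test_ms_extension_high_force_asymptote():
    f = 50.0  # kBT/nm, deep in the 1/sqrt(f) regime
    x = marko_siggia_extension(f, 50.0)
    assert 1.0 - x == pytest.approx(1.0 / np.sqrt(4 * 50.0 * f), rel=0.02)


def test_ms_monotone():
    xs = np.linspace(0, 0.99, 200)
    fs = marko_siggia_force(xs, 50.0)
    assert np.all(np.diff(fs) > 0)


# ---------------------------------------------------------------------------
# discrete chain energies
# ---------------------------------------------------------------------------

def _two_segment_conf(euler2, b=0.495):
    euler = np.vstack([[0.0, 0.0, 0.0], euler2])
    return ChainConformation(euler, np.array(["B", "B"], dtype=object), np.full(2, b))


def test_straight_chain_zero_elastic(table):
    chain = ChainSpec(n_bp=30, q=1.5)
    conf = build_fixture("straight", chain, table)
    e = bend_twist_energy(conf, chain, table)
    assert e.e_bend == 0.0 and e.e_twist == 0.0


def test_single_joint_bend(table):
    """One junction bent by theta: E = a (1 - cos theta); 0.4996 kBT for
    a=100 at theta=0.1."""
    theta = 0.1
    chain = ChainSpec(n_bp=3, q=1.5)
    conf = _two_segment_conf([0.0, theta, 0.0])
    a, _ = chain.dimensionless_stiffness(table["B"])
    e = bend_twist_energy(conf, chain, table)
    assert e.e_bend == pytest.approx(a * (1 - np.cos(theta)), rel=1e-12)
    assert 100.0 * (1 - np.cos(theta)) == pytest.approx(0.4996, abs=1e-4)
    assert e.e_twist == pytest.approx(0.0, abs=1e-25)


def test_single_joint_twist(table):
    """One junction twisted by phi about the shared tangent: the
    cross-product twist gives E = (c/2) sin^2(phi)."""
    phi = 0.05
    chain = ChainSpec(n_bp=3, q=1.5)
    conf = _two_segment_conf([0.0, 0.0, phi])
    _, c = chain.dimensionless_stiffness(table["B"])
    e = bend_twist_energy(conf, chain, table)
    assert e.e_bend == pytest.approx(0.0, abs=1e-25)
    assert e.e_twist == pytest.approx(0.5 * c * np.sin(phi) ** 2, rel=1e-12)
    # reference value at c=190
    assert 0.5 * 190 * np.sin(phi) ** 2 == pytest.approx(0.2372, abs=2e-4)


def test_total_energy_straight_chain(table):
    chain = ChainSpec(n_bp=150, q=1.5)
    conf = build_fixture("straight", chain, table)
    e0 = total_energy(conf, chain, Constraint(f=0.0, tau=0.0), table)
    assert e0.e_total == pytest.approx(0.0, abs=1e-12)
    f = 0.5
    ef = total_energy(conf, chain, Constraint(f=f, tau=0.0), table)
    L = conf.n_segments * 0.495
    assert ef.e_total == pytest.approx(-f * L, rel=1e-12)


def test_total_energy_linear_in_torque(table):
    chain = ChainSpec(n_bp=120, q=1.5)
    conf = build_fixture(
        "helix", chain, table, turns=2, radius=4, pitch=10, twist_per_segment=0.03
    )
    e_plus = total_energy(conf, chain, Constraint(f=0.1, tau=1.3), table).e_total
    e_minus = total_energy(conf, chain, Constraint(f=0.1, tau=-1.3), table).e_total
    e_zero = total_energy(conf, chain, Constraint(f=0.1, tau=0.0), table).e_total
    assert e_plus + e_minus == pytest.approx(2 * e_zero, rel=1e-9)


def test_energy_invariant_under_rotation_about_force_axis(table):
    chain = ChainSpec(n_bp=90, q=1.5)
    conf = build_fixture(
        "random_walk", chain, table, stiffness_a=15.0, seed=2
    )
    con = Constraint(f=0.3, tau=0.7)
    e = total_energy(conf, chain, con, table).e_total
    Rz = euler_to_matrix(np.array([0.9, 0.0, 0.0]))
    rotated = ChainConformation(
        matrix_to_euler(np.einsum("ab,nbc->nac", Rz, conf.rotations())),
        conf.states,
        conf.seg_lengths,
    )
    e_rot = total_energy(rotated, chain, con, table).e_total
    assert e_rot == pytest.approx(e, rel=1e-9, abs=1e-9)


def test_breakdown_sums(table):
    chain = ChainSpec(n_bp=90, q=1.5)
    conf = build_fixture("random_walk", chain, table, stiffness_a=15.0, seed=4)
    e = total_energy(conf, chain, Constraint(f=0.2, tau=0.4), table)
    assert e.e_total == pytest.approx(
        e.e_bend + e.e_twist + e.e_force + e.e_torque + e.e_state, rel=1e-9
    )


def test_mixed_state_energy_counts_mu(table):
    chain = ChainSpec(n_bp=30, q=1.5)
    conf = build_fixture("straight", chain, table)
    conf.states[:5] = "S"
    conf.seg_lengths[:5] = chain.segment_length(table["S"])
    e = total_energy(conf, chain, Constraint(), table)
    assert e.e_state == pytest.approx(5 * 1.5 * 5.1, rel=1e-12)


def test_discrete_bend_energy_converges_on_smooth_helix(table):
    """Halving the segment length drives the discrete bend energy toward the
    thin-rod integral (Lp/2) kappa^2 L with ~O(b) error."""
    Lp = 50.0
    radius, pitch = 5.0, 20.0
    slope = pitch / (2 * np.pi * radius)
    norm = np.hypot(1.0, slope)
    curvature = 1.0 / (radius * norm**2)
    errors = []
    for n in (100, 200, 400, 800):
        phi = 2 * np.pi * 2 * (np.arange(n) + 0.5) / n  # 2 turns
        t = np.column_stack(
            [-np.sin(phi) / norm, np.cos(phi) / norm, np.full(n, slope / norm)]
        )
        from twlc.chain import frames_from_tangents

        L_arc = 2 * 2 * np.pi * radius * norm  # fixed arc length
        b = L_arc / n
        conf = ChainConformation(
            frames_from_tangents(t), np.array(["B"] * n, dtype=object), np.full(n, b)
        )
        # evaluate with a chain spec matching this b
        chain = ChainSpec(n_bp=max(3, round(n * b / 0.33)), q=b / 0.33)
        e = bend_twist_energy(conf, chain, table)
        exact = 0.5 * Lp * curvature**2 * L_arc
        errors.append(abs(e.e_bend - exact) / exact)
    # error shrinks roughly linearly in b
    assert errors[-1] < errors[0] / 4
    assert errors[-1] < 0.01
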