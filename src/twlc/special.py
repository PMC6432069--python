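"""Special-function kernel of the rotational transfer matrix.

Provides the diagonal Wigner small-d elements d^k_rr(theta), their bilateral
Laplace transforms

    L_r^k(s) = integral_{-1}^{1} d^k_rr(arccos x) e^{-s x} dx ,

Wigner 3-j symbols in exact rational arithmetic, and (spherical) modified
Bessel functions of the first kind.  The transfer-matrix elements are sums of
products of these; each function here is cross-validated against independent
oracles in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy.special import eval_jacobi, ive, iv, spherical_in
from numpy.polynomial.legendre import leggauss

__all__ = [
    "TruncationOrder",
    "wigner_d_diag",
    "laplace_wigner_d",
    "laplace_wigner_d_table",
    "wigner_3j",
    "three_j_squared_table",
    "bessel_iv",
    "sph_bessel_iv",
]


@dataclass(frozen=True)
class TruncationOrder:
    """Series truncation controls for the transfer-matrix assembly.

    ``kmax`` bounds every angular-momentum-like index (k, k', p, s, s');
    ``quad_points`` is the Gauss–Legendre node count used for the L_r^k
    integrals (None picks a count that resolves both the polynomial degree
    and the exponential factor); ``tolerance`` is the relative convergence
    target used by adaptive drivers.
    """

    kmax: int = 30
    quad_points: int | None = None
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.kmax < 0:
            raise ValueError("kmax must be non-negative")
        if self.quad_points is not None and self.quad_points < self.kmax + 10:
            raise ValueError("quad_points must be at least kmax + 10")

    def nodes_for(self, max_abs_s: float) -> int:
        if self.quad_points is not None:
            return self.quad_points
        # enough nodes for polynomials of degree 2*kmax times exp(|s|)
        return max(2 * self.kmax + 20, int(1.2 * max_abs_s) + 40)


def wigner_d_diag(k: int, r: int, theta):
    """Diagonal Wigner small-d element d^k_rr(theta).

    Uses the closed Jacobi-polynomial form
    d^k_rr = cos^{2|r|}(theta/2) * P^{(0, 2|r|)}_{k-|r|}(cos theta),
    valid for |r| <= k (d is invariant under r -> -r on the diagonal).
    """
    if abs(r) > k:
        raise ValueError(f"|r|={abs(r)} exceeds order k={k}")
    r = abs(r)
    theta = np.asarray(theta, dtype=float)
    x = np.cos(theta)
    out = np.cos(theta / 2.0) ** (2 * r) * eval_jacobi(k - r, 0, 2 * r, x)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=64)
def _gl_nodes(n: int):
    return leggauss(n)


def _d_diag_at_x(k: int, r: int, x: np.ndarray) -> np.ndarray:
    r = abs(r)
    return ((1.0 + x) / 2.0) ** r * eval_jacobi(k - r, 0, 2 * r, x)


def laplace_wigner_d(k: int, r: int, s: float, tolerance: float = 1e-10) -> float:
    """Bilateral Laplace transform L_r^k(s) of the diagonal Wigner element.

    Gauss–Legendre quadrature on [-1, 1], with the node count doubled until
    two successive evaluations agree to ``tolerance`` (relative).
    """
    if abs(r) > k:
        raise ValueError(f"|r|={abs(r)} exceeds order k={k}")
    n = max(2 * k + 16, int(1.2 * abs(s)) + 16)
    prev = None
    for _ in range(12):
        x, w = _gl_nodes(n)
        val = float(np.sum(w * _d_diag_at_x(k, r, x) * np.exp(-s * x)))
        if prev is not None and abs(val - prev) <= tolerance * max(1.0, abs(val)):
            return val
        prev = val
        n *= 2
    raise RuntimeError(
        f"L_r^k quadrature did not converge for k={k}, r={r}, s={s}; last two "
        f"values {prev} (n={n // 2} nodes)"
    )


def laplace_wigner_d_table(
    kmax: int, rmax: int, s: float, n_nodes: int, shift: float = 0.0
) -> np.ndarray:
    """Table of e^{shift} * L_r^k(s) for 0 <= k <= kmax, 0 <= r <= min(k, rmax).

    The optional shift folds an overall factor e^{shift} into the integrand
    (as e^{shift - s*x}), which keeps strongly peaked integrands (|s| ~ a of
    order 100) in floating range.  Entries with r > k are zero.
    """
    x, w = _gl_nodes(n_nodes)
    expf = w * np.exp(shift - s * x)
    out = np.zeros((kmax + 1, rmax + 1))
    degrees = np.arange(kmax + 1)[:, None]
    for r in range(rmax + 1):
        base = expf * ((1.0 + x) / 2.0) ** r
        jac = eval_jacobi(degrees[: kmax + 1 - r], 0, 2 * r, x[None, :])
        out[r:, r] = jac @ base
    return out


# ----------------------------------------------------------------------------
# Wigner 3-j symbols (exact rational arithmetic, Racah's formula)
# ----------------------------------------------------------------------------

_fact = math.factorial


def _racah_sum(j1, j2, j3, m1, m2, m3) -> tuple[int, int]:
    """Racah's alternating sum as an exact integer pair (numerator, common
    denominator): sum_t (-1)^t / D_t = S / L with

        D_t = t! (a1+t)! (a2+t)! (b1-t)! (b2-t)! (b3-t)!

    and L the product of the extremal factorials, so that every L/D_t is an
    integer product of falling factorials (math.perm).
    """
    a1 = j3 - j2 + m1
    a2 = j3 - j1 - m2
    b1 = j1 + j2 - j3
    b2 = j1 - m1
    b3 = j2 + m2
    t_lo = max(0, -a1, -a2)
    t_hi = min(b1, b2, b3)
    acc = 0
    for t in range(t_lo, t_hi + 1):
        up = t_hi - t
        dn = t - t_lo
        term = (
            math.perm(t_hi, up)
            * math.perm(a1 + t_hi, up)
            * math.perm(a2 + t_hi, up)
            * math.perm(b1 - t_lo, dn)
            * math.perm(b2 - t_lo, dn)
            * math.perm(b3 - t_lo, dn)
        )
        acc += -term if t % 2 else term
    L = (
        _fact(t_hi) * _fact(a1 + t_hi) * _fact(a2 + t_hi)
        * _fact(b1 - t_lo) * _fact(b2 - t_lo) * _fact(b3 - t_lo)
    )
    return acc, L


def _three_j_squared_fraction(j1, j2, j3, m1, m2, m3) -> Fraction:
    """(3j)^2 as an exact Fraction; zero outside the selection rules."""
    if m1 + m2 + m3 != 0:
        return Fraction(0)
    if not (abs(j1 - j2) <= j3 <= j1 + j2):
        return Fraction(0)
    if abs(m1) > j1 or abs(m2) > j2 or abs(m3) > j3:
        return Fraction(0)
    pref = (
        _fact(j1 + j2 - j3) * _fact(j1 - j2 + j3) * _fact(-j1 + j2 + j3)
        * _fact(j1 + m1) * _fact(j1 - m1) * _fact(j2 + m2) * _fact(j2 - m2)
        * _fact(j3 + m3) * _fact(j3 - m3)
    )
    acc, L = _racah_sum(j1, j2, j3, m1, m2, m3)
    if acc == 0:
        return Fraction(0)
    return Fraction(pref * acc * acc, _fact(j1 + j2 + j3 + 1) * L * L)


def _three_j_sum_sign(j1, j2, j3, m1, m2, m3) -> int:
    acc, _ = _racah_sum(j1, j2, j3, m1, m2, m3)
    if acc == 0:
        return 0
    sgn = 1 if acc > 0 else -1
    return sgn * (-1 if (j1 - j2 - m3) % 2 else 1)


def wigner_3j(j1: int, j2: int, j3: int, m1: int, m2: int, m3: int) -> float:
    """Signed Wigner 3-j symbol for integer arguments.

    Evaluated from Racah's single-sum formula in exact rational arithmetic
    and returned as a float; returns 0.0 outside the selection rules.
    """
    sq = _three_j_squared_fraction(j1, j2, j3, m1, m2, m3)
    if sq == 0:
        return 0.0
    return _three_j_sum_sign(j1, j2, j3, m1, m2, m3) * math.sqrt(float(sq))


@lru_cache(maxsize=256)
def three_j_squared_table(pmax: int, kmax: int, r: int) -> np.ndarray:
    """Cached table W[p, s, k] = (2s+1) * wigner_3j(p, s, k; -r, r, 0)^2
    for p, s <= pmax and k <= kmax.

    The (2p+1) weight of the shared index p is applied once by the caller
    (the table is contracted twice per matrix element, once against each of
    the s and s' sums).  These geometric weights depend only on the
    truncation order and the magnetic index r, so they are shared across all
    forces, torques and structural states (and W is even in r).
    """
    r = abs(r)
    W = np.zeros((pmax + 1, pmax + 1, kmax + 1))
    for p in range(r, pmax + 1):
        for s in range(r, pmax + 1):
            k_lo = abs(p - s)
            k_hi = min(p + s, kmax)
            for k in range(k_lo, k_hi + 1):
                if r == 0 and (p + s + k) % 2:
                    continue  # parity selection rule at m = 0
                sq = _three_j_squared_fraction(p, s, k, -r, r, 0)
                if sq:
                    W[p, s, k] = (2 * s + 1) * float(sq)
    return W


# ----------------------------------------------------------------------------
# Modified Bessel functions
# ----------------------------------------------------------------------------

def bessel_iv(r: int, x: float) -> float:
    """Modified Bessel function of the first kind I_r(x), integer order.

    Even orders are even in x, odd orders odd (I_r(-x) = (-1)^r I_r(x)).
    """
    return float(iv(r, x))


def bessel_iv_scaled(r, x: float):
    """exp(-|x|) * I_r(x): overflow-safe for large twist stiffness arguments."""
    return ive(r, x)


def sph_bessel_iv(k: int, x: float) -> float:
    """Modified spherical Bessel function of the first kind i_k(x).

    i_0(x) = sinh(x)/x with i_0(0) = 1 and i_k(0) = 0 for k > 0.
    """
    if k < 0:
        raise ValueError("order must be non-negative")
    return float(spherical_in(k, x))
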