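"""Twist, writhe and linking number of discretised DNA conformations.

For a closed ribbon the Calugareanu–White theorem states Lk = Tw + Wr.  For
the open chains handled here the same decomposition is used with

* ``Tw``        sum over junctions of the local twist angle / 2*pi, computed
                from the frame vectors as ( [u_n x u_{n+1}] . t_n ) / 2*pi;
* ``Wr`` (Gauss) the double sum over non-adjacent segment pairs of the mutual
                solid angle Omega_nn' / 4*pi — the discrete equivalent of the
                Gauss double contour integral, evaluated with the exact
                closed form for two straight segments;
* ``Wr`` (Fuller) the single-sum surrogate obtained from the unwrapped Euler
                angles: DLk_F = (alpha~_N + gamma~_N - alpha~_1 - gamma~_1) / 2*pi
                and Wr_F = DLk_F - Tw.  It equals the Gauss writhe only for
                conformations continuously deformable from the extended
                state without tangent-antipodal points or self-crossings —
                nearly extended or solenoidal shapes, but not plectonemes.

The linking-number change of a mixed-state chain additionally carries the
structural term sum_n q * dlk0(u_n) accounting for the different relaxed
helicity of non-B segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chain import ChainConformation, unwrap_angles
from .model import ChainSpec, ParamTable

try:  # optional jit acceleration for the O(N^2) pair sums
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "TopologyReport",
    "twist_number",
    "writhe_gauss",
    "writhe_fuller",
    "dlk_fuller",
    "pair_writhe",
    "topology_report",
]


class SingularPairError(ValueError):
    """Raised when two segments touch or cross (Gauss kernel singular)."""

    def __init__(self, i: int, j: int):
        super().__init__(f"segments {i} and {j} intersect or touch; writhe undefined")
        self.pair = (i, j)


def twist_number(conf: ChainConformation) -> float:
    """Total twist in turns: sum of ([u_n x u_{n+1}] . t_n) / 2*pi over junctions."""
    R = conf.rotations()
    u = R[..., :, 0]
    t = R[..., :, 2]
    cross = np.cross(u[:-1], u[1:])
    return float(np.einsum("ij,ij->i", cross, t[:-1]).sum() / (2 * np.pi))


def _pair_solid_angle(p1, p2, p3, p4):
    """Signed solid angle Omega of the quadrangle spanned by segments
    (p1->p2) and (p3->p4), vectorised over leading axes.

    This is the exact closed form of the Gauss double integral over two
    straight segments (the integral equals Omega / 4*pi for one ordered
    pair).  Degenerate (coplanar) pairs give 0; touching pairs give nan.
    """
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = np.cross(r13, r14)
    n2 = np.cross(r14, r24)
    n3 = np.cross(r24, r23)
    n4 = np.cross(r23, r13)

    def _unit(v):
        norm = np.linalg.norm(v, axis=-1, keepdims=True)
        small = norm < 1e-300
        return np.where(small, 0.0, v / np.where(small, 1.0, norm))

    n1, n2, n3, n4 = _unit(n1), _unit(n2), _unit(n3), _unit(n4)

    def _dot(a, b):
        return np.clip(np.einsum("...i,...i->...", a, b), -1.0, 1.0)

    omega = (
        np.arcsin(_dot(n1, n2))
        + np.arcsin(_dot(n2, n3))
        + np.arcsin(_dot(n3, n4))
        + np.arcsin(_dot(n4, n1))
    )
    triple = np.einsum("...i,...i->...", np.cross(p4 - p3, p2 - p1), r13)
    # coplanar pairs have exactly zero writhe; zero the ill-conditioned sign
    scale = (
        np.linalg.norm(p4 - p3, axis=-1)
        * np.linalg.norm(p2 - p1, axis=-1)
        * np.linalg.norm(r13, axis=-1)
    )
    sign = np.where(np.abs(triple) <= 1e-10 * scale, 0.0, np.sign(triple))
    return omega * sign


@_njit(cache=False)
def _omega_scalar(p1, p2, p3, p4) -> float:  # pragma: no cover - jit kernel
    r13x = p3[0] - p1[0]; r13y = p3[1] - p1[1]; r13z = p3[2] - p1[2]
    r14x = p4[0] - p1[0]; r14y = p4[1] - p1[1]; r14z = p4[2] - p1[2]
    r23x = p3[0] - p2[0]; r23y = p3[1] - p2[1]; r23z = p3[2] - p2[2]
    r24x = p4[0] - p2[0]; r24y = p4[1] - p2[1]; r24z = p4[2] - p2[2]
    # normals of the spherical quadrangle
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x
    m1 = math.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = math.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = math.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = math.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if m1 < 1e-300 or m2 < 1e-300 or m3 < 1e-300 or m4 < 1e-300:
        return 0.0
    d12 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
    d23 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
    d34 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
    d41 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
    d12 = min(1.0, max(-1.0, d12))
    d23 = min(1.0, max(-1.0, d23))
    d34 = min(1.0, max(-1.0, d34))
    d41 = min(1.0, max(-1.0, d41))
    omega = math.asin(d12) + math.asin(d23) + math.asin(d34) + math.asin(d41)
    # orientation sign: ((p4-p3) x (p2-p1)) . r13, zeroed for coplanar pairs
    ax = p4[0] - p3[0]; ay = p4[1] - p3[1]; az = p4[2] - p3[2]
    bx = p2[0] - p1[0]; by = p2[1] - p1[1]; bz = p2[2] - p1[2]
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    trip = cx * r13x + cy * r13y + cz * r13z
    la = math.sqrt(ax * ax + ay * ay + az * az)
    lb = math.sqrt(bx * bx + by * by + bz * bz)
    lc = math.sqrt(r13x * r13x + r13y * r13y + r13z * r13z)
    if abs(trip) <= 1e-10 * la * lb * lc:
        return 0.0
    return omega if trip > 0 else -omega


@_njit(cache=False)
def _full_writhe_kernel(starts, ends) -> float:  # pragma: no cover - jit kernel
    n = starts.shape[0]
    total = 0.0
    for i in range(n - 2):
        for j in range(i + 2, n):
            total += _omega_scalar(starts[i], ends[i], starts[j], ends[j])
    return total / (2.0 * np.pi)


@_njit(cache=False)
def _cross_writhe_kernel(s1, e1, i1, s2, e2, i2) -> float:  # pragma: no cover
    total = 0.0
    for i in range(s1.shape[0]):
        for j in range(s2.shape[0]):
            if abs(i1[i] - i2[j]) >= 2:
                total += _omega_scalar(s1[i], e1[i], s2[j], e2[j])
    return total / (2.0 * np.pi)


def pair_writhe(p1, p2, p3, p4) -> np.ndarray:
    """Writhe contribution of one unordered pair of segments (both orders),
    i.e. 2 * Omega / 4*pi = Omega / 2*pi.  Vectorised over leading axes."""
    return _pair_solid_angle(
        np.asarray(p1, float), np.asarray(p2, float), np.asarray(p3, float), np.asarray(p4, float)
    ) / (2 * np.pi)


def writhe_gauss(conf: ChainConformation, raise_on_singular: bool = True) -> float:
    """Gauss writhe in turns from the double sum over non-adjacent segment pairs.

    Adjacent segments (sharing a vertex) are skipped: the Gauss integrand of
    two contiguous straight segments vanishes identically.
    """
    n = conf.n_segments
    if n < 3:
        return 0.0
    verts = conf.vertices()
    starts = np.ascontiguousarray(verts[:-1])
    ends = np.ascontiguousarray(verts[1:])
    if _HAVE_NUMBA:
        total = float(_full_writhe_kernel(starts, ends))
        if np.isfinite(total):
            return total
        # fall through to the numpy path to identify the singular pair
    total = 0.0
    for i in range(n - 2):
        j = np.arange(i + 2, n)
        w = pair_writhe(starts[i], ends[i], starts[j], ends[j])
        if raise_on_singular and not np.all(np.isfinite(w)):
            bad = j[~np.isfinite(w)][0]
            raise SingularPairError(i, int(bad))
        total += float(np.nansum(w))
    return total


def dlk_fuller(conf: ChainConformation) -> float:
    """Fuller linking-number change in turns from the unwrapped Euler angles.

    DLk_F = (alpha~_N + gamma~_N - alpha~_1 - gamma~_1) / 2*pi.  Requires no
    tangent to point along -z0 (the Fuller integrand diverges there).
    """
    t = conf.tangents()
    if np.any(t[:, 2] < -1.0 + 1e-9):
        idx = int(np.argmin(t[:, 2]))
        raise ValueError(
            f"segment {idx} has tangent (anti)parallel to -z0; the Fuller "
            "form is only valid for conformations deformable from the "
            "extended state without antipodal tangents"
        )
    c = conf if conf.unwrapped is not None else unwrap_angles(conf)
    alpha, gamma = c.unwrapped[:, 0], c.unwrapped[:, 1]
    return float((alpha[-1] + gamma[-1] - alpha[0] - gamma[0]) / (2 * np.pi))


def writhe_fuller(conf: ChainConformation) -> float:
    """Fuller writhe in turns: Wr_F = DLk_F - Tw."""
    return dlk_fuller(conf) - twist_number(conf)


@dataclass(frozen=True)
class TopologyReport:
    """Topological summary of one conformation (all writhe/twist in turns)."""

    tw: float
    wr_gauss: float
    wr_fuller: float
    dlk_fuller: float
    dlk: float
    sigma: float

    def to_tsv_row(self) -> str:
        cols = (self.tw, self.wr_gauss, self.wr_fuller, self.dlk_fuller, self.dlk, self.sigma)
        return "\t".join(f"{v:.10e}" for v in cols)


def topology_report(
    conf: ChainConformation,
    chain: ChainSpec,
    table: ParamTable | None = None,
    fuller: bool = True,
) -> TopologyReport:
    """Full topology report: Tw, Wr (both forms), DLk and superhelical density.

    DLk = Tw + Wr_Gauss + sum_n q * dlk0(u_n) with the structural term
    accounting for the relaxed helicity of non-B segments; sigma = DLk / Lk0_B.
    """
    if table is None:
        table = ParamTable.default()
    tw = twist_number(conf)
    wr = writhe_gauss(conf)
    if fuller:
        dlkf = dlk_fuller(conf)
        wrf = dlkf - tw
    else:
        dlkf = float("nan")
        wrf = float("nan")
    structural = sum(chain.q * table.relaxed_linking_density(u) for u in conf.states)
    dlk = tw + wr + structural
    return TopologyReport(
        tw=tw,
        wr_gauss=wr,
        wr_fuller=wrf,
        dlk_fuller=dlkf,
        dlk=dlk,
        sigma=dlk / chain.lk0_b(table),
    )
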