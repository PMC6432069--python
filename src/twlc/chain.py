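"""Discretised DNA conformations as ordered rigid-body frames.

A conformation is an ordered list of N segment frames.  Each frame is a
right-handed orthonormal triad (u, v, t) obtained by rotating the laboratory
axes (x0, y0, z0) with a z-y-z Euler rotation

    R = Rz(alpha) Ry(beta) Rz(gamma),        t = R z0 ,

with alpha, gamma in [0, 2*pi) and beta in [0, pi].  The Euler angles are the
authoritative representation; rotation matrices, tangents and vertex positions
are derived from them.  Vertex n+1 sits at vertex n plus b_u * t_n, where b_u
is the segment length of the segment's structural state.

The module also provides deterministic fixture builders (straight chain,
planar circle, helix/solenoid, plectoneme-like interwound braid, direct-
sampled random walk) used heavily by the topology, energy and sampling tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ChainSpec, ParamTable

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "ChainConformation",
    "build_fixture",
    "unwrap_angles",
    "frames_from_tangents",
]


def euler_to_matrix(euler: np.ndarray) -> np.ndarray:
    """z-y-z Euler angles (..., 3) -> rotation matrices (..., 3, 3)."""
    euler = np.asarray(euler, dtype=float)
    a, b, g = euler[..., 0], euler[..., 1], euler[..., 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    R = np.empty(euler.shape[:-1] + (3, 3))
    R[..., 0, 0] = ca * cb * cg - sa * sg
    R[..., 0, 1] = -ca * cb * sg - sa * cg
    R[..., 0, 2] = ca * sb
    R[..., 1, 0] = sa * cb * cg + ca * sg
    R[..., 1, 1] = -sa * cb * sg + ca * cg
    R[..., 1, 2] = sa * sb
    R[..., 2, 0] = -sb * cg
    R[..., 2, 1] = sb * sg
    R[..., 2, 2] = cb
    return R


def matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) -> z-y-z Euler angles (..., 3).

    At the gimbal-degenerate poles (beta = 0 or pi) only alpha+gamma
    (resp. alpha-gamma) is defined; alpha is set to 0 there.
    """
    R = np.asarray(R, dtype=float)
    cb = np.clip(R[..., 2, 2], -1.0, 1.0)
    beta = np.arccos(cb)
    sb_ok = np.abs(np.sin(beta)) > 1e-12
    alpha = np.where(sb_ok, np.arctan2(R[..., 1, 2], R[..., 0, 2]), 0.0)
    gamma = np.where(
        sb_ok,
        np.arctan2(R[..., 2, 1], -R[..., 2, 0]),
        np.where(cb > 0, np.arctan2(R[..., 1, 0], R[..., 0, 0]), np.arctan2(-R[..., 1, 0], -R[..., 0, 0])),
    )
    out = np.stack([alpha % (2 * np.pi), beta, gamma % (2 * np.pi)], axis=-1)
    return out


@dataclass
class ChainConformation:
    """Ordered rigid-body frames of N segments plus per-segment state labels.

    Attributes
    ----------
    euler:
        (N, 3) wrapped z-y-z Euler angles.
    states:
        length-N array of state ids from {B, L, P, S}.
    seg_lengths:
        (N,) segment lengths in nm (fixed by state and discretisation).
    unwrapped:
        optional (N, 2) array of cumulative (alpha~, gamma~) angles from the
        extended range (-inf, inf); populated by :func:`unwrap_angles`.
    """

    euler: np.ndarray
    states: np.ndarray
    seg_lengths: np.ndarray
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.euler = np.atleast_2d(np.asarray(self.euler, dtype=float))
        self.states = np.asarray(self.states, dtype=object)
        self.seg_lengths = np.asarray(self.seg_lengths, dtype=float)
        n = len(self.euler)
        if self.states.shape != (n,) or self.seg_lengths.shape != (n,):
            raise ValueError("euler, states and seg_lengths must have matching lengths")

    # Derived geometry -----------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.euler)

    def rotations(self) -> np.ndarray:
        return euler_to_matrix(self.euler)

    def tangents(self) -> np.ndarray:
        """Unit tangents t_n = R_n z0, shape (N, 3)."""
        return self.rotations()[..., :, 2]

    def u_vectors(self) -> np.ndarray:
        """Frame vectors u_n = R_n x0 that track the twist, shape (N, 3)."""
        return self.rotations()[..., :, 0]

    def vertices(self) -> np.ndarray:
        """(N+1, 3) vertex positions in nm, first vertex at the origin."""
        steps = self.seg_lengths[:, None] * self.tangents()
        verts = np.zeros((self.n_segments + 1, 3))
        np.cumsum(steps, axis=0, out=verts[1:])
        return verts

    def end_to_end(self) -> np.ndarray:
        return self.vertices()[-1]

    def extension_z(self) -> float:
        """Signed end-to-end projection on the force axis z0, nm."""
        return float(self.end_to_end()[2])

    def copy(self) -> "ChainConformation":
        return ChainConformation(
            self.euler.copy(),
            self.states.copy(),
            self.seg_lengths.copy(),
            None if self.unwrapped is None else self.unwrapped.copy(),
        )

    # Serialisation --------------------------------------------------------
    def to_tsv(self) -> str:
        """Plain-text table (1-based segment index, start vertex, angles, state)."""
        verts = self.vertices()
        df = pd.DataFrame(
            {
                "segment": np.arange(1, self.n_segments + 1),
                "x_nm": verts[:-1, 0],
                "y_nm": verts[:-1, 1],
                "z_nm": verts[:-1, 2],
                "alpha": self.euler[:, 0],
                "beta": self.euler[:, 1],
                "gamma": self.euler[:, 2],
                "b_nm": self.seg_lengths,
                "state": self.states,
            }
        )
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False, float_format="%.10e")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ChainConformation":
        df = pd.read_csv(io.StringIO(text), sep="\t")
        euler = df[["alpha", "beta", "gamma"]].to_numpy(float)
        return cls(euler, df["state"].to_numpy(object), df["b_nm"].to_numpy(float))


def uniform_chain(euler: np.ndarray, b: float, state: str = "B") -> ChainConformation:
    """Conformation with a single structural state and uniform segment length."""
    euler = np.atleast_2d(np.asarray(euler, dtype=float))
    n = len(euler)
    return ChainConformation(euler, np.array([state] * n, dtype=object), np.full(n, float(b)))


def frames_from_tangents(tangents: np.ndarray) -> np.ndarray:
    """Build minimally-twisting frames along a given unit-tangent sequence.

    The first frame takes u along the projection of x0 perpendicular to t_0;
    subsequent frames are parallel-transported (rotated about t_n x t_{n+1}),
    which yields zero twist by construction.  Returns Euler angles (N, 3).
    """
    t = np.asarray(tangents, dtype=float)
    t = t / np.linalg.norm(t, axis=1, keepdims=True)
    n = len(t)
    R = np.empty((n, 3, 3))
    # initial u: any unit vector perpendicular to t[0]
    ref = np.array([1.0, 0.0, 0.0])
    if abs(t[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ t[0]) * t[0]
    u /= np.linalg.norm(u)
    R[0] = np.column_stack([u, np.cross(t[0], u), t[0]])
    for i in range(1, n):
        axis = np.cross(t[i - 1], t[i])
        s = np.linalg.norm(axis)
        c = float(np.clip(t[i - 1] @ t[i], -1.0, 1.0))
        if s < 1e-14:
            rot = np.eye(3) if c > 0 else None
            if rot is None:
                raise ValueError("antipodal successive tangents: parallel transport undefined")
        else:
            axis = axis / s
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            theta = np.arctan2(s, c)
            rot = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        R[i] = rot @ R[i - 1]
        # re-orthonormalise to keep the triad clean over long chains
        ti = t[i]
        ui = R[i][:, 0] - (R[i][:, 0] @ ti) * ti
        ui /= np.linalg.norm(ui)
        R[i] = np.column_stack([ui, np.cross(ti, ui), ti])
    return matrix_to_euler(R)


def _apply_twist(euler: np.ndarray, twist_per_segment: float) -> np.ndarray:
    """Add a uniform twist by incrementing gamma cumulatively along the chain."""
    out = euler.copy()
    out[:, 2] = (out[:, 2] + twist_per_segment * np.arange(len(out))) % (2 * np.pi)
    return out


def build_fixture(
    kind: str,
    chain: ChainSpec,
    table: ParamTable | None = None,
    *,
    state: str = "B",
    twist_per_segment: float = 0.0,
    turns: float = 5.0,
    radius: float | None = None,
    pitch: float | None = None,
    stiffness_a: float | None = None,
    cap_segments: int = 0,
    seed: int | None = None,
) -> ChainConformation:
    """Deterministic conformation builders used as test fixtures.

    Parameters
    ----------
    kind:
        ``straight``   all tangents along +z0, optional uniform twist;
        ``circle``     closed planar polygon in the x-z plane;
        ``helix``      regular solenoid with ``turns`` full turns, given
                       ``radius`` and ``pitch`` (nm per turn); ``cap_segments``
                       straight segments along +z0 are prepended/appended
                       (out of the total N), mimicking the extended chain a
                       physical solenoid region is embedded in;
        ``plectoneme`` two interwound helical strands joined by a cap — a
                       geometric stand-in for a supercoiled plectoneme;
        ``random_walk`` Boltzmann-weighted bend angles for stiffness
                       ``stiffness_a`` (direct sampling, no Monte Carlo).
    """
    if table is None:
        table = ParamTable.default()
    b = chain.segment_length(table[state])
    n = chain.n_segments

    if kind == "straight":
        euler = np.zeros((n, 3))
        euler = _apply_twist(euler, twist_per_segment)
        return uniform_chain(euler, b, state)

    if kind == "circle":
        if n < 3:
            raise ValueError("a closed polygon needs at least 3 segments")
        # regular N-gon in the x-z plane; exterior angle 2*pi/N
        ang = 2 * np.pi * (np.arange(n) + 0.5) / n
        t = np.column_stack([np.sin(ang), np.zeros(n), np.cos(ang)])
        euler = frames_from_tangents(t)
        return uniform_chain(_apply_twist(euler, twist_per_segment), b, state)

    if kind == "helix":
        if radius is None or pitch is None:
            raise ValueError("helix fixture needs radius and pitch")
        if radius <= 0 or pitch <= 0:
            raise ValueError("helix radius and pitch must be positive")
        # unit tangent of a circular helix traversed at constant speed
        circumference = 2 * np.pi * radius
        slope = pitch / circumference  # tan of the pitch angle
        norm = np.hypot(1.0, slope)
        n_coil = n - 2 * cap_segments
        if n_coil < 3:
            raise ValueError("cap_segments leave too few segments for the coil")
        phi = 2 * np.pi * turns * (np.arange(n_coil) + 0.5) / n_coil
        t = np.column_stack(
            [-np.sin(phi) / norm, np.cos(phi) / norm, np.full(n_coil, slope / norm)]
        )
        if cap_segments:
            cap = np.tile([[0.0, 0.0, 1.0]], (cap_segments, 1))
            t = np.vstack([cap, t, cap])
        euler = frames_from_tangents(t)
        return uniform_chain(_apply_twist(euler, twist_per_segment), b, state)

    if kind == "plectoneme":
        if radius is None:
            radius = 4.0
        if pitch is None:
            pitch = 6.0
        # Down-strand and up-strand interwound helices (opposite phase keeps
        # the two strands 2*radius apart), joined by a semicircular cap.
        n_cap = max(6, n // 10)
        n_strand = (n - n_cap) // 2
        circumference = 2 * np.pi * radius
        slope = pitch / circumference
        norm = np.hypot(1.0, slope)
        phi1 = 2 * np.pi * turns * (np.arange(n_strand) + 0.5) / n_strand
        t_up = np.column_stack(
            [-np.sin(phi1) / norm, np.cos(phi1) / norm, np.full(n_strand, slope / norm)]
        )
        # cap: half-circle bringing the tangent from +z-ish to -z-ish
        th = np.pi * (np.arange(n_cap) + 0.5) / n_cap
        t_cap = np.column_stack([np.sin(th), np.zeros(n_cap), np.cos(th)])
        phi2 = phi1[::-1] + np.pi
        t_down = np.column_stack(
            [np.sin(phi2) / norm, -np.cos(phi2) / norm, np.full(n_strand, -slope / norm)]
        )
        t = np.vstack([t_up, t_cap, t_down])
        if len(t) < n:  # pad with straight tail
            t = np.vstack([t, np.tile([[0.0, 0.0, -1.0]], (n - len(t), 1))])
        euler = frames_from_tangents(t[:n])
        return uniform_chain(euler, b, state)

    if kind == "random_walk":
        a = stiffness_a
        if a is None:
            a, _ = chain.dimensionless_stiffness(table[state])
        rng = np.random.default_rng(seed)
        # exact direct sampling: relative polar angle beta' has density
        # proportional to exp(a*cos(beta')) sin(beta') on [0, pi], i.e. the
        # cosine x = cos(beta') has density ~ exp(a*x); invert the CDF.
        u = rng.random(n - 1)
        x = 1.0 + np.log1p(u * np.expm1(-2.0 * a)) / a
        azim = rng.random(n - 1) * 2 * np.pi
        R = np.empty((n, 3, 3))
        R[0] = np.eye(3)
        sb = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
        for i in range(1, n):
            # relative rotation: tilt by beta' about an axis at random azimuth
            ca, sa = np.cos(azim[i - 1]), np.sin(azim[i - 1])
            rel = euler_to_matrix(np.array([azim[i - 1], np.arccos(x[i - 1]), -azim[i - 1]]))
            R[i] = R[i - 1] @ rel
        return uniform_chain(matrix_to_euler(R), b, state)

    raise ValueError(f"unknown fixture kind {kind!r}")


def unwrap_angles(conf: ChainConformation) -> ChainConformation:
    """Populate the cumulative (alpha~, gamma~) angles of a conformation.

    Successive differences of the unwrapped angles lie in (-pi, pi]; each
    unwrapped angle differs from the wrapped one by an integer multiple of
    2*pi.  Returns a new conformation; the wrapped angles are untouched.
    """
    out = conf.copy()
    alpha = np.unwrap(conf.euler[:, 0])
    gamma = np.unwrap(conf.euler[:, 2])
    out.unwrapped = np.column_stack([alpha, gamma])
    return out
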