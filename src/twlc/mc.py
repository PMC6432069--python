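"""Metropolis Monte-Carlo sampling of twistable worm-like-chain conformations.

Samples equilibrium conformations of a single-state (B-form) discretised
chain under force and torque from the Boltzmann weight exp(-E_tot) with

    E_tot = E_bend + E_twist - f * d_z - 2 pi tau (Tw + Wr_Gauss) ,

i.e. the torque couples to the exact (Gauss double-sum) writhe — the sampler
has no locality constraint, so no Fuller surrogate is needed.  This makes it
the independent oracle for the transfer-matrix observables below the
buckling transition, and the reference for the Gauss-vs-Fuller writhe
comparison beyond it.

Move set (standard for supercoiled-DNA Monte Carlo):

* crankshaft — rotate a sub-chain rigidly about the chord through two of its
  vertices (extension and boundary tangents unchanged);
* tail/head pivot — rotate the tail (or head) rigidly about a random axis
  through a vertex;
* twist — increment the gamma Euler angle of a single segment (frame spins
  about its own tangent; positions unchanged).

All moves preserve segment lengths and frame orthonormality exactly.  The
writhe is updated incrementally: a rigid move leaves intra-block pair
contributions unchanged, so only moved-static segment pairs are recomputed
(O(m (N-m)) per move instead of O(N^2)).  Energies and topology are
resynchronised from scratch at a fixed cadence to keep round-off drift below
reporting precision.  Runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .chain import ChainConformation, matrix_to_euler
from .model import ChainSpec, Constraint, ParamTable
from .topology import (
    _HAVE_NUMBA,
    _cross_writhe_kernel,
    _full_writhe_kernel,
    pair_writhe,
)

__all__ = ["MCConfig", "EnsembleStats", "MetropolisSampler", "metropolis_sample",
           "incremental_writhe_update"]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class MCConfig:
    """Sampler controls.

    ``move_mix`` gives selection probabilities for (crankshaft, tail_pivot,
    head_pivot, twist); ``max_rotation`` caps every random rotation angle (radians);
    ``hard_core_diameter`` (nm) optionally rejects moves bringing
    non-adjacent segments closer than the given diameter (0 disables;
    without it the chain is a phantom chain and strand passage is allowed).
    """

    n_steps: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    move_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "crankshaft": 0.4,
            "tail_pivot": 0.2,
            "head_pivot": 0.2,
            "twist": 0.2,
        }
    )
    max_rotation: float = 0.35
    max_twist: float = 0.25
    hard_core_diameter: float = 0.0
    resync_every: int = 20_000
    measure_writhe: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.move_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("move_mix probabilities must sum to 1")
        if not (self.n_steps > self.burn_in >= 0):
            raise ValueError("need n_steps > burn_in >= 0")


def _batch_stats(x: np.ndarray, n_batches: int = 20) -> tuple[float, float]:
    """Mean and batch-means standard error (>= 20 batches).

    The series is first decimated by its measured integrated autocorrelation
    time so the batches are built from effectively independent values —
    plain batch means on a strongly correlated series underestimates the
    error when batches are shorter than ~10 autocorrelation times.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        return float("nan"), float("nan")
    mean = float(np.mean(x))
    step = max(1, int(round(_autocorr_time(x))))
    y = x[::step]
    n = len(y)
    if n < 2 * n_batches:
        return mean, float(np.std(y, ddof=1) / math.sqrt(max(n - 1, 1)))
    m = n // n_batches
    batches = y[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return mean, float(np.std(batches, ddof=1) / math.sqrt(n_batches))


def _autocorr_time(x: np.ndarray, c: float = 6.0) -> float:
    """Integrated autocorrelation time with an adaptive window."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10:
        return float("nan")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    tau = 1.0
    for lag in range(1, n // 2):
        rho = np.dot(x[:-lag], x[lag:]) / ((n - lag) * var)
        tau += 2.0 * rho
        if lag >= c * tau:
            break
    return max(tau, 1.0)


@dataclass
class EnsembleStats:
    """Averages (with batch-means standard errors) of an equilibrium run."""

    mean_ext: float
    stderr_ext: float
    mean_tw: float
    stderr_tw: float
    mean_wr: float
    stderr_wr: float
    mean_dlk: float
    stderr_dlk: float
    acceptance: Dict[str, float]
    autocorr_time: float
    n_samples: int

    def row(self) -> dict:
        d = {
            "mean_ext_nm": self.mean_ext,
            "stderr_ext_nm": self.stderr_ext,
            "mean_tw": self.mean_tw,
            "stderr_tw": self.stderr_tw,
            "mean_wr": self.mean_wr,
            "stderr_wr": self.stderr_wr,
            "mean_dlk": self.mean_dlk,
            "stderr_dlk": self.stderr_dlk,
            "autocorr_time": self.autocorr_time,
            "n_samples": self.n_samples,
        }
        for k, v in self.acceptance.items():
            d[f"acc_{k}"] = v
        return d


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def _cross_pair_writhe(starts, ends, moved_idx, static_idx) -> float:
    """Sum of pair-writhe contributions between two disjoint index sets,
    skipping vertex-sharing (adjacent) pairs."""
    if len(moved_idx) == 0 or len(static_idx) == 0:
        return 0.0
    if _HAVE_NUMBA:
        return float(
            _cross_writhe_kernel(
                np.ascontiguousarray(starts[moved_idx]),
                np.ascontiguousarray(ends[moved_idx]),
                np.ascontiguousarray(moved_idx),
                np.ascontiguousarray(starts[static_idx]),
                np.ascontiguousarray(ends[static_idx]),
                np.ascontiguousarray(static_idx),
            )
        )
    mi = moved_idx[:, None]
    si = static_idx[None, :]
    keep = np.abs(mi - si) >= 2
    if not np.any(keep):
        return 0.0
    p1 = starts[moved_idx][:, None, :]
    p2 = ends[moved_idx][:, None, :]
    p3 = starts[static_idx][None, :, :]
    p4 = ends[static_idx][None, :, :]
    w = pair_writhe(
        np.broadcast_to(p1, keep.shape + (3,)),
        np.broadcast_to(p2, keep.shape + (3,)),
        np.broadcast_to(p3, keep.shape + (3,)),
        np.broadcast_to(p4, keep.shape + (3,)),
    )
    return float(np.sum(np.where(keep, w, 0.0)))


def incremental_writhe_update(
    starts_before: np.ndarray,
    ends_before: np.ndarray,
    starts_after: np.ndarray,
    ends_after: np.ndarray,
    changed: np.ndarray,
) -> float:
    """Writhe change when only the segments in ``changed`` moved rigidly.

    Intra-block pair geometry is invariant under a rigid move (as is the
    static block's), so the change reduces exactly to the moved-static cross
    pairs — writhe updates cost O(m (N-m)) instead of O(N^2).  Exactness
    against the full double sum is asserted in the test suite.
    """
    n = len(starts_before)
    changed = np.asarray(changed, dtype=int)
    static = np.setdiff1d(np.arange(n), changed, assume_unique=False)
    before = _cross_pair_writhe(starts_before, ends_before, changed, static)
    after = _cross_pair_writhe(starts_after, ends_after, changed, static)
    return after - before


def _full_writhe(starts, ends) -> float:
    """All-pairs Gauss writhe over non-adjacent segment pairs."""
    n = len(starts)
    if n < 3:
        return 0.0
    if _HAVE_NUMBA:
        return float(
            _full_writhe_kernel(np.ascontiguousarray(starts), np.ascontiguousarray(ends))
        )
    i, j = np.triu_indices(n, k=2)
    w = pair_writhe(starts[i], ends[i], starts[j], ends[j])
    return float(np.nansum(w))


class MetropolisSampler:
    """Mutable sampler state for one (chain, constraint) condition."""

    def __init__(
        self,
        chain: ChainSpec,
        constraint: Constraint,
        table: ParamTable | None = None,
        config: MCConfig | None = None,
        state: str = "B",
    ):
        if table is None:
            table = ParamTable.default()
        self.table = table
        self.chain = chain
        self.constraint = constraint
        self.config = config or MCConfig()
        st = table[state]
        self.a, self.c = chain.dimensionless_stiffness(st)
        self.b = chain.segment_length(st)
        self.n = chain.n_segments
        self.rng = np.random.default_rng(self.config.seed)
        # The Gauss writhe only enters the Boltzmann weight through the
        # torque term, so at tau = 0 it is not tracked per move (it is still
        # measured on sampled snapshots).
        self.track_writhe = constraint.tau != 0.0
        # start from a straight chain pre-twisted at the mean-field twist
        # angle sin(psi) = 2 pi tau / (2 pi c) per junction — an allowed
        # initial condition that removes the slow initial twist relaxation
        psi0 = math.asin(max(-0.99, min(0.99, constraint.tau / self.c)))
        gam = (psi0 * np.arange(self.n)) % TWO_PI
        cg, sg = np.cos(gam), np.sin(gam)
        self.R = np.zeros((self.n, 3, 3))
        self.R[:, 0, 0] = cg
        self.R[:, 0, 1] = -sg
        self.R[:, 1, 0] = sg
        self.R[:, 1, 1] = cg
        self.R[:, 2, 2] = 1.0
        self._resync()
        self.accepted = {k: 0 for k in ("crankshaft", "tail_pivot", "head_pivot", "twist")}
        self.proposed = {k: 0 for k in self.accepted}

    # -- state bookkeeping -------------------------------------------------
    def _resync(self) -> None:
        """Recompute vertices, topology and elastic energies from frames."""
        t = self.R[:, :, 2]
        self.verts = np.zeros((self.n + 1, 3))
        np.cumsum(self.b * t, axis=0, out=self.verts[1:])
        self.tw = self._twist_all()
        self.wr = (
            _full_writhe(self.verts[:-1], self.verts[1:]) if self.track_writhe else 0.0
        )
        self.e_bend, self.e_twist = self._elastic_all()

    def _twist_all(self) -> float:
        u = self.R[:, :, 0]
        t = self.R[:, :, 2]
        return float(
            np.einsum("ij,ij->i", np.cross(u[:-1], u[1:]), t[:-1]).sum() / TWO_PI
        )

    def _elastic_all(self) -> tuple[float, float]:
        t = self.R[:, :, 2]
        u = self.R[:, :, 0]
        dt2 = np.sum((t[1:] - t[:-1]) ** 2, axis=1)
        sphi = np.einsum("ij,ij->i", np.cross(u[:-1], u[1:]), t[:-1])
        return float(0.5 * self.a * dt2.sum()), float(0.5 * self.c * (sphi**2).sum())

    def _junction_terms(self, junctions: np.ndarray, R=None) -> tuple[float, float, float]:
        """(bend, twist-energy, twist-number) summed over given junctions."""
        if R is None:
            R = self.R
        junctions = junctions[(junctions >= 0) & (junctions < self.n - 1)]
        if len(junctions) == 0:
            return 0.0, 0.0, 0.0
        t0 = R[junctions, :, 2]
        t1 = R[junctions + 1, :, 2]
        u0 = R[junctions, :, 0]
        u1 = R[junctions + 1, :, 0]
        dt2 = np.sum((t1 - t0) ** 2, axis=1)
        sphi = np.einsum("ij,ij->i", np.cross(u0, u1), t0)
        return (
            float(0.5 * self.a * dt2.sum()),
            float(0.5 * self.c * (sphi**2).sum()),
            float(sphi.sum() / TWO_PI),
        )

    @property
    def dz(self) -> float:
        return float(self.verts[-1, 2])

    def total_energy(self) -> float:
        return (
            self.e_bend
            + self.e_twist
            - self.constraint.f * self.dz
            - TWO_PI * self.constraint.tau * (self.tw + self.wr)
        )

    def conformation(self) -> ChainConformation:
        euler = matrix_to_euler(self.R)
        return ChainConformation(
            euler, np.array(["B"] * self.n, dtype=object), np.full(self.n, self.b)
        )

    # -- hard-core check ---------------------------------------------------
    def _clash(self, new_verts, moved) -> bool:
        d = self.config.hard_core_diameter
        if d <= 0:
            return False
        static = np.setdiff1d(np.arange(self.n), moved)
        if len(static) == 0 or len(moved) == 0:
            return False
        # midpoint distance screen (segments are short against Lp)
        mid_m = 0.5 * (new_verts[moved] + new_verts[moved + 1])
        mid_s = 0.5 * (new_verts[static] + new_verts[static + 1])
        keep = np.abs(moved[:, None] - static[None, :]) >= 2
        dist = np.linalg.norm(mid_m[:, None, :] - mid_s[None, :, :], axis=-1)
        return bool(np.any(dist[keep] < d))

    # -- moves -------------------------------------------------------------
    def _attempt_crankshaft(self) -> bool:
        n = self.n
        wmax = max(4, n // 4)
        i = int(self.rng.integers(0, n - 2))
        j = int(self.rng.integers(i + 2, min(i + wmax, n) + 1))
        angle = float(self.rng.uniform(-self.config.max_rotation, self.config.max_rotation))
        axis = self.verts[j] - self.verts[i]
        nrm = np.linalg.norm(axis)
        if nrm < 1e-12:
            return False
        rot = _rotation_about(axis / nrm, angle)
        moved = np.arange(i, j)
        newR = self.R.copy()
        newR[moved] = np.einsum("ab,nbc->nac", rot, self.R[moved])
        new_verts = self.verts.copy()
        new_verts[i + 1 : j] = self.verts[i] + (self.verts[i + 1 : j] - self.verts[i]) @ rot.T
        return self._metropolis(newR, new_verts, moved, dz_changes=False)

    def _attempt_tail_pivot(self) -> bool:
        n = self.n
        i = int(self.rng.integers(1, n))
        angle = float(self.rng.uniform(-self.config.max_rotation, self.config.max_rotation))
        axis = self.rng.normal(size=3)
        rot = _rotation_about(axis, angle)
        moved = np.arange(i, n)
        newR = self.R.copy()
        newR[moved] = np.einsum("ab,nbc->nac", rot, self.R[moved])
        new_verts = self.verts.copy()
        new_verts[i + 1 :] = self.verts[i] + (self.verts[i + 1 :] - self.verts[i]) @ rot.T
        return self._metropolis(newR, new_verts, moved, dz_changes=True)

    def _attempt_head_pivot(self) -> bool:
        """Rotate the head block (segments 0..i-1) about vertex i.

        The mirror image of the tail pivot.  Without it the first segments
        are only reachable through chord-constrained crankshafts and their
        orientations equilibrate far too slowly under force (the tracked
        origin pins vertex 0, so the rotated head is re-translated to keep
        vertex 0 at the origin — a pure gauge choice)."""
        n = self.n
        i = int(self.rng.integers(1, n))
        angle = float(self.rng.uniform(-self.config.max_rotation, self.config.max_rotation))
        axis = self.rng.normal(size=3)
        rot = _rotation_about(axis, angle)
        moved = np.arange(0, i)
        newR = self.R.copy()
        newR[moved] = np.einsum("ab,nbc->nac", rot, self.R[moved])
        new_verts = self.verts.copy()
        new_verts[:i] = self.verts[i] + (self.verts[:i] - self.verts[i]) @ rot.T
        new_verts -= new_verts[0]  # keep vertex 0 at the origin
        return self._metropolis(newR, new_verts, moved, dz_changes=True)

    def _attempt_twist(self) -> bool:
        i = int(self.rng.integers(0, self.n))
        dphi = float(self.rng.uniform(-self.config.max_twist, self.config.max_twist))
        cg, sg = math.cos(dphi), math.sin(dphi)
        rz = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
        newR = self.R.copy()
        newR[i] = self.R[i] @ rz  # spin about own tangent; positions unchanged
        junctions = np.array([i - 1, i])
        b0, tE0, tw0 = self._junction_terms(junctions)
        b1, tE1, tw1 = self._junction_terms(junctions, newR)
        dE = (tE1 - tE0) - TWO_PI * self.constraint.tau * (tw1 - tw0)
        if dE <= 0 or self.rng.random() < math.exp(-dE):
            self.R = newR
            self.e_twist += tE1 - tE0
            self.tw += tw1 - tw0
            return True
        return False

    def _metropolis(self, newR, new_verts, moved, dz_changes: bool) -> bool:
        junctions = np.array([moved[0] - 1, moved[-1]])
        b0, tE0, tw0 = self._junction_terms(junctions)
        b1, tE1, tw1 = self._junction_terms(junctions, newR)
        dwr = 0.0
        if self.track_writhe:
            dwr = incremental_writhe_update(
                self.verts[:-1], self.verts[1:], new_verts[:-1], new_verts[1:], moved
            )
        dE = (b1 - b0) + (tE1 - tE0) - TWO_PI * self.constraint.tau * ((tw1 - tw0) + dwr)
        if dz_changes:
            dE -= self.constraint.f * (new_verts[-1, 2] - self.verts[-1, 2])
        if not (dE <= 0 or self.rng.random() < math.exp(-dE)):
            return False
        if self._clash(new_verts, moved):
            return False
        self.R = newR
        self.verts = new_verts
        self.e_bend += b1 - b0
        self.e_twist += tE1 - tE0
        self.tw += tw1 - tw0
        self.wr += dwr
        return True

    # -- driver ------------------------------------------------------------
    def run(self, collect_trajectory: bool = False):
        cfg = self.config
        movers = {
            "crankshaft": self._attempt_crankshaft,
            "tail_pivot": self._attempt_tail_pivot,
            "head_pivot": self._attempt_head_pivot,
            "twist": self._attempt_twist,
        }
        names = list(cfg.move_mix)
        probs = np.array([cfg.move_mix[k] for k in names])
        choices = self.rng.choice(len(names), size=cfg.n_steps, p=probs)
        samples = {"ext": [], "tw": [], "wr": []}
        trajectory = []
        window_attempts = 0
        window_accepts = 0
        for step in range(cfg.n_steps):
            name = names[choices[step]]
            self.proposed[name] += 1
            ok = movers[name]()
            if ok:
                self.accepted[name] += 1
            window_attempts += 1
            window_accepts += ok
            if window_attempts == 2000:
                if window_accepts == 0:
                    raise RuntimeError(
                        "no accepted moves in 2000 attempts; reduce max_rotation"
                    )
                window_attempts = window_accepts = 0
            if (step + 1) % cfg.resync_every == 0:
                self._resync()
            if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0:
                samples["ext"].append(self.dz)
                samples["tw"].append(self.tw)
                if self.track_writhe:
                    samples["wr"].append(self.wr)
                elif cfg.measure_writhe:
                    samples["wr"].append(_full_writhe(self.verts[:-1], self.verts[1:]))
                else:
                    samples["wr"].append(float("nan"))
                if collect_trajectory:
                    trajectory.append(self.conformation())
        self._resync()
        ext = np.array(samples["ext"])
        tw = np.array(samples["tw"])
        wr = np.array(samples["wr"])
        dlk = tw + wr
        m_ext, se_ext = _batch_stats(ext)
        m_tw, se_tw = _batch_stats(tw)
        m_wr, se_wr = _batch_stats(wr)
        m_dlk, se_dlk = _batch_stats(dlk)
        acc = {
            k: (self.accepted[k] / self.proposed[k] if self.proposed[k] else float("nan"))
            for k in self.accepted
        }
        stats = EnsembleStats(
            mean_ext=m_ext, stderr_ext=se_ext,
            mean_tw=m_tw, stderr_tw=se_tw,
            mean_wr=m_wr, stderr_wr=se_wr,
            mean_dlk=m_dlk, stderr_dlk=se_dlk,
            acceptance=acc,
            autocorr_time=_autocorr_time(ext),
            n_samples=len(ext),
        )
        if collect_trajectory:
            return stats, trajectory
        return stats


def metropolis_sample(
    chain: ChainSpec,
    constraint: Constraint,
    table: ParamTable | None = None,
    config: MCConfig | None = None,
    collect_trajectory: bool = False,
):
    """Equilibrium ensemble statistics of the single-state chain (see
    :class:`MetropolisSampler`)."""
    sampler = MetropolisSampler(chain, constraint, table, config)
    return sampler.run(collect_trajectory=collect_trajectory)
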