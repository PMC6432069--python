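"""Physical constants, per-state DNA parameters, chain discretisation and unit handling.

The mechanical model treats double-stranded DNA as a discretised twistable
worm-like chain whose segments can each adopt one of four structural states:

``B``
    canonical right-handed duplex (the reference state),
``L``
    left-handed duplex formed under large negative torque,
``P``
    strongly overwound right-handed form favoured by large positive torque,
``S``
    elongated underwound form produced by overstretching.

Each state ``u`` is described by a bending persistence length ``Lp(u)`` and a
twisting persistence length ``Ltw(u)`` (both in nm, energies being measured in
units of kBT), a contour length per base pair relative to B-DNA, a helical
repeat ``h_u`` (bp/turn) with an explicit handedness sign, a base-pairing free
energy ``mu_u`` per bp relative to B-DNA (kBT) and a dimensionless parameter
``lambda_u`` weighting the single-writhe (Fuller) part of the torque coupling
in the transfer-matrix model.

All energies are expressed in kBT; forces therefore carry units of 1/nm
(kBT/nm) and torques are dimensionless multiples of kBT.  Helper conversions
to/from pN and pN*nm are provided; they require a temperature, which defaults
to 298.15 K.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Tuple

import yaml

__all__ = [
    "KB_PN_NM_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "RHO_B_NM",
    "STATE_IDS",
    "StateParams",
    "ParamTable",
    "ChainSpec",
    "Constraint",
    "kbt_pn_nm",
    "convert_units",
]

#: Boltzmann constant in pN*nm per kelvin (1.380649e-23 J/K = 1.380649e-2 pN*nm/K).
KB_PN_NM_PER_K = 1.380649e-2

#: Default absolute temperature used for unit conversions, K.
DEFAULT_TEMPERATURE_K = 298.15

#: Base-pair rise of B-DNA, nm.
RHO_B_NM = 0.33

STATE_IDS: Tuple[str, ...] = ("B", "L", "P", "S")


def kbt_pn_nm(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB*T expressed in pN*nm."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return KB_PN_NM_PER_K * temperature_K


_UNIT_PAIRS = {
    ("pN", "kBT_per_nm"): lambda v, kbt: v / kbt,
    ("kBT_per_nm", "pN"): lambda v, kbt: v * kbt,
    ("pN·nm", "kBT"): lambda v, kbt: v / kbt,
    ("kBT", "pN·nm"): lambda v, kbt: v * kbt,
}
# ASCII aliases accepted everywhere the dotted forms are.
_UNIT_ALIASES = {"pN.nm": "pN·nm", "pN*nm": "pN·nm", "pNnm": "pN·nm"}


def convert_units(
    value: float,
    from_unit: str,
    to_unit: str,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> float:
    """Convert between laboratory and thermal units.

    Supported pairs: pN <-> kBT_per_nm (forces) and pN·nm <-> kBT (torques /
    energies).  Round-tripping is the identity to machine precision.
    """
    f = _UNIT_ALIASES.get(from_unit, from_unit)
    t = _UNIT_ALIASES.get(to_unit, to_unit)
    if f == t:
        return value
    try:
        conv = _UNIT_PAIRS[(f, t)]
    except KeyError:
        raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}") from None
    return conv(value, kbt_pn_nm(temperature_K))


@dataclass(frozen=True)
class StateParams:
    """Mechanical and thermodynamic constants of one DNA structural state.

    Parameters
    ----------
    state_id:
        One of ``"B"``, ``"L"``, ``"P"``, ``"S"``.
    Lp, Ltw:
        Bending and twisting persistence lengths, nm.
    contour_ratio:
        Base-pair rise relative to B-DNA (dimensionless).
    h:
        Helical repeat, bp per turn (always positive; chirality is carried by
        ``handedness``).
    handedness:
        +1 for right-handed helices, -1 for left-handed ones.
    mu:
        Base-pairing free energy per bp relative to B-DNA, kBT.
    lam:
        Dimensionless weight of the Fuller-writhe part of the torque coupling.
    """

    state_id: str
    Lp: float
    Ltw: float
    contour_ratio: float
    h: float
    handedness: int
    mu: float
    lam: float

    def __post_init__(self) -> None:
        if self.state_id not in STATE_IDS:
            raise ValueError(f"unknown state id {self.state_id!r}")
        for name in ("Lp", "Ltw", "h", "contour_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive for state {self.state_id}")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be +1 or -1")
        if self.state_id == "B":
            if self.mu != 0.0 or self.handedness != 1 or self.contour_ratio != 1.0:
                raise ValueError(
                    "state B is the reference state: mu must be 0, handedness +1 "
                    "and contour_ratio 1"
                )

    @property
    def rise(self) -> float:
        """Base-pair rise in this state, nm."""
        return self.contour_ratio * RHO_B_NM

    @property
    def lk0_per_bp(self) -> float:
        """Relaxed linking number per bp (signed turns/bp): handedness / h."""
        return self.handedness / self.h


class ParamTable(Mapping[str, StateParams]):
    """Immutable mapping from state id to :class:`StateParams`.

    ``ParamTable.default()`` returns the packaged four-state table; subsets are
    allowed (useful in tests), but state ``B`` must always be present because
    it defines the topological and energetic reference.
    """

    def __init__(self, states: Iterable[StateParams]):
        self._states: Dict[str, StateParams] = {}
        for s in states:
            if s.state_id in self._states:
                raise ValueError(f"duplicate state {s.state_id!r}")
            self._states[s.state_id] = s
        if "B" not in self._states:
            raise ValueError("parameter table must contain the reference state B")

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, key: str) -> StateParams:
        try:
            return self._states[key]
        except KeyError:
            raise KeyError(f"unknown DNA state {key!r}; known: {sorted(self._states)}") from None

    def __iter__(self):
        return iter(self._states)

    def __len__(self) -> int:
        return len(self._states)

    # Construction ---------------------------------------------------------
    @classmethod
    def default(cls) -> "ParamTable":
        """The packaged default four-state parameter table."""
        path = importlib.resources.files("twlc.data").joinpath("default_states.yaml")
        return cls.from_yaml(path.read_text())

    @classmethod
    def from_yaml(cls, text: str) -> "ParamTable":
        doc = yaml.safe_load(text)
        states = [
            StateParams(
                state_id=row["state_id"],
                Lp=float(row["Lp_nm"]),
                Ltw=float(row["Ltw_nm"]),
                contour_ratio=float(row["contour_ratio"]),
                h=float(row["helical_repeat_bp"]),
                handedness=int(row["handedness"]),
                mu=float(row["mu_kBT"]),
                lam=float(row["lambda"]),
            )
            for row in doc["states"]
        ]
        return cls(states)

    def to_yaml(self) -> str:
        doc = {
            "states": [
                {
                    "state_id": s.state_id,
                    "Lp_nm": s.Lp,
                    "Ltw_nm": s.Ltw,
                    "contour_ratio": s.contour_ratio,
                    "helical_repeat_bp": s.h,
                    "handedness": s.handedness,
                    "mu_kBT": s.mu,
                    "lambda": s.lam,
                }
                for s in self._states.values()
            ]
        }
        return yaml.safe_dump(doc, sort_keys=False)

    def with_mu(self, **mu_by_state: float) -> "ParamTable":
        """Copy of the table with selected base-pairing energies replaced."""
        rows = []
        for sid, s in self._states.items():
            rows.append(replace(s, mu=mu_by_state[sid]) if sid in mu_by_state else s)
        return ParamTable(rows)

    # Derived quantities ---------------------------------------------------
    def relaxed_linking_density(self, state_id: str) -> float:
        """Relaxed linking-number density of ``state_id`` relative to B, turns/bp.

        Defined as ``handedness_u / h_u - 1 / h_B``; identically zero for B.
        """
        s = self[state_id]
        return s.lk0_per_bp - self["B"].lk0_per_bp


@dataclass(frozen=True)
class ChainSpec:
    """Discretisation of a DNA molecule of ``n_bp`` base pairs.

    ``q`` is the (real-valued) number of base pairs per segment; the number of
    segments is ``N = round(n_bp / q)``.  A segment in state ``u`` has length
    ``b_u = q * rise_u`` which must remain small against the persistence
    lengths for the discrete elastic energy to be meaningful; ``b_u <= Lp/5``
    is enforced by :meth:`validate_against`.
    """

    n_bp: int
    q: float = 1.5

    def __post_init__(self) -> None:
        if self.n_bp <= 0 or self.q <= 0:
            raise ValueError("n_bp and q must be positive")
        if self.n_segments < 2:
            raise ValueError("chain must discretise into at least 2 segments")

    @property
    def n_segments(self) -> int:
        return int(round(self.n_bp / self.q))

    @property
    def contour_length_b(self) -> float:
        """Contour length of the molecule in the B-form, nm."""
        return self.n_bp * RHO_B_NM

    def segment_length(self, state: StateParams) -> float:
        """Segment length b_u = q * rise_u, nm."""
        return self.q * state.rise

    def lk0_b(self, table: ParamTable) -> float:
        """Relaxed linking number of the whole molecule in B-form, turns."""
        return self.n_bp / table["B"].h

    def validate_against(self, table: ParamTable) -> None:
        for s in table.values():
            b = self.segment_length(s)
            if b > s.Lp / 5.0 or b > s.Ltw / 5.0:
                raise ValueError(
                    f"segment length b={b:.3f} nm too coarse for state "
                    f"{s.state_id} (Lp={s.Lp}, Ltw={s.Ltw}); reduce q"
                )

    def dimensionless_stiffness(self, state: StateParams) -> Tuple[float, float]:
        """Dimensionless bending/twisting stiffnesses (a, c) = (Lp/b, Ltw/b)."""
        b = self.segment_length(state)
        if b <= 0:
            raise ValueError("segment length must be positive")
        return state.Lp / b, state.Ltw / b


@dataclass(frozen=True)
class Constraint:
    """Mechanical constraint: stretching force and torque in thermal units.

    ``f`` is the force in kBT/nm applied along the fixed laboratory z axis
    (must be >= 0) and ``tau`` the torque in kBT about that axis.
    ``temperature_K`` is only used when converting to/from pN and pN*nm.
    """

    f: float = 0.0
    tau: float = 0.0
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("force magnitude must be non-negative")

    @classmethod
    def from_pn(
        cls,
        f_pN: float = 0.0,
        tau_pN_nm: float = 0.0,
        temperature_K: float = DEFAULT_TEMPERATURE_K,
    ) -> "Constraint":
        kbt = kbt_pn_nm(temperature_K)
        return cls(f=f_pN / kbt, tau=tau_pN_nm / kbt, temperature_K=temperature_K)

    @property
    def f_pn(self) -> float:
        return self.f * kbt_pn_nm(self.temperature_K)

    @property
    def tau_pn_nm(self) -> float:
        return self.tau * kbt_pn_nm(self.temperature_K)


def relaxed_linking_density(state_id: str, table: ParamTable | None = None) -> float:
    """Module-level convenience wrapper around :meth:`ParamTable.relaxed_linking_density`."""
    if table is None:
        table = ParamTable.default()
    return table.relaxed_linking_density(state_id)
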