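"""Kinetic parameterization of the promoter--spacer--operator system.

Connects biochemical quantities (repressor concentration, operator
affinity) to the rate constants used by the simulator and the analytic
model:

* ``k_F``  -- promoter firing rate (s^-1), one elongating RNAP per firing
* ``k_B``  -- roadblocker binding rate (s^-1), [repressor] x on-rate constant
* ``k_U``  -- roadblocker unbinding rate (s^-1), set by operator affinity
* ``k_T``  -- termination rate of a paused RNAP (s^-1), Mfd-dependent
* ``k_SD`` -- roadblock dislodgement rate by a single paused RNAP (s^-1)
* ``k_MD`` -- dislodgement rate when trailing RNAPs are queued behind (s^-1)

Geometry: the RNAP occupies a 30 bp footprint and advances 1 bp per time
step (dt = 1/40 s at 40 bp/s); the operator is 20 bp, its upstream edge a
``spacer`` bp downstream of the transcription start; a promoter can reload
only while no footprint overlaps the +5 position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "KineticParams",
    "OperatorSpec",
    "RepressorSpec",
    "PromoterLadder",
    "binding_rate",
    "unbinding_rate",
    "calibrate_reference_kU",
    "equilibrium_occupancy",
    "promoter_ladder",
    "K_ON",
    "VACANCY_OID_250NM",
    "K_U_OID",
    "OPERATOR_RELATIVE_KD",
    "default_operators",
]

#: LacI tetramer on-rate constant, M^-1 s^-1 (in vivo imaging estimate).
K_ON = 2.51e6

#: Fraction of time the ideal operator is vacant at the reference 250 nM
#: repressor concentration; anchors the reference unbinding rate.
VACANCY_OID_250NM = 0.0007

#: Relative in vivo dissociation constants of the three lac operators.
OPERATOR_RELATIVE_KD = {"Oid": 1.0, "O1": 5.2, "O2": 22.9}


@dataclass(frozen=True)
class KineticParams:
    """Full rate/geometry parameterization of one simulation condition.

    Rates in s^-1, lengths in bp, dt in s. The elongation step is 1 bp per
    dt, so ``velocity * dt`` must equal 1 bp.
    """

    k_F: float
    k_B: float
    k_U: float
    k_T: float
    k_SD: float
    k_MD: float
    velocity: float = 40.0
    rnap_footprint: int = 30
    operator_length: int = 20
    occlusion_position: int = 5
    spacer: int = 102
    dt: float = 1.0 / 40.0

    def __post_init__(self) -> None:
        for name in ("k_F", "k_B", "k_U", "k_T", "k_SD", "k_MD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.velocity <= 0:
            raise ValueError("velocity must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("rnap_footprint", "operator_length", "spacer"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if abs(self.velocity * self.dt - 1.0) > 1e-9:
            raise ValueError(
                "velocity * dt must equal 1 bp (advancement is 1 bp per step); "
                f"got {self.velocity * self.dt}"
            )

    def replace(self, **changes) -> "KineticParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParams":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        kwargs = {}
        for k, v in d.items():
            if k not in known:
                raise KeyError(f"unknown kinetic parameter {k!r}")
            kwargs[k] = int(v) if k in ("rnap_footprint", "operator_length",
                                        "occlusion_position", "spacer") else float(v)
        return cls(**kwargs)


@dataclass(frozen=True)
class OperatorSpec:
    """A repressor binding site with affinity relative to the ideal site."""

    name: str
    relative_kd: float
    k_U: float

    def __post_init__(self) -> None:
        if self.relative_kd <= 0:
            raise ValueError("relative_kd must be > 0")
        if self.k_U < 0:
            raise ValueError("k_U must be >= 0")


@dataclass(frozen=True)
class RepressorSpec:
    """A roadblocking protein at a cellular concentration (nM)."""

    concentration: float
    k_on: float = K_ON

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0 nM")
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")


@dataclass(frozen=True)
class PromoterLadder:
    """Ordered set of constitutive promoters spanning a firing-rate range."""

    names: tuple
    k_F_values: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.k_F_values, dtype=float)
        if len(self.names) != v.size:
            raise ValueError("names and k_F_values must have equal length")
        if np.any(v <= 0):
            raise ValueError("firing rates must be strictly positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("firing rates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.k_F_values)


def binding_rate(rep: RepressorSpec) -> float:
    """Roadblocker binding rate k_B = k_on x [repressor].

    Concentration is supplied in nM and converted to M internally, so
    250 nM at the default on-rate gives k_B = 0.6275 s^-1 (a mean wait of
    ~1.5 s for the operator to refill).
    """
    return rep.k_on * rep.concentration * 1e-9


def unbinding_rate(op: OperatorSpec | float, k_U_ref: float) -> float:
    """Unbinding rate of an operator: k_U = k_U_ref x relative_kd.

    ``op`` may be an :class:`OperatorSpec` or a bare relative Kd. The
    reference rate is the ideal operator's; see
    :func:`calibrate_reference_kU`.
    """
    rel = op.relative_kd if isinstance(op, OperatorSpec) else float(op)
    if rel <= 0 or k_U_ref <= 0:
        raise ValueError("relative_kd and k_U_ref must be > 0")
    return k_U_ref * rel


def calibrate_reference_kU(vacancy_fraction: float, k_B: float) -> float:
    """Solve vacancy = k_U / (k_B + k_U) for k_U.

    Used to anchor the ideal operator's unbinding rate from its observed
    vacancy at the reference repressor concentration.
    """
    if not 0.0 < vacancy_fraction < 1.0:
        raise ValueError("vacancy_fraction must lie in (0, 1)")
    if k_B <= 0:
        raise ValueError("k_B must be > 0")
    return vacancy_fraction * k_B / (1.0 - vacancy_fraction)


def equilibrium_occupancy(k_B: float, k_U: float) -> float:
    """Stationary probability the operator is bound: k_B / (k_B + k_U)."""
    if k_B < 0 or k_U < 0:
        raise ValueError("rates must be >= 0")
    if k_B + k_U == 0:
        raise ValueError("occupancy undefined when both rates are zero")
    return k_B / (k_B + k_U)


def promoter_ladder(n: int, k_F_min: float, k_F_max: float) -> PromoterLadder:
    """n log-spaced promoter firing rates inclusive of both anchors."""
    if n < 2:
        raise ValueError("a ladder needs at least 2 promoters")
    if not 0 < k_F_min < k_F_max:
        raise ValueError("need 0 < k_F_min < k_F_max")
    values = np.geomspace(k_F_min, k_F_max, n)
    names = tuple(f"P{i + 1:02d}" for i in range(n))
    return PromoterLadder(names=names, k_F_values=tuple(values))


#: Reference unbinding rate of the ideal operator, calibrated from its
#: 0.07% vacancy at 250 nM repressor.
K_U_OID = calibrate_reference_kU(
    VACANCY_OID_250NM, binding_rate(RepressorSpec(250.0))
)


def default_operators(k_U_ref: float = K_U_OID) -> dict:
    """The three lac operators with unbinding rates from the reference."""
    return {
        name: OperatorSpec(name=name, relative_kd=rel,
                           k_U=unbinding_rate(rel, k_U_ref))
        for name, rel in OPERATOR_RELATIVE_KD.items()
    }
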