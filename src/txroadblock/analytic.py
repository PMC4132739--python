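"""Closed-form results for the low-RNAP-flux regime.

When the promoter fires far more slowly than a paused RNAP is resolved
(k_F << k_T + k_U + k_SD), each RNAP meets the roadblock alone.  Its fate
decomposes into competing first-order processes, giving the readthrough
fraction

    Rf = k_U/(k_B + k_U)  +  k_B/(k_B + k_U) * (k_SD + k_U)/(k_SD + k_U + k_T)

where the first term is *avoidance* (arrival at a vacant operator) and the
second is a pause resolved by single-RNAP dislodgement (k_SD) or
spontaneous roadblocker unbinding (k_U) before termination (k_T).

Also implemented here: the transient-occlusion probability for closely
spaced elongating RNAPs, headway arithmetic, the power-law coupling of the
dislodgement rate to the unbinding rate, and the occupancy-preserving
(k_U, k_B) tuning surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticParams

__all__ = [
    "TuningSpec",
    "low_flux_readthrough",
    "unoccluded_probability",
    "binding_window",
    "mean_headway",
    "powerlaw_dislodgement",
    "powerlaw_exponent",
    "tuning_surface",
]


def low_flux_readthrough(p: KineticParams | None = None, *, k_B: float = None,
                         k_U: float = None, k_T: float = None,
                         k_SD: float = None) -> float:
    """Analytic readthrough fraction in the single-RNAP (low-flux) limit.

    Accepts either a :class:`KineticParams` or the four rates directly.
    k_F and k_MD play no role in this limit.
    """
    if p is not None:
        k_B, k_U, k_T, k_SD = p.k_B, p.k_U, p.k_T, p.k_SD
    for name, v in (("k_B", k_B), ("k_U", k_U), ("k_T", k_T), ("k_SD", k_SD)):
        if v is None or v < 0:
            raise ValueError(f"{name} must be a nonnegative rate")
    if k_B + k_U == 0:
        # operator can never be bound nor vacated: roadblock absent forever
        return 1.0
    if k_SD + k_U + k_T == 0:
        raise ValueError("k_SD + k_U + k_T must be > 0 (pause never resolves)")
    avoidance = k_U / (k_B + k_U)
    paused = k_B / (k_B + k_U)
    resolved = (k_SD + k_U) / (k_SD + k_U + k_T)
    return avoidance + paused * resolved


def unoccluded_probability(k_F: float, gap_needed: float) -> float:
    """Probability a Poisson headway exceeds ``gap_needed``: exp(-k_F * gap).

    The chance that the gap behind a freely elongating RNAP is long enough
    for the roadblocker's site to be exposed at all.
    """
    if k_F < 0 or gap_needed < 0:
        raise ValueError("k_F and gap_needed must be >= 0")
    return float(np.exp(-k_F * gap_needed))


def binding_window(operator_length: float, rnap_footprint: float,
                   velocity: float) -> float:
    """Minimum front-to-front gap (s) leaving the operator fully exposed.

    An RNAP front must clear the operator plus its own footprint before the
    next front arrives: (operator_length + rnap_footprint) / velocity.
    """
    if operator_length < 0 or rnap_footprint <= 0 or velocity <= 0:
        raise ValueError("lengths must be >= 0 and velocity > 0")
    return (operator_length + rnap_footprint) / velocity


def mean_headway(k_F: float, rnap_footprint: float, velocity: float) -> float:
    """Mean clear time between successive RNAP fronts, floored at zero.

    1/k_F between firings minus the footprint transit time; a saturated
    promoter (headway 0) is a meaningful input for clogging analysis.
    """
    if k_F <= 0:
        raise ValueError("k_F must be > 0")
    return max(1.0 / k_F - rnap_footprint / velocity, 0.0)


def powerlaw_dislodgement(k_U: float, anchor: tuple, exponent: float) -> float:
    """Extrapolate a dislodgement rate as k_ref * (k_U / k_U_ref)^exponent."""
    k_U_ref, k_rate_ref = anchor
    if k_U <= 0 or k_U_ref <= 0 or k_rate_ref < 0:
        raise ValueError("rates must be positive")
    return k_rate_ref * (k_U / k_U_ref) ** exponent


def powerlaw_exponent(anchor_a: tuple, anchor_b: tuple) -> float:
    """Exponent of the power law through two (k_U, k_rate) anchors."""
    (ku_a, kr_a), (ku_b, kr_b) = anchor_a, anchor_b
    if min(ku_a, kr_a, ku_b, kr_b) <= 0 or ku_a == ku_b:
        raise ValueError("anchors must be positive with distinct k_U")
    return float(np.log(kr_b / kr_a) / np.log(ku_b / ku_a))


@dataclass(frozen=True)
class TuningSpec:
    """Occupancy-preserving sweep of the roadblocker's kinetic regime.

    For each k_U in the grid, k_B is raised to hold the stationary
    occupancy k_B/(k_B+k_U) at ``occupancy_target``, and k_SD follows the
    power law anchored at ``powerlaw_ref``.
    """

    k_T: float = 0.063
    occupancy_target: float = 0.9993
    k_U_grid: tuple = ()
    powerlaw_exponent_SD: float = 0.4583
    powerlaw_ref: tuple = (4.3956e-4, 0.0015)

    def __post_init__(self) -> None:
        g = np.asarray(self.k_U_grid, dtype=float)
        if g.size == 0 or np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("k_U_grid must be positive and ascending")
        if not 0.0 < self.occupancy_target < 1.0:
            raise ValueError("occupancy_target must lie in (0, 1) "
                             "(1.0 is unreachable with finite k_B)")
        if self.k_T < 0:
            raise ValueError("k_T must be >= 0")


def tuning_surface(spec: TuningSpec) -> pd.DataFrame:
    """Rf along a (k_U, k_B)-at-constant-occupancy line, low-flux limit.

    Returns a tidy frame with columns k_U, k_B, k_SD, rf.  Rf is
    non-decreasing along the grid: faster unbinding always helps once
    occupancy is held fixed.
    """
    occ = spec.occupancy_target
    rows = []
    for k_U in spec.k_U_grid:
        k_B = occ / (1.0 - occ) * k_U
        k_SD = powerlaw_dislodgement(k_U, spec.powerlaw_ref,
                                     spec.powerlaw_exponent_SD)
        rf = low_flux_readthrough(k_B=k_B, k_U=k_U, k_T=spec.k_T, k_SD=k_SD)
        rows.append((k_U, k_B, k_SD, rf))
    return pd.DataFrame(rows, columns=["k_U", "k_B", "k_SD", "rf"])
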