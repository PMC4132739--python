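"""Synthetic readthrough tables with the experiment's design and noise.

The real Rf measurements exist only as figure points, so every downstream
stage (fitting, attribution, clogging analysis) is exercised against
tables generated here: each design-grid cell is simulated at a known
"truth" parameter set, replicate noise is added, and mean + 95% CI are
computed from n pseudo-replicates — the same shape as the reporter-assay
data (9 replicates per condition).

``published_rates`` returns the published best-fit rates; values not printed
anywhere (the intermediate-affinity operator's dislodgement rates) are
geometric interpolations between the printed anchors and are flagged as
synthetic stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import RFTABLE_COLUMNS, validate_rf_table
from .kinetics import (
    OPERATOR_RELATIVE_KD,
    K_U_OID,
    KineticParams,
    RepressorSpec,
    binding_rate,
    promoter_ladder,
)
from .sim import SimConfig, readthrough_fraction

__all__ = [
    "DesignGrid",
    "NoiseModel",
    "generate_rf_table",
    "published_rates",
    "truth_rates",
]


@dataclass(frozen=True)
class DesignGrid:
    """Axes of the experimental design.

    Defaults reproduce the full measured grid: 15 log-spaced promoters
    over the 611-fold firing-rate range, three operators, five repressor
    concentrations, three promoter--operator spacers, two genotypes and
    9 replicates.  The strongest promoter is excluded from the short
    spacers (its sequence extends past the shortened spacer windows).
    """

    promoters: tuple = field(
        default_factory=lambda: tuple(zip(*_default_ladder())))
    operators: tuple = ("Oid", "O1", "O2")
    concentrations_nM: tuple = (250.0, 120.0, 70.0, 35.0, 15.0)
    spacers: tuple = (102, 60, 30)
    genotypes: tuple = ("wt", "dmfd")
    n_replicates: int = 9
    exclude_strongest_from_short_spacers: bool = True

    def __post_init__(self) -> None:
        for name in ("promoters", "operators", "concentrations_nM",
                     "spacers", "genotypes"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"design axis {name} is empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def cells(self):
        k_F_max = max(k for _, k in self.promoters)
        long_spacer = max(self.spacers)
        for name, k_F in self.promoters:
            for op in self.operators:
                for conc in self.concentrations_nM:
                    for spacer in self.spacers:
                        if (self.exclude_strongest_from_short_spacers
                                and spacer < long_spacer and k_F == k_F_max):
                            continue
                        for gt in self.genotypes:
                            yield name, k_F, op, conc, spacer, gt


def _default_ladder():
    ladder = promoter_ladder(15, 3.3e-4, 0.2)
    return ladder.names, ladder.k_F_values


def small_grid(operators=("Oid",), concentrations_nM=(250.0,),
               spacers=(102,), genotypes=("wt",), n_promoters=15,
               n_replicates=9) -> DesignGrid:
    """Convenience subset of the default grid (single condition column)."""
    ladder = promoter_ladder(n_promoters, 3.3e-4, 0.2)
    return DesignGrid(
        promoters=tuple(zip(ladder.names, ladder.k_F_values)),
        operators=tuple(operators),
        concentrations_nM=tuple(concentrations_nM),
        spacers=tuple(spacers),
        genotypes=tuple(genotypes),
        n_replicates=n_replicates,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise on Rf: sd = slope * rf + floor_sd, truncated at 0."""

    sd_slope: float = 0.1
    sd_floor: float = 0.005
    background_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_slope < 0 or self.sd_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    def sd(self, rf: float) -> float:
        return self.sd_slope * rf + self.sd_floor


def published_rates() -> dict:
    """Published best-fit rate map for the default design grid.

    Printed anchors: wild-type global k_T = 0.063 s^-1 (0.066 for the
    ideal-operator-only fit, kept under ``k_T_oid_only``), k_SD = 0.0015
    and k_MD = 0.026 s^-1 for the ideal operator; the weakest operator's
    rates are 4.2-fold (k_SD) and 1.7-fold (k_MD) higher; the mfd-deletion
    strain has k_T = 0.0045 s^-1 and ~3-fold lower dislodgement rates;
    short spacers raise k_SD 2.1-fold (60 bp) and 5.3-fold (30 bp).

    The intermediate operator O1's dislodgement rates were never printed:
    the geometric mean of the Oid and O2 values is used as a synthetic
    stand-in.
    """
    k_SD_oid, k_MD_oid = 0.0015, 0.026
    k_SD_o2, k_MD_o2 = 4.2 * k_SD_oid, 1.7 * k_MD_oid
    ops_wt = {
        "Oid": {"k_SD": k_SD_oid, "k_MD": k_MD_oid},
        "O1": {  # synthetic interpolation (geometric mean of anchors)
            "k_SD": float(np.sqrt(k_SD_oid * k_SD_o2)),
            "k_MD": float(np.sqrt(k_MD_oid * k_MD_o2)),
        },
        "O2": {"k_SD": k_SD_o2, "k_MD": k_MD_o2},
    }
    mfd_factor = 3.0
    ops_dmfd = {
        op: {k: v / mfd_factor for k, v in d.items()}
        for op, d in ops_wt.items()
    }
    spacer_scale = {102: 1.0, 60: 2.1, 30: 5.3}
    return {
        "wt": {"k_T": 0.063, "operators": ops_wt,
               "spacer_k_SD_scale": dict(spacer_scale)},
        "dmfd": {"k_T": 0.0045, "operators": ops_dmfd,
                 "spacer_k_SD_scale": dict(spacer_scale)},
        "k_T_oid_only": 0.066,
        "k_U_ref": K_U_OID,
    }


def truth_rates(truth: dict, operator: str, genotype: str,
                spacer: int) -> tuple:
    """(k_T, k_SD, k_MD) for one design cell, or a KeyError naming it."""
    try:
        g = truth[genotype]
        ops = g["operators"][operator]
        scale = g.get("spacer_k_SD_scale", {}).get(spacer, None)
        if scale is None:
            raise KeyError
        return g["k_T"], ops["k_SD"] * scale, ops["k_MD"]
    except KeyError:
        raise KeyError(
            f"truth map has no entry for cell (operator={operator!r}, "
            f"genotype={genotype!r}, spacer={spacer})") from None


def generate_rf_table(grid: DesignGrid, truth: dict,
                      noise: Optional[NoiseModel] = None, seed: int = 0,
                      fires: int = 2000,
                      k_U_ref: float = K_U_OID) -> pd.DataFrame:
    """Simulate every grid cell at the truth rates and add replicate noise.

    Deterministic given the seed.  Each cell is simulated once (a window
    of ``fires`` expected firings) to obtain the underlying Rf; the n
    pseudo-replicates are that value plus truncated Gaussian noise, and
    the row carries their mean and 95% CI half-width (Student t).
    """
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)
    rows = []
    for idx, (name, k_F, op, conc, spacer, gt) in enumerate(grid.cells()):
        k_T, k_SD, k_MD = truth_rates(truth, op, gt, spacer)
        params = KineticParams(
            k_F=k_F,
            k_B=binding_rate(RepressorSpec(conc)),
            k_U=k_U_ref * OPERATOR_RELATIVE_KD[op],
            k_T=k_T, k_SD=k_SD, k_MD=k_MD, spacer=spacer,
        )
        sim_seed = int(rng.integers(0, 2 ** 31))
        cfg = SimConfig(params=params, t_max=fires / k_F, seed=sim_seed)
        rf = readthrough_fraction(cfg)
        n = grid.n_replicates
        if noise.sd(rf) > 0 and n >= 1:
            reps = rf + noise.sd(rf) * rng.standard_normal(n)
            reps = np.maximum(reps, noise.background_floor)
        else:
            reps = np.full(n, rf)
        rf_mean = float(np.mean(reps))
        if n > 1 and np.std(reps, ddof=1) > 0:
            ci = float(stats.t.ppf(0.975, n - 1)
                       * np.std(reps, ddof=1) / np.sqrt(n))
        else:
            ci = 0.0
        rows.append((name, k_F, op, conc, spacer, gt, rf_mean, ci, n))
    table = pd.DataFrame(rows, columns=RFTABLE_COLUMNS)
    return validate_rf_table(table)
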