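"""Stochastic simulator: invariants, oracle agreement, mechanism logic."""

import numpy as np
import pytest

from txroadblock.analytic import low_flux_readthrough
from txroadblock.kinetics import K_U_OID, KineticParams
from txroadblock.sim import (
    MECHANISMS,
    SimConfig,
    attribute_mechanisms,
    clogging_fraction,
    readthrough_fraction,
    simulate,
    variant_mfd_deleted,
)


def test_config_validation(oid_params):
    with pytest.raises(ValueError):
        SimConfig(params=oid_params)  # neither stopping rule
    with pytest.raises(ValueError):
        SimConfig(params=oid_params, t_max=100.0, target_fires=10)
    with pytest.raises(ValueError):
        SimConfig(params=oid_params, t_max=100.0, burn_in=100.0)
    with pytest.raises(ValueError):
        SimConfig(params=oid_params, target_fires=10, model_variant="bogus")
    with pytest.raises(ValueError):
        SimConfig(params=oid_params.replace(k_F=0.0), target_fires=10)


def test_determinism_same_seed_same_result(oid_params):
    cfg = SimConfig(params=oid_params.replace(k_F=0.02), target_fires=2000,
                    seed=42)
    a, b = simulate(cfg), simulate(cfg)
    assert a.passes == b.passes
    assert a.terminations == b.terminations
    assert a.mechanism_counts == b.mechanism_counts
    assert a.time == b.time
    c = simulate(cfg.replace(seed=43))
    assert (a.passes, a.terminations) != (c.passes, c.terminations)


def test_conservation_fires_split_into_fates(oid_params):
    for k_F in (3.3e-4, 0.02, 0.2):
        cfg = SimConfig(params=oid_params.replace(k_F=k_F),
                        target_fires=3000, seed=7)
        res = simulate(cfg)
        assert res.fires == res.passes + res.terminations + res.on_lattice
        assert sum(res.mechanism_counts.values()) == res.passes
        assert 0.0 <= res.promoter_clogged_fraction <= 1.0
        assert 0.0 <= res.operator_occupied_fraction <= 1.0


def test_exclusion_invariant_checked_in_uncompiled_kernel(oid_params):
    # the uncompiled kernel asserts no footprint overlap at every step
    cfg = SimConfig(params=oid_params.replace(k_F=0.2), t_max=2000.0, seed=3)
    res = simulate(cfg, check=True, compiled=False)
    assert res.fires > 100
    assert res.fires == res.passes + res.terminations + res.on_lattice


def test_no_roadblocker_every_rnap_passes(oid_params):
    p = oid_params.replace(k_B=0.0, k_F=0.1)
    cfg = SimConfig(params=p, target_fires=2000, seed=1)
    res = simulate(cfg)
    assert res.terminations == 0
    assert res.passes == res.fires - res.on_lattice
    assert readthrough_fraction(SimConfig(params=p, target_fires=2000,
                                          seed=1)) == pytest.approx(1.0)


def test_low_flux_matches_analytic_oracle(oid_params):
    """Central correctness check: at negligible flux the simulated Rf
    equals the closed-form competing-rates solution."""
    analytic = low_flux_readthrough(oid_params)
    cfg = SimConfig(params=oid_params, target_fires=10000, seed=5)
    rf, plus, _ = readthrough_fraction(cfg, return_results=True)
    se = np.sqrt(analytic * (1 - analytic) / plus.fires)
    assert abs(rf - analytic) < 3 * se


def test_operator_occupancy_near_equilibrium_at_low_flux(oid_params):
    cfg = SimConfig(params=oid_params, target_fires=2000, seed=9)
    res = simulate(cfg)
    expected = oid_params.k_B / (oid_params.k_B + oid_params.k_U)
    assert res.operator_occupied_fraction == pytest.approx(expected, abs=5e-3)


def test_full_lattice_capacity_and_promoter_block(oid_params):
    # frozen roadblock, saturating promoter: the 102 bp spacer holds
    # exactly 4 stalled RNAPs (fronts 102/72/42/12) and blocks reloading
    p = oid_params.replace(k_F=10.0, k_U=0.0, k_T=0.0, k_SD=0.0, k_MD=0.0)
    cfg = SimConfig(params=p, t_max=600.0, seed=2)
    res = simulate(cfg)
    assert res.fires == 4
    assert res.on_lattice == 4
    assert res.passes == 0
    assert res.promoter_clogged_fraction > 0.9

    # a 30 bp spacer holds a single RNAP whose footprint reaches +1
    cfg30 = SimConfig(params=p.replace(spacer=30), t_max=600.0, seed=2)
    res30 = simulate(cfg30)
    assert res30.fires == 1
    assert res30.promoter_clogged_fraction > 0.9


class TestMechanismAttribution:
    def test_counts_sum_and_event_log_agrees(self, oid_params):
        cfg = SimConfig(params=oid_params.replace(k_F=0.02),
                        target_fires=4000, seed=11, record_events=True)
        res = simulate(cfg)
        assert sum(res.mechanism_counts.values()) == res.passes
        assert attribute_mechanisms(res.event_log) == res.mechanism_counts
        assert len(res.event_log) == res.passes
        assert np.all(np.diff(res.event_log.times) >= 0)

    def test_no_dislodgement_rate_no_dislodgement_passes(self, oid_params):
        p = oid_params.replace(k_SD=0.0, k_MD=0.0)
        res = simulate(SimConfig(params=p, target_fires=4000, seed=3))
        assert res.mechanism_counts["SD"] == 0
        assert res.mechanism_counts["MD"] == 0

    def test_never_bound_operator_gives_absence(self, oid_params):
        p = oid_params.replace(k_B=0.0, k_F=1e-3)
        res = simulate(SimConfig(params=p, target_fires=200, seed=4))
        assert res.mechanism_counts["absence"] == res.passes
        assert res.passes > 0

    def test_single_dislodgement_dominates_weak_promoters(self, oid_params):
        # at the weakest promoter nearly every pass that is not escape is
        # a single-RNAP dislodgement
        res = simulate(SimConfig(params=oid_params, target_fires=8000,
                                 seed=6, record_events=True))
        frac = res.mechanism_fractions()
        assert frac["SD"] > 0.5
        assert frac["MD"] + frac["occlusion"] < 0.2


class TestModelVariants:
    def test_mfd_deletion_parameter_map(self, oid_params):
        p = variant_mfd_deleted(oid_params.replace(k_T=0.063))
        assert 0.063 / p.k_T == pytest.approx(14.0)
        assert p.k_SD == pytest.approx(oid_params.k_SD / 3)
        assert p.k_MD == pytest.approx(oid_params.k_MD / 3)
        ident = variant_mfd_deleted(oid_params, k_T=oid_params.k_T,
                                    dislodgement_factor=1.0)
        assert ident == oid_params

    def test_mfd_deletion_raises_weak_promoter_readthrough(self, oid_params):
        # with termination 14-fold slower, weak-promoter readthrough far
        # exceeds the wild-type level
        base = oid_params.replace(k_F=1e-3,
                                  k_U=22.9 * K_U_OID,
                                  k_SD=4.2 * 0.0015, k_MD=1.7 * 0.026)
        wt = readthrough_fraction(SimConfig(params=base, target_fires=4000,
                                            seed=8))
        dm = readthrough_fraction(
            SimConfig(params=variant_mfd_deleted(base), target_fires=4000,
                      seed=8))
        assert dm > wt + 0.2

    def test_termination_protection_reduces_terminations(self, oid_params):
        p = oid_params.replace(k_F=0.2)
        std = simulate(SimConfig(params=p, target_fires=5000, seed=12))
        prot = simulate(SimConfig(params=p, target_fires=5000, seed=12,
                                  model_variant="termination_protection"))
        assert prot.terminations < std.terminations
        assert prot.passes > std.passes


class TestCloggingAndSpacing:
    def test_clogging_vanishes_at_negligible_flux(self, oid_params):
        res = simulate(SimConfig(params=oid_params, target_fires=2000,
                                 seed=13))
        assert clogging_fraction(res) < 0.01

    def test_short_spacer_clogs_more(self, oid_params):
        p = oid_params.replace(k_F=0.2)
        fracs = {}
        for spacer in (102, 30):
            res = simulate(SimConfig(params=p.replace(spacer=spacer),
                                     target_fires=5000, seed=14))
            fracs[spacer] = clogging_fraction(res)
        assert fracs[30] > fracs[102]


def test_paired_seed_monotonicity_in_rates(oid_params):
    """Rf responds in the physical direction to each kinetic rate."""
    base = oid_params.replace(k_F=0.02)
    fires = 4000

    def rf_at(**changes):
        return readthrough_fraction(
            SimConfig(params=base.replace(**changes), target_fires=fires,
                      seed=21))

    mid = rf_at()
    assert rf_at(k_U=base.k_U * 30) >= mid
    assert rf_at(k_SD=base.k_SD * 30) >= mid
    assert rf_at(k_MD=base.k_MD * 5) >= mid
    assert rf_at(k_B=base.k_B / 30) >= mid  # fewer rebinds -> more passes
    assert rf_at(k_T=base.k_T * 5) <= mid
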