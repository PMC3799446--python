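"""Pathway analysis: mechanism classification, Arrhenius, ensembles, ratios."""

import math

import numpy as np
import pytest

from hybkin import (
    UsageError,
    arrhenius_apparent_enthalpy,
    classify_transition,
    dissociation_rate_from_equilibrium,
    ensemble_compare,
    make_toy,
    mechanism_census,
    relative_rate,
)
from hybkin.ffs import InterfaceSet, StageRecord, WalkerFFSSystem, estimate_rate, run_ffs
from hybkin.fixtures import FixtureSpec, brute_force_crossing_rate, build_configuration, sequence_presets
from hybkin.pathways import (
    ComparabilityError,
    ConditioningError,
    OpenRecordError,
    R_GAS_KCAL,
    first_contact_positions,
    native_partner_separation_nm,
)

from conftest import synthetic_structure

N = 14


def _ss(*blocks):
    return synthetic_structure(N, list(blocks))


def _rep(ss, k=15):
    return [ss] * k


UNBOUND = _ss()
FULL = _ss((0, range(0, N)))


class TestClassifier:
    def test_monotone_zippering(self):
        rec = _rep(UNBOUND, 12)
        for k in range(1, 15):
            lo = 7 - k // 2
            rec += _rep(_ss((0, range(lo, lo + k))), 12)
        out = classify_transition(rec, dwell_min=10, n_full=N)
        assert out.mechanism == "zippering"
        assert out.end_label == "full_duplex"

    def test_inchworm_bulge_migration(self):
        rec = (
            _rep(_ss((4, range(4, 14))))
            + _rep(_ss((4, range(7, 14)), (0, range(0, 3))))
            + _rep(_ss((4, range(10, 14)), (0, range(0, 6))))
            + _rep(FULL)
        )
        out = classify_transition(rec, dwell_min=10, n_full=N)
        assert out.mechanism == "inchworm"
        assert out.start_label == "register 4"

    def test_pseudoknot_displacement(self):
        rec = (
            _rep(_ss((10, range(10, 14))))
            + _rep(_ss((10, range(10, 14)), (0, range(0, 4))))
            + _rep(FULL)
        )
        out = classify_transition(rec, dwell_min=10, n_full=N)
        assert out.mechanism == "pseudoknot_displacement"
        assert out.start_label == "register 10"

    def test_detachment(self):
        rec = _rep(_ss((4, range(4, 14)))) + _rep(UNBOUND, 12)
        out = classify_transition(rec, dwell_min=10, n_full=N)
        assert out.mechanism == "detachment"
        assert out.end_label == "unbound"

    def test_mixed_route_keeps_ordered_mechanism_list(self):
        rec = (
            _rep(_ss((-10, range(0, 4))))
            + _rep(_ss((-10, range(0, 4)), (2, range(8, 12))))
            + _rep(_ss((2, range(2, 14))))
            + _rep(FULL)
        )
        out = classify_transition(rec, dwell_min=10, n_full=N)
        assert out.mechanism == "mixed"
        assert out.mechanisms == ("pseudoknot_displacement", "inchworm")
        assert out.headline == "pseudoknot_displacement"

    def test_flickers_below_dwell_are_ignored(self):
        base = _rep(_ss((4, range(4, 14))), 20)
        flicker = [_ss((4, range(4, 14)), (0, range(0, 2)))] * 3  # < dwell_min
        rec = base + flicker + base + _rep(FULL)
        out = classify_transition(rec, dwell_min=10, n_full=N)
        # register 4 -> register 0 directly: inchworm, the flicker is invisible
        assert out.mechanism == "inchworm"

    def test_subsampling_coarser_than_dwell_is_stable(self):
        rec = (
            _rep(_ss((10, range(10, 14))), 30)
            + _rep(_ss((10, range(10, 14)), (0, range(0, 4))), 30)
            + _rep(FULL, 30)
        )
        full = classify_transition(rec, dwell_min=10, n_full=N)
        sub = classify_transition(rec[::3], dwell_min=4, n_full=N)
        assert full.mechanism == sub.mechanism == "pseudoknot_displacement"

    def test_open_record_rejected(self):
        with pytest.raises(OpenRecordError):
            classify_transition([], dwell_min=10)
        # ends in a pseudoknot: not absorbing
        rec = _rep(_ss((10, range(10, 14)), (0, range(0, 4))))
        with pytest.raises(OpenRecordError):
            classify_transition(rec, dwell_min=10, n_full=N)

    def test_census_counts(self):
        recs = [
            classify_transition(_rep(UNBOUND, 12) + _rep(FULL, 12), dwell_min=10, n_full=N)
            for _ in range(3)
        ]
        rows = mechanism_census(recs)
        assert rows == [
            {"start": "unbound", "end": "full_duplex", "mechanism": "zippering", "count": 3}
        ]


class TestArrhenius:
    def test_exact_recovery_of_planted_enthalpy(self):
        dH = -5.0  # kcal/mol
        T = np.array([300.0, 310.0, 320.0, 340.9])
        k = 1e3 * np.exp(-dH / (R_GAS_KCAL * T))
        fit = arrhenius_apparent_enthalpy(T, k)
        assert np.allclose(fit.activation_enthalpy_kcal, dH, atol=1e-9)

    def test_temperature_dependent_enthalpy_recovered_at_midpoints(self):
        # dH(T) = a + b T  ->  ln k = -(1/R) * integral dH dT / T^2 ...
        a, b = -2.0, -0.03
        T = np.linspace(300.0, 340.0, 9)
        # construct ln k whose local slope encodes dH(T) = a + b*T:
        # d ln k / d(1/T) = -dH/R  integrates to -a/(RT) + (b/R) ln T
        lnk = -(a / R_GAS_KCAL) / T + (b / R_GAS_KCAL) * np.log(T)
        fit = arrhenius_apparent_enthalpy(T, np.exp(lnk))
        expected = a + b * fit.pair_midpoints
        assert np.allclose(fit.activation_enthalpy_kcal, expected, rtol=5e-3)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(UsageError):
            arrhenius_apparent_enthalpy([300, 310], [1.0, 0.0])

    def test_single_temperature_rejected(self):
        with pytest.raises(UsageError):
            arrhenius_apparent_enthalpy([300.0], [1.0])


def _toy_estimate(k=1.0, scale=1.0):
    est = estimate_rate(
        k, 0.05 * k, [StageRecord(0.0, 100, 100, 1.0, 0.0)]
    )
    est.diffusion_scale = scale
    return est


class TestRelativeRate:
    def test_identity_ratio(self):
        a = _toy_estimate(2.0)
        out = relative_rate(a, a, n_boot=200, seed=1)
        assert out["ratio"] == 1.0
        assert out["ci95"][0] <= 1.0 <= out["ci95"][1]

    def test_mismatched_diffusion_scale_refused(self):
        with pytest.raises(ComparabilityError):
            relative_rate(_toy_estimate(1.0, scale=1.0), _toy_estimate(1.0, scale=10.0))


class TestDissociation:
    @pytest.mark.parametrize("k_on,K,expected", [(1.0, 1.0, 1.0), (2.0, 4.0, 0.5)])
    def test_identities(self, k_on, K, expected):
        assert dissociation_rate_from_equilibrium(k_on, K)["k_off"] == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(UsageError):
            dissociation_rate_from_equilibrium(0.0, 1.0)

    def test_toy_two_state_detailed_balance(self):
        """k_off = k_on / K_eq matches the directly simulated reverse rate."""
        toy = make_toy("double_well_walker", {"h": 4.0, "kT": 1.0, "tilt": 0.8}, seed=5)
        rng = np.random.default_rng(55)
        fwd = brute_force_crossing_rate(toy, rng, n_walkers=160, max_steps=400_000,
                                        x_start=-1.0, x_target=1.0)
        rev = brute_force_crossing_rate(toy, rng, n_walkers=160, max_steps=400_000,
                                        x_start=1.0, x_target=-1.0)
        K_eq = toy.reference("occupancy_ratio")  # right over left, quadrature
        out = dissociation_rate_from_equilibrium(fwd["rate"], K_eq,
                                                 fwd["rate_se"], 0.0)
        z = abs(out["k_off"] - rev["rate"]) / math.hypot(out["k_off_se"], rev["rate_se"])
        assert z < 2.0


class TestEnsembleCompare:
    def _states(self, params, seeds, positions=(3, 4)):
        seqs = sequence_presets()["gc8"]["strands"]
        return [
            build_configuration(
                FixtureSpec(strands=seqs, mode="partial_native",
                            paired_positions=positions, relax_steps=60, seed=s),
                params,
            )
            for s in seeds
        ]

    def test_identical_ensembles_have_zero_differences(self, params_avg):
        states = self._states(params_avg, range(4))
        out = ensemble_compare(states, states, n=2, params=params_avg,
                               n_boot=50, seed=0)
        assert out.kinetic_separation_nm == out.equilibrium_separation_nm
        assert out.kinetic_stacking == out.equilibrium_stacking

    def test_wrong_pair_count_is_conditioning_error(self, params_avg):
        two = self._states(params_avg, range(2))
        three = self._states(params_avg, range(2), positions=(2, 3, 4))
        with pytest.raises(ConditioningError):
            ensemble_compare(two, three, n=2, params=params_avg, n_boot=10)

    def test_separation_reported_in_nanometres(self, params_avg):
        seqs = sequence_presets()["gc8"]["strands"]
        duplex = build_configuration(
            FixtureSpec(strands=seqs, mode="native_duplex"), params_avg
        )
        sep = native_partner_separation_nm(duplex, params_avg)
        # paired base sites sit ~0.4 simulation units (~0.34 nm) apart
        assert 0.2 < sep < 0.6


def test_first_contact_positions(make_structure):
    rec1 = [_ss(), _ss((0, [2])), _ss((0, [2, 3]))]
    rec2 = [_ss(), _ss((0, [10]))]
    assert first_contact_positions([rec1, rec2]) == [2, 10]
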