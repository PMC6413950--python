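"""Core-network assembly: leg differencing, repeat aggregation, racemate
combination, Ki conversion and network-wide reconstruction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from fepnet import (
    FreeEnergyValue,
    NetworkEstimator,
    ValueKind,
    aggregate_repeats,
    combine_racemate,
    ddg_from_legs,
    dg_to_ki,
    ki_to_dg,
    kt_kcal,
    network_estimate,
)
from conftest import make_network

KT300 = kt_kcal(300.0)

leg = lambda v, s=0.0, tag="": FreeEnergyValue(v, s, ValueKind.LEG, tag)


class TestDdgFromLegs:
    @pytest.mark.parametrize(
        "complex_leg, free_leg, expect_v, expect_s",
        [
            ((-5.0, 0.3), (-3.0, 0.4), -2.0, 0.5),     # 3-4-5 quadrature
            ((1.7, 0.2), (1.7, 0.2), 0.0, 0.2 * math.sqrt(2)),
            ((-7.2, 0.0), (-7.2, 0.0), 0.0, 0.0),
        ],
    )
    def test_examples(self, complex_leg, free_leg, expect_v, expect_s):
        out = ddg_from_legs(leg(*complex_leg), leg(*free_leg))
        assert out.value == pytest.approx(expect_v)
        assert out.sigma == pytest.approx(expect_s)
        assert out.kind is ValueKind.EDGE_REPEAT

    @given(a=st.floats(-20, 20), b=st.floats(-20, 20),
           sa=st.floats(0, 2), sb=st.floats(0, 2))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetric_under_leg_swap(self, a, b, sa, sb):
        fwd = ddg_from_legs(leg(a, sa), leg(b, sb))
        rev = ddg_from_legs(leg(b, sb), leg(a, sa))
        assert fwd.value == -rev.value
        assert fwd.sigma == rev.sigma

    def test_identity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            ddg_from_legs(leg(1.0, tag="a~b#r1:complex"),
                          leg(0.5, tag="a~c#r1:free"))

    def test_requires_leg_kind(self):
        bad = FreeEnergyValue(1.0, 0.1, ValueKind.EDGE_MEAN)
        with pytest.raises(ValueError, match="leg"):
            ddg_from_legs(bad, leg(0.0))


class TestAggregateRepeats:
    def test_two_repeat_mean_and_sem(self):
        # the printed 45->44 run values: mean 1.65, sem |1.8-1.5|/2 = 0.15
        out = aggregate_repeats([leg(1.8, 0.1), leg(1.5, 0.1)])
        assert out.value == pytest.approx(1.65)
        assert out.sigma == pytest.approx(0.15)
        assert out.kind is ValueKind.EDGE_MEAN

    def test_single_repeat_passthrough(self):
        out = aggregate_repeats([leg(-0.7, 0.23)])
        assert (out.value, out.sigma) == (-0.7, 0.23)

    def test_zero_variance(self):
        out = aggregate_repeats([leg(2.0)] * 3)
        assert out.value == 2.0 and out.sigma == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_repeats([])


class TestCombineRacemate:
    def test_equal_enantiomers_identity(self):
        out = combine_racemate(leg(-1.0), leg(-1.0), 300.0)
        assert out.value == pytest.approx(-1.0)

    def test_dominant_enantiomer_limit(self):
        # one enantiomer 100 kcal/mol worse: the mixture pays kT ln 2
        out = combine_racemate(leg(0.0), leg(100.0), 300.0)
        assert out.value == pytest.approx(KT300 * math.log(2), abs=1e-9)
        assert out.value == pytest.approx(0.4132, abs=5e-4)

    def test_zero_case(self):
        assert combine_racemate(leg(0.0), leg(0.0), 300.0).value == pytest.approx(0.0)

    def test_no_overflow_at_hundreds_of_kt(self):
        out = combine_racemate(leg(-300.0), leg(300.0), 300.0)
        assert math.isfinite(out.value)
        assert out.value == pytest.approx(-300.0 + KT300 * math.log(2), abs=1e-6)

    @given(a=st.floats(-250, 250), b=st.floats(-250, 250))
    @settings(derandomize=True, max_examples=200)
    def test_bounds(self, a, b):
        # mixture lies within kT ln 2 above the better enantiomer
        out = combine_racemate(leg(a), leg(b), 300.0).value
        lo = min(a, b)
        assert lo - 1e-9 <= out <= lo + KT300 * math.log(2) + 1e-9

    def test_sigma_weights_follow_boltzmann(self):
        # far-dominant enantiomer: only its sigma survives
        out = combine_racemate(leg(0.0, 0.3), leg(50.0, 5.0), 300.0)
        assert out.sigma == pytest.approx(0.3, rel=1e-6)

    def test_bad_temperature(self):
        with pytest.raises(ValueError):
            combine_racemate(leg(0.0), leg(0.0), -1.0)


class TestKiConversion:
    def test_standard_state_cancels(self):
        assert ki_to_dg(1.0, 300.0) == pytest.approx(0.0)

    def test_ten_micromolar(self):
        assert ki_to_dg(1e-5, 300.0) == pytest.approx(-6.86, abs=5e-3)

    def test_monotone_and_inverse(self):
        kis = [1e-9, 1e-7, 1e-5]
        dgs = [ki_to_dg(k, 300.0) for k in kis]
        assert dgs == sorted(dgs)
        for k in kis:
            assert dg_to_ki(ki_to_dg(k, 300.0), 300.0) == pytest.approx(k, rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ki_to_dg(0.0)


class TestNetworkEstimate:
    def test_chain_telescopes(self):
        net = make_network([("ref", "A", 1.0), ("A", "B", 2.0)],
                           reference_dg=-6.86)
        dg = network_estimate(net)
        assert dg["ref"].value == pytest.approx(-6.86)
        assert dg["A"].value == pytest.approx(-5.86)
        assert dg["B"].value == pytest.approx(-3.86)

    def test_reference_always_anchored(self):
        net = make_network([("ref", "A", 1.0), ("A", "B", -0.5),
                            ("B", "ref", 2.2)], reference_dg=-6.86)
        dg = network_estimate(net)
        assert dg["ref"].value == -6.86
        assert dg["ref"].sigma == 0.0

    def test_noiseless_consistent_network_recovers_truth(self):
        # edges derived from a potential: WLS must reproduce it exactly
        truth = {"ref": -6.86, "A": -8.1, "B": -10.3, "C": -7.7}
        edges = [(s, t, truth[t] - truth[s], 0.0)
                 for s, t in [("ref", "A"), ("A", "B"), ("B", "C"),
                              ("C", "ref"), ("A", "C"), ("B", "ref")]]
        dg = network_estimate(make_network(edges, reference_dg=truth["ref"]))
        for lig, v in truth.items():
            assert dg[lig].value == pytest.approx(v, abs=1e-8)

    def test_matches_brute_force_minimizer(self):
        # independent oracle: numerically minimize the same weighted
        # objective over the free ligand values
        edges = [("ref", "A", 1.1, 0.2), ("A", "B", 2.3, 0.4),
                 ("B", "ref", -3.1, 0.3), ("A", "C", 0.7, 0.5),
                 ("C", "B", 1.9, 0.2)]
        ref_dg = -6.86
        net = make_network(edges, reference_dg=ref_dg)
        dg = network_estimate(net)

        free = ["A", "B", "C"]

        def objective(x):
            vals = dict(zip(free, x), ref=ref_dg)
            return sum(((vals[t] - vals[s] - d) / sig) ** 2
                       for s, t, d, sig in edges)

        res = minimize(objective, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000})
        for lig, x in zip(free, res.x):
            assert dg[lig].value == pytest.approx(x, abs=1e-6)

    def test_invariant_to_splitting_edge_weight(self):
        # an edge of weight w equals two half-weight observations; the
        # reversed duplicate with negated value is the same observation
        base = [("ref", "A", 1.3, 0.2), ("A", "B", -0.4, 0.3)]
        split = [("ref", "A", 1.3, 0.2 * math.sqrt(2)),
                 ("A", "ref", -1.3, 0.2 * math.sqrt(2)),
                 ("A", "B", -0.4, 0.3)]
        dg_a = network_estimate(make_network(base))
        dg_b = network_estimate(make_network(split))
        for lig in dg_a:
            assert dg_a[lig].value == pytest.approx(dg_b[lig].value, abs=1e-10)

    def test_disconnected_ligand_reported_not_dropped(self):
        net = make_network([("ref", "A", 1.0), ("X", "Y", 0.5)])
        with pytest.warns(UserWarning, match="unresolvable"):
            est = NetworkEstimator().fit(net)
        assert est.unresolvable_ == ["X", "Y"]
        assert "X" not in est.dg_
        frame = est.to_frame().set_index("ligand_id")
        assert set(frame.index) == {"ref", "A", "X", "Y"}
        assert np.isnan(frame.loc["X", "dg_kcal_mol"])

    def test_sklearn_param_interface(self):
        est = NetworkEstimator(sigma_floor=1e-3)
        assert est.get_params()["sigma_floor"] == 1e-3
        est.set_params(sigma_floor=1e-2)
        assert est.sigma_floor == 1e-2
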