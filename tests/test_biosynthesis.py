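import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthctrl import biosynthesis as bio
from growthctrl import fixtures
from growthctrl.errors import DomainError, FitError, IdentifierError


def single_aa_net(loss="none"):
    return bio.AANetwork(amino_acids=("X",), upstream={"X": frozenset()}, root="X",
                         loss_kind={"X": loss})


def single_aa_kin(kcat_f=1.0, kcat_loss=0.0, ki=100.0, scale=1.0, km_loss=1000.0):
    return bio.AAKinetics(kcat_f={"X": kcat_f}, kcat_loss={"X": kcat_loss},
                          K_I={"X": ki}, K_M_up={}, K_M_loss={"X": km_loss},
                          inhibition_scale={"X": scale})


class TestSynthesisRate:
    def test_zero_enzyme(self):
        v = bio.synthesis_rate(single_aa_net(), single_aa_kin(), {"X": 50.0}, {"X": 0.0})
        assert v["X"] == 0.0

    def test_half_inhibition_no_upstream(self):
        # AA at K_I with no upstream set -> kcat * E / 2
        v = bio.synthesis_rate(single_aa_net(), single_aa_kin(kcat_f=3.0, ki=100.0),
                               {"X": 100.0}, {"X": 4.0})
        assert v["X"] == pytest.approx(3.0 * 4.0 / 2.0)

    def test_hand_evaluation_with_upstream(self):
        # kcat=1, E=2, AA=K_I, one upstream AA at its K_M -> 2 * 1/2 * 1/2 = 0.5
        net = bio.AANetwork(amino_acids=("U", "X"),
                            upstream={"U": frozenset(), "X": frozenset({"U"})}, root="U")
        kin = bio.AAKinetics(kcat_f={"U": 0.0, "X": 1.0}, kcat_loss={},
                             K_I={"U": 1.0, "X": 100.0}, K_M_up={("X", "U"): 40.0},
                             K_M_loss={})
        v = bio.synthesis_rate(net, kin, {"U": 40.0, "X": 100.0}, {"U": 0.0, "X": 2.0})
        assert v["X"] == pytest.approx(0.5)

    def test_zero_upstream_concentration_kills_rate(self):
        net = bio.AANetwork(amino_acids=("U", "X"),
                            upstream={"U": frozenset(), "X": frozenset({"U"})}, root="U")
        kin = bio.AAKinetics(kcat_f={"X": 1.0}, kcat_loss={}, K_I={"U": 1.0, "X": 100.0},
                             K_M_up={("X", "U"): 40.0}, K_M_loss={})
        v = bio.synthesis_rate(net, kin, {"U": 0.0, "X": 100.0}, {"U": 0.0, "X": 2.0})
        assert v["X"] == 0.0

    def test_unknown_aa_raises(self):
        with pytest.raises(IdentifierError):
            bio.synthesis_rate(single_aa_net(), single_aa_kin(), {"Y": 1.0}, {"Y": 1.0})

    def test_negative_concentration_raises(self):
        with pytest.raises(DomainError):
            bio.synthesis_rate(single_aa_net(), single_aa_kin(), {"X": -1.0}, {"X": 1.0})

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_in_own_concentration(self, lo, delta):
        v_lo = bio.synthesis_rate(single_aa_net(), single_aa_kin(), {"X": lo}, {"X": 1.0})
        v_hi = bio.synthesis_rate(single_aa_net(), single_aa_kin(), {"X": lo + delta},
                                  {"X": 1.0})
        assert v_hi["X"] < v_lo["X"]

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_monotone_increasing_in_upstream(self, lo, delta):
        net = bio.AANetwork(amino_acids=("U", "X"),
                            upstream={"U": frozenset(), "X": frozenset({"U"})}, root="U")
        kin = bio.AAKinetics(kcat_f={"X": 1.0}, kcat_loss={}, K_I={"U": 1.0, "X": 100.0},
                             K_M_up={("X", "U"): 40.0}, K_M_loss={})
        v_lo = bio.synthesis_rate(net, kin, {"U": lo, "X": 10.0}, {"U": 0.0, "X": 1.0})
        v_hi = bio.synthesis_rate(net, kin, {"U": lo + delta, "X": 10.0},
                                  {"U": 0.0, "X": 1.0})
        assert v_hi["X"] > v_lo["X"]

    @given(st.floats(0.1, 1e4))
    @settings(max_examples=30, deadline=None)
    def test_inhibition_removal_dominates(self, conc):
        v_wt = bio.synthesis_rate(single_aa_net(), single_aa_kin(scale=1.0),
                                  {"X": conc}, {"X": 1.0})
        v_mut = bio.synthesis_rate(single_aa_net(), single_aa_kin(scale=math.inf),
                                   {"X": conc}, {"X": 1.0})
        assert v_mut["X"] >= v_wt["X"]
        assert v_mut["X"] == pytest.approx(1.0)  # inhibition factor exactly 1

    def test_inhibition_scale_equality_iff_zero_concentration(self):
        v_wt = bio.synthesis_rate(single_aa_net(), single_aa_kin(scale=1.0),
                                  {"X": 0.0}, {"X": 1.0})
        v_mut = bio.synthesis_rate(single_aa_net(), single_aa_kin(scale=math.inf),
                                   {"X": 0.0}, {"X": 1.0})
        assert v_wt["X"] == v_mut["X"]


class TestLossRates:
    def test_leaf_has_zero_downstream(self, chain3):
        net, kin = chain3
        conc = {"GLU": 100.0, "A": 50.0, "B": 25.0}
        enz = {aa: 1.0 for aa in net.amino_acids}
        v_synth = bio.synthesis_rate(net, kin, conc, enz)
        v_down, _ = bio.loss_rates(net, kin, conc, enz, v_synth)
        assert v_down["B"] == 0.0

    def test_half_saturated_loss(self):
        net = single_aa_net(loss="degradation")
        kin = single_aa_kin(kcat_loss=2.0, km_loss=300.0)
        v_synth = bio.synthesis_rate(net, kin, {"X": 300.0}, {"X": 5.0})
        _, v_loss = bio.loss_rates(net, kin, {"X": 300.0}, {"X": 5.0}, v_synth)
        assert v_loss["X"] == pytest.approx(2.0 * 5.0 / 2.0)

    def test_chain_downstream_sums_immediate_children_only(self, chain3):
        net, kin = chain3
        conc = {"GLU": 200.0, "A": 50.0, "B": 25.0}
        enz = {aa: 2.0 for aa in net.amino_acids}
        v_synth = bio.synthesis_rate(net, kin, conc, enz)
        v_down, _ = bio.loss_rates(net, kin, conc, enz, v_synth)
        assert v_down["A"] == pytest.approx(v_synth["B"])
        # root's downstream holds A only: B must not appear transitively
        assert v_down["GLU"] == pytest.approx(v_synth["A"])


class TestSupplyRate:
    def test_all_zero(self):
        v = bio.supply_rate(single_aa_net(), single_aa_kin(kcat_f=0.0),
                            {"X": 10.0}, {"X": 0.0})
        assert v["X"] == 0.0

    def test_arithmetic(self):
        # v_synth=1, v_down=0.3, v_loss=0.2, v_exchange=0.1 -> 0.6
        assert 1.0 - 0.3 - 0.2 + 0.1 == pytest.approx(0.6)
        net = single_aa_net(loss="degradation")
        kin = single_aa_kin(kcat_f=2.0, kcat_loss=0.4, ki=100.0, km_loss=100.0)
        conc, enz = {"X": 100.0}, {"X": 1.0}
        v = bio.supply_rate(net, kin, conc, enz, {"X": 0.1})
        v_synth = bio.synthesis_rate(net, kin, conc, enz)
        _, v_loss = bio.loss_rates(net, kin, conc, enz, v_synth)
        assert v["X"] == pytest.approx(v_synth["X"] - v_loss["X"] + 0.1)


class TestAssignDefaults:
    def test_default_constants_from_minimal_conc(self):
        net = single_aa_net(loss="degradation")
        kin = bio.assign_default_constants(net, {"X": 100.0})
        assert kin.K_M_loss["X"] == pytest.approx(1000.0)
        assert kin.K_I["X"] == pytest.approx(100.0)

    def test_upstream_km_defaults_to_minimal_conc(self):
        net = bio.AANetwork(amino_acids=("U", "X"),
                            upstream={"U": frozenset(), "X": frozenset({"U"})}, root="U")
        kin = bio.assign_default_constants(net, {"U": 100.0, "X": 40.0})
        assert kin.K_M_up[("X", "U")] == pytest.approx(100.0)

    @pytest.mark.parametrize("bounds,expected", [((50.0, 80.0), 80.0),
                                                 ((120.0, 200.0), 120.0),
                                                 ((50.0, 150.0), 100.0)])
    def test_ki_clamped_to_curated_bounds(self, bounds, expected):
        net = single_aa_net()
        kin = bio.assign_default_constants(net, {"X": 100.0},
                                           curated_K_I_bounds={"X": bounds})
        assert kin.K_I["X"] == pytest.approx(expected)

    def test_empty_bounds_interval_raises(self):
        with pytest.raises(DomainError):
            bio.assign_default_constants(single_aa_net(), {"X": 100.0},
                                         curated_K_I_bounds={"X": (80.0, 50.0)})


class TestFitKcats:
    def test_round_trip_recovery(self, toy_fit_fixture):
        net, planted, cond_min, cond_rich = toy_fit_fixture
        kin = bio.AAKinetics(kcat_f={}, kcat_loss={}, K_I=planted.K_I,
                             K_M_up=planted.K_M_up, K_M_loss=planted.K_M_loss)
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        for aa in net.amino_acids:
            assert fit.kcat_f[aa] == pytest.approx(planted.kcat_f[aa], rel=1e-6)
            assert fit.kcat_loss[aa] == pytest.approx(planted.kcat_loss[aa],
                                                      rel=1e-6, abs=1e-9)

    def test_two_aa_explicit_round_trip(self):
        spec = fixtures.FixtureSpec(seed=3, n_aa=2)
        net, planted, cond_min, cond_rich = fixtures.generate_toy_aa_network(spec)
        kin = bio.AAKinetics(kcat_f={}, kcat_loss={}, K_I=planted.K_I,
                             K_M_up=planted.K_M_up, K_M_loss=planted.K_M_loss)
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        for aa in net.amino_acids:
            assert fit.kcat_f[aa] == pytest.approx(planted.kcat_f[aa], rel=1e-6)

    def test_mass_balance_residuals(self, toy_fit_fixture):
        net, planted, cond_min, cond_rich = toy_fit_fixture
        kin = bio.AAKinetics(kcat_f={}, kcat_loss={}, K_I=planted.K_I,
                             K_M_up=planted.K_M_up, K_M_loss=planted.K_M_loss)
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        for cond in (cond_min, cond_rich):
            for aa, resid in fit.residuals[cond.name].items():
                assert abs(resid) <= 1e-6 * max(cond.demand[aa], 1.0)

    def test_nonnegativity(self, toy_fit_fixture):
        net, planted, cond_min, cond_rich = toy_fit_fixture
        kin = bio.AAKinetics(kcat_f={}, kcat_loss={}, K_I=planted.K_I,
                             K_M_up=planted.K_M_up, K_M_loss=planted.K_M_loss)
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        assert all(v >= 0 for v in fit.kcat_f.values())
        assert all(v >= 0 for v in fit.kcat_loss.values())

    def test_null_demand_admits_zero_kcats(self):
        net = single_aa_net(loss="none")
        kin = bio.assign_default_constants(net, {"X": 100.0})
        zero = {"X": 0.0}
        cond_min = bio.ConditionTable(name="minimal", aa_conc={"X": 100.0},
                                      enzyme_conc={"X": 1.0}, demand=zero,
                                      v_exchange_lit=zero, kcat_lit=zero)
        cond_rich = bio.ConditionTable(name="rich", aa_conc={"X": 200.0},
                                       enzyme_conc={"X": 1.0}, demand=zero,
                                       v_exchange_lit=zero, kcat_lit=zero)
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        assert fit.kcat_f["X"] == pytest.approx(0.0)
        assert fit.kcat_loss["X"] == pytest.approx(0.0)

    def test_infeasible_at_lit_exchange_shifts_exchange(self):
        # without a loss reaction the minimal balance pins kcat_f; the rich
        # balance then forces the exchange away from its (zero) literature
        # value -- mirroring "varying the uptake rate is sufficient".
        net = single_aa_net(loss="none")
        kin = bio.assign_default_constants(net, {"X": 100.0})
        cond_min = bio.ConditionTable(name="minimal", aa_conc={"X": 100.0},
                                      enzyme_conc={"X": 1.0}, demand={"X": 1.0},
                                      v_exchange_lit={"X": 0.0}, kcat_lit={"X": 2.0})
        cond_rich = bio.ConditionTable(name="rich", aa_conc={"X": 200.0},
                                       enzyme_conc={"X": 1.0}, demand={"X": 3.0},
                                       v_exchange_lit={"X": 0.0}, kcat_lit={"X": 2.0})
        fit = bio.fit_kcats_and_exchange(net, kin, cond_min, cond_rich)
        assert fit.kcat_f["X"] >= 0
        assert fit.v_exchange["X"] != 0.0
        for cond in (cond_min, cond_rich):
            for aa, resid in fit.residuals[cond.name].items():
                assert abs(resid) <= 1e-6 * max(cond.demand[aa], 1.0)


class TestNetworkValidation:
    def test_cycle_detection(self):
        with pytest.raises(DomainError):
            bio.AANetwork(amino_acids=("A", "B"),
                          upstream={"A": frozenset({"B"}), "B": frozenset({"A"})},
                          root="A")

    def test_downstream_is_inverse_of_upstream(self, chain3):
        net, _ = chain3
        down = net.downstream
        for aa, ups in net.upstream.items():
            for up in ups:
                assert aa in down[up]

    def test_unknown_root_raises(self):
        with pytest.raises(IdentifierError):
            bio.AANetwork(amino_acids=("A",), upstream={"A": frozenset()}, root="Z")
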