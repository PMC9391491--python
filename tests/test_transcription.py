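import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthctrl import fixtures
from growthctrl import transcription as txn
from growthctrl.errors import DomainError, FitError


class TestFractionBound:
    def test_half_saturation(self):
        b = txn.RnapBinding(K_M_ppgpp=40.0)
        assert txn.fraction_bound(b, 40.0) == pytest.approx(0.5)

    def test_zero(self):
        assert txn.fraction_bound(txn.RnapBinding(K_M_ppgpp=40.0), 0.0) == 0.0

    def test_three_km_gives_nine_tenths(self):
        b = txn.RnapBinding(K_M_ppgpp=10.0)
        assert txn.fraction_bound(b, 30.0) == pytest.approx(0.9)

    @given(st.floats(0.0, 1e4), st.floats(0.1, 1e3))
    @settings(max_examples=40, deadline=None)
    def test_in_unit_interval_and_increasing(self, c, delta):
        b = txn.RnapBinding(K_M_ppgpp=35.0)
        lo, hi = txn.fraction_bound(b, c), txn.fraction_bound(b, c + delta)
        assert 0.0 <= lo <= hi <= 1.0
        assert hi > lo

    def test_hill_exponent_is_fixed(self):
        with pytest.raises(DomainError):
            txn.RnapBinding(K_M_ppgpp=40.0, hill=3.0)


class TestFitKmRnap:
    def test_noiseless_planted_recovery(self):
        table, planted = fixtures.generate_growth_law_table(
            fixtures.FixtureSpec(seed=1, n_rows=8), K_M=35.0)
        fit = txn.fit_km_rnap(table)
        assert fit.K_M_ppgpp == pytest.approx(planted["K_M"], rel=1e-6)
        assert fit.exp_free == pytest.approx(planted["exp_free"], rel=1e-6)
        assert fit.exp_ppgpp == pytest.approx(planted["exp_ppgpp"], rel=1e-6)
        assert fit.residual < 1e-10

    def test_degenerate_constant_ppgpp_raises(self):
        table = txn.GrowthLawTable(
            doubling_time_min=np.array([30.0, 40.0, 60.0]),
            rna_mass_fraction=np.array([0.3, 0.25, 0.2]),
            rnap_conc=np.array([8.0, 7.0, 6.0]),
            ppgpp_conc=np.array([50.0, 50.0, 50.0]))
        with pytest.raises(FitError):
            txn.fit_km_rnap(table)

    def test_noisy_recovery_within_twenty_percent(self):
        table, planted = fixtures.generate_growth_law_table(
            fixtures.FixtureSpec(seed=5, n_rows=10, noise=0.05), K_M=35.0)
        fit = txn.fit_km_rnap(table)
        assert fit.K_M_ppgpp == pytest.approx(planted["K_M"], rel=0.20)

    def test_too_few_rows_raise(self):
        table, _ = fixtures.generate_growth_law_table(fixtures.FixtureSpec(seed=1, n_rows=3))
        txn.fit_km_rnap(table)  # 3 rows is the minimum
        with pytest.raises(FitError):
            txn.fit_km_rnap(txn.GrowthLawTable(
                doubling_time_min=table.doubling_time_min[:2],
                rna_mass_fraction=table.rna_mass_fraction[:2],
                rnap_conc=table.rnap_conc[:2], ppgpp_conc=table.ppgpp_conc[:2]))


class TestSolveGeneExpression:
    def test_zero_fold_change_is_flat(self):
        ef, ep = txn.solve_gene_expression({"g": 0.0}, {"g": 0.4}, f_rich=0.6,
                                           f_basal=0.3)
        assert ef["g"] == pytest.approx(0.4)
        assert ep["g"] == pytest.approx(0.4)

    def test_forward_round_trip(self):
        ef_true, ep_true, f_rich, f_basal = 0.8, 0.2, 0.7, 0.3
        fc = np.log2(ep_true / ((1 - f_rich) * ef_true + f_rich * ep_true))
        basal = (1 - f_basal) * ef_true + f_basal * ep_true
        ef, ep = txn.solve_gene_expression({"g": fc}, {"g": basal}, f_rich, f_basal)
        assert ef["g"] == pytest.approx(ef_true, rel=1e-12)
        assert ep["g"] == pytest.approx(ep_true, rel=1e-12)

    def test_truncation_branch(self):
        # a fold change larger than achievable with exp_free >= 0 truncates
        f_rich, f_basal = 0.5, 0.25
        max_fc = np.log2(1.0 / f_rich)  # reached at exp_free = 0
        ef, ep = txn.solve_gene_expression({"g": max_fc + 1.0}, {"g": 0.2},
                                           f_rich, f_basal)
        assert ef["g"] == 0.0
        assert ep["g"] == pytest.approx(0.2 / f_basal)

    def test_sign_matched_fallbacks(self):
        ef, ep = txn.solve_gene_expression({"g": None}, {"g": 0.3}, 0.6, 0.3,
                                           reg_sign={"g": 1}, fc_plus=1.0, fc_minus=-1.0)
        ef2, ep2 = txn.solve_gene_expression({"g": 1.0}, {"g": 0.3}, 0.6, 0.3)
        assert ef["g"] == pytest.approx(ef2["g"])

    def test_consistency_invariant(self):
        # solved pairs reproduce the basal relation for all genes and the FC
        # relation for non-truncated genes
        rng = np.random.default_rng(0)
        f_rich, f_basal = 0.65, 0.35
        fc = {f"g{i}": float(rng.uniform(-2, 2)) for i in range(20)}
        basal = {f"g{i}": float(rng.uniform(0.05, 1.0)) for i in range(20)}
        ef, ep = txn.solve_gene_expression(fc, basal, f_rich, f_basal)
        for g in fc:
            assert (1 - f_basal) * ef[g] + f_basal * ep[g] == pytest.approx(basal[g],
                                                                            rel=1e-9)
            if ef[g] > 0:
                denom = (1 - f_rich) * ef[g] + f_rich * ep[g]
                assert np.log2(ep[g] / denom) == pytest.approx(fc[g], rel=1e-9)

    def test_f_rich_one_unsolvable(self):
        with pytest.raises(DomainError):
            txn.solve_gene_expression({"g": 0.5}, {"g": 0.3}, f_rich=1.0, f_basal=0.3)


class TestConditionMatch:
    def test_planted_linear_round_trip(self):
        f = [0.2, 0.5, 0.8]
        ef_true, ep_true = 0.7, 0.1
        e = [(1 - fi) * ef_true + fi * ep_true for fi in f]
        ef, ep = txn.condition_match({"g": e}, f)
        assert ef["g"] == pytest.approx(ef_true, rel=1e-12)
        assert ep["g"] == pytest.approx(ep_true, rel=1e-12)

    def test_tf_contribution_subtracted(self):
        f = [0.2, 0.8]
        ef_true, ep_true = 0.6, 0.2
        tf = [0.05, 0.02]
        e = [(1 - fi) * ef_true + fi * ep_true + t for fi, t in zip(f, tf)]
        ef, ep = txn.condition_match({"g": e}, f, tf_cond={"g": tf})
        assert ef["g"] == pytest.approx(ef_true, rel=1e-12)

    def test_identical_conditions_rank_deficient(self):
        with pytest.raises(FitError):
            txn.condition_match({"g": [0.5, 0.5]}, [0.4, 0.4])

    def test_unbiased_under_zero_mean_noise(self):
        rng = np.random.default_rng(1)
        f = np.array([0.2, 0.5, 0.8])
        ef_true, ep_true = 0.7, 0.1
        clean = (1 - f) * ef_true + f * ep_true
        estimates = []
        for _ in range(2000):
            e = clean + 0.05 * rng.standard_normal(3)
            ef, ep = txn.condition_match({"g": e}, f)
            estimates.append([ef["g"], ep["g"]])
        mean = np.mean(estimates, axis=0)
        assert mean[0] == pytest.approx(ef_true, abs=0.005)
        assert mean[1] == pytest.approx(ep_true, abs=0.005)

    def test_tf_contribution_formula(self):
        assert txn.tf_contribution(0.4, 0.01, 0.02) == pytest.approx(0.2)
        with pytest.raises(DomainError):
            txn.tf_contribution(0.4, 0.01, 0.0)


def make_gene_params(delta_r=0.0):
    return txn.GeneExpressionParams(
        genes=("g",), exp_free={"g": 0.6}, exp_ppgpp={"g": 0.2},
        alpha_o={"g": 0.5},
        delta_r={("tf", "g"): delta_r} if delta_r else {},
        P_T={"tf": 0.4} if delta_r else {})


class TestSynthProbability:
    def test_no_tfs_probability_is_alpha(self):
        p = make_gene_params()
        fixed = txn.synth_probability(p, {"g": 0.5}, "fixed")
        pp = txn.synth_probability(p, {"g": 0.5}, "ppgpp")
        assert fixed["g"] == pp["g"] == pytest.approx(0.5)

    def test_alpha_equal_alpha_o_reduces_to_fixed(self):
        p = make_gene_params(delta_r=-0.3)
        fixed = txn.synth_probability(p, {"g": 0.5}, "fixed")
        pp = txn.synth_probability(p, {"g": 0.5}, "ppgpp")
        assert pp["g"] == pytest.approx(fixed["g"])

    def test_negative_probability_clipped_and_counted(self):
        p = make_gene_params(delta_r=-2.0)
        counter = {}
        out = txn.synth_probability(p, {"g": 0.5}, "fixed", clip_counter=counter)
        assert out["g"] == 0.0
        assert counter["g"] == 1

    def test_tf_scale_correction_matches_modes_at_basal(self):
        binding = txn.RnapBinding(K_M_ppgpp=35.0)
        p = txn.GeneExpressionParams(
            genes=("g",), exp_free={"g": 0.6}, exp_ppgpp={"g": 0.2},
            alpha_o={"g": 0.5}, delta_r={("tf", "g"): -0.2}, P_T={"tf": 0.5})
        basal_ppgpp = 45.0
        f = txn.fraction_bound(binding, basal_ppgpp)

        def alpha_fn(c):
            fc = txn.fraction_bound(binding, c)
            return {g: (1 - fc) * p.exp_free[g] + fc * p.exp_ppgpp[g] for g in p.genes}

        ef, ep = txn.tf_scale_correction(p, binding, basal_ppgpp, alpha_fn)
        scaled = txn.GeneExpressionParams(genes=("g",), exp_free=ef, exp_ppgpp=ep,
                                          alpha_o=p.alpha_o, delta_r=p.delta_r,
                                          P_T=p.P_T)
        alpha_scaled = {g: (1 - f) * ef[g] + f * ep[g] for g in p.genes}
        v_ppgpp = txn.synth_probability(scaled, alpha_scaled, "ppgpp")
        v_fixed = txn.synth_probability(p, p.alpha_o, "fixed")
        assert v_ppgpp["g"] == pytest.approx(v_fixed["g"], abs=1e-12)


class TestAlphaOfPpgpp:
    def test_dosage_limits(self):
        # terminus gene with replication periods much shorter than tau -> ~1 copy
        assert txn.gene_dosage(1e6, 1.0, C_min=40.0, D_min=20.0) == pytest.approx(
            1.0, rel=1e-4)
        # origin-proximal gene at fast growth has more copies
        assert txn.gene_dosage(24.0, 0.0) > txn.gene_dosage(24.0, 1.0)

    def test_alpha_linearity_in_expression(self):
        table, _ = fixtures.generate_growth_law_table(fixtures.FixtureSpec(seed=1))
        tau = txn.make_tau_interpolant(table)
        binding = txn.RnapBinding(K_M_ppgpp=35.0)
        p1 = txn.GeneExpressionParams(genes=("g",), exp_free={"g": 0.3},
                                      exp_ppgpp={"g": 0.1}, alpha_o={"g": 1.0},
                                      rna_halflife_s={"g": 300.0},
                                      gene_position={"g": 0.5})
        p2 = txn.GeneExpressionParams(genes=("g",), exp_free={"g": 0.6},
                                      exp_ppgpp={"g": 0.2}, alpha_o={"g": 1.0},
                                      rna_halflife_s={"g": 300.0},
                                      gene_position={"g": 0.5})
        c = float(table.ppgpp_conc.mean())
        a1 = txn.alpha_of_ppgpp(p1, binding, c, tau)
        a2 = txn.alpha_of_ppgpp(p2, binding, c, tau)
        assert a2["g"] == pytest.approx(2.0 * a1["g"])

    def test_loss_combines_dilution_and_decay(self):
        table, _ = fixtures.generate_growth_law_table(fixtures.FixtureSpec(seed=1))
        tau = txn.make_tau_interpolant(table)
        binding = txn.RnapBinding(K_M_ppgpp=35.0)
        c = float(table.ppgpp_conc.mean())
        stable = txn.GeneExpressionParams(genes=("g",), exp_free={"g": 0.3},
                                          exp_ppgpp={"g": 0.3}, alpha_o={"g": 1.0},
                                          gene_position={"g": 0.5})
        fast = txn.GeneExpressionParams(genes=("g",), exp_free={"g": 0.3},
                                        exp_ppgpp={"g": 0.3}, alpha_o={"g": 1.0},
                                        rna_halflife_s={"g": 60.0},
                                        gene_position={"g": 0.5})
        a_stable = txn.alpha_of_ppgpp(stable, binding, c, tau)["g"]
        a_fast = txn.alpha_of_ppgpp(fast, binding, c, tau)["g"]
        tau_s = float(tau(c)) * 60.0
        expected_ratio = (np.log(2) / tau_s + np.log(2) / 60.0) / (np.log(2) / tau_s)
        assert a_fast / a_stable == pytest.approx(expected_ratio)

    def test_extrapolation_error(self):
        table, _ = fixtures.generate_growth_law_table(fixtures.FixtureSpec(seed=1))
        tau = txn.make_tau_interpolant(table)
        binding = txn.RnapBinding(K_M_ppgpp=35.0)
        p = make_gene_params()
        with pytest.raises(DomainError):
            txn.alpha_of_ppgpp(p, binding, 1e6, tau)
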