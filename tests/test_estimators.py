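"""Estimator suite: Wald, IVW, Egger, weighted median, mode, SIMEX, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_instrument_set, random_instrument_set
from twosample_mr.estimators import (
    EstimationError,
    egger_simex,
    ivw,
    mode_based,
    mr_egger,
    rescale,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from twosample_mr.harmonize import HarmonizedPair, InstrumentSet
from twosample_mr.simulate import Scenario, harmonized_from_simulation, oracle_wls


class TestWaldRatio:
    def test_direct_formula(self):
        est = wald_ratio(HarmonizedPair("rs1", 0.1, 0.01, 0.05, 0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(HarmonizedPair("rs1", 0.1, 0.01, 0.0, 0.01)).beta == 0.0

    def test_sign_flip_invariance(self):
        a = wald_ratio(HarmonizedPair("rs1", 0.1, 0.01, 0.05, 0.01))
        b = wald_ratio(HarmonizedPair("rs1", -0.1, 0.01, -0.05, 0.01))
        assert (a.beta, a.se) == (b.beta, b.se)

    def test_zero_gamma_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(HarmonizedPair("rs1", 0.0, 0.01, 0.05, 0.01))


class TestIVW:
    def test_homogeneous_set_recovers_common_ratio(self, homogeneous_set):
        fe = ivw(homogeneous_set, model="fixed")
        re = ivw(homogeneous_set, model="multiplicative_random")
        assert fe.beta == pytest.approx(0.5)
        assert fe.settings["Q"] == pytest.approx(0.0, abs=1e-20)
        assert re.se == pytest.approx(fe.se)  # no excess heterogeneity

    def test_toy_s4_closed_form(self, toy_s4):
        est = ivw(toy_s4, model="fixed")
        assert est.beta == pytest.approx(0.05125 / 0.0825, abs=1e-12)
        assert est.beta == pytest.approx(0.6212, abs=5e-5)

    def test_matches_wls_oracle_through_origin(self, toy_s4):
        g, _, G, seG = toy_s4.gammas()
        slope, _, _ = oracle_wls(g, G, 1.0 / seG**2, with_intercept=False)
        assert ivw(toy_s4, model="fixed").beta == pytest.approx(slope, abs=1e-12)

    def test_single_snp_equals_wald(self):
        s = make_instrument_set([0.1], [0.01], [0.05], [0.01])
        assert ivw(s).beta == pytest.approx(wald_ratio(s.pairs[0]).beta)
        assert ivw(s).se == pytest.approx(wald_ratio(s.pairs[0]).se)

    def test_random_effects_se_never_smaller_than_fixed(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = random_instrument_set(rng, int(rng.integers(3, 30)))
            assert ivw(s, "multiplicative_random").se >= ivw(s, "fixed").se - 1e-15


class TestEgger:
    def test_exact_fit_zero_intercept(self, homogeneous_set):
        slope, intercept = mr_egger(homogeneous_set)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_toy_s4_equal_weights(self, toy_s4):
        slope, intercept = mr_egger(toy_s4)
        assert slope.beta == pytest.approx(-1 / 22, abs=1e-12)  # -0.0455
        assert intercept.beta == pytest.approx(0.1, abs=1e-12)

    def test_matches_wls_oracle_with_intercept(self, toy_s4):
        g, _, G, seG = toy_s4.gammas()
        slope, intercept, _ = oracle_wls(g, G, 1.0 / seG**2, with_intercept=True)
        got_slope, got_int = mr_egger(toy_s4)
        assert got_slope.beta == pytest.approx(slope, abs=1e-12)
        assert got_int.beta == pytest.approx(intercept, abs=1e-12)

    def test_constant_gamma_is_rank_deficient(self):
        s = make_instrument_set([0.1] * 4, [0.01] * 4, [0.05, 0.1, 0.02, 0.07], [0.01] * 4)
        with pytest.raises(EstimationError, match="rank"):
            mr_egger(s)

    def test_unoriented_set_rejected(self):
        s = InstrumentSet(
            "e", "o",
            pairs=[HarmonizedPair(f"rs{i}", g, 0.01, 0.5 * g, 0.01)
                   for i, g in enumerate([-0.1, 0.2, 0.15])],
        )
        with pytest.raises(EstimationError, match="orient"):
            mr_egger(s)

    def test_too_few_snps_rejected(self):
        s = make_instrument_set([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(EstimationError, match=">=3"):
            mr_egger(s)


class TestWeightedMedian:
    def test_cluster_of_three_beats_outlier(self, toy_s4):
        est = weighted_median(toy_s4, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_equal_weight_symmetric_ratios(self):
        g = np.array([0.1, 0.1, 0.1])
        G = g * np.array([0.4, 0.5, 0.6])
        s = make_instrument_set(g, [0.01] * 3, G, [0.01] * 3)
        est = weighted_median(s, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_equal_weights_equals_plain_median_odd_L(self):
        rng = np.random.default_rng(8)
        g = np.full(7, 0.1)
        ratios = rng.normal(0.3, 0.5, 7)
        s = make_instrument_set(g, [0.01] * 7, g * ratios, [0.01] * 7)
        est = weighted_median(s, n_boot=100, seed=2)
        assert est.beta == pytest.approx(np.median(ratios))

    def test_single_pair_degrades_to_wald(self):
        s = make_instrument_set([0.1], [0.01], [0.05], [0.01])
        assert weighted_median(s, seed=3).beta == pytest.approx(0.5)

    def test_seed_required(self, toy_s4):
        with pytest.raises(EstimationError, match="seed"):
            weighted_median(toy_s4, n_boot=200)

    def test_bit_reproducible(self, toy_s4):
        a = weighted_median(toy_s4, n_boot=300, seed=11)
        b = weighted_median(toy_s4, n_boot=300, seed=11)
        assert (a.beta, a.se, a.ci_low, a.ci_high, a.pval) == (
            b.beta, b.se, b.ci_low, b.ci_high, b.pval
        )


class TestModeBased:
    def test_point_mass(self, homogeneous_set):
        est = mode_based(homogeneous_set, seed=1, n_boot=100)
        assert est.beta == pytest.approx(0.5, abs=1e-9)

    def test_majority_cluster_wins(self, toy_s4):
        est = mode_based(toy_s4, phi=1.0, seed=1, n_boot=100)
        assert est.beta == pytest.approx(0.5, abs=0.02)

    def test_matches_grid_density_oracle(self, toy_s4):
        # independent KDE-argmax via scipy.stats.gaussian_kde on a fine grid
        from scipy import stats as sps

        g, _, G, _ = toy_s4.gammas()
        ratios = G / g
        est = mode_based(toy_s4, phi=1.0, seed=1, n_boot=100)
        h = est.settings["bandwidth"]
        kde = sps.gaussian_kde(ratios, bw_method=h / ratios.std(ddof=1))
        grid = np.linspace(ratios.min() - h, ratios.max() + h, 4096)
        oracle = grid[np.argmax(kde(grid))]
        assert est.beta == pytest.approx(oracle, abs=0.02)

    def test_weighted_equals_simple_under_equal_weights(self):
        g = np.full(5, 0.1)
        G = g * np.array([0.2, 0.5, 0.5, 0.55, 1.0])
        s = make_instrument_set(g, [0.01] * 5, G, [0.01] * 5)
        a = mode_based(s, weighting="simple", seed=4, n_boot=100)
        b = mode_based(s, weighting="weighted", seed=4, n_boot=100)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_invalid_phi_rejected(self, toy_s4):
        with pytest.raises(ValueError):
            mode_based(toy_s4, phi=0.0, seed=1)


class TestSimex:
    def test_no_measurement_error_equals_egger(self):
        sc = Scenario(beta_true=-0.4, L=40, se_gamma=1e-6, se_Gamma=0.01, seed=21)
        instruments, _ = harmonized_from_simulation(sc)
        slope, _ = mr_egger(instruments)
        sx = egger_simex(instruments, n_sim=200, seed=5)
        assert sx.beta == pytest.approx(slope.beta, abs=1e-4)
        by_lambda = sx.settings["slopes_by_lambda"]
        assert np.allclose(by_lambda, slope.beta, atol=1e-4)

    def test_single_lambda_rejected(self, toy_s4):
        with pytest.raises(EstimationError, match="lambda"):
            egger_simex(toy_s4, lambdas=[0.0], seed=1)

    def test_lambdas_must_start_at_zero_and_increase(self, toy_s4):
        with pytest.raises(EstimationError):
            egger_simex(toy_s4, lambdas=[0.5, 1.0, 1.5], seed=1)
        with pytest.raises(EstimationError):
            egger_simex(toy_s4, lambdas=[0.0, 1.0, 0.5], seed=1)

    def test_seed_required(self, toy_s4):
        with pytest.raises(EstimationError, match="seed"):
            egger_simex(toy_s4)

    def test_bit_reproducible(self):
        sc = Scenario(beta_true=-0.4, L=30, se_gamma=0.01, se_Gamma=0.01, seed=6)
        instruments, _ = harmonized_from_simulation(sc)
        a = egger_simex(instruments, n_sim=150, seed=7)
        b = egger_simex(instruments, n_sim=150, seed=7)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestScaleConversions:
    def test_null_effect_is_or_one(self):
        est = ivw(make_instrument_set([0.1], [0.01], [0.0], [0.01]))
        assert to_odds_ratio(est)[0] == pytest.approx(1.0)

    def test_log_odds_to_or(self, homogeneous_set):
        # beta -0.4005 corresponds to OR 0.67
        s = make_instrument_set([0.1, 0.2, 0.15], [0.01] * 3,
                                [-0.04005, -0.0801, -0.060075], [0.01] * 3)
        or_, lo, hi = to_odds_ratio(ivw(s, "fixed"))
        assert round(or_, 2) == 0.67
        assert lo <= or_ <= hi

    def test_rescale_identity(self, toy_s4):
        est = ivw(toy_s4)
        assert rescale(est, 1.0).beta == est.beta

    def test_sd_to_years_to_days(self):
        est = ivw(make_instrument_set([0.1], [0.01], [0.000183], [0.01]))
        days = rescale(rescale(est, 3.6, "years"), 365.25, "days")
        assert days.beta == pytest.approx(2.4, abs=0.01)
        assert days.unit == "days"

    def test_negative_factor_keeps_ci_ordered(self, toy_s4):
        est = rescale(ivw(toy_s4), -2.0)
        assert est.ci_low <= est.beta <= est.ci_high


@given(seed=st.integers(0, 10_000), L=st.integers(3, 25))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_estimators_invariant_to_permutation_and_joint_sign_flips(seed, L):
    """IVW, Egger, the weighted median and the mode depend only on the
    unordered set of oriented (gamma, Gamma) pairs."""
    rng = np.random.default_rng(seed)
    base = random_instrument_set(rng, L)
    perm = rng.permutation(L)
    flip = rng.random(L) < 0.5
    pairs = []
    for i in perm:
        p = base.pairs[i]
        if flip[i]:
            p = HarmonizedPair(p.snp_id, -p.gamma, p.se_gamma, -p.Gamma, p.se_Gamma)
        pairs.append(p)
    from twosample_mr.harmonize import orient_to_exposure_increasing

    other = orient_to_exposure_increasing(
        InstrumentSet("e", "o", pairs=pairs)
    )
    assert ivw(base).beta == pytest.approx(ivw(other).beta, rel=1e-12)
    assert mr_egger(base)[0].beta == pytest.approx(mr_egger(other)[0].beta, rel=1e-9)
    a = weighted_median(base, n_boot=100, seed=1).beta
    b = weighted_median(other, n_boot=100, seed=1).beta
    assert a == pytest.approx(b, rel=1e-12)
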