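"""The five MR estimators against hand computations and simulations."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrtriage.estimators import EstimationError, MRModel, _weighted_median
from mrtriage.simdata import RegionTruth, simulate_region_pair
from mrtriage.instruments import build_instruments


def model(bx, sx, by, sy, **kw):
    return MRModel(bx, sx, by, sy, **kw)


class TestWaldRatio:
    def test_zero_effect_gives_p_one(self):
        est = model([1.0], [0.1], [0.0], [0.02]).wald_ratio()
        assert est.beta == 0.0 and est.pvalue == 1.0

    def test_hand_computed_ratio_and_delta_se(self):
        est = model([0.5], [0.05], [0.1], [0.02]).wald_ratio()
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.04)

    def test_doubling_exposure_halves_estimate_and_se(self):
        a = model([0.5], [0.05], [0.1], [0.02]).wald_ratio()
        b = model([1.0], [0.05], [0.1], [0.02]).wald_ratio()
        assert b.beta == pytest.approx(a.beta / 2)
        assert b.se == pytest.approx(a.se / 2)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(EstimationError, match="ratio"):
            model([0.0], [0.05], [0.1], [0.02]).wald_ratio()

    def test_second_order_se_exceeds_first_order(self):
        m = model([0.5], [0.05], [0.1], [0.02])
        assert m.wald_ratio(second_order=True).se > m.wald_ratio().se


class TestIVW:
    BX = [0.5, 0.4]
    SY = [0.02, 0.03]
    BY = [0.1, 0.12]
    SX = [0.01, 0.01]

    def test_matches_weighted_ls_through_origin(self):
        est = model(self.BX, self.SX, self.BY, self.SY).ivw("fixed")
        # independent oracle: weighted least squares without intercept
        fit = sm.WLS(
            self.BY, np.asarray(self.BX)[:, None],
            weights=1.0 / np.asarray(self.SY) ** 2,
        ).fit()
        assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-12)
        assert est.beta == pytest.approx(0.222146, abs=1e-6)
        assert est.se == pytest.approx(0.035294, abs=1e-6)

    def test_single_snp_delegates_to_wald(self):
        m = model([0.5], [0.05], [0.1], [0.02])
        ivw = m.ivw()
        wald = m.wald_ratio()
        assert ivw.beta == wald.beta and ivw.se == wald.se
        assert ivw.method == "ivw_mre"

    def test_homogeneous_ratios_make_rem_equal_fe(self):
        bx = np.array([0.5, 0.4, 0.3])
        by = 0.25 * bx
        m = model(bx, [0.01] * 3, by, [0.02, 0.03, 0.04])
        assert m.ivw("multiplicative_random").se == pytest.approx(
            m.ivw("fixed").se
        )
        assert m.ivw("fixed").beta == pytest.approx(0.25)

    def test_rem_never_deflates_below_fe(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 8))
            m = model(
                rng.normal(0.3, 0.1, k), np.full(k, 0.02),
                rng.normal(0.1, 0.05, k), rng.uniform(0.01, 0.05, k),
            )
            assert m.ivw("multiplicative_random").se >= m.ivw("fixed").se

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_fe_equals_ivw_mean_of_wald_ratios(self, k, seed):
        """IVW-FE is the inverse-variance mean of per-SNP Wald ratios
        under first-order weights (algebraic identity)."""
        r = np.random.default_rng(seed)
        bx = r.uniform(0.1, 0.6, k) * r.choice([-1, 1], k)
        sy = r.uniform(0.01, 0.05, k)
        by = r.normal(0.05, 0.03, k)
        est = model(bx, np.full(k, 0.01), by, sy).ivw("fixed")
        ratios = by / bx
        w = (bx / sy) ** 2
        assert est.beta == pytest.approx(np.sum(w * ratios) / np.sum(w), abs=1e-10)
        assert est.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-10)

    def test_all_zero_exposure_is_degenerate(self):
        with pytest.raises(EstimationError, match="degenerate"):
            model([0.0, 0.0], [0.01] * 2, [0.1, 0.2], [0.02] * 2).ivw()


class TestEgger:
    def test_exact_fit_recovers_slope_and_zero_intercept(self):
        bx = np.array([0.2, 0.35, 0.5, 0.65])
        by = 0.3 * bx
        est = model(bx, [0.01] * 4, by, [0.02] * 4).egger()
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.extra["intercept_p"] > 0.99

    def test_orientation_invariance(self):
        bx = np.array([0.2, -0.35, 0.5, 0.65])
        by = np.array([0.07, -0.09, 0.16, 0.18])
        base = model(bx, [0.01] * 4, by, [0.02] * 4).egger()
        flipped = model(-bx, [0.01] * 4, -by, [0.02] * 4).egger()
        assert base.beta == pytest.approx(flipped.beta, abs=1e-12)
        assert base.extra["intercept"] == pytest.approx(
            flipped.extra["intercept"], abs=1e-12
        )

    def test_recovers_injected_directional_pleiotropy(self):
        """50 independent strong instruments with a constant direct
        effect of 0.05 on the outcome: the intercept estimate lands
        within 2 SE of 0.05."""
        r = np.random.default_rng(5)
        truth = RegionTruth(
            m_snps=50, ld_rho=0.0,
            causal_exp_indices=tuple(range(50)),
            causal_exp_effects=tuple(r.uniform(0.15, 0.45, 50)),
            theta=0.1, pleiotropy_mean=0.05, pleiotropy_sd=0.0,
            n_out=5_000_000, seed=21,
        )
        exposure, outcome, _ = simulate_region_pair(truth)
        est = model(
            exposure["beta"], exposure["se"], outcome["beta"], outcome["se"]
        ).egger()
        a, a_se = est.extra["intercept"], est.extra["intercept_se"]
        assert abs(a - 0.05) < 2 * a_se
        assert est.beta == pytest.approx(0.1, abs=0.05)

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError, match="3"):
            model([0.5, 0.4], [0.01] * 2, [0.1, 0.1], [0.02] * 2).egger()


class TestWeightedMedian:
    def test_equal_ratios_returned_exactly(self):
        bx = np.array([0.5, 0.4, 0.3])
        est = model(bx, [0.01] * 3, 0.2 * bx, [0.02] * 3).weighted_median(
            n_boot=200, seed=1
        )
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_equal_weights_pick_middle_ratio(self):
        # ratios {0.1, 0.2, 0.9} with identical weights -> 0.2
        assert _weighted_median(
            np.array([0.1, 0.2, 0.9]), np.ones(3)
        ) == pytest.approx(0.2)

    def test_majority_valid_weight_dominates_outlier(self):
        # >50% of weight shares ratio 0.3; tiny noise -> estimate near 0.3
        bx = np.array([0.5, 0.5, 0.5, 0.2])
        by = np.array([0.15, 0.15, 0.15, 0.5])
        est = model(bx, [0.005] * 4, by, [0.005] * 4).weighted_median(
            n_boot=500, seed=2
        )
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_bootstrap_se_is_seed_reproducible(self):
        m = model([0.5, 0.4, 0.3], [0.01] * 3, [0.1, 0.09, 0.05], [0.02] * 3)
        a = m.weighted_median(n_boot=300, seed=7)
        b = m.weighted_median(n_boot=300, seed=7)
        assert a.se == b.se


class TestMaxLikelihood:
    def test_single_snp_equals_wald(self):
        m = model([0.5], [0.05], [0.1], [0.02])
        assert m.max_likelihood().beta == m.wald_ratio().beta

    def test_zero_noise_common_ratio_recovered(self):
        bx = np.array([0.2, 0.4, 0.6])
        m = model(bx, [0.01] * 3, 0.37 * bx, [0.02] * 3)
        assert m.max_likelihood().beta == pytest.approx(0.37, abs=1e-8)

    def test_agrees_with_ivw_on_homogeneous_data(self):
        truth = RegionTruth(seed=33, theta=0.3, ld_rho=0.0)
        exposure, outcome, ld = simulate_region_pair(truth)
        iset = build_instruments(truth.gene(), exposure, outcome, ld)
        m = MRModel.from_instruments(iset)
        ml, ivw = m.max_likelihood(), m.ivw("fixed")
        assert abs(ml.beta - ivw.beta) < 0.01 * ivw.se


class TestOddsRatioScale:
    def test_null_beta_gives_unit_or(self):
        est = model([1.0], [0.1], [0.0], [0.02]).wald_ratio()
        assert est.or_ == 1.0

    def test_hand_computed_or_and_ci(self):
        est = model([0.5], [0.05], [0.1], [0.02]).wald_ratio()
        assert est.beta == pytest.approx(0.2)
        assert est.or_ == pytest.approx(1.2214, abs=1e-4)
        assert est.ci_low == pytest.approx(1.1293, abs=1e-4)
        assert est.ci_high == pytest.approx(1.3211, abs=1e-4)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(-1, 1), st.floats(0.001, 0.5))
    def test_ci_brackets_or(self, beta, se):
        est = model([1.0], [0.01], [beta], [se]).wald_ratio()
        assert est.ci_low < est.or_ < est.ci_high


def test_all_estimators_agree_on_noiseless_single_ratio_data():
    bx = np.array([0.2, 0.35, 0.5, 0.65, 0.8])
    m = model(bx, [0.01] * 5, 0.3 * bx, [0.02] * 5)
    results = m.fit_all(seed=4, n_boot=200)
    for name in ("ivw_mre", "ivw_fe", "egger", "weighted_median", "max_likelihood"):
        assert results[name].beta == pytest.approx(0.3, abs=1e-6), name


def test_fit_all_single_snp_primary_is_wald():
    results = model([0.5], [0.05], [0.1], [0.02]).fit_all()
    assert results.primary_method == "wald_ratio"
    assert set(results.estimates) == {"wald_ratio"}


def test_summary_mentions_gene_and_intercept():
    bx = np.array([0.2, 0.35, 0.5, 0.65])
    m = model(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4, gene_id="ANPEP")
    text = m.fit_all(seed=0, n_boot=100).summary()
    assert "ANPEP" in text and "Egger intercept" in text
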