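import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr import (
    ValidationError,
    SingularDesignError,
    cochran_q,
    correct_for_overlap,
    ivw,
    mr_egger,
    wald_ratios,
    weighted_median,
)
from ivmr.estimators import weighted_median_point
from conftest import make_set


def random_set(rng, n=8):
    bx = rng.uniform(0.02, 0.3, n) * rng.choice([-1, 1], n)
    by = rng.normal(0, 0.01, n)
    sy = rng.uniform(0.001, 0.01, n)
    return make_set(bx, by, se_outcome=sy)


class TestWaldRatios:
    def test_zero_outcome_gives_zero_ratio(self):
        r = wald_ratios(make_set([0.1], [0.0]))
        assert r[0].ratio == 0.0

    def test_first_order_formula(self):
        r = wald_ratios(make_set([0.05], [0.001], se_outcome=[0.0005]))
        assert r[0].ratio == pytest.approx(0.02)
        assert r[0].se_ratio == pytest.approx(0.01)
        assert r[0].weight == pytest.approx(0.01**-2)

    def test_second_order_never_smaller(self):
        rng = np.random.default_rng(3)
        s = random_set(rng, 20)
        first = wald_ratios(s, "first")
        second = wald_ratios(s, "second")
        for a, b in zip(first, second):
            assert b.se_ratio >= a.se_ratio

    def test_zero_exposure_excluded(self):
        s = make_set([0.0, 0.1], [0.01, 0.01])
        assert [r.rsid for r in wald_ratios(s)] == ["rs2"]


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        s = make_set([0.1], [0.002], se_outcome=[0.001])
        est = ivw(s, effects_model="fixed")
        assert est.beta == pytest.approx(0.02)
        assert est.se == pytest.approx(0.001 / 0.1)

    def test_identical_ratios_are_homogeneous(self):
        s = make_set([0.1, 0.2, 0.05], [0.01, 0.02, 0.005])
        fixed = ivw(s, "fixed")
        rand = ivw(s, "random_multiplicative")
        assert fixed.beta == pytest.approx(0.1)
        assert fixed.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert rand.se == pytest.approx(fixed.se)
        assert fixed.p_heterogeneity == pytest.approx(1.0)

    def test_three_snp_closed_form(self, three_snp_set):
        bx = np.array([0.1, 0.2, 0.05])
        by = np.array([0.002, 0.003, 0.0005])
        sy = np.array([0.001, 0.001, 0.002])
        w = sy**-2
        expected = (bx * by * w).sum() / (bx**2 * w).sum()
        est = ivw(three_snp_set, "fixed")
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.se == pytest.approx((bx**2 * w).sum() ** -0.5, rel=1e-12)

    def test_matches_zero_intercept_weighted_regression(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            s = random_set(rng)
            est = ivw(s, "fixed")
            bx = s.data["beta_exposure"].to_numpy()
            by = s.data["beta_outcome"].to_numpy()
            sy = s.data["se_outcome"].to_numpy()
            slope = np.linalg.lstsq(
                (bx / sy)[:, None], by / sy, rcond=None
            )[0][0]
            assert est.beta == pytest.approx(slope, rel=1e-12)

    def test_random_multiplicative_keeps_point_inflates_se(self):
        rng = np.random.default_rng(5)
        s = make_set(
            rng.uniform(0.05, 0.2, 10), rng.normal(0, 0.05, 10), se_outcome=[0.001] * 10
        )
        fixed, rand = ivw(s, "fixed"), ivw(s, "random_multiplicative")
        assert rand.beta == pytest.approx(fixed.beta, rel=1e-12)
        assert rand.q_statistic > 9  # heterogeneous by construction
        assert rand.se == pytest.approx(
            fixed.se * np.sqrt(rand.q_statistic / (rand.n_snps - 1)), rel=1e-12
        )

    def test_random_additive_dersimonian_laird(self):
        rng = np.random.default_rng(6)
        s = make_set(
            rng.uniform(0.05, 0.2, 10), rng.normal(0, 0.05, 10), se_outcome=[0.001] * 10
        )
        ratios = wald_ratios(s)
        r = np.array([x.ratio for x in ratios])
        w = np.array([x.weight for x in ratios])
        beta_f = (w * r).sum() / w.sum()
        q = (w * (r - beta_f) ** 2).sum()
        tau2 = max(0.0, (q - 9) / (w.sum() - (w**2).sum() / w.sum()))
        w_star = 1 / (1 / w + tau2)
        est = ivw(s, "random_additive")
        assert est.beta == pytest.approx((w_star * r).sum() / w_star.sum(), rel=1e-12)
        assert est.se == pytest.approx(w_star.sum() ** -0.5, rel=1e-12)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(7)
        s = random_set(rng)
        flip = rng.choice([-1.0, 1.0], len(s))
        s2 = make_set(
            s.data["beta_exposure"] * flip,
            s.data["beta_outcome"] * flip,
            se_outcome=s.data["se_outcome"],
        )
        for model in ("fixed", "random_multiplicative", "random_additive"):
            assert ivw(s, model).beta == pytest.approx(ivw(s2, model).beta, rel=1e-12)

    def test_empty_set_errors(self):
        with pytest.raises(ValidationError):
            ivw(make_set([0.1], [0.0]).subset([]))

    def test_ci_brackets_beta(self):
        est = ivw(make_set([0.1, 0.2, 0.3], [0.01, 0.03, 0.02]), "random_multiplicative")
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.ci_high - est.beta == pytest.approx(1.96 * est.se, rel=1e-9)


class TestMREgger:
    def test_exact_interpolation(self):
        a, b = 0.005, 0.12
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        s = make_set(bx, a + b * bx, se_outcome=[0.001, 0.002, 0.001, 0.003])
        slope, intercept = mr_egger(s)
        assert slope.beta == pytest.approx(b, rel=1e-9)
        assert intercept.beta == pytest.approx(a, rel=1e-9)

    def test_three_point_normal_equations(self):
        bx = np.array([0.05, 0.12, 0.3])
        by = np.array([0.004, 0.001, 0.01])
        sy = np.array([0.001, 0.003, 0.002])
        w = sy**-2
        # closed-form 2x2 weighted normal equations
        sw, swx, swx2 = w.sum(), (w * bx).sum(), (w * bx**2).sum()
        swy, swxy = (w * by).sum(), (w * bx * by).sum()
        det = sw * swx2 - swx**2
        a_hat = (swx2 * swy - swx * swxy) / det
        b_hat = (sw * swxy - swx * swy) / det
        slope, intercept = mr_egger(make_set(bx, by, se_outcome=sy))
        assert slope.beta == pytest.approx(b_hat, rel=1e-10)
        assert intercept.beta == pytest.approx(a_hat, rel=1e-10)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(8)
        s = random_set(rng, 10)
        flip = rng.choice([-1.0, 1.0], 10)
        s2 = make_set(
            s.data["beta_exposure"] * flip,
            s.data["beta_outcome"] * flip,
            se_outcome=s.data["se_outcome"],
        )
        slope1, int1 = mr_egger(s)
        slope2, int2 = mr_egger(s2)
        assert slope1.beta == pytest.approx(slope2.beta, rel=1e-12)
        assert int1.beta == pytest.approx(int2.beta, rel=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        # refit through the origin: the IVW estimate is the no-intercept Egger
        rng = np.random.default_rng(9)
        s = random_set(rng, 12)
        import statsmodels.api as sm

        bx = np.abs(s.data["beta_exposure"].to_numpy())
        by = s.data["beta_outcome"].to_numpy() * np.sign(s.data["beta_exposure"].to_numpy())
        fit = sm.WLS(by, bx[:, None], weights=s.data["se_outcome"].to_numpy() ** -2).fit()
        assert ivw(s, "fixed").beta == pytest.approx(float(fit.params[0]), rel=1e-12)

    def test_se_never_below_fixed_level(self):
        # homogeneous data: residual scale < 1 must not deflate the SE
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        s = make_set(bx, 0.1 * bx + 1e-6, se_outcome=[0.01] * 4)
        slope, _ = mr_egger(s)
        import statsmodels.api as sm

        fit = sm.WLS(
            s.data["beta_outcome"], sm.add_constant(bx), weights=np.full(4, 0.01**-2)
        ).fit()
        unscaled = float(fit.bse[1] / np.sqrt(fit.scale))
        assert slope.se >= unscaled * 0.999

    def test_too_few_instruments(self):
        with pytest.raises(ValidationError):
            mr_egger(make_set([0.1, 0.2], [0.0, 0.0]))

    def test_no_spread_is_singular(self):
        with pytest.raises(SingularDesignError):
            mr_egger(make_set([0.1, 0.1, -0.1], [0.01, 0.02, 0.03]))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        s = make_set([0.1, 0.1, 0.1], [0.1, 0.2, 0.9], se_outcome=[0.01] * 3)
        est = weighted_median(s, n_bootstrap=100, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_equal_weights_equals_plain_median_odd_n(self):
        rng = np.random.default_rng(10)
        ratios = rng.normal(0, 1, 9)
        assert weighted_median_point(ratios, np.ones(9)) == pytest.approx(
            np.median(ratios)
        )

    def test_dominant_weight_approaches_dominant_ratio(self):
        ratios = [1.0, 2.0, 9.0]
        prev_gap = np.inf
        for w_dom in (0.6, 0.8, 0.95, 0.999):
            rest = (1 - w_dom) / 2
            est = weighted_median_point(ratios, [rest, w_dom, rest])
            # brute-force cumulative-weight oracle
            order = [0, 1, 2]
            w = np.array([rest, w_dom, rest])
            cum = np.cumsum(w) - w / 2
            expected = np.interp(0.5, cum, ratios)
            assert est == pytest.approx(expected, rel=1e-12)
            gap = abs(est - 2.0)
            assert gap <= prev_gap
            prev_gap = gap
        assert 1.0 <= est <= 2.0

    def test_point_estimate_seed_independent(self):
        rng = np.random.default_rng(11)
        s = random_set(rng, 10)
        e1 = weighted_median(s, n_bootstrap=200, seed=1)
        e2 = weighted_median(s, n_bootstrap=200, seed=99)
        assert e1.beta == e2.beta
        assert e1.se != e2.se  # bootstrap noise only
        assert e1.se == pytest.approx(e2.se, rel=0.5)

    def test_bootstrap_floor(self):
        s = make_set([0.1, 0.2, 0.3], [0.01, 0.02, 0.03])
        with pytest.raises(ValidationError):
            weighted_median(s, n_bootstrap=50)


class TestCochranQ:
    def test_identical_ratios(self):
        ratios = wald_ratios(make_set([0.1, 0.2], [0.01, 0.02]))
        q, df, p, contrib = cochran_q(ratios, 0.1)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_symmetric_pair_formula(self):
        # ratios r +/- d, equal weights w, center r -> Q = 2 w d^2
        s = make_set([0.1, 0.1], [0.012, 0.008], se_outcome=[0.001, 0.001])
        ratios = wald_ratios(s)
        w = ratios[0].weight
        q, _, _, contrib = cochran_q(ratios, 0.1)
        assert q == pytest.approx(2 * w * 0.02**2, rel=1e-9)
        assert q == pytest.approx(sum(contrib.values()), rel=1e-15)

    def test_single_ratio_errors(self):
        ratios = wald_ratios(make_set([0.1], [0.01]))
        with pytest.raises(ValidationError):
            cochran_q(ratios, 0.0)


class TestOverlapCorrection:
    def base(self):
        return ivw(make_set([0.1, 0.2, 0.3], [0.01, 0.03, 0.02]), "fixed")

    def test_zero_overlap_unchanged(self):
        est = self.base()
        corr = correct_for_overlap(est, 0.0, observational_estimate=0.5, mean_f=30)
        assert corr.beta == est.beta and corr.se == est.se

    def test_strong_instrument_limit(self):
        est = self.base()
        corr = correct_for_overlap(est, 1.0, observational_estimate=0.5, mean_f=1e12)
        assert corr.beta == pytest.approx(est.beta, abs=1e-9)

    def test_bias_formula_and_relabel(self):
        est = self.base()
        corr = correct_for_overlap(est, 0.43, observational_estimate=0.2, mean_f=40)
        assert corr.beta == pytest.approx(est.beta - 0.43 * 0.2 / 40, rel=1e-12)
        assert corr.method == "ivw_overlap_corrected"
        assert corr.ci_low <= corr.beta <= corr.ci_high

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            correct_for_overlap(self.base(), 1.5, 0.1, 30)


@settings(max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_ivw_closed_form_matches_regression_property(seed):
    """IVW sums and zero-intercept weighted regression agree to 1e-12."""
    rng = np.random.default_rng(seed)
    s = random_set(rng, int(rng.integers(2, 15)))
    est = ivw(s, "fixed")
    bx = s.data["beta_exposure"].to_numpy()
    by = s.data["beta_outcome"].to_numpy()
    sy = s.data["se_outcome"].to_numpy()
    slope = np.linalg.lstsq((bx / sy)[:, None], by / sy, rcond=None)[0][0]
    assert est.beta == pytest.approx(slope, rel=1e-12, abs=1e-15)
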