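import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrphewas import (
    HarmonisedSet,
    egger,
    ivw,
    leave_one_out,
    mode_based,
    wald_ratio,
    weighted_median,
)


def _hset(bx, by, se_out, se_exp=0.01, **kw):
    return HarmonisedSet.from_arrays(bx, se_exp, by, se_out, **kw)


class TestWaldRatio:
    def test_zero_numerator_gives_null_estimate(self):
        r = wald_ratio(0.1, 0.0, 0.05)
        assert r.estimate == 0 and r.pvalue == pytest.approx(1.0)

    def test_closed_form(self):
        r = wald_ratio(0.1, 0.2, 0.04)
        assert r.estimate == pytest.approx(2.0)
        assert r.se == pytest.approx(0.4)
        assert r.ci_low == pytest.approx(2.0 - 1.96 * 0.4)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.1, 0.05)

    def test_second_order_close_to_first_order_for_strong_instruments(self, rng):
        # F > 10 means the exposure-uncertainty term is a small correction
        rel = []
        for _ in range(1000):
            se_x = rng.uniform(0.005, 0.02)
            bx = se_x * np.sqrt(rng.uniform(10.1, 40.0))
            se_y = rng.uniform(0.01, 0.05)
            by = se_y * rng.standard_normal()
            r1 = wald_ratio(bx, by, se_y, se_x)
            r2 = wald_ratio(bx, by, se_y, se_x, second_order=True)
            rel.append(abs(r2.se - r1.se) / r1.se)
        assert np.median(rel) < 0.05


class TestIVW:
    def test_homogeneous_ratios_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3])
        r, het = ivw(_hset(bx, 0.4 * bx, 0.02))
        assert r.estimate == pytest.approx(0.4)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert r.se == pytest.approx(np.sqrt(1 / np.sum(bx**2 / 0.02**2)))

    def test_matches_wls_through_origin_oracle(self, rng):
        bx = rng.normal(0, 0.1, 3)
        by = rng.normal(0, 0.05, 3)
        so = rng.uniform(0.01, 0.05, 3)
        r, het = ivw(_hset(bx, by, so))
        fit = sm.WLS(by, bx[:, None], weights=1 / so**2).fit()
        assert r.estimate == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels' bse uses the residual scale; our RE factor floors it at 1
        se_fe = float(fit.bse[0] / np.sqrt(fit.scale))
        q = float(np.sum((by - fit.params[0] * bx) ** 2 / so**2))
        assert het.Q == pytest.approx(q, abs=1e-10)
        assert r.se == pytest.approx(se_fe * np.sqrt(max(1, q / 2)), abs=1e-10)

    def test_single_instrument_falls_back_to_wald(self):
        r, het = ivw(_hset([0.1], [0.2], [0.04]))
        assert r.method == "wald" and r.fallback
        assert r.estimate == pytest.approx(2.0)
        assert het.df == 0

    def test_order_invariance(self, rng):
        bx = rng.normal(0, 0.1, 8)
        by = rng.normal(0, 0.05, 8)
        so = rng.uniform(0.01, 0.05, 8)
        perm = rng.permutation(8)
        r1, _ = ivw(_hset(bx, by, so))
        r2, _ = ivw(_hset(bx[perm], by[perm], so[perm]))
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-14)

    def test_additive_random_effects_variant(self, rng):
        bx = rng.normal(0, 0.2, 10)
        by = 0.3 * bx + rng.normal(0, 0.08, 10)
        so = np.full(10, 0.02)
        r_add, het = ivw(_hset(bx, by, so), method="additive")
        # independent DerSimonian-Laird on the Wald ratios
        ratios, vr = by / bx, so**2 / bx**2
        w = 1 / vr
        q = het.Q
        tau2 = max(0.0, (q - 9) / (w.sum() - (w**2).sum() / w.sum()))
        est = np.sum(ratios / (vr + tau2)) / np.sum(1 / (vr + tau2))
        assert r_add.estimate == pytest.approx(est, abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        bx = np.ones(5)
        by = np.array([1.0, 2, 3, 4, 5])
        r = weighted_median(_hset(bx, by, 0.1), seed=1)
        assert r.estimate == pytest.approx(3.0)

    def test_matches_cumulative_weight_interpolation_oracle(self):
        # 4 instruments engineered so ratio weights are 0.4/0.3/0.2/0.1
        ratios = np.array([1.0, 2.0, 3.0, 4.0])
        weights = np.array([0.4, 0.3, 0.2, 0.1])
        bx = np.ones(4)
        so = 1 / np.sqrt(weights)  # weight = bx^2/so^2
        r = weighted_median(_hset(bx, ratios * bx, so), seed=1)
        cum = np.cumsum(weights) - 0.5 * weights  # 0.2, 0.55, ...
        expected = ratios[0] + (0.5 - cum[0]) / (cum[1] - cum[0]) * (ratios[1] - ratios[0])
        assert r.estimate == pytest.approx(expected, abs=1e-12)

    def test_seed_reproducibility_and_requirement(self, strong_hset):
        with pytest.raises(ValueError):
            weighted_median(strong_hset)
        r1 = weighted_median(strong_hset, n_boot=200, seed=5)
        r2 = weighted_median(strong_hset, n_boot=200, seed=5)
        assert r1.se == r2.se

    def test_more_robust_than_ivw_with_forty_pct_invalid(self, rng):
        # 40% of instruments carry a shared directional pleiotropic effect;
        # the majority-valid weighted median should be less biased than IVW
        bias_ivw, bias_wme = [], []
        for rep in range(60):
            n = 20
            bx = rng.uniform(0.05, 0.3, n)
            alpha = np.zeros(n)
            alpha[: int(0.4 * n)] = 0.05
            so = np.full(n, 0.015)
            by = 0.2 * bx + alpha + so * rng.standard_normal(n)
            h = _hset(bx, by, so, se_exp=1e-6)
            bias_ivw.append(ivw(h)[0].estimate - 0.2)
            bias_wme.append(weighted_median(h, n_boot=100, seed=rep).estimate - 0.2)
        assert abs(np.mean(bias_wme)) < abs(np.mean(bias_ivw))


class TestModeBased:
    def test_point_mass_returns_common_ratio(self):
        bx = np.array([0.1, 0.2, 0.4])
        r = mode_based(_hset(bx, 0.7 * bx, 0.02), seed=3)
        assert r.estimate == pytest.approx(0.7)

    def test_majority_mode_wins_in_bimodal_ratios(self):
        bx = np.ones(9)
        by = np.array([0.0] * 6 + [1.0] * 3) + np.linspace(-0.01, 0.01, 9)
        r = mode_based(_hset(bx, by, 0.05), seed=3)
        assert abs(r.estimate) < 0.2

    def test_matches_density_grid_oracle(self, rng):
        bx = rng.normal(0, 0.2, 8)
        by = rng.normal(0, 0.1, 8)
        so = rng.uniform(0.02, 0.05, 8)
        r = mode_based(_hset(bx, by, so), seed=4, grid_size=512)
        # independent nested-loop kernel density argmax
        ratios = by / bx
        n = len(ratios)
        s = 0.9 * min(np.std(ratios, ddof=1),
                      stats.median_abs_deviation(ratios, scale="normal")) * n**-0.2
        grid = np.linspace(ratios.min() - 3 * s, ratios.max() + 3 * s, 512)
        dens = [sum(np.exp(-0.5 * ((g - t) / s) ** 2) for t in ratios) for g in grid]
        assert r.estimate == pytest.approx(grid[int(np.argmax(dens))], abs=1e-12)

    def test_point_estimate_deterministic_under_reordering_and_seed(self, rng, strong_hset):
        r1 = mode_based(strong_hset, n_boot=100, seed=1)
        r2 = mode_based(strong_hset, n_boot=100, seed=99)
        assert r1.estimate == r2.estimate and r1.se != r2.se
        perm = rng.permutation(len(strong_hset))
        df = strong_hset.df.iloc[perm]
        h = HarmonisedSet.from_arrays(df["beta_exp"], df["se_exp"], df["beta_out"],
                                      df["se_out"])
        assert mode_based(h, n_boot=100, seed=1).estimate == r1.estimate


class TestEgger:
    def test_noiseless_intercept_and_slope_exact(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        by = 0.05 + 0.3 * bx
        r = egger(_hset(bx, by, 0.02))
        assert r.intercept == pytest.approx(0.05, abs=1e-12)
        assert r.slope.estimate == pytest.approx(0.3, abs=1e-12)

    def test_orientation_makes_exposure_effects_positive(self, rng):
        bx = rng.normal(0, 0.2, 10)
        by = 0.02 + 0.3 * bx + rng.normal(0, 0.02, 10)
        r1 = egger(_hset(bx, by, 0.02))
        r2 = egger(_hset(-bx, -by, 0.02))  # same data, alleles re-labelled
        assert r1.slope.estimate == pytest.approx(r2.slope.estimate, abs=1e-12)
        assert r1.intercept == pytest.approx(r2.intercept, abs=1e-12)

    def test_refuses_fewer_than_three_instruments(self):
        with pytest.raises(ValueError):
            egger(_hset([0.1, 0.2], [0.05, 0.1], 0.02))

    def test_intercept_test_calibrated_under_balanced_pleiotropy(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            n = 15
            bx = rng.normal(0, 0.2, n)
            alpha = rng.normal(0, 0.02, n)
            so = np.full(n, 0.02)
            by = 0.1 * bx + alpha + so * rng.standard_normal(n)
            hits += egger(_hset(bx, by, so, se_exp=1e-6)).intercept_pvalue < 0.05
        rate = hits / reps
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / reps) < rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps) + 0.02


class TestLeaveOneOut:
    def test_homogeneous_set_gives_identical_refits(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        res = leave_one_out(_hset(bx, 0.25 * bx, 0.02))
        assert len(res.results) == 4
        np.testing.assert_allclose(res.results["estimate"], res.full.estimate)
        assert res.max_shift == pytest.approx(0.0, abs=1e-12)

    def test_gross_outlier_identified(self, strong_hset):
        df = strong_hset.df.copy()
        df.loc[df.index[5], "beta_out"] += 0.5
        h = HarmonisedSet.from_arrays(df["beta_exp"], df["se_exp"], df["beta_out"],
                                      df["se_out"], variant_ids=df["variant_id"].tolist())
        res = leave_one_out(h)
        assert res.max_shift_variant == df["variant_id"].iloc[5]
        assert len(res.results) == len(df)


class TestEquivariance:
    """Structural symmetries shared by all estimators."""

    @pytest.mark.parametrize("fit", [
        lambda h: ivw(h)[0].estimate,
        lambda h: weighted_median(h, n_boot=100, seed=0).estimate,
        lambda h: mode_based(h, n_boot=100, seed=0).estimate,
        lambda h: egger(h).slope.estimate,
    ], ids=["ivw", "wme", "mbe", "egger"])
    def test_sign_and_scale_equivariance(self, fit, rng):
        bx = rng.normal(0, 0.2, 12)
        by = 0.3 * bx + rng.normal(0, 0.03, 12)
        so = rng.uniform(0.01, 0.04, 12)
        base = fit(_hset(bx, by, so, se_exp=1e-9))
        neg = fit(_hset(bx, -by, so, se_exp=1e-9))
        assert neg == pytest.approx(-base, rel=1e-6, abs=1e-9)
        scaled = fit(_hset(3 * bx, by, so, se_exp=1e-9))
        assert scaled == pytest.approx(base / 3, rel=1e-6, abs=1e-9)
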