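"""Causal estimators against closed-form and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tsmr.estimators import (
    IVW,
    ModeEstimator,
    MultivariableIVW,
    WaldRatio,
    WeightedMedian,
    beta_from_odds_ratio,
    egger,
    ivw,
    mode_estimate,
    mvmr_ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from tsmr.exceptions import ArityError, CollinearityError, DegenerateInstrumentError


def frame(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, float)
    sy = np.full_like(by, 0.02) if sy is None else np.asarray(sy, float)
    return pd.DataFrame({"beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy})


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx, sx, by, sy, want_beta, want_se",
        [
            (0.5, 0.05, 0.1, 0.02, 0.2, 0.04),
            (0.5, 0.05, 0.0, 0.02, 0.0, 0.04),
            (-0.4, 0.05, 0.2, 0.04, -0.5, 0.1),
        ],
    )
    def test_ratio_and_first_order_se(self, bx, sx, by, sy, want_beta, want_se):
        est = wald_ratio(bx, sx, by, sy)
        assert est.beta == pytest.approx(want_beta)
        assert est.se == pytest.approx(want_se)

    def test_null_effect_gives_p_one(self):
        assert wald_ratio(0.5, 0.05, 0.0, 0.02).pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.05, 0.1, 0.02)


class TestIVW:
    def test_single_snp_equals_wald(self):
        h = frame([0.5], [0.1], [0.05], [0.02])
        est = ivw(h, mode="fixed")
        wald = wald_ratio(0.5, 0.05, 0.1, 0.02)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_symmetric_ratios_average(self):
        # three ratios 0.2/0.3/0.4 with equal Wald SE 0.1
        h = frame([1, 1, 1], [0.2, 0.3, 0.4], sy=[0.1, 0.1, 0.1])
        est = ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(math.sqrt(1 / 300))

    def test_matches_wls_through_origin_oracle(self, harmonized_frame):
        est = ivw(harmonized_frame, mode="fixed")
        w = 1 / harmonized_frame["se_out"] ** 2
        oracle = sm.WLS(
            harmonized_frame["beta_out"],
            harmonized_frame[["beta_exp"]],
            weights=w,
        ).fit()
        assert est.beta == pytest.approx(oracle.params.iloc[0], abs=1e-10)
        # fixed-effect SE is the unscaled WLS slope SE
        se_oracle = float(oracle.bse.iloc[0] / np.sqrt(oracle.scale))
        assert est.se == pytest.approx(se_oracle, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(2, 12)
            h = frame(
                rng.normal(0.3, 0.1, j),
                rng.normal(0.05, 0.05, j),
                rng.uniform(0.01, 0.05, j),
                rng.uniform(0.01, 0.05, j),
            )
            assert ivw(h, "random").se >= ivw(h, "fixed").se - 1e-15

    def test_arity(self):
        with pytest.raises(ArityError):
            ivw(frame([0.5], [0.1]), mode="random")


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        h = frame(bx, 0.05 + 0.3 * bx)
        res = egger(h)
        assert res.slope.beta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.05, abs=1e-12)

    def test_zero_intercept_data_matches_ivw_fixed(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = frame(bx, 0.25 * bx)
        res = egger(h)
        assert res.slope.beta == pytest.approx(ivw(h, "fixed").beta, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.intercept_pvalue == pytest.approx(1.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self, harmonized_frame):
        """Slope/intercept/SEs vs a hand-built weighted normal-equations solve."""
        df = harmonized_frame
        sign = np.sign(df["beta_exp"].to_numpy())
        x = df["beta_exp"].to_numpy() * sign
        y = df["beta_out"].to_numpy() * sign
        w = 1 / df["se_out"].to_numpy() ** 2
        X = np.column_stack([np.ones_like(x), x])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * y))
        resid = y - X @ coef
        sigma2 = float(np.sum(w * resid**2) / (len(x) - 2))
        cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
        res = egger(df)
        assert res.intercept == pytest.approx(coef[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(coef[1], abs=1e-10)
        assert res.intercept_se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)
        assert res.slope.se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)

    def test_orientation_makes_result_sign_invariant(self, harmonized_frame):
        flipped = harmonized_frame.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        base, alt = egger(harmonized_frame), egger(flipped)
        assert base.slope.beta == pytest.approx(alt.slope.beta)
        assert base.intercept == pytest.approx(alt.intercept)

    def test_arity(self):
        with pytest.raises(ArityError):
            egger(frame([0.1, 0.2], [0.02, 0.05]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        h = frame([1, 1, 1], [0.1, 0.2, 0.9], sy=[0.1, 0.1, 0.1])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.2)

    def test_identical_ratios_shrinking_se(self):
        h = frame([1, 1, 1], [0.4, 0.4, 0.4], sy=[1e-6, 1e-6, 1e-6],
                  sx=[1e-6, 1e-6, 1e-6])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.4)
        assert est.se < 1e-5

    def test_matches_weighted_cdf_oracle(self):
        """Interpolated estimate vs brute-force scan of the weighted CDF."""
        # Wald SEs chosen so normalized weights are exactly {0.7, 0.2, 0.1}
        weights = np.array([0.7, 0.2, 0.1])
        ratios = np.array([0.1, 0.5, 0.9])
        se_wald = 1 / np.sqrt(weights)
        h = frame(np.ones(3), ratios, sy=se_wald)

        grid = np.linspace(0.0, 1.0, 2_000_001)
        order = np.argsort(ratios)
        cum = np.cumsum(weights[order]) - weights[order] / 2
        cdf = np.interp(grid, ratios[order], cum)
        oracle = grid[np.searchsorted(cdf, 0.5)]

        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(oracle, abs=1e-6)
        # hand value: 0.1 + (0.5-0.1) * (0.5-0.35)/(0.80-0.35)
        assert est.beta == pytest.approx(0.1 + 0.4 * 0.15 / 0.45, abs=1e-12)

    def test_bootstrap_seed_reproducible(self, harmonized_frame):
        a = weighted_median(harmonized_frame, n_boot=300, seed=5)
        b = weighted_median(harmonized_frame, n_boot=300, seed=5)
        assert a == b

    def test_seed_mandatory(self, harmonized_frame):
        with pytest.raises(ValueError, match="random_state"):
            WeightedMedian(n_boot=100).fit(harmonized_frame)


class TestModeEstimator:
    def test_robust_to_single_outlier(self):
        h = frame([1, 1, 1, 1], [0.30, 0.31, 0.29, 1.5], sy=np.full(4, 0.05))
        est = mode_estimate(h, weighted=False, n_boot=100, seed=0)
        assert abs(est.beta - 0.30) < 0.05

    def test_degenerate_identical_ratios(self):
        h = frame([1, 1, 1], [0.4, 0.4, 0.4])
        est = mode_estimate(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.4)
        assert est.se == 0.0

    def test_matches_dense_grid_density_oracle(self):
        """512-grid argmax within one grid step of a 1e5-point brute force."""
        rng = np.random.default_rng(21)
        j = 8
        ratios = rng.normal(0.3, 0.1, j)
        h = frame(np.ones(j), ratios, sy=rng.uniform(0.05, 0.2, j))
        est = ModeEstimator(weighted=True, n_boot=100, random_state=0).fit(h)

        w = 1 / (h["se_out"].to_numpy() / np.abs(h["beta_exp"].to_numpy())) ** 2
        w = w / w.sum()
        bw = est.bandwidth_
        dense = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 100_000)
        dens = np.exp(-0.5 * ((dense[:, None] - ratios) / bw) ** 2) @ w
        oracle = dense[np.argmax(dens)]
        step = (dense[-1] - dense[0]) / 511  # implementation grid spacing
        assert abs(est.beta_ - oracle) <= step

    def test_weighted_vs_simple_method_labels(self, harmonized_frame):
        wm = mode_estimate(harmonized_frame, weighted=True, n_boot=50, seed=1)
        sm_ = mode_estimate(harmonized_frame, weighted=False, n_boot=50, seed=1)
        assert wm.method == "weighted_mode"
        assert sm_.method == "simple_mode"


class TestMultivariableIVW:
    def test_zero_mediator_column_reduces_to_univariable(self, harmonized_frame):
        df = harmonized_frame.copy()
        df["beta_med"] = 0.0
        df["se_med"] = 0.01
        exp_est, med_est = mvmr_ivw(df)
        assert exp_est.beta == pytest.approx(ivw(df, "fixed").beta, abs=1e-10)
        assert med_est.beta == 0.0

    def test_noise_free_plane_recovered(self):
        rng = np.random.default_rng(3)
        bx = rng.normal(0.3, 0.1, 6)
        bm = rng.normal(0.5, 0.2, 6)
        df = pd.DataFrame(
            {
                "beta_exp": bx, "se_exp": 0.01,
                "beta_med": bm, "se_med": 0.01,
                "beta_out": 0.2 * bx + 0.1 * bm, "se_out": 0.02,
            }
        )
        exp_est, med_est = mvmr_ivw(df)
        assert exp_est.beta == pytest.approx(0.2, abs=1e-10)
        assert med_est.beta == pytest.approx(0.1, abs=1e-10)

    def test_matches_normal_equations_oracle(self, mvmr_frame):
        df = mvmr_frame
        X = df[["beta_exp", "beta_med"]].to_numpy()
        y = df["beta_out"].to_numpy()
        w = 1 / df["se_out"].to_numpy() ** 2
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * y))
        resid = y - X @ coef
        sigma2 = float(np.sum(w * resid**2) / (len(y) - 2))
        cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
        exp_est, med_est = mvmr_ivw(df)
        assert exp_est.beta == pytest.approx(coef[0], abs=1e-10)
        assert med_est.beta == pytest.approx(coef[1], abs=1e-10)
        assert exp_est.se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)
        assert med_est.se == pytest.approx(math.sqrt(cov[1, 1]), abs=1e-10)

    def test_collinear_columns_rejected(self):
        df = pd.DataFrame(
            {
                "beta_exp": [0.1, 0.2, 0.3, 0.4],
                "se_exp": 0.01,
                "beta_med": [0.2, 0.4, 0.6, 0.8],  # exact multiple
                "se_med": 0.01,
                "beta_out": [0.1, 0.2, 0.25, 0.3],
                "se_out": 0.02,
            }
        )
        with pytest.raises(CollinearityError):
            mvmr_ivw(df)


class TestOddsRatio:
    def test_published_style_ci(self):
        # log-odds 0.0971 with se 0.0439 maps to OR 1.102 (1.011-1.201)
        or_value, lo, hi = to_odds_ratio(0.0971, 0.0439)
        assert or_value == pytest.approx(1.102, abs=5e-4)
        assert lo == pytest.approx(1.011, abs=5e-4)
        assert hi == pytest.approx(1.201, abs=5e-4)

    def test_null_beta_symmetric_about_one(self):
        or_value, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_value == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_roundtrip_identity(self):
        for b in (-1.2, 0.0, 0.33):
            assert beta_from_odds_ratio(to_odds_ratio(b, 0.1)[0]) == pytest.approx(b)


class TestEstimatorProperties:
    def test_sign_equivariance_all_estimators(self, harmonized_frame):
        """Relabeling every exposure effect allele leaves estimates unchanged."""
        flipped = harmonized_frame.copy()
        flipped["beta_exp"] *= -1
        flipped["beta_out"] *= -1
        assert ivw(harmonized_frame).beta == pytest.approx(ivw(flipped).beta)
        assert weighted_median(harmonized_frame, 200, seed=2).beta == pytest.approx(
            weighted_median(flipped, 200, seed=2).beta
        )
        assert mode_estimate(harmonized_frame, n_boot=50, seed=2).beta == pytest.approx(
            mode_estimate(flipped, n_boot=50, seed=2).beta
        )

    def test_consistency_as_ses_shrink(self):
        """All five estimators converge to theta with tiny instrument SEs."""
        rng = np.random.default_rng(17)
        theta = 0.25
        j = 30
        gamma = rng.normal(0.3, 0.05, j)
        se = 1e-4
        h = frame(
            rng.normal(gamma, se),
            rng.normal(theta * gamma, se),
            np.full(j, se),
            np.full(j, se),
        )
        estimates = [
            ivw(h, "fixed").beta,
            ivw(h, "random").beta,
            egger(h).slope.beta,
            weighted_median(h, 200, seed=3).beta,
            mode_estimate(h, weighted=True, n_boot=100, seed=3).beta,
        ]
        for value in estimates:
            assert value == pytest.approx(theta, abs=1e-3)

    def test_sklearn_params_roundtrip(self):
        est = IVW(mode="fixed")
        assert est.get_params() == {"mode": "fixed"}
        est.set_params(mode="random")
        assert est.mode == "random"
        clone_params = WeightedMedian(n_boot=77, random_state=1).get_params()
        assert clone_params == {"n_boot": 77, "random_state": 1}

    def test_fitted_attributes(self, harmonized_frame):
        model = IVW().fit(harmonized_frame)
        assert model.n_snp_ == len(harmonized_frame)
        assert model.ci_[0] < model.or_ < model.ci_[1]
        assert 0 < model.pvalue_ <= 1
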