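"""MR estimators against direct-formula and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from gutmr.estimators import (
    EggerRegression,
    IVW,
    WeightedMedian,
    WeightedMode,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from gutmr.exceptions import (
    CollinearityError,
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from gutmr.io import harmonize
from gutmr.simulate import SimulationConfig, simulate_summary_pair

from conftest import make_instruments


def wls_origin_oracle(bx, by, sy):
    """Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out^2 — the IVW equivalence oracle."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
    se = np.sqrt(1.0 / np.sum(w * bx * bx))
    return slope, se


def egger_normal_equations_oracle(bx, by, sy):
    """Closed-form weighted normal equations for slope+intercept, with the
    multiplicative overdispersion scale floored at 1."""
    sign = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    x, y = np.asarray(bx) * sign, np.asarray(by) * sign
    w = 1.0 / np.asarray(sy) ** 2
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    inter = (swy - slope * swx) / sw
    rss = np.sum(w * (y - inter - slope * x) ** 2)
    scale = max(1.0, rss / (len(x) - 2))
    slope_se = np.sqrt(sw / det * scale)
    inter_se = np.sqrt(swxx / det * scale)
    return slope, slope_se, inter, inter_se


def weighted_median_oracle(ratios, weights):
    """Direct implementation of the cumulative-midpoint interpolation."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r))


class TestWaldRatio:
    def test_direct_arithmetic(self):
        insts = pd.DataFrame({"snp_id": ["rs1"], "beta_exp": [0.5], "se_exp": [0.05],
                              "beta_out": [0.2], "se_out": [0.1]})
        est = wald_ratio(insts)
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome_gives_or_one(self):
        insts = pd.DataFrame({"beta_exp": [0.5], "se_exp": [0.05],
                              "beta_out": [0.0], "se_out": [0.1]})
        est = wald_ratio(insts)
        assert est.beta == 0.0 and est.or_ == pytest.approx(1.0)

    def test_sign_cancellation(self):
        a = pd.DataFrame({"beta_exp": [0.5], "se_exp": [0.05],
                          "beta_out": [0.2], "se_out": [0.1]})
        b = a.copy()
        b["beta_exp"], b["beta_out"] = -a["beta_exp"], -a["beta_out"]
        assert wald_ratio(a).beta == pytest.approx(wald_ratio(b).beta)

    def test_zero_exposure_beta_raises(self):
        insts = pd.DataFrame({"beta_exp": [0.0], "se_exp": [0.05],
                              "beta_out": [0.2], "se_out": [0.1]})
        with pytest.raises(UndefinedRatioError):
            wald_ratio(insts)


class TestIVW:
    def test_homogeneous_ratios_fixed_equals_random(self):
        insts = make_instruments([0.4, 0.4], [0.1, 0.2])
        fixed, random = ivw(insts, "fixed"), ivw(insts, "random")
        assert fixed.beta == pytest.approx(0.4)
        assert fixed.se == pytest.approx(random.se)  # Q = 0 => no inflation

    def test_three_instrument_direct_formula(self):
        insts = make_instruments([0.2, 0.4, 0.6], [0.1, 0.1, 0.1])
        est = ivw(insts, "fixed")
        assert est.beta == pytest.approx(0.4, rel=1e-12)
        assert est.se == pytest.approx(0.1 / np.sqrt(3), rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equals_wls_through_origin(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        insts = pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)],
            "beta_exp": rng.uniform(0.05, 0.4, n) * rng.choice([-1, 1], n),
            "se_exp": rng.uniform(0.01, 0.05, n),
            "beta_out": rng.normal(0, 0.2, n),
            "se_out": rng.uniform(0.05, 0.2, n),
        })
        est = ivw(insts, "fixed")
        slope, se = wls_origin_oracle(insts["beta_exp"], insts["beta_out"], insts["se_out"])
        assert est.beta == pytest.approx(slope, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_two_identical_ratio_instruments_equal_wald(self):
        insts = make_instruments([0.4, 0.4], [0.1, 0.1])
        assert ivw(insts).beta == pytest.approx(wald_ratio(insts.iloc[:1]).beta)

    def test_random_se_never_below_fixed(self):
        insts = make_instruments([0.1, 0.9, 0.5], [0.1, 0.1, 0.1])
        assert ivw(insts, "random").se >= ivw(insts, "fixed").se

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_instruments([0.4], [0.1]))


class TestEgger:
    def test_perfect_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        insts = pd.DataFrame({"beta_exp": bx, "se_exp": 0.02,
                              "beta_out": 0.1 + 0.4 * bx,
                              "se_out": [0.05, 0.08, 0.06, 0.07]})
        fit = mr_egger(insts)
        assert fit.slope.beta == pytest.approx(0.4, abs=1e-10)
        assert fit.intercept == pytest.approx(0.1, abs=1e-10)

    def test_four_point_fixture_matches_normal_equations(self):
        insts = pd.DataFrame({"beta_exp": [0.15, -0.2, 0.3, 0.25],
                              "se_exp": [0.02, 0.03, 0.02, 0.04],
                              "beta_out": [0.07, -0.02, 0.12, 0.05],
                              "se_out": [0.05, 0.08, 0.06, 0.07]})
        fit = mr_egger(insts)
        slope, slope_se, inter, inter_se = egger_normal_equations_oracle(
            insts["beta_exp"], insts["beta_out"], insts["se_out"])
        assert fit.slope.beta == pytest.approx(slope, rel=1e-10)
        assert fit.slope.se == pytest.approx(slope_se, rel=1e-10)
        assert fit.intercept == pytest.approx(inter, rel=1e-10)
        assert fit.intercept_se == pytest.approx(inter_se, rel=1e-10)

    def test_orientation_invariance(self):
        # negating an instrument's exposure AND outcome beta is a relabeling
        insts = pd.DataFrame({"beta_exp": [0.15, 0.2, 0.3, 0.25],
                              "se_exp": 0.02,
                              "beta_out": [0.07, 0.02, 0.12, 0.05],
                              "se_out": [0.05, 0.08, 0.06, 0.07]})
        flipped = insts.copy()
        flipped.loc[1, ["beta_exp", "beta_out"]] *= -1
        a, b = mr_egger(insts), mr_egger(flipped)
        assert a.slope.beta == pytest.approx(b.slope.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self):
        insts = make_instruments([0.2, 0.5, 0.3, 0.6], [0.1, 0.15, 0.12, 0.2])
        slope, se = wls_origin_oracle(insts["beta_exp"], insts["beta_out"], insts["se_out"])
        est = ivw(insts, "fixed")
        assert est.beta == pytest.approx(slope, rel=1e-12)
        assert est.se == pytest.approx(se, rel=1e-12)

    def test_collinear_exposure_raises(self):
        insts = pd.DataFrame({"beta_exp": [0.2, 0.2, -0.2], "se_exp": 0.02,
                              "beta_out": [0.1, 0.2, 0.1], "se_out": 0.05})
        with pytest.raises(CollinearityError):
            mr_egger(insts)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_instruments([0.4, 0.5], [0.1, 0.1]))

    def test_less_biased_than_ivw_under_directional_pleiotropy(self):
        # InSIDE holds: pleiotropic offsets independent of instrument strength
        theta, reps = 0.3, 300
        ivw_err, egger_err = [], []
        for r in range(reps):
            cfg = SimulationConfig(n_snp=100, theta=theta,
                                   pleiotropy_mode="directional",
                                   alpha_mean=0.04, alpha_sd=0.02,
                                   gamma_range=(0.1, 0.3),
                                   se_exp_range=(0.015, 0.025), seed=r)
            e, o, _ = simulate_summary_pair(cfg)
            insts = harmonize(e, o)
            ivw_err.append(ivw(insts, "fixed").beta - theta)
            egger_err.append(mr_egger(insts).slope.beta - theta)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))


class TestWeightedMedian:
    def test_equal_weights_symmetric_positions(self):
        insts = make_instruments([0.1, 0.4, 0.9], [0.1, 0.1, 0.1])
        assert weighted_median(insts, n_boot=100, seed=0).beta == pytest.approx(0.4)

    def test_dominant_weight_instrument_wins(self):
        insts = make_instruments([0.1, 0.7, 0.9], [10.0, 0.001, 10.0])
        est = weighted_median(insts, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.7, abs=1e-3)

    def test_unequal_weight_fixture_matches_direct_formula(self):
        ratios, ses = [0.1, 0.25, 0.4, 0.8], [0.05, 0.2, 0.1, 0.3]
        insts = make_instruments(ratios, ses)
        est = weighted_median(insts, n_boot=100, seed=0)
        oracle = weighted_median_oracle(ratios, 1.0 / np.asarray(ses) ** 2)
        assert est.beta == pytest.approx(oracle, rel=1e-10)

    def test_bootstrap_se_reproducible(self):
        insts = make_instruments([0.1, 0.25, 0.4, 0.8], [0.05, 0.2, 0.1, 0.3])
        a = weighted_median(insts, n_boot=200, seed=7)
        b = weighted_median(insts, n_boot=200, seed=7)
        assert a.se == b.se

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_instruments([0.4, 0.5], [0.1, 0.1]))


class TestWeightedMode:
    def test_point_mass(self):
        insts = make_instruments([0.4, 0.4, 0.4, 0.4], [0.1, 0.1, 0.1, 0.1])
        assert weighted_mode(insts, n_boot=100, seed=0).beta == pytest.approx(0.4)

    def test_outlier_does_not_pull_mode_from_cluster(self):
        insts = make_instruments([0.39, 0.40, 0.41, 2.0],
                                 [0.02, 0.02, 0.02, 1.0])
        est = weighted_mode(insts, n_boot=100, seed=0)
        assert 0.35 < est.beta < 0.45

    def test_matches_fine_grid_oracle(self):
        ratios = np.array([0.39, 0.40, 0.41, 2.0])
        ses = np.array([0.02, 0.02, 0.02, 1.0])
        insts = make_instruments(ratios, ses)
        w = 1.0 / ses ** 2
        n = len(ratios)
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.34) * n ** (-0.2)
        grid = np.arange(ratios.min(), ratios.max() + 1e-4, 1e-4)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(1)
        oracle = grid[np.argmax(dens)]
        est = weighted_mode(insts, n_boot=100, seed=0)
        assert est.beta == pytest.approx(oracle, abs=2e-4)

    def test_phi_change_stays_finite(self):
        insts = make_instruments([0.1, 0.3, 0.5, 0.9], [0.1, 0.1, 0.1, 0.1])
        for phi in (0.5, 1.0, 2.0):
            est = weighted_mode(insts, phi=phi, n_boot=100, seed=0)
            assert np.isfinite(est.beta) and np.isfinite(est.se)
            assert insts["ratio"].min() <= est.beta <= insts["ratio"].max()

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_mode(make_instruments([0.4, 0.5], [0.1, 0.1]))


class TestEquivariance:
    @pytest.fixture
    def insts(self, clean_instruments):
        return clean_instruments[0]

    def test_sign_equivariance_point_estimates(self, insts):
        neg = insts.copy()
        neg["beta_out"] = -neg["beta_out"]
        neg["ratio"] = -neg["ratio"]
        for fit in (lambda d: ivw(d, "fixed"), lambda d: ivw(d, "random"),
                    lambda d: mr_egger(d).slope,
                    lambda d: weighted_median(d, n_boot=100, seed=3),
                    lambda d: weighted_mode(d, n_boot=100, seed=3)):
            a, b = fit(insts), fit(neg)
            assert b.beta == pytest.approx(-a.beta, rel=1e-6, abs=1e-9)

    def test_sign_equivariance_analytic_ses(self, insts):
        neg = insts.copy()
        neg["beta_out"] = -neg["beta_out"]
        neg["ratio"] = -neg["ratio"]
        assert ivw(neg, "random").se == pytest.approx(ivw(insts, "random").se, rel=1e-12)
        assert mr_egger(neg).slope.se == pytest.approx(mr_egger(insts).slope.se, rel=1e-12)

    def test_scale_equivariance(self, insts):
        c = 3.0
        scaled = insts.copy()
        scaled["beta_exp"] *= c
        scaled["se_exp"] *= c
        scaled["ratio"] /= c
        scaled["ratio_se"] /= c
        for fit in (lambda d: ivw(d, "fixed"),
                    lambda d: mr_egger(d).slope,
                    lambda d: weighted_median(d, n_boot=100, seed=3),
                    lambda d: weighted_mode(d, n_boot=100, seed=3)):
            a, b = fit(insts), fit(scaled)
            assert b.beta == pytest.approx(a.beta / c, rel=1e-6)
            assert b.se == pytest.approx(a.se / c, rel=1e-6)


def test_estimator_params_roundtrip_sklearn_style():
    est = WeightedMode(phi=2.0, n_boot=50, seed=9)
    params = est.get_params()
    assert params["phi"] == 2.0
    clone = WeightedMode(**params)
    assert clone.get_params() == params
    est.set_params(phi=1.5)
    assert est.phi == 1.5
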