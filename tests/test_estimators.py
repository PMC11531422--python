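"""Causal-effect estimators: oracles, invariances and recovery behavior."""

import numpy as np
import pandas as pd
import pytest

from mrkit.estimators import (EstimatorConfig, EggerEstimator, IVWEstimator,
                              MRConfigError, MRInputError, MRLassoEstimator,
                              MRPressoEstimator, MRRapsEstimator,
                              WeightedMedianEstimator, WeightedModeEstimator,
                              ivw, run_battery, wald_ratio,
                              weighted_median_point, weighted_mode_point,
                              _ratio_weights, results_frame)
from mrkit.simulate import SimConfig, simulate_two_sample
from mrkit.sumstats import harmonize, usable_frame


def _frame(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(len(bx))],
        "BETA_EXP": bx,
        "SE_EXP": np.full(len(bx), 0.01) if sx is None else np.asarray(sx),
        "BETA_OUT": np.asarray(by, float),
        "SE_OUT": np.asarray(sy, float),
    })


def _sim_table(**kw):
    exposure, outcome, truth = simulate_two_sample(SimConfig(**kw))
    return usable_frame(harmonize(exposure, outcome)), truth


class TestWaldRatio:
    @pytest.mark.parametrize("args, expected", [
        ((0.1, 0.01, 0.05, 0.02), (0.5, 0.2)),
        ((0.1, 0.01, 0.0, 0.02), (0.0, 0.2)),
        ((-0.1, 0.01, -0.05, 0.02), (0.5, 0.2)),
    ])
    def test_values(self, args, expected):
        est, se = wald_ratio(*args)
        assert est == pytest.approx(expected[0])
        assert se == pytest.approx(expected[1])

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(MRInputError, match="exclude"):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_two_row_oracle(self, two_row_frame):
        # weighted-mean and residual oracle computed independently:
        # w = (0.04/0.0025, 0.01/0.0009), ratios (0.5, 0.6)
        est = IVWEstimator(re_mode="fixed").fit(two_row_frame)
        assert est.estimate_ == pytest.approx(0.5409836065573771, rel=1e-12)
        assert est.se_ == pytest.approx(0.19205531989934393, rel=1e-12)
        assert est.extras_["Q"] == pytest.approx(0.06557377049180, rel=1e-10)

    def test_random_effects_floor_at_one(self, two_row_frame):
        fe = IVWEstimator(re_mode="fixed").fit(two_row_frame)
        re = IVWEstimator(re_mode="multiplicative_random").fit(two_row_frame)
        # Q/(J-1) = 0.0656 < 1, so the multiplicative scale floors at 1
        assert re.se_ == pytest.approx(fe.se_)
        assert re.extras_["re_scale"] == 1.0

    def test_identical_ratios_zero_q(self):
        tab = _frame([0.1, 0.2, 0.4], [0.05, 0.1, 0.2], [0.02, 0.03, 0.05])
        est = IVWEstimator().fit(tab)
        assert est.estimate_ == pytest.approx(0.5)
        assert est.extras_["Q"] == pytest.approx(0.0, abs=1e-20)
        assert est.extras_["I2"] == 0.0

    def test_duplicating_rows_halves_variance(self, two_row_frame):
        single = IVWEstimator(re_mode="fixed").fit(two_row_frame)
        doubled = IVWEstimator(re_mode="fixed").fit(
            pd.concat([two_row_frame.assign(SNP=["a", "b"]),
                       two_row_frame.assign(SNP=["c", "d"])],
                      ignore_index=True))
        assert doubled.estimate_ == pytest.approx(single.estimate_)
        assert doubled.se_ == pytest.approx(single.se_ / np.sqrt(2))

    def test_single_variant_rejected(self):
        with pytest.raises(MRInputError, match="wald_ratio"):
            IVWEstimator().fit(_frame([0.1], [0.05], [0.02]))

    def test_or_fields_exponentiate(self, two_row_frame):
        res = ivw(two_row_frame, EstimatorConfig(outcome_scale="lnor"))
        assert res.or_estimate == pytest.approx(np.exp(res.estimate))
        assert res.or_ci_low == pytest.approx(np.exp(res.ci_low))


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.1 + 0.5 * bx
        est = EggerEstimator().fit(_frame(bx, by, [0.02, 0.03, 0.04]))
        assert est.estimate_ == pytest.approx(0.5, rel=1e-9)
        assert est.extras_["intercept"] == pytest.approx(0.1, rel=1e-9)

    def test_zero_intercept_equal_weights_matches_ivw(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.7 * bx
        tab = _frame(bx, by, np.full(4, 0.02))
        eg = EggerEstimator().fit(tab)
        fe = IVWEstimator(re_mode="fixed").fit(tab)
        assert eg.estimate_ == pytest.approx(fe.estimate_, rel=1e-9)
        assert eg.extras_["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_exposure_rows_reoriented(self):
        bx = np.array([0.1, 0.2, 0.3, 0.15])
        by = 0.02 + 0.5 * bx
        sy = np.array([0.02, 0.03, 0.04, 0.025])
        base = EggerEstimator().fit(_frame(bx, by, sy))
        flip = np.array([1, -1, 1, -1.0])
        flipped = EggerEstimator().fit(_frame(bx * flip, by * flip, sy))
        assert flipped.estimate_ == pytest.approx(base.estimate_, rel=1e-9)
        assert flipped.extras_["intercept"] == pytest.approx(
            base.extras_["intercept"], rel=1e-9)

    def test_directional_pleiotropy_intercept_recovery(self):
        """Mean intercept over 200 replicates recovers the pleiotropy mean."""
        intercepts = []
        for s in range(200):
            tab, _ = _sim_table(seed=900 + s, theta=0.3, n_snps=50,
                                total_r2=0.05, pleiotropy_mode="directional",
                                mu_pleio=0.02, tau2=1e-4, prop_invalid=1.0)
            intercepts.append(EggerEstimator().fit(tab).extras_["intercept"])
        intercepts = np.array(intercepts)
        mc_se = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean() - 0.02) < 3 * mc_se


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        assert weighted_median_point(np.array([0.4, 0.5, 0.6]),
                                     np.ones(3)) == pytest.approx(0.5)

    def test_cumulative_weight_interpolation_oracle(self):
        # hand-worked: sorted midpoint positions 0.125/0.375/0.625/0.875;
        # 0.5 interpolates between two ratios both equal to 0.5
        assert weighted_median_point(np.array([0.5, 0.5, 0.5, 5.0]),
                                     np.ones(4)) == pytest.approx(0.5)

    def test_degenerate_weight_returns_that_ratio(self):
        r = np.array([0.1, 0.9, 0.4])
        w = np.array([1e-12, 1e-12, 1.0])
        assert weighted_median_point(r, w) == pytest.approx(0.4)

    def test_equal_weights_match_interpolated_median(self):
        rng = np.random.default_rng(5)
        for n in (4, 7, 10):
            r = rng.normal(size=n)
            expected = np.quantile(r, 0.5, method="midpoint") if n % 2 == 0 \
                else np.median(r)
            assert weighted_median_point(r, np.ones(n)) == pytest.approx(
                expected)

    def test_bootstrap_se_deterministic_under_seed(self, clean_sim_table):
        tab, _ = clean_sim_table
        a = WeightedMedianEstimator(bootstrap_reps=200, seed=42).fit(tab)
        b = WeightedMedianEstimator(bootstrap_reps=200, seed=42).fit(tab)
        assert a.se_ == b.se_
        assert a.se_ > 0


class TestWeightedMode:
    def test_dominant_cluster(self):
        r = np.array([0.5, 0.5, 0.5, 2.0])
        assert weighted_mode_point(r, np.ones(4)) == pytest.approx(0.5,
                                                                   abs=0.01)

    def test_all_identical_exact(self):
        r = np.full(5, 0.7)
        assert weighted_mode_point(r, np.ones(5)) == pytest.approx(0.7)

    def test_kde_argmax_oracle(self):
        """Matches an independent weighted-KDE argmax on the same grid."""
        rng = np.random.default_rng(8)
        r = np.concatenate([rng.normal(0.3, 0.02, 20),
                            rng.normal(1.0, 0.05, 10)])
        w = np.ones(30)
        est = weighted_mode_point(r, w, bandwidth_factor=1.0)
        # independent oracle: same bandwidth rule, brute-force dense grid
        sd = r.std(ddof=1)
        mad = np.median(np.abs(r - np.median(r))) / 0.6745
        h = 0.9 * min(sd, mad) * 30 ** (-0.2)
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 20001)
        dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(1)
        oracle = grid[np.argmax(dens)]
        assert est == pytest.approx(oracle, abs=1e-3)
        assert abs(est - 0.3) < 0.05

    def test_duplication_near_invariance(self):
        rng = np.random.default_rng(9)
        r = rng.normal(0.4, 0.05, 25)
        w = rng.uniform(0.5, 2.0, 25)
        once = weighted_mode_point(r, w)
        twice = weighted_mode_point(np.tile(r, 2), np.tile(w, 2))
        # bandwidth shrinks by 2^(-1/5) on duplication; the argmax of a
        # single-cluster density moves only marginally
        assert twice == pytest.approx(once, abs=0.01)


class TestMRLasso:
    def test_clean_data_retains_all(self):
        bx = np.linspace(0.05, 0.4, 8)
        by = 0.5 * bx
        sy = np.full(8, 0.02)
        est = MRLassoEstimator().fit(_frame(bx, by, sy))
        fe = IVWEstimator(re_mode="fixed").fit(_frame(bx, by, sy))
        assert est.extras_["n_retained"] == 8
        assert est.estimate_ == pytest.approx(fe.estimate_, rel=1e-9)

    def test_gross_outlier_excluded(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.05, 0.4, 20)
        sy = np.full(20, 0.02)
        by = 0.5 * bx + rng.normal(0, 0.002, 20)
        by[7] += 20 * sy[7]
        est = MRLassoEstimator().fit(_frame(bx, by, sy))
        assert "rs7" in est.extras_["removed"]
        keep = np.ones(20, bool)
        keep[7] = False
        pruned = IVWEstimator(re_mode="fixed").fit(
            _frame(bx[keep], by[keep], sy[keep]))
        assert est.estimate_ == pytest.approx(pruned.estimate_, rel=1e-9)

    def test_too_few_retained_reports_path(self):
        with pytest.raises(MRInputError):
            MRLassoEstimator().fit(_frame([0.1, 0.2], [0.05, 0.1],
                                          [0.02, 0.02]))


class TestMRRaps:
    def test_reduces_to_ivw_when_exposure_error_vanishes(self):
        bx = np.array([0.1, 0.25, 0.3, 0.15, 0.4])
        by = 0.6 * bx + np.array([0.01, -0.005, 0.003, -0.002, 0.006])
        sy = np.array([0.02, 0.025, 0.03, 0.02, 0.04])
        tab = _frame(bx, by, sy, sx=np.full(5, 1e-9))
        raps = MRRapsEstimator(overdispersion=False).fit(tab)
        fe = IVWEstimator(re_mode="fixed").fit(tab)
        assert raps.estimate_ == pytest.approx(fe.estimate_, rel=1e-6)

    def test_valid_instruments_match_ivw_on_average(self):
        diffs = []
        for s in range(200):
            tab, _ = _sim_table(seed=1500 + s, theta=0.4, n_snps=50,
                                total_r2=0.05)
            raps = MRRapsEstimator().fit(tab)
            fe = IVWEstimator(re_mode="fixed").fit(tab)
            diffs.append(raps.estimate_ - fe.estimate_)
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * max(diffs.std(ddof=1), 1e-6) / np.sqrt(200)

    def test_overdispersion_recovery(self):
        """tau^2 = 0.001 injected as balanced pleiotropy at 300 instruments."""
        tau2s = []
        for s in range(200):
            tab, _ = _sim_table(seed=1700 + s, theta=0.3, n_snps=300,
                                total_r2=0.15, pleiotropy_mode="balanced",
                                tau2=0.001, prop_invalid=1.0)
            tau2s.append(MRRapsEstimator().fit(tab).extras_["tau2"])
        tau2s = np.array(tau2s)
        mc_se = tau2s.std(ddof=1) / np.sqrt(len(tau2s))
        assert abs(tau2s.mean() - 0.001) < 3 * mc_se


class TestMRPresso:
    def test_outlier_correction_equals_pruned_ivw(self):
        tab, _ = _sim_table(seed=33, theta=0.5, n_snps=50, total_r2=0.05)
        tab = tab.copy()
        j = int((tab["BETA_EXP"] ** 2 / tab["SE_OUT"] ** 2).idxmax())
        tab.loc[j, "BETA_OUT"] += 10 * tab.loc[j, "SE_OUT"]
        # n_sims must satisfy J/(n_sims+1) < alpha for the Bonferroni
        # outlier p to be attainable at all
        est = MRPressoEstimator(n_sims=1000, seed=1).fit(tab)
        assert tab.loc[j, "SNP"] in est.extras_["outliers"]
        pruned = IVWEstimator().fit(tab.drop(index=j))
        assert est.estimate_ == pytest.approx(pruned.estimate_, rel=1e-12)
        assert est.extras_["distortion_p"] <= 1.0

    def test_clean_data_keeps_raw_ivw(self):
        tab, _ = _sim_table(seed=34, theta=0.5, n_snps=40, total_r2=0.05)
        est = MRPressoEstimator(n_sims=500, seed=2).fit(tab)
        raw = IVWEstimator().fit(tab)
        if est.extras_["n_outliers"] == 0:
            assert est.estimate_ == pytest.approx(raw.estimate_)
        assert 0 < est.extras_["global_p"] <= 1

    def test_minimum_variant_count(self):
        with pytest.raises(MRInputError):
            MRPressoEstimator(seed=0).fit(
                _frame([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.02] * 3))


class TestInvariances:
    @pytest.mark.parametrize("make", [
        lambda: IVWEstimator(),
        lambda: EggerEstimator(),
        lambda: WeightedMedianEstimator(bootstrap_reps=50, seed=3),
        lambda: WeightedModeEstimator(bootstrap_reps=50, seed=3),
        lambda: MRLassoEstimator(),
        lambda: MRRapsEstimator(),
    ])
    def test_outcome_scale_equivariance(self, make, clean_sim_table):
        """Scaling all outcome betas and SEs by c scales estimate and SE by c."""
        tab, _ = clean_sim_table
        c = 2.5
        scaled = tab.assign(BETA_OUT=tab["BETA_OUT"] * c,
                            SE_OUT=tab["SE_OUT"] * c)
        a = make().fit(tab)
        b = make().fit(scaled)
        assert b.estimate_ == pytest.approx(c * a.estimate_, rel=1e-6)
        assert b.se_ == pytest.approx(c * a.se_, rel=1e-5)

    @pytest.mark.parametrize("make", [
        lambda: IVWEstimator(),
        lambda: EggerEstimator(),
        lambda: MRRapsEstimator(),
        lambda: MRLassoEstimator(),
    ])
    def test_allele_reorientation_invariance(self, make, clean_sim_table):
        """Flipping (beta_exp, beta_out) signs on any subset changes nothing."""
        tab, _ = clean_sim_table
        rng = np.random.default_rng(0)
        flip = np.where(rng.random(len(tab)) < 0.5, -1.0, 1.0)
        flipped = tab.assign(BETA_EXP=tab["BETA_EXP"] * flip,
                             BETA_OUT=tab["BETA_OUT"] * flip)
        a = make().fit(tab)
        b = make().fit(flipped)
        assert b.estimate_ == pytest.approx(a.estimate_, rel=1e-8)

    def test_ci_brackets_estimate(self, clean_sim_table):
        tab, _ = clean_sim_table
        for res in run_battery(tab, EstimatorConfig(seed=0, bootstrap_reps=50,
                                                    presso_sims=200)):
            assert res.ci_low <= res.estimate <= res.ci_high


class TestBattery:
    def test_requested_methods_in_order(self, clean_sim_table):
        tab, _ = clean_sim_table
        res = run_battery(tab, EstimatorConfig(seed=1), ["ivw", "egger"])
        assert [r.method for r in res] == ["ivw", "egger"]

    def test_repeat_method_deterministic(self, clean_sim_table):
        tab, _ = clean_sim_table
        res = run_battery(tab, EstimatorConfig(seed=5, bootstrap_reps=100),
                          ["weighted_median", "weighted_median"])
        assert res[0].estimate == res[1].estimate
        assert res[0].se == res[1].se

    def test_unknown_method_fatal(self, clean_sim_table):
        tab, _ = clean_sim_table
        with pytest.raises(MRConfigError, match="unknown"):
            run_battery(tab, EstimatorConfig(seed=0), ["ivw", "mrmagic"])

    def test_full_battery_recovers_truth(self):
        """All 7 methods agree with the generating effect on clean data."""
        theta = 0.4
        tab, truth = _sim_table(seed=77, theta=theta, n_snps=100,
                                total_r2=0.08)
        res = run_battery(tab, EstimatorConfig(seed=8, bootstrap_reps=200,
                                               presso_sims=300))
        frame = results_frame(res)
        assert len(frame) == 7
        for r in res:
            assert np.isfinite(r.estimate), r.extras.get("error")
            assert abs(r.estimate - theta) < 4 * r.se

    def test_method_failure_captured_not_fatal(self):
        tab = _frame([0.1, 0.2], [0.05, 0.1], [0.02, 0.02])
        res = run_battery(tab, EstimatorConfig(seed=0), ["ivw", "egger"])
        assert np.isfinite(res[0].estimate)
        assert "error" in res[1].extras
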