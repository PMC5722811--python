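import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from hipshape.association import (
    SeparationError,
    bonferroni_threshold,
    collapse_sparse_levels,
    default_battery,
    encode_covariates,
    fit_logistic,
    fit_ordinal,
    run_association_battery,
)


def _logistic_data(rng, n=2000, beta=0.0, alpha=-1.5):
    x = rng.normal(size=n)
    y = (rng.uniform(size=n) < expit(alpha + beta * x)).astype(float)
    return x, y


class TestLogistic:
    def test_two_by_two_matches_cross_product_odds_ratio(self):
        a, b, c, d = 20, 80, 10, 90
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = fit_logistic(y, x)
        assert res.or_per_sd == pytest.approx((a * d) / (b * c), abs=1e-6)

    def test_null_exposure_or_near_one(self, rng):
        x, y = _logistic_data(rng, n=5000, beta=0.0)
        res = fit_logistic(y, x)
        assert res.ci95[0] < 1.0 < res.ci95[1]
        assert res.or_per_sd == pytest.approx(1.0, abs=0.15)

    def test_planted_effect_recovery(self):
        """Mean estimate over replicates sits within 3 MC SEs of log(1.25)."""
        beta = np.log(1.25)
        betas = []
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            x, y = _logistic_data(r, n=2000, beta=beta)
            betas.append(np.log(fit_logistic(y, x).or_per_sd))
        mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - beta) < 3 * mc_se

    def test_sign_inversion(self, rng):
        x, y = _logistic_data(rng, beta=0.4)
        plus = fit_logistic(y, x)
        minus = fit_logistic(y, -x)
        assert minus.or_per_sd == pytest.approx(1.0 / plus.or_per_sd, rel=1e-10)
        assert minus.p == pytest.approx(plus.p, abs=1e-14)

    def test_single_class_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.zeros(100), rng.normal(size=100))

    def test_perfect_separation_detected(self):
        x = np.linspace(-2, 2, 200)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, x)

    def test_complete_case_count(self, rng):
        x, y = _logistic_data(rng, n=500, beta=0.3)
        y[:25] = np.nan
        res = fit_logistic(y, x)
        assert res.n_used == 475

    def test_adjustment_with_race_indicators(self, rng):
        x, y = _logistic_data(rng, n=1500, beta=0.4)
        cov = pd.DataFrame({
            "age": rng.normal(73, 5, 1500),
            "height": rng.normal(174, 7, 1500),
            "weight": rng.normal(84, 13, 1500),
            "race": rng.choice(["white", "asian", "other"], 1500,
                               p=[0.9, 0.05, 0.05]),
        })
        res = fit_logistic(y, x, cov)
        assert res.adjusted
        assert res.ci95[0] < res.or_per_sd < res.ci95[1]

    def test_collapsibility_under_independent_covariates(self):
        """Unadjusted and adjusted ORs agree when covariates are independent
        of both exposure and outcome (large n, 2% tolerance)."""
        r = np.random.default_rng(5)
        x, y = _logistic_data(r, n=40_000, beta=np.log(1.5))
        cov = pd.DataFrame({
            "age": r.normal(73, 5, 40_000),
            "height": r.normal(174, 7, 40_000),
            "weight": r.normal(84, 13, 40_000),
            "race": r.choice(["white", "asian"], 40_000, p=[0.9, 0.1]),
        })
        unadj = fit_logistic(y, x)
        adj = fit_logistic(y, x, cov)
        assert adj.or_per_sd == pytest.approx(unadj.or_per_sd, rel=0.02)


class TestOrdinal:
    def test_binary_outcome_matches_logistic(self, rng):
        x, y = _logistic_data(rng, n=800, beta=0.5)
        lg = fit_logistic(y, x)
        od = fit_ordinal(y.astype(int), x)
        assert np.log(od.or_per_sd) == pytest.approx(np.log(lg.or_per_sd), abs=1e-6)
        assert od.p == pytest.approx(lg.p, abs=1e-8)

    def test_planted_proportional_odds_recovery(self):
        """K=5 levels, true common log-OR log(0.87), recovered within CI."""
        beta = np.log(0.87)
        r = np.random.default_rng(11)
        n = 4000
        x = r.normal(size=n)
        theta = np.array([-0.5, 0.5, 1.5, 2.5])
        cdf = expit(theta[None, :] - beta * x[:, None])
        y = (r.uniform(size=n)[:, None] > cdf).sum(axis=1)
        res = fit_ordinal(y, x)
        lo, hi = np.log(res.ci95[0]), np.log(res.ci95[1])
        assert lo < beta < hi

    def test_collapse_sparse_levels(self):
        y = pd.Series([0] * 50 + [1] * 20 + [2] * 4 + [3] * 2 + [5] * 1)
        collapsed = collapse_sparse_levels(y, min_count=5)
        counts = collapsed.value_counts()
        assert (counts >= 5).all()
        assert collapsed.min() == 0
        # order preserved: originally-higher values never map below lower ones
        assert collapsed[y == 5].min() >= collapsed[y == 2].max()

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_ordinal(np.zeros(100, dtype=int), rng.normal(size=100))


class TestBonferroni:
    def test_ten_exposures_at_alpha_05(self):
        assert bonferroni_threshold(0.05, 10) == 0.005

    def test_single_test_identity(self):
        assert bonferroni_threshold(0.03, 1) == 0.03

    def test_threshold_times_m_is_alpha(self):
        for m in (1, 3, 10, 17):
            assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestBattery:
    @pytest.fixture()
    def small_tables(self, rng):
        n = 400
        ids = [f"p{i}" for i in range(n)]
        scores = pd.DataFrame(
            rng.normal(size=(n, 10)), columns=[f"mode_{j+1}" for j in range(10)]
        )
        scores.insert(0, "image_id", ids)
        outcomes = pd.DataFrame({
            "image_id": ids,
            "croft_grade": rng.choice([0, 1, 2, 3], n, p=[0.8, 0.12, 0.05, 0.03]),
        })
        covariates = pd.DataFrame({
            "image_id": ids,
            "age": rng.normal(73, 5, n),
            "height": rng.normal(174, 7, n),
            "weight": rng.normal(84, 13, n),
            "race": rng.choice(["white", "asian"], n, p=[0.9, 0.1]),
        })
        return scores, outcomes, covariates

    def test_cardinality_one_outcome(self, small_tables):
        scores, outcomes, covariates = small_tables
        battery = [{"name": "rhoa_croft2", "column": "croft_grade",
                    "threshold": 2, "model": "logistic"}]
        res = run_association_battery(scores, outcomes, covariates,
                                      battery=battery, n_modes=10)
        assert len(res) == 20  # 10 modes x 1 outcome x {unadjusted, adjusted}
        assert set(res["adjusted"]) == {True, False}

    def test_default_battery_structure(self):
        items = default_battery()
        names = [i["name"] for i in items]
        assert "rhoa_croft2" in names and "rhoa_croft3" in names
        assert "womac" in names
        assert len(names) == len(set(names)) == 17

    def test_join_loss_warning(self, small_tables):
        scores, outcomes, covariates = small_tables
        battery = [{"name": "rhoa_croft2", "column": "croft_grade",
                    "threshold": 2, "model": "logistic"}]
        with pytest.warns(UserWarning, match="join lost"):
            run_association_battery(
                scores, outcomes.iloc[:100], covariates,
                battery=battery, n_modes=2,
            )

    def test_cell_errors_recorded_not_fatal(self, small_tables):
        scores, outcomes, covariates = small_tables
        outcomes = outcomes.assign(croft_grade=0)  # no cases anywhere
        battery = [{"name": "rhoa_croft2", "column": "croft_grade",
                    "threshold": 2, "model": "logistic"}]
        res = run_association_battery(scores, outcomes, covariates,
                                      battery=battery, n_modes=2)
        assert (res["error"] != "").all()
        assert res["or"].isna().all()


def test_encode_covariates_reference_category():
    df = pd.DataFrame({
        "age": [70, 71, 72],
        "race": ["white", "asian", "other"],
    })
    enc = encode_covariates(df)
    assert "race_white" not in enc.columns
    assert {"race_asian", "race_other"} <= set(enc.columns)
    assert enc.loc[0, ["race_asian", "race_other"]].sum() == 0
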