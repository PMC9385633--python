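import itertools

import numpy as np
import pandas as pd
import pytest

from mrgradient import cox_fit, km_logrank, optimal_cutpoint, pca_cox
from mrgradient.gradient import GradientScore
from mrgradient.io import SurvivalTable


def _surv(times, events, prefix="s"):
    ids = [f"{prefix}{j}" for j in range(len(times))]
    return ids, SurvivalTable(pd.DataFrame(
        {"sample": ids, "time": times, "event": events}))


class TestLogrank:
    def test_identical_groups_score_zero(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 0, 1, 1] * 2
        ids, surv = _surv(times, events)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        chi2, p = km_logrank(groups, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        ids, surv = _surv([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            km_logrank(pd.Series(["a", "a"], index=ids), surv)

    def test_no_events_flagged_as_p_one(self):
        ids, surv = _surv([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=ids)
        assert km_logrank(groups, surv) == (0.0, 1.0)

    def test_against_exhaustive_permutation_oracle(self):
        """Clear separation at n=8: the chi2 p and the exact label-permutation
        tail should both call it significant and roughly agree."""
        times = [1.0, 1.5, 2.0, 2.5, 8.0, 9.0, 10.0, 11.0]
        events = [1] * 8
        ids, surv = _surv(times, events)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        chi2_obs, p_obs = km_logrank(pd.Series(labels, index=ids), surv)
        stats = []
        for combo in itertools.combinations(range(8), 4):
            lab = np.array(["b"] * 8)
            lab[list(combo)] = "a"
            chi2, _ = km_logrank(pd.Series(lab, index=ids), surv)
            stats.append(chi2)
        p_perm = np.mean(np.asarray(stats) >= chi2_obs - 1e-9)
        assert p_obs < 0.05
        assert p_perm == pytest.approx(2 / 70, abs=1e-9)  # only the two extremes
        assert abs(p_obs - p_perm) < 0.05


class TestOptimalCutpoint:
    def test_planted_groups_found(self):
        rng = np.random.default_rng(0)
        n = 100
        score = np.concatenate([rng.normal(-2, 0.3, n // 2),
                                rng.normal(2, 0.3, n // 2)])
        time = np.where(score < 0, rng.exponential(0.3, n),
                        rng.exponential(3.0, n))
        ids = [f"s{j}" for j in range(n)]
        surv = SurvivalTable(pd.DataFrame(
            {"sample": ids, "time": time, "event": 1}))
        g = GradientScore(pd.Series(score, index=ids), {"A": 1.0}, 0.0, 1.0)
        cut = optimal_cutpoint(g, surv)
        assert -1.5 < cut.threshold < 1.5  # inside the central gap
        assert cut.corrected_p < 0.05
        assert cut.logrank_p <= cut.corrected_p

    def test_min_frac_constrains_thresholds(self):
        rng = np.random.default_rng(1)
        score = pd.Series(np.arange(10.0), index=[f"s{j}" for j in range(10)])
        surv = SurvivalTable(pd.DataFrame({
            "sample": score.index, "time": rng.exponential(1, 10),
            "event": 1}))
        cut = optimal_cutpoint(GradientScore(score, {"A": 1.0}, 0, 1),
                               surv, min_frac=0.4)
        assert 4 <= cut.group_sizes[0] <= 6

    def test_validation_errors(self, toy_surv):
        s = pd.Series(np.arange(5.0), index=[f"s{j}" for j in range(5)])
        g = GradientScore(s, {"A": 1.0}, 0, 1)
        with pytest.raises(ValueError, match="10 samples"):
            optimal_cutpoint(g, toy_surv)


def _sim_cox(rng, n, log_hr):
    x = rng.normal(size=n)
    lam = np.exp(log_hr * x)
    t = rng.exponential(1 / lam)
    c = rng.exponential(3.0, n)
    ids = [f"s{j}" for j in range(n)]
    surv = SurvivalTable(pd.DataFrame({
        "sample": ids, "time": np.minimum(t, c),
        "event": (t <= c).astype(int)}))
    return pd.DataFrame({"x": x}, index=ids), surv


class TestCox:
    def test_null_covariate_recovers_unit_hr(self):
        rng = np.random.default_rng(2)
        cov, surv = _sim_cox(rng, 2000, 0.0)
        res = cox_fit(cov, surv)[0]
        assert 0.9 < res.hazard_ratio < 1.1
        assert res.ci_low < 1.0 < res.ci_high

    def test_planted_protective_hr_recovered(self):
        rng = np.random.default_rng(3)
        cov, surv = _sim_cox(rng, 2000, np.log(0.7))
        res = cox_fit(cov, surv)[0]
        assert abs(np.log(res.hazard_ratio) - np.log(0.7)) < 0.05

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(4)
        cov, surv = _sim_cox(rng, 300, np.log(0.8))
        hr1 = cox_fit(cov, surv)[0].hazard_ratio
        scaled = SurvivalTable(surv.data.assign(time=surv.data["time"] * 365.25))
        hr2 = cox_fit(cov, scaled)[0].hazard_ratio
        assert hr1 == pytest.approx(hr2, rel=1e-6)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(5)
        cov, surv = _sim_cox(rng, 100, 0.0)
        cov["y"] = 2.0 * cov["x"]
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(cov, surv, mode="multivariate")

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(6)
        cov, surv = _sim_cox(rng, 50, 0.0)
        cov["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(cov, surv)


class TestPCACox:
    def test_hazard_driving_component_identified(self):
        rng = np.random.default_rng(7)
        n = 400
        comps = pd.DataFrame({
            "driver": rng.normal(size=n) * 2.0,
            "bystander": rng.normal(size=n),
        }, index=[f"s{j}" for j in range(n)])
        lam = np.exp(-0.8 * comps["driver"] / comps["driver"].std())
        t = rng.exponential(1 / lam)
        surv = SurvivalTable(pd.DataFrame({
            "sample": comps.index, "time": t, "event": 1}))
        results, best, contributions = pca_cox(comps, surv)
        assert contributions["driver"] > 50.0
        assert results[best].p_value < 0.01

    def test_duplicated_informative_axis_splits_evenly(self):
        rng = np.random.default_rng(8)
        n = 300
        base = rng.normal(size=n)
        comps = pd.DataFrame({
            "c1": base + 0.01 * rng.normal(size=n),
            "c2": base + 0.01 * rng.normal(size=n),
        }, index=[f"s{j}" for j in range(n)])
        lam = np.exp(-0.7 * base)
        surv = SurvivalTable(pd.DataFrame({
            "sample": comps.index, "time": rng.exponential(1 / lam),
            "event": 1}))
        _, best, contributions = pca_cox(comps, surv)
        assert contributions["c1"] == pytest.approx(50.0, abs=5.0)

    def test_shape_requirements(self, toy_surv):
        s = pd.DataFrame({"a": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="2 components"):
            pca_cox(s, toy_surv)
        wide = pd.DataFrame(np.eye(3)[:2], index=["s0", "s1"],
                            columns=list("abc"))
        with pytest.raises(ValueError, match="fewer samples"):
            pca_cox(wide, toy_surv)
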