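import numpy as np
import pandas as pd
import pytest

from mrgradient import (
    MethylationMatrix,
    correlate_with_axis,
    lipid_subfamily_summary,
    marker_score,
    methyl_component_profile,
)
from mrgradient.gradient import GradientScore
from mrgradient.io import ExpressionMatrix
from mrgradient.omics import axis_selected


def _expr(rows: dict[str, list[float]]):
    n = len(next(iter(rows.values())))
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T)


class TestMarkerScore:
    def test_mean_of_log_values(self):
        expr = _expr({"m1": [2.0, 6.0], "m2": [4.0, 2.0]})
        out = marker_score(expr, {"tcell": ["m1", "m2"]})
        assert np.allclose(out[0].scores.to_numpy(), [3.0, 4.0])

    def test_equal_markers_give_that_value(self):
        expr = _expr({"m1": [5.0, 5.0], "m2": [5.0, 5.0]})
        out = marker_score(expr, {"x": ["m1", "m2"]})
        assert (out[0].scores == 5.0).all()

    def test_absent_markers_skipped(self):
        expr = _expr({"m1": [1.0, 2.0], "m2": [3.0, 4.0], "m3": [5.0, 6.0]})
        out = marker_score(expr, {"x": ["m1", "m2", "m3", "gone1", "gone2"]})
        assert out[0].markers_used == ["m1", "m2", "m3"]
        assert np.allclose(out[0].scores.to_numpy(), [3.0, 4.0])

    def test_type_without_markers_omitted(self):
        expr = _expr({"m1": [1.0, 2.0]})
        out = marker_score(expr, {"ok": ["m1"], "gone": ["zz"]})
        assert [a.cell_type for a in out] == ["ok"]

    def test_marker_order_and_duplicates_irrelevant(self):
        expr = _expr({"m1": [1.0, 2.0], "m2": [3.0, 4.0]})
        a = marker_score(expr, {"x": ["m1", "m2"]})[0].scores
        b = marker_score(expr, {"x": ["m2", "m1", "m1", "absent"]})[0].scores
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestAxisCorrelation:
    def test_identity_selected(self):
        s = pd.Series(np.arange(10.0), index=[f"s{j}" for j in range(10)])
        r, p, sel = correlate_with_axis(s, s * 3 + 1)
        assert r == pytest.approx(1.0) and sel

    @pytest.mark.parametrize("r,p,expected", [
        (0.21, 0.03, True),     # passes both thresholds
        (0.19, 0.001, False),   # strong p cannot rescue a weak r
        (0.5, 0.2, False),
        (-0.3, 0.01, True),     # sign-free effect size
    ])
    def test_threshold_rule(self, r, p, expected):
        assert axis_selected(r, p) is expected

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=30), index=[f"s{j}" for j in range(30)])
        a = pd.Series(rng.normal(size=30), index=s.index) + 0.5 * s
        r1, p1, _ = correlate_with_axis(s, a)
        r2, p2, _ = correlate_with_axis(np.exp(s), a**3 + 2 * a)
        # a**3 + 2a is strictly monotone; spearman depends on ranks only
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)

    def test_constant_input_rejected(self):
        s = pd.Series(1.0, index=[f"s{j}" for j in range(10)])
        a = pd.Series(np.arange(10.0), index=s.index)
        with pytest.raises(ValueError, match="constant"):
            correlate_with_axis(s, a)


def _gradient(n, rng):
    vals = rng.normal(size=n)
    vals = (vals - vals.mean()) / vals.std(ddof=1)
    return GradientScore(
        pd.Series(vals, index=[f"s{j}" for j in range(n)]), {"A": 1.0}, 0, 1)


class TestMethylation:
    def test_beta_bounds_enforced(self):
        with pytest.raises(ValueError, match="0, 1"):
            MethylationMatrix(pd.DataFrame([[1.2]], index=["cg1"],
                                           columns=["s0"]))

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(1)
        grad = _gradient(30, rng)
        beta = MethylationMatrix(pd.DataFrame(
            0.5, index=[f"cg{i}" for i in range(20)],
            columns=grad.sample_ids))
        with pytest.raises(ValueError, match="constant"):
            methyl_component_profile(beta, grad)

    def test_planted_hypermethylation_block_tracks_gradient(self):
        rng = np.random.default_rng(2)
        n, n_cpg = 60, 300
        grad = _gradient(n, rng)
        z = grad.values.to_numpy()
        logit = rng.normal(0, 0.3, size=(n_cpg, n))
        logit[:20] += -2.0 * z[None, :]  # methylation rises as gradient falls
        beta = MethylationMatrix(pd.DataFrame(
            1 / (1 + np.exp(-logit)), index=[f"cg{i:03d}" for i in range(n_cpg)],
            columns=grad.sample_ids))
        selected, median_beta, r = methyl_component_profile(
            beta, grad, sd_mult=2.0, n_components=2, seed=0)
        assert len(selected & {f"cg{i:03d}" for i in range(20)}) >= 15
        assert r < -0.8

    def test_extreme_threshold_flags_empty_selection(self):
        rng = np.random.default_rng(3)
        n = 40
        grad = _gradient(n, rng)
        beta = MethylationMatrix(pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(50, n)),
            index=[f"cg{i}" for i in range(50)], columns=grad.sample_ids))
        selected, median_beta, r = methyl_component_profile(
            beta, grad, sd_mult=1e6, n_components=2, seed=0)
        assert selected == set() and median_beta is None and np.isnan(r)


class TestLipids:
    def test_single_metabolite_subfamily_is_identity(self):
        rng = np.random.default_rng(4)
        grad = _gradient(20, rng)
        intens = pd.DataFrame([rng.normal(size=20)], index=["m1"],
                              columns=grad.sample_ids)
        out = lipid_subfamily_summary(intens, {"m1": "F"}, grad)
        assert np.allclose(out.attrs["profiles"].loc["F"].to_numpy(),
                           intens.loc["m1"].to_numpy())

    def test_median_within_subfamily(self):
        rng = np.random.default_rng(5)
        grad = _gradient(6, rng)
        intens = pd.DataFrame(
            [[1.0] * 6, [2.0] * 6, [9.0] * 6],
            index=["a", "b", "c"], columns=grad.sample_ids)
        out = lipid_subfamily_summary(
            intens, {"a": "F", "b": "F", "c": "F"}, grad)
        assert (out.attrs["profiles"].loc["F"] == 2.0).all()

    def test_planted_subfamily_flagged(self):
        rng = np.random.default_rng(6)
        n = 50
        grad = _gradient(n, rng)
        z = grad.values.to_numpy()
        rows, mapping = [], {}
        for i in range(3):
            rows.append(2.0 * z + 0.2 * rng.normal(size=n))
            mapping[f"hit{i}"] = "LINKED"
        for i in range(3):
            rows.append(rng.normal(size=n))
            mapping[f"bg{i}"] = "NOISE"
        intens = pd.DataFrame(rows, index=list(mapping), columns=grad.sample_ids)
        out = lipid_subfamily_summary(intens, mapping, grad)
        assert out.loc["LINKED", "selected"]
        assert abs(out.loc["LINKED", "r"]) > 0.8

    def test_unmapped_metabolite_rejected(self):
        rng = np.random.default_rng(7)
        grad = _gradient(10, rng)
        intens = pd.DataFrame([rng.normal(size=10)], index=["m1"],
                              columns=grad.sample_ids)
        with pytest.raises(ValueError, match="unmapped"):
            lipid_subfamily_summary(intens, {}, grad)
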