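"""Normality, correlation, layer proportions and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foveamorph.stats import (
    correlation_matrix,
    group_compare,
    group_compare_from_summary,
    layer_proportions,
    normality_test,
)

# Frozen 24-point samples with Shapiro-Wilk W/p computed by an independent
# reference implementation (R 4.3 `shapiro.test`).
NORMALISH = [
    6.315387, 14.790744, 12.99709, 10.366244, 9.988789, 12.593531, 5.760685,
    5.426648, 6.830296, 9.295154, 10.957844, 9.149652, 11.534871, 11.671532,
    10.279698, 11.266056, 10.47447, 8.602763, 7.545853, 8.122016, 11.00898,
    8.475405, 9.990004, 8.70276,
]
LOGNORMALISH = [
    1.685683, 1.689359, 1.357862, 1.736924, 3.754441, 1.68894, 1.107932,
    3.628948, 0.723606, 4.126861, 1.020944, 3.178394, 0.342044, 1.265249,
    0.87525, 0.759613, 2.623849, 0.078231, 1.16147, 1.396676, 0.494298,
    2.591676, 0.605704, 0.897041,
]


class TestNormalityTest:
    @pytest.mark.parametrize(
        "sample,w_ref,p_ref",
        [(NORMALISH, 0.9851217965, 0.9686656558), (LOGNORMALISH, 0.8978199110, 0.0193562955)],
        ids=["gaussian-like", "lognormal-like"],
    )
    def test_matches_reference_implementation(self, sample, w_ref, p_ref):
        res = normality_test(sample)
        assert res.W == pytest.approx(w_ref, abs=1e-6)
        assert res.p == pytest.approx(p_ref, abs=1e-4)

    def test_type_one_error_calibration(self):
        # at alpha = 0.05 the rejection rate on normal data should be ~5 %
        rng = np.random.default_rng(55)
        rejections = sum(
            normality_test(rng.normal(size=50)).p < 0.05 for _ in range(1000)
        )
        assert 30 <= rejections <= 70

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(56)
        rejections = sum(
            normality_test(rng.lognormal(0, 1, size=100)).p < 0.05 for _ in range(100)
        )
        assert rejections >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_test([2.0] * 10)

    def test_out_of_range_n_rejected(self):
        with pytest.raises(ValueError, match="3 <= n <= 5000"):
            normality_test([1.0, 2.0])


class TestCorrelationMatrix:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        cm = correlation_matrix(df, ["x", "y", "z"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.r.loc["x", "z"] == pytest.approx(-1.0)
        assert bool(cm.significant.loc["x", "y"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_definitional_formula(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        cm = correlation_matrix(df, ["a", "b", "c"])
        a, b = df["a"].to_numpy(), df["b"].to_numpy()
        da, db = a - a.mean(), b - b.mean()
        r_brute = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
        assert cm.r.loc["a", "b"] == pytest.approx(r_brute, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        cm0 = correlation_matrix(df, ["a", "b"])
        cm1 = correlation_matrix(df.assign(a=5 * df.a - 7), ["a", "b"])
        assert cm1.r.loc["a", "b"] == pytest.approx(cm0.r.loc["a", "b"], abs=1e-12)

    def test_pairwise_complete_handling(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4, np.nan], "b": [2.0, 4, 6, 8, 10], "c": [1.0, 3, 2, 5, 4]})
        cm = correlation_matrix(df, ["a", "b", "c"])
        assert cm.n.loc["a", "b"] == 4
        assert cm.n.loc["b", "c"] == 5
        assert cm.r.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_column_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="zero variance"):
            cm = correlation_matrix(df, ["a", "b"])
        assert np.isnan(cm.r.loc["a", "b"])


class TestLayerProportions:
    def test_single_eye_printed_group_means(self):
        # (13.95 + 150.52) / 247.09 = 0.6656
        df = pd.DataFrame(
            {"eye_id": ["e"], "GCLp_FC": [13.95], "ONL_FC": [150.52], "RT_FC": [247.09]}
        )
        per_eye, _ = layer_proportions(df)
        assert per_eye["prop_inner_plus_onl"].iloc[0] == pytest.approx(0.6656, abs=5e-5)

    def test_boundary_ratio_one(self):
        df = pd.DataFrame({"eye_id": ["e"], "GCLp_FC": [0.0], "ONL_FC": [200.0], "RT_FC": [200.0]})
        per_eye, _ = layer_proportions(df)
        assert per_eye["prop_inner_plus_onl"].iloc[0] == 1.0

    def test_additivity_holds_exactly_per_eye(self, mixed_cohort):
        per_eye, _ = layer_proportions(mixed_cohort)
        np.testing.assert_allclose(
            per_eye["prop_inner_plus_onl"], per_eye["prop_onl"] + per_eye["prop_gclp"]
        )
        assert per_eye[["prop_inner_plus_onl", "prop_onl", "prop_gclp"]].le(1).all().all()
        assert per_eye[["prop_inner_plus_onl", "prop_onl", "prop_gclp"]].ge(0).all().all()

    def test_nonpositive_rt_row_rejected_with_diagnostic(self):
        df = pd.DataFrame(
            {"eye_id": ["good", "bad"], "GCLp_FC": [1.0, 1.0], "ONL_FC": [100.0, 100.0],
             "RT_FC": [200.0, 0.0]}
        )
        with pytest.warns(UserWarning, match="bad"):
            per_eye, _ = layer_proportions(df)
        assert per_eye["eye_id"].tolist() == ["good"]


class TestGroupCompare:
    def test_identical_groups_t_zero_p_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=15)
        df = pd.DataFrame({"v": np.concatenate([x, x]), "g": ["a"] * 15 + ["b"] * 15})
        res = group_compare(df, ["v"], "g", welch=True)
        assert res["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_from_summary_matches_textbook_formula(self):
        # gestational age (weeks): 25.83±0.39 (n=12) vs 25.71±0.49 (n=7)
        res = group_compare_from_summary(
            [{"variable": "ga", "mean1": 25.83, "sd1": 0.39, "n1": 12,
              "mean2": 25.71, "sd2": 0.49, "n2": 7}], welch=True,
        ).iloc[0]
        v1, v2 = 0.39**2 / 12, 0.49**2 / 7
        t_hand = (25.83 - 25.71) / np.sqrt(v1 + v2)
        df_hand = (v1 + v2) ** 2 / (v1**2 / 11 + v2**2 / 6)
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df_hand)
        assert res["t"] == pytest.approx(t_hand, abs=1e-10)
        assert res["df"] == pytest.approx(df_hand, abs=1e-9)
        assert res["p"] == pytest.approx(p_hand, abs=1e-10)
        assert 0.55 <= res["p"] <= 0.63  # consistent with the published 0.591

    def test_welch_p_agrees_with_exact_permutation_p(self):
        # same-variance balanced design: the Welch p should agree with the
        # exact permutation distribution of the mean difference
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        df = pd.DataFrame({"v": np.concatenate([a, b]), "g": ["a"] * 8 + ["b"] * 8})
        p_welch = group_compare(df, ["v"], "g", welch=True)["p"].iloc[0]
        from itertools import combinations

        pooled = np.concatenate([a, b])
        observed = abs(a.mean() - b.mean())
        total = pooled.sum()
        count = 0
        n_perm = 0
        for idx in combinations(range(16), 8):
            ga = pooled[list(idx)]
            diff = abs(ga.mean() - (total - ga.sum()) / 8)
            count += diff >= observed - 1e-12
            n_perm += 1
        p_perm = count / n_perm
        assert abs(p_welch - p_perm) < 0.05

    def test_small_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="at least 2"):
            group_compare(df, ["v"], "g")
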