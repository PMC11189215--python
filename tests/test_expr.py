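"""Expression preparation: filter, size factors, VST, residualize, INT."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from teqtl.expr import (
    CountMatrix,
    ExpressionMatrix,
    cpm_for_reads,
    estimate_hidden_factors,
    filter_low_expression,
    inverse_normal_transform,
    read_counts_tsv,
    residualize_covariates,
    size_factors_median_ratio,
    vst_transform,
)


def make_counts(arr, kinds=None):
    arr = np.asarray(arr)
    features = [f"f{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        counts=pd.DataFrame(arr, index=features, columns=samples),
        kinds=pd.Series(kinds or ["gene"] * arr.shape[0], index=features),
    )


class TestFilterLowExpression:
    def test_required_sample_count_at_cohort_scale(self):
        # 90% of 358 samples rounds up to 323
        assert math.ceil(0.9 * 358) == 323
        rng = np.random.default_rng(0)
        c = make_counts(rng.integers(50, 200, (5, 358)))
        out = filter_low_expression(c, cpm_min=0.0, min_fraction=0.9)
        assert out.counts.shape[0] == 5  # everything expressed everywhere

    def test_all_zero_feature_removed(self):
        c = make_counts([[0, 0, 0, 0], [10, 12, 9, 11]])
        out = filter_low_expression(c, cpm_min=0.5)
        assert out.features == ["f1"]

    def test_hand_cpm_table(self):
        counts = np.array(
            [
                [5, 5, 5, 5],      # cpm 1e6/4.003e6... depends on libsize
                [0, 100, 100, 100],
                [100, 100, 100, 100],
            ]
        )
        c = make_counts(counts)
        lib = c.library_size.to_numpy()
        cpm = counts * 1e6 / lib
        keep_expected = [( (cpm[i] > 1.0).sum() >= math.ceil(0.75 * 4) ) for i in range(3)]
        out = filter_low_expression(c, cpm_min=1.0, min_fraction=0.75)
        assert [f in out.features for f in c.features] == keep_expected

    def test_strict_inequality(self):
        # feature sits exactly at the threshold in every sample -> dropped
        c = make_counts([[1, 1], [999999, 999999]])
        cpm_min = 1e6 / 1_000_000  # exactly the cpm of count 1 here
        out = filter_low_expression(c, cpm_min=cpm_min, min_fraction=0.5)
        assert "f0" not in out.features

    def test_cpm_for_reads_median_library(self):
        assert cpm_for_reads(10, [1e6, 2e6, 4e6]) == pytest.approx(10 * 1e6 / 2e6)

    def test_negative_cpm_errors(self):
        with pytest.raises(ValueError):
            filter_low_expression(make_counts([[1, 1]]), cpm_min=-1)


class TestSizeFactors:
    def test_identical_columns_unity(self):
        c = make_counts(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(size_factors_median_ratio(c), 1.0)

    def test_doubled_column_relative_factor(self):
        base = np.array([[10, 10, 10], [20, 20, 20], [40, 40, 40]])
        doubled = base.copy()
        doubled[:, 2] *= 2
        f = size_factors_median_ratio(make_counts(doubled))
        assert f.iloc[2] / f.iloc[0] == pytest.approx(2.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, (50, 6))
        c = make_counts(counts)
        f = size_factors_median_ratio(c)
        logc = np.log(counts.astype(float))
        ratios = logc - logc.mean(axis=1, keepdims=True)
        raw = np.exp(np.median(ratios, axis=0))
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(f, expected, rtol=1e-12)

    def test_no_all_positive_feature_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors_median_ratio(make_counts([[0, 5], [5, 0]]))


class TestVst:
    def test_zero_count_maps_to_zero(self):
        c = make_counts(np.tile([[0], [7], [100]], (1, 3)))
        e = vst_transform(c)
        assert e.values.iloc[0, 0] == pytest.approx(0.0)
        assert e.values.iloc[1, 0] == pytest.approx(3.0)  # log2(7/1 + 1)

    def test_matches_formula_with_module_size_factors(self):
        # log2(count/factor + 1), and doubling counts alongside factors is a no-op
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 300, (20, 5))
        c = make_counts(counts)
        f = size_factors_median_ratio(c).to_numpy()
        expected = np.log2(counts / f + 1.0)
        np.testing.assert_allclose(vst_transform(c).values, expected, atol=1e-12)
        np.testing.assert_allclose(
            np.log2(2 * counts / (2 * f) + 1.0), expected, atol=1e-12
        )

    def test_state_and_provenance(self):
        e = vst_transform(make_counts([[1, 2], [3, 4]]))
        assert e.state == "transformed"
        assert e.provenance[0]["step"] == "vst"


def covariate_fixture(n=30, seed=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "lab": rng.choice(["a", "b"], n),
            "x": rng.normal(size=n),
        },
        index=[f"s{j}" for j in range(n)],
    )


class TestResidualize:
    def _expr(self, values):
        values = np.atleast_2d(values)
        return ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=[f"f{i}" for i in range(values.shape[0])],
                columns=[f"s{j}" for j in range(values.shape[1])],
            ),
            kinds=pd.Series("gene", index=[f"f{i}" for i in range(values.shape[0])]),
            state="transformed",
        )

    def test_feature_equal_to_covariate_becomes_constant(self):
        cov = covariate_fixture()
        e = self._expr(cov["x"].to_numpy())
        out = residualize_covariates(e, cov)
        np.testing.assert_allclose(
            out.values.iloc[0], cov["x"].mean(), atol=1e-10
        )

    def test_orthogonal_covariate_leaves_feature(self):
        n = 40
        x = np.ones(n)
        x[: n // 2] = -1  # orthogonal to the feature below
        feature = np.tile([1.0, -1.0], n // 2)
        assert abs(x @ feature) < 1e-12
        cov = pd.DataFrame({"x": x}, index=[f"s{j}" for j in range(n)])
        e = self._expr(feature)
        out = residualize_covariates(e, cov)
        np.testing.assert_allclose(out.values.iloc[0], feature, atol=1e-10)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(4)
        cov = covariate_fixture()
        y = rng.normal(size=(5, 30))
        e = self._expr(y)
        out = residualize_covariates(e, cov)
        # explicit hat matrix on the one-hot design
        design = np.column_stack(
            [np.ones(30), (cov["lab"] == "b").astype(float), cov["x"]]
        )
        h = design @ np.linalg.inv(design.T @ design) @ design.T
        expected = (np.eye(30) - h) @ y.T + y.mean(axis=1)
        np.testing.assert_allclose(out.values.to_numpy(), expected.T, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        cov = covariate_fixture()
        e = self._expr(rng.normal(size=(4, 30)))
        once = residualize_covariates(e, cov)
        again = residualize_covariates(
            ExpressionMatrix(values=once.values, kinds=once.kinds, state="transformed"),
            cov,
        )
        np.testing.assert_allclose(once.values, again.values, atol=1e-10)

    def test_collinear_design_names_columns(self):
        cov = covariate_fixture()
        cov["x2"] = 2 * cov["x"]
        e = self._expr(np.random.default_rng(0).normal(size=30))
        with pytest.raises(ValueError, match="x2"):
            residualize_covariates(e, cov)


class TestInverseNormal:
    def _resid(self, values):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=[f"f{i}" for i in range(values.shape[0])],
                columns=[f"s{j}" for j in range(values.shape[1])],
            ),
            kinds=pd.Series("gene", index=[f"f{i}" for i in range(values.shape[0])]),
            state="residualized",
        )

    def test_blom_scores_n3(self):
        out = inverse_normal_transform(self._resid([10.0, 20.0, 30.0]))
        expected = norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out.values.iloc[0], expected, atol=1e-10)
        assert out.values.iloc[0, 1] == 0.0
        assert expected[0] == pytest.approx(-0.8694, abs=2e-4)

    def test_middle_sample_maps_to_zero_odd_n(self):
        out = inverse_normal_transform(self._resid([5.0, 1.0, 9.0, 2.0, 7.0]))
        row = out.values.iloc[0].to_numpy()
        assert row[0] == pytest.approx(0.0, abs=1e-12)  # median value

    def test_rank_invariance_under_monotone_rescale(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        a = inverse_normal_transform(self._resid(x))
        b = inverse_normal_transform(self._resid(np.exp(3 * x) + 7))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_rows_share_exact_score_multiset_and_zero_mean(self):
        rng = np.random.default_rng(7)
        out = inverse_normal_transform(self._resid(rng.normal(size=(6, 41))))
        ref = np.sort(out.values.iloc[0].to_numpy())
        for i in range(6):
            row = out.values.iloc[i].to_numpy()
            np.testing.assert_array_equal(np.sort(row), ref)
            assert abs(row.mean()) < 1e-10

    def test_constant_row_errors(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal_transform(self._resid(np.ones(10)))

    def test_state_gate(self):
        e = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0]], index=["f0"], columns=list("abc")),
            kinds=pd.Series("gene", index=["f0"]),
            state="transformed",
        )
        with pytest.raises(ValueError, match="residualized"):
            inverse_normal_transform(e)
        out = inverse_normal_transform(e, allow_transformed=True)
        assert out.state == "inverse_normal"


class TestHiddenFactors:
    def _resid(self, values):
        values = np.asarray(values, dtype=float)
        return ExpressionMatrix(
            values=pd.DataFrame(
                values,
                index=[f"f{i}" for i in range(values.shape[0])],
                columns=[f"s{j}" for j in range(values.shape[1])],
            ),
            kinds=pd.Series("gene", index=[f"f{i}" for i in range(values.shape[0])]),
            state="residualized",
        )

    def test_k_zero_empty(self):
        rng = np.random.default_rng(8)
        hf = estimate_hidden_factors(self._resid(rng.normal(size=(10, 20))), 0)
        assert hf.shape[1] == 0

    def test_recovers_planted_rank_one_batch(self):
        rng = np.random.default_rng(9)
        loading = rng.normal(size=60)  # per-sample hidden factor
        effect = rng.normal(size=(100, 1))
        data = effect @ loading[None, :] + 0.3 * rng.normal(size=(100, 60))
        hf = estimate_hidden_factors(self._resid(data), 1)
        r = np.corrcoef(hf["HF1"], loading)[0, 1]
        assert abs(r) > 0.9

    def test_factors_orthogonal(self):
        rng = np.random.default_rng(10)
        hf = estimate_hidden_factors(self._resid(rng.normal(size=(30, 25))), 3)
        gram = hf.to_numpy().T @ hf.to_numpy()
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)


class TestRoundTrip:
    def test_counts_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        c = make_counts(rng.integers(0, 100, (8, 5)), kinds=["gene"] * 6 + ["te_locus", "viral"])
        c.to_tsv(tmp_path / "c.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv")
        pd.testing.assert_frame_equal(
            back.counts, c.counts, check_dtype=False, check_names=False
        )
        assert list(back.kinds) == list(c.kinds)
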