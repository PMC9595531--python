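"""Filtering, normalization, outlier screening, and residualization."""

import numpy as np
import pandas as pd
import pytest

from receptorfunc.containers import ExpressionMatrix
from receptorfunc.preprocess import (
    build_design,
    filter_genes,
    filter_samples_by_death,
    log2_transform,
    quantile_normalize,
    remove_outlier_samples,
    residualize,
)


def _expr(values, stage="tpm", genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), stage=stage
    )


def _meta(n, hardy=None, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "batch": rng.choice(["B1", "B2"], n),
            "ischemic_time": rng.uniform(100, 900, n),
            "sex": rng.choice(["F", "M"], n),
            "age_bracket": rng.choice([20, 30, 40, 50, 60, 70], n),
            "hardy_code": hardy if hardy is not None else rng.choice([0, 1, 2, 3], n),
        },
        index=[f"s{j}" for j in range(n)],
    )


class TestDeathFilter:
    def test_excludes_hardy_code_four(self, rng):
        expr = _expr(rng.uniform(0, 10, (4, 10)))
        meta = _meta(10, hardy=[0, 1, 4, 2, 3, 4, 0, 1, 2, 3])
        out, meta_out = filter_samples_by_death(expr, meta)
        assert out.n_samples == 8
        assert (meta_out["hardy_code"] != 4).all()
        assert list(out.sample_ids) == [s for s in expr.sample_ids if s not in ("s2", "s5")]

    def test_empty_exclusion_is_identity(self, rng):
        expr = _expr(rng.uniform(0, 10, (3, 6)))
        meta = _meta(6)
        out, _ = filter_samples_by_death(expr, meta, excluded_codes=set())
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_excluding_every_code_raises(self, rng):
        expr = _expr(rng.uniform(0, 10, (3, 6)))
        with pytest.raises(ValueError, match="no samples remain"):
            filter_samples_by_death(expr, _meta(6), excluded_codes={0, 1, 2, 3, 4})

    def test_sample_missing_from_metadata_is_named(self, rng):
        expr = _expr(rng.uniform(0, 10, (3, 6)))
        with pytest.raises(KeyError, match="s5"):
            filter_samples_by_death(expr, _meta(6).drop(index="s5"))


class TestGeneFilter:
    def test_enumerated_pass_pattern(self):
        # six genes with known per-gene counts above 0.1 TPM (5 samples: 80% = 4)
        vals = np.array(
            [
                [1.0, 1.0, 1.0, 1.0, 1.0],    # 5/5, variance 0 -> dropped
                [0.2, 0.3, 0.4, 0.5, 0.05],   # 4/5 -> kept
                [0.2, 0.3, 0.4, 0.05, 0.05],  # 3/5 -> dropped
                [0.1, 0.1, 0.1, 0.1, 5.0],    # boundary ">= 0.1", 5/5 -> kept
                [0.0, 0.0, 0.0, 0.0, 0.0],    # all zero -> dropped
                [2.0, 3.0, 4.0, 5.0, 6.0],    # kept
            ]
        )
        out = filter_genes(_expr(vals))
        assert list(out.gene_ids) == ["g1", "g3", "g5"]

    def test_missing_values_drop_gene(self):
        vals = np.array([[1.0, np.nan, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0, 5.0]])
        out = filter_genes(_expr(vals))
        assert list(out.gene_ids) == ["g1"]

    def test_requires_tpm_stage(self, rng):
        with pytest.raises(ValueError, match="stage"):
            filter_genes(_expr(rng.uniform(0, 10, (3, 5)), stage="log2"))


class TestLog2:
    def test_closed_form_values(self):
        out = log2_transform(_expr([[0.0, 1.0, 3.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[0.0, 1.0, 2.0]])
        assert out.stage == "log2"

    def test_zero_pseudocount_on_zero_value_raises(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_transform(_expr([[0.0, 1.0]]), pseudocount=0.0)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(_expr([[-1.0, 1.0]]))

    def test_matches_scalar_loop_oracle(self, rng):
        vals = rng.uniform(0, 50, (20, 7))
        out = log2_transform(_expr(vals)).values.to_numpy()
        for i in range(20):
            for j in range(7):
                assert abs(out[i, j] - np.log2(vals[i, j] + 1.0)) < 1e-12


class TestQuantileNormalize:
    def test_single_sample_unchanged(self):
        expr = _expr([[3.0], [1.0], [2.0]], stage="log2")
        out = quantile_normalize(expr)
        np.testing.assert_allclose(out.values.to_numpy(), expr.values.to_numpy())

    def test_two_sample_hand_example(self):
        expr = _expr(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]), stage="log2")
        out = quantile_normalize(expr).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_sorted_columns_identical_and_ranks_preserved(self, rng):
        vals = rng.normal(size=(50, 8))
        out = quantile_normalize(_expr(vals, stage="log2")).values.to_numpy()
        ref = np.sort(out, axis=0)
        for j in range(1, 8):
            np.testing.assert_allclose(ref[:, j], ref[:, 0], atol=1e-12)
            assert (np.argsort(out[:, j]) == np.argsort(vals[:, j])).all()

    def test_ties_get_mean_of_tied_reference_values(self):
        # sample 0 has a tie at the two lowest ranks
        expr = _expr(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]), stage="log2")
        out = quantile_normalize(expr).values.to_numpy()
        ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (5 + 30) / 2])
        assert out[0, 0] == out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[2, 0] == pytest.approx(ref[2])


class TestOutlierRemoval:
    def test_zero_contamination_removes_nothing(self, rng):
        expr = _expr(rng.normal(size=(30, 12)), stage="qnorm")
        out, removed = remove_outlier_samples(expr, contamination=0.0, seed=1)
        assert len(removed) == 0
        assert out.n_samples == 12

    def test_identical_seed_identical_removal(self, rng):
        expr = _expr(rng.normal(size=(40, 25)), stage="qnorm")
        _, r1 = remove_outlier_samples(expr, contamination=0.1, seed=5)
        _, r2 = remove_outlier_samples(expr, contamination=0.1, seed=5)
        assert list(r1) == list(r2)

    def test_contamination_bound(self, rng):
        expr = _expr(rng.normal(size=(30, 12)), stage="qnorm")
        with pytest.raises(ValueError, match="contamination"):
            remove_outlier_samples(expr, contamination=0.6)

    def test_recovers_planted_shifted_samples(self, dataset, truth):
        """5% planted shifted samples: >= 90% of them among the removed set."""
        expr = dataset[0]
        qnorm = quantile_normalize(log2_transform(filter_genes(expr)))
        _, removed = remove_outlier_samples(qnorm, contamination=0.05, seed=2)
        planted = set(truth.outlier_samples)
        assert len(planted & set(removed)) >= 0.9 * len(planted)


class TestResidualize:
    def test_perfectly_explained_gene_has_zero_residuals(self):
        meta = _meta(20)
        gene = 2.0 * meta["ischemic_time"].to_numpy() + 5.0
        expr = _expr(gene[None, :], stage="qnorm", samples=list(meta.index))
        resid, model = residualize(expr, meta, ["ischemic_time"])
        assert np.abs(resid.values.to_numpy()).max() <= 1e-8
        assert model.coefficients.loc["g0", "ischemic_time"] == pytest.approx(2.0)

    def test_no_confounders_demeans(self, rng):
        meta = _meta(15)
        vals = rng.normal(size=(4, 15))
        expr = _expr(vals, stage="qnorm", samples=list(meta.index))
        resid, _ = residualize(expr, meta, [])
        np.testing.assert_allclose(
            resid.values.to_numpy(), vals - vals.mean(axis=1, keepdims=True), atol=1e-10
        )

    def test_matches_normal_equations_oracle(self, rng):
        meta = _meta(40, seed=3)
        batch_effect = (meta["batch"] == "B2").to_numpy(float) * 1.5
        vals = rng.normal(size=(6, 40)) + batch_effect
        expr = _expr(vals, stage="qnorm", samples=list(meta.index))
        resid, model = residualize(expr, meta, ["batch", "ischemic_time"])
        X = model.design.to_numpy()
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ vals.T)
        np.testing.assert_allclose(
            model.coefficients.to_numpy(), beta_oracle.T, atol=1e-8
        )
        # residuals orthogonal to every design column
        dots = resid.values.to_numpy() @ X
        assert np.abs(dots).max() < 1e-7

    def test_idempotent(self, rng):
        meta = _meta(30, seed=4)
        expr = _expr(rng.normal(size=(5, 30)), stage="qnorm", samples=list(meta.index))
        r1, _ = residualize(expr, meta, ["batch", "sex", "ischemic_time"])
        r2, _ = residualize(r1, meta, ["batch", "sex", "ischemic_time"])
        np.testing.assert_allclose(
            r1.values.to_numpy(), r2.values.to_numpy(), atol=1e-8
        )

    def test_collinear_design_names_columns(self):
        meta = _meta(20)
        meta["dup"] = meta["ischemic_time"]
        expr = _expr(np.ones((2, 20)), stage="qnorm", samples=list(meta.index))
        with pytest.raises(ValueError, match="collinear"):
            residualize(expr, meta, ["ischemic_time", "dup"])


def test_design_encodes_categoricals_drop_first():
    meta = _meta(12)
    design = build_design(meta, ["batch", "sex", "age_bracket"])
    assert "intercept" in design.columns
    assert "batch[B1]" not in design.columns  # first level dropped
    assert any(c.startswith("batch[") for c in design.columns)
    assert "age_bracket" in design.columns  # ordinal stays numeric
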