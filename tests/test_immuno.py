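"""CYT scoring, correlation screens, DE gating, prognostic Z, PCA,
row clustering."""

import numpy as np
import pandas as pd
import pytest

import tcaflux as tf
from tcaflux.errors import DataError, DomainError, ValidationError
from tcaflux.immuno import ClusterResult, row_zscore


def _expr(data: dict, samples=None) -> tf.ExpressionMatrix:
    df = pd.DataFrame(data).T
    if samples is not None:
        df.columns = samples
    return tf.ExpressionMatrix(df)


class TestExpressionMatrix:
    def test_uppercases_and_validates(self):
        expr = _expr({"gzma": [1.0, 2.0], "Prf1": [3.0, 4.0]})
        assert expr.genes == ["GZMA", "PRF1"]
        with pytest.raises(ValidationError):
            _expr({"A": [1.0], "a": [2.0]})
        with pytest.raises(ValidationError):
            _expr({"A": [-1.0]})


class TestCytScore:
    def test_geometric_mean_of_equals(self):
        expr = _expr({"GZMA": [4.0], "PRF1": [4.0]})
        assert tf.cyt_score(expr).iloc[0] == pytest.approx(4.0)

    def test_geometric_mean_spread(self):
        expr = _expr({"GZMA": [1.0], "PRF1": [100.0]})
        assert tf.cyt_score(expr).iloc[0] == pytest.approx(10.0)

    def test_zero_expression_needs_pseudocount(self):
        expr = _expr({"GZMA": [0.0], "PRF1": [25.0]})
        with pytest.raises(DomainError):
            tf.cyt_score(expr)
        score = tf.cyt_score(expr, pseudocount=0.01)
        assert score.iloc[0] == pytest.approx(np.sqrt(0.01 * 25.01))

    def test_missing_gene_named(self):
        expr = _expr({"GZMA": [1.0]})
        with pytest.raises(KeyError, match="PRF1"):
            tf.cyt_score(expr)

    def test_scale_equivariance(self):
        expr = _expr({"GZMA": [2.0, 8.0], "PRF1": [18.0, 2.0]})
        base = tf.cyt_score(expr)
        scaled = tf.cyt_score(
            _expr({"GZMA": [6.0, 24.0], "PRF1": [54.0, 6.0]})
        )
        assert np.allclose(scaled.to_numpy(), 3.0 * base.to_numpy())


class TestCorrelateGenes:
    def test_planted_genes_classified_with_correct_sign(self, small_cohort):
        expr, covariate = small_cohort
        cov = covariate.set_index("sample_id")["leukocyte_fraction"]
        res = tf.correlate_genes(expr, cov).set_index("gene")
        assert res.loc["SLC7A7", "class"] == "positive"
        assert res.loc["SLC7A5", "class"] == "negative"

    def test_permuted_covariate_mostly_ns(self, small_cohort):
        expr, covariate = small_cohort
        cov = covariate.set_index("sample_id")["leukocyte_fraction"]
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(cov.to_numpy()), index=cov.index)
        res = tf.correlate_genes(expr, perm)
        background = res[res["gene"].str.startswith("GENE")]
        assert (background["class"] == "ns").mean() >= 0.9

    def test_empty_gene_set_gives_empty_table(self, small_cohort):
        expr, covariate = small_cohort
        cov = covariate.set_index("sample_id")["leukocyte_fraction"]
        assert tf.correlate_genes(expr, cov, gene_set=[]).empty

    def test_sample_mismatch_reported(self, small_cohort):
        expr, covariate = small_cohort
        cov = covariate.set_index("sample_id")["leukocyte_fraction"].iloc[:-5]
        with pytest.raises(DataError, match="mismatch"):
            tf.correlate_genes(expr, cov)

    def test_ordered_by_absolute_r(self, small_cohort):
        expr, covariate = small_cohort
        cov = covariate.set_index("sample_id")["leukocyte_fraction"]
        res = tf.correlate_genes(expr, cov)
        r = res["r"].abs().to_numpy()
        assert np.all(np.diff(r) <= 1e-12)


class TestClassifyDE:
    def test_single_strong_gene_is_up(self):
        table = pd.DataFrame({"gene": ["A"], "log2fc": [3.0], "pvalue": [1e-6]})
        assert tf.classify_de(table)["class"].iloc[0] == "up"

    def test_fold_change_gate_blocks_significant_p(self):
        table = pd.DataFrame({"gene": ["A"], "log2fc": [1.5], "pvalue": [1e-9]})
        assert tf.classify_de(table)["class"].iloc[0] == "not_significant"

    def test_bh_then_gates_matches_oracle_counts(self):
        # 10 genes, p_i = 0.0005 * i: BH-adjusted p = 0.005 for every gene
        # (step-up minimum), below alpha; alternating log2fc signs split
        # the table 5 up / 5 down.
        p = [0.0005 * i for i in range(1, 11)]
        lfc = [3.0 if i % 2 == 0 else -3.0 for i in range(10)]
        table = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(10)], "log2fc": lfc, "pvalue": p}
        )
        out = tf.classify_de(table)
        assert np.allclose(out["padj"], 0.005)
        counts = out["class"].value_counts()
        assert counts["up"] == 5 and counts["down"] == 5

    def test_counts_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(30)],
                "log2fc": rng.normal(0, 3, 30),
                "pvalue": rng.uniform(size=30),
            }
        )
        a = tf.classify_de(table)["class"].value_counts().to_dict()
        shuffled = table.sample(frac=1.0, random_state=2)
        b = tf.classify_de(shuffled)["class"].value_counts().to_dict()
        assert a == b

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame(
            {"gene": ["A", "A"], "log2fc": [3.0, 3.0], "pvalue": [0.1, 0.2]}
        )
        with pytest.raises(ValidationError):
            tf.classify_de(table)


class TestZConversions:
    def test_anchor_values(self):
        assert tf.z_to_p(0.0) == pytest.approx(0.5)
        # the survival-Z significance anchor: 3.09 <-> one-sided p 0.001
        assert tf.z_to_p(3.09) == pytest.approx(0.001, abs=5e-5)
        assert tf.p_to_z(0.001) == pytest.approx(3.09, abs=5e-3)

    @pytest.mark.parametrize("x", [-2.0, 0.0, 1.5])
    def test_mutually_inverse(self, x):
        assert tf.p_to_z(tf.z_to_p(x)) == pytest.approx(x, abs=1e-10)

    def test_strictly_decreasing(self):
        z = np.linspace(-4, 4, 100)
        p = [tf.z_to_p(v) for v in z]
        assert np.all(np.diff(p) < 0)

    def test_p_domain_checked(self):
        with pytest.raises(DomainError):
            tf.p_to_z(0.0)


class TestClassifyPrognostic:
    def test_threshold_classification(self):
        table = pd.DataFrame({"gene": ["A", "B", "C"], "zscore": [3.2, -3.2, 0.0]})
        out = tf.classify_prognostic(table).set_index("gene")["class"]
        assert out["A"] == "detrimental"
        assert out["B"] == "beneficial"
        assert out["C"] == "neutral"

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(200)],
             "zscore": rng.normal(0, 2.5, 200)}
        )
        out = tf.classify_prognostic(table)
        assert set(out["class"]) <= {"detrimental", "beneficial", "neutral"}
        assert len(out) == 200
        for _, row in out.iterrows():
            n_true = sum(
                [row["zscore"] > 3.09, row["zscore"] < -3.09,
                 abs(row["zscore"]) <= 3.09]
            )
            assert n_true == 1

    def test_non_numeric_rejected(self):
        table = pd.DataFrame({"gene": ["A"], "zscore": ["high"]})
        with pytest.raises(ValidationError):
            tf.classify_prognostic(table)


class TestPCA:
    def test_rank_one_matrix(self):
        g = np.outer([1.0, 2.0, 3.0], [1.0, 4.0, 2.0, 0.5])
        expr = tf.ExpressionMatrix(pd.DataFrame(g, index=["A", "B", "C"]))
        frac = tf.pca_variance_explained(expr)
        assert frac[0] == pytest.approx(1.0)

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(6)
        k = 50
        data = np.abs(rng.standard_normal((k, 1000))) + 5.0
        expr = tf.ExpressionMatrix(
            pd.DataFrame(data, index=[f"G{i}" for i in range(k)])
        )
        frac = tf.pca_variance_explained(expr)
        assert frac[0] < 2.0 / k
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_needs_two_samples(self):
        expr = tf.ExpressionMatrix(pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"]))
        with pytest.raises(DataError):
            tf.pca_variance_explained(expr)


class TestClusterRows:
    def test_row_zscore_normalizes(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(5, 2, (4, 10)))
        z = row_zscore(df)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.to_numpy().std(axis=1), 1.0, atol=1e-12)

    def test_identical_rows_merge_first(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 1.0, 0.0]],
            index=["A", "B", "C"],
        )
        # A and B are identical after z-scoring: first merge at distance 0
        res = tf.cluster_rows(df)
        assert isinstance(res, ClusterResult)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {res.row_order.index("A"), res.row_order.index("B")}
        assert first in ({0, 1}, {1, 2})

    def test_blocks_cluster_together(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 12)
        up = [t + rng.normal(0, 0.05, 12) for _ in range(4)]
        down = [-t + rng.normal(0, 0.05, 12) for _ in range(4)]
        df = pd.DataFrame(
            up + down, index=[f"U{i}" for i in range(4)] + [f"D{i}" for i in range(4)]
        )
        order = tf.cluster_rows(df).row_order
        labels = [g[0] for g in order]
        assert labels in (["U"] * 4 + ["D"] * 4, ["D"] * 4 + ["U"] * 4)

    def test_constant_rows_dropped_with_report(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["FLAT", "A", "B"],
        )
        res = tf.cluster_rows(df)
        assert res.dropped_rows == ["FLAT"]
        assert "FLAT" not in res.row_order

    def test_all_constant_rejected(self):
        df = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], index=["A", "B"])
        with pytest.raises(DataError):
            tf.cluster_rows(df)
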