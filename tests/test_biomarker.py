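"""Expression preprocessing, Spearman associations, leave-one-out robustness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from dsrt import biomarker as bm
from dsrt import synthdata as sd


def matrix(values, genes=None, samples=None, stage=bm.STAGE_RAW):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return bm.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                               stage=stage)


class TestPreprocess:
    def test_dedup_keeps_highest_sd_row(self):
        df = pd.DataFrame([[0, 5, 10], [4, 4.1, 4.2]],
                          index=["GENE", "GENE"], columns=list("abc"))
        kept = bm.dedup_genes(df)
        assert len(kept) == 1
        assert kept.iloc[0].tolist() == [0, 5, 10]

    def test_quantile_normalization_hand_worked(self):
        # columns [5,2,3] and [4,1,2]; sorted means give ref [1.5, 2.5, 4.5]
        m = matrix([[5, 4], [2, 1], [3, 2]])
        out = bm.quantile_normalize(m.values)
        expected = np.array([[4.5, 4.5], [1.5, 1.5], [2.5, 2.5]])
        assert np.allclose(out.to_numpy(), expected)

    def test_quantile_normalization_tie_handling(self):
        # tie in column a spans reference quantiles 1.5 and 2.5 -> both get 2.0
        m = matrix([[1, 2], [1, 5], [3, 4]])
        out = bm.quantile_normalize(m.values)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        assert out["s0"].tolist() == [(ref[0] + ref[1]) / 2,
                                      (ref[0] + ref[1]) / 2, ref[2]]

    def test_identical_columns_fixed_point(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        m = matrix(np.column_stack([col, col, col]))
        out = bm.quantile_normalize(m.values)
        assert np.allclose(out.to_numpy(), m.values.to_numpy())

    def test_column_distributions_identical_after_qn(self):
        rng = np.random.default_rng(1)
        m = matrix(rng.lognormal(1, 1, size=(30, 4)))
        out = bm.quantile_normalize(m.values).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_full_preprocess_stage_and_log(self):
        m = matrix([[10, 10], [1, 1], [100, 100]])
        out = bm.preprocess_expression(m)
        assert out.stage == bm.STAGE_LOG
        assert np.allclose(out.values.to_numpy(),
                           np.log10(m.values.to_numpy() + 1e-5))

    def test_negative_fpkm_rejected(self):
        with pytest.raises(bm.BiomarkerError):
            bm.preprocess_expression(matrix([[1, -2], [3, 4]]))


class TestFilterExpressed:
    def test_below_floor_everywhere_dropped(self):
        m = matrix([[9.9] * 13, [9.9] * 12 + [10.1]])
        out = bm.filter_expressed(m)
        assert out.values.index.tolist() == ["g1"]

    def test_floor_zero_identity(self):
        m = matrix([[0.5, 3], [9, 1]])
        assert bm.filter_expressed(m, floor=0.0).values.equals(m.values)


class TestCorrelate:
    def make_processed(self, X, samples=None):
        return matrix(X, samples=samples, stage=bm.STAGE_LOG)

    def test_monotone_function_gives_unit_rho(self):
        y = pd.Series(np.arange(13.0), index=[f"s{j}" for j in range(13)])
        m = self.make_processed([np.exp(np.arange(13.0))])
        assoc = bm.correlate_gene_drug(m, y)
        assert assoc.rho.iloc[0] == pytest.approx(1.0)
        assert assoc.p_value.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert assoc.direction.iloc[0] == "resistance"

    def test_reversed_response_negates_rho(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 10))
        y = pd.Series(rng.normal(size=10), index=[f"s{j}" for j in range(10)])
        m = self.make_processed(X)
        a = bm.correlate_gene_drug(m, y)
        b = bm.correlate_gene_drug(m, -y)
        assert np.allclose(a.rho, -b.rho)
        assert np.allclose(a.p_value, b.p_value)

    def test_matches_scipy_per_gene(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 13))
        X[3] = np.round(X[3])  # introduce ties
        y = pd.Series(rng.normal(size=13), index=[f"s{j}" for j in range(13)])
        m = self.make_processed(X)
        assoc = bm.correlate_gene_drug(m, y)
        for i in range(20):
            rho, p = stats.spearmanr(X[i], y.to_numpy())
            assert assoc.rho.iloc[i] == pytest.approx(rho, abs=1e-12)
            assert assoc.p_value.iloc[i] == pytest.approx(p, abs=1e-10)

    def test_t_approximation_close_to_exact_permutation_at_n6(self):
        """The t-based p stays within a small tolerance of the exact null at n=6."""
        X = np.array([[0.2, 1.0, 0.5, 1.4, 0.9, 0.1],
                      [1.0, 2.0, 3.0, 4.0, 5.0, 5.5]])
        yv = np.array([3.0, 1.0, 2.5, 0.5, 1.5, 2.8])
        m = self.make_processed(X)
        y = pd.Series(yv, index=m.values.columns)
        assoc = bm.correlate_gene_drug(m, y)
        ry = stats.rankdata(yv)
        for i in range(2):
            obs = abs(stats.spearmanr(X[i], yv).statistic)
            rx = stats.rankdata(X[i])
            null = [abs(stats.spearmanr(rx, perm).statistic)
                    for perm in itertools.permutations(ry)]
            p_exact = np.mean(np.array(null) >= obs - 1e-12)
            assert abs(assoc.p_value.iloc[i] - p_exact) < 0.1

    @given(st.sampled_from(["exp", "cube", "logit"]))
    def test_invariant_under_monotone_transforms(self, kind):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 9))
        y = pd.Series(rng.uniform(0.1, 0.9, 9), index=[f"s{j}" for j in range(9)])
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "logit": lambda v: np.log(v / (1 - v))}[kind]
        a = bm.correlate_gene_drug(self.make_processed(X), y)
        b = bm.correlate_gene_drug(self.make_processed(X), f(y))
        assert np.allclose(a.rho, b.rho)

    def test_constant_gene_recorded_not_dropped(self):
        m = self.make_processed([[1.0] * 8, list(range(8))])
        y = pd.Series(np.arange(8.0), index=m.values.columns)
        assoc = bm.correlate_gene_drug(m, y)
        assert np.isnan(assoc.rho.iloc[0])
        assert assoc.skip_reason.iloc[0] is not None
        assert not assoc.passes_single.iloc[0]

    def test_too_few_shared_samples(self):
        m = self.make_processed(np.zeros((2, 3)))
        y = pd.Series([1.0, 2.0, 3.0], index=m.values.columns)
        with pytest.raises(bm.BiomarkerError):
            bm.correlate_gene_drug(m, y)


class TestLeaveOneOut:
    def test_planted_monotone_biomarker_selected(self):
        n = 13
        samples = [f"s{j}" for j in range(n)]
        y = pd.Series(np.arange(float(n)), index=samples)
        m = matrix([np.arange(float(n)), -np.arange(float(n))],
                   samples=samples, stage=bm.STAGE_LOG)
        out = bm.loo_robust_biomarkers(m, y)
        assert out.passes_loo.all()
        assert out.min_abs_rho.iloc[0] == pytest.approx(1.0)

    def test_outlier_driven_gene_fails(self):
        """A gene flat in 12 lines and extreme in one fails the fold dropping it."""
        n = 13
        samples = [f"s{j}" for j in range(n)]
        y = pd.Series(np.arange(float(n)), index=samples)
        gene = np.zeros(n)
        gene[-1] = 5.0  # aligns with the largest response value
        m = matrix([gene], samples=samples, stage=bm.STAGE_LOG)
        out = bm.loo_robust_biomarkers(m, y)
        assert not out.passes_loo.iloc[0]

    def test_sign_flip_across_folds_fails(self):
        n = 8
        samples = [f"s{j}" for j in range(n)]
        y = pd.Series(np.arange(float(n)), index=samples)
        rng = np.random.default_rng(6)
        m = matrix(rng.normal(size=(5, n)), samples=samples, stage=bm.STAGE_LOG)
        out = bm.loo_robust_biomarkers(m, y, rho_fold=0.0)
        flagged = out[out.passes_loo]
        for _, row in flagged.iterrows():
            assert row.rho_fold_min * row.rho_fold_max > 0

    def test_null_background_rarely_selected(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = [f"s{j}" for j in range(13)]
            y = pd.Series(rng.normal(size=13), index=samples)
            m = matrix(rng.normal(size=(1000, 13)), samples=samples,
                       stage=bm.STAGE_LOG)
            out = bm.loo_robust_biomarkers(m, y)
            counts.append(int(out.passes_loo.sum()))
        assert np.mean(counts) < 0.5

    def test_needs_five_samples(self):
        m = matrix(np.zeros((2, 4)), stage=bm.STAGE_LOG)
        y = pd.Series(np.arange(4.0), index=m.values.columns)
        with pytest.raises(bm.BiomarkerError):
            bm.loo_robust_biomarkers(m, y)
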