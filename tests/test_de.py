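import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexbias import de
from sexbias.datatypes import CountMatrix
from sexbias.synth import CohortConfig, generate_bulk


def _cm(array, features=None, samples=None):
    array = np.asarray(array)
    features = features or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{i}" for i in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=features, columns=samples))


# ---------------------------------------------------------------------------
# filter_low_expression
# ---------------------------------------------------------------------------

class TestFilter:
    def test_all_zero_feature_removed(self):
        cm = _cm([[0, 0, 0], [5, 5, 5]])
        out = de.filter_low_expression(cm, min_count=1, min_fraction=0.1)
        assert list(out.feature_ids) == ["g1"]

    def test_boundary_feature_retained(self):
        # counts >= 10 in exactly half the samples at min_fraction 0.5
        cm = _cm([[10, 10, 0, 0]])
        out = de.filter_low_expression(cm, min_count=10, min_fraction=0.5)
        assert list(out.feature_ids) == ["g0"]

    def test_min_count_zero_is_identity(self, tiny_counts):
        out = de.filter_low_expression(tiny_counts, min_count=0, min_fraction=1.0)
        pd.testing.assert_frame_equal(out.counts, tiny_counts.counts)

    def test_order_preserved(self):
        cm = _cm([[20, 20], [0, 0], [30, 30], [15, 15]])
        out = de.filter_low_expression(cm, min_count=10, min_fraction=1.0)
        assert list(out.feature_ids) == ["g0", "g2", "g3"]

    def test_empty_result_warns(self):
        cm = _cm([[1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="removed every feature"):
            out = de.filter_low_expression(cm, min_count=100, min_fraction=0.5)
        assert out.shape[0] == 0


# ---------------------------------------------------------------------------
# size_factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _cm([[5, 5, 5], [9, 9, 9]])
        np.testing.assert_allclose(de.size_factors(cm), 1.0)

    def test_doubled_column_hand_value(self):
        # B = 2*A exactly: factors (1/sqrt(2), sqrt(2)) by median-of-ratios
        cm = _cm([[4, 8], [10, 20], [6, 12]])
        np.testing.assert_allclose(
            de.size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_single_sample_factor_one(self):
        cm = _cm([[5], [7]])
        np.testing.assert_allclose(de.size_factors(cm), 1.0)

    def test_no_ubiquitous_feature_errors(self):
        cm = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="stricter low-expression filter"):
            de.size_factors(cm)


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------

class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.04, 0.03, 0.002]),
            [0.02, 0.04, 0.04, 0.008])

    def test_ties_all_equal(self):
        np.testing.assert_allclose(de.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_single_p(self):
        np.testing.assert_allclose(de.bh_adjust([0.2]), [0.2])

    def test_nan_excluded_from_family(self):
        out = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], de.bh_adjust([0.01, 0.04]))

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert (de.bh_adjust(p) >= p - 1e-15).all()

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_statsmodels_oracle(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(de.bh_adjust(pvals), expected, atol=1e-12)

    def test_thousand_random_vectors_match_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(
                de.bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                atol=1e-12)


# ---------------------------------------------------------------------------
# call_significance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "padj,log2fc,expected_sig,expected_dir",
    [
        (0.04, 0.60, True, "male_biased"),
        (0.04, 0.50, False, "none"),
        (0.05, 2.00, False, "none"),     # strict inequality on padj
        (0.04, 0.58, False, "none"),     # strict inequality on lfc
        (0.01, -0.90, True, "female_biased"),
    ],
)
def test_call_significance(padj, log2fc, expected_sig, expected_dir):
    res = pd.DataFrame({"padj": [padj], "log2fc": [log2fc]})
    out = de.call_significance(res)
    assert bool(out["significant"].iloc[0]) is expected_sig
    assert out["direction"].iloc[0] == expected_dir


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

class TestDesign:
    def _samples(self):
        return pd.DataFrame({
            "sex": ["male", "male", "female", "female"],
            "tissue": "tumor",
            "age": [60, 70, 65, 55],
            "stage": [1, 2, 2, 3],
        }, index=pd.Index(list("abcd"), name="sample_id"))

    def test_sex_coding_male_one(self):
        X = de.design_matrix(self._samples())
        np.testing.assert_array_equal(X["sex"], [1, 1, 0, 0])

    def test_collinear_covariate_named(self):
        samples = self._samples()
        samples["sexcopy"] = (samples["sex"] == "male").astype(int)
        with pytest.raises(ValueError, match="sexcopy"):
            de.design_matrix(samples, covariates=["sexcopy"])

    def test_ordinal_categorical_encoding(self):
        samples = self._samples()
        samples["grade"] = pd.Categorical(["G1", "G3", "G2", "G1"])
        X = de.design_matrix(samples, covariates=["grade"])
        np.testing.assert_array_equal(X["grade"], [0, 2, 1, 0])

    def test_missing_covariate_errors(self):
        with pytest.raises(ValueError, match="not in sample sheet"):
            de.design_matrix(self._samples(), covariates=["bmi"])


# ---------------------------------------------------------------------------
# nb_wald
# ---------------------------------------------------------------------------

def _null_cohort(seed, n=30, n_genes=40):
    cfg = CohortConfig(seed=seed, n_male_tumor=n, n_female_tumor=n,
                       frac_sex_biased_tumor=0.0, frac_sex_biased_normal=0.0,
                       n_planted_pairs=0, n_genes=n_genes)
    mrna, _, samples, _ = generate_bulk(cfg)
    tumor = samples[samples["tissue"] == "tumor"]
    return mrna.subset_samples(tumor.index), tumor


class TestNBWald:
    def test_null_log2fc_near_zero(self):
        cm, samples = _null_cohort(0, n=60, n_genes=50)
        res = de.nb_wald(cm, samples)
        assert res["log2fc"].abs().median() < 0.2
        # p roughly uniform: between 1% and 15% below 0.05 on 50 features
        assert (res["p"] < 0.05).mean() < 0.15

    def test_poisson_limit_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        cfg = CohortConfig(seed=5, n_male_tumor=15, n_female_tumor=15,
                           n_genes=20, n_planted_pairs=0, nb_dispersion=0.05)
        mrna, _, samples, _ = generate_bulk(cfg)
        tumor = samples[samples["tissue"] == "tumor"]
        cm = mrna.subset_samples(tumor.index)
        res = de.nb_wald(cm, tumor, dispersions=1e-10)
        sf = de.size_factors(cm).to_numpy()
        X = de.design_matrix(tumor).to_numpy()
        for i in range(cm.shape[0]):
            fit = sm.GLM(cm.counts.iloc[i].to_numpy(float), X,
                         family=sm.families.Poisson(),
                         offset=np.log(sf)).fit()
            oracle = fit.params[1] / fit.bse[1]
            assert res["wald_stat"].iloc[i] == pytest.approx(oracle, rel=1e-3)

    def test_depth_invariance_under_doubling(self):
        # size factors absorb depth: exact in the Poisson limit, approximate
        # once the NB variance term is active
        cm, samples = _null_cohort(3, n=25, n_genes=50)
        doubled = CountMatrix(cm.counts * 2, cm.annotation)
        res = de.nb_wald(cm, samples, dispersions=1e-10)
        res2 = de.nb_wald(doubled, samples, dispersions=1e-10)
        np.testing.assert_allclose(res["log2fc"], res2["log2fc"], atol=1e-6)
        res = de.nb_wald(cm, samples, dispersions=0.1)
        res2 = de.nb_wald(doubled, samples, dispersions=0.1)
        np.testing.assert_allclose(res["log2fc"], res2["log2fc"], atol=0.05)

    def test_log2fc_antisymmetry(self):
        cm, samples = _null_cohort(4)
        a = de.nb_wald(cm, samples, reference_sex="female")
        b = de.nb_wald(cm, samples, reference_sex="male")
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-9)

    def test_planted_effect_recovery(self):
        cfg = CohortConfig(seed=9, n_male_tumor=100, n_female_tumor=100,
                           frac_sex_biased_tumor=0.2, n_genes=100,
                           n_planted_pairs=0, effect_log2fc=1.5,
                           nb_dispersion=0.1)
        mrna, _, samples, truth = generate_bulk(cfg)
        tumor = samples[samples["tissue"] == "tumor"]
        res = de.nb_wald(mrna.subset_samples(tumor.index), tumor)
        planted = truth.biased_features("mrna", "tumor").set_index("feature")
        hits = res.loc[planted.index]
        assert hits["significant"].mean() >= 0.9
        assert (np.sign(hits["log2fc"]) ==
                np.sign(planted["log2fc"])).mean() >= 0.95

    def test_covariates_accepted(self):
        cm, samples = _null_cohort(6)
        res = de.nb_wald(cm, samples, covariates=["age", "stage", "grade"])
        assert res["converged"].all()

    def test_type_one_error_envelope(self):
        # pooled across 10 seeds for both nominal alphas
        pvals = []
        for seed in range(10):
            cm, samples = _null_cohort(seed, n=50, n_genes=200)
            pvals.append(de.nb_wald(cm, samples)["p"].dropna().to_numpy())
        p = np.concatenate(pvals)
        for alpha in (0.01, 0.05):
            half = 1.96 * np.sqrt(alpha * (1 - alpha) / p.size)
            assert abs((p < alpha).mean() - alpha) <= half


# ---------------------------------------------------------------------------
# pca_qc
# ---------------------------------------------------------------------------

class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        block = rng.poisson(40, size=(20, 3))
        cm = _cm(np.hstack([block, block]))
        scores, _ = de.pca_qc(cm)
        np.testing.assert_allclose(scores.iloc[:3].to_numpy(),
                                   scores.iloc[3:].to_numpy(), atol=1e-8)

    def test_two_batches_separate_on_pc1(self):
        # batches differ in expression profile, not just depth (which the
        # size factors would absorb)
        rng = np.random.default_rng(3)
        mean_a = rng.uniform(10, 100, size=30)
        mean_b = mean_a.copy()
        mean_b[:15] = mean_b[:15] * 8  # half the genes shifted in batch B
        a = rng.poisson(mean_a[:, None], size=(30, 6))
        b = rng.poisson(mean_b[:, None], size=(30, 6))
        cm = _cm(np.hstack([a, b]))
        scores, _ = de.pca_qc(cm)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:6] < pc1[6:].min()).all() or (pc1[:6] > pc1[6:].max()).all()

    def test_variance_fractions_valid(self, tiny_counts):
        _, frac = de.pca_qc(tiny_counts, n_components=5)
        assert frac.sum() <= 1 + 1e-12
        assert (np.diff(frac) <= 1e-12).all()

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 3 samples"):
            de.pca_qc(_cm([[1, 2], [3, 4]]))
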