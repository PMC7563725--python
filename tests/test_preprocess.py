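"""Merging, scaling, batch correction and PCA QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_matrix
from coexfeat.containers import ExpressionMatrix, ValidationError
from coexfeat.preprocess import (
    BatchCorrector,
    batch_f_test,
    correct_batch,
    log2_if_needed,
    merge_datasets,
    pca_qc,
    standardize,
)


def _dataset(values, genes, samples, batch):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(batch, index=samples),
        pd.Series([0] * (len(samples) // 2) + [1] * (len(samples) - len(samples) // 2),
                  index=samples),
    )


class TestMerge:
    def test_duplicate_probes_collapse_to_median(self):
        d = _dataset(
            [[2.0, 1.0], [4.0, 5.0], [6.0, 9.0]],
            ["TP53", "TP53", "TP53"],
            ["a", "b"],
            ["B1", "B1"],
        )
        merged = merge_datasets([d])
        assert merged.values.loc["TP53", "a"] == 4.0
        assert merged.values.loc["TP53", "b"] == 5.0

    def test_single_input_with_unique_symbols_is_identity(self):
        d = _dataset(np.arange(6.0).reshape(3, 2), ["g1", "g2", "g3"], ["a", "b"], ["B1"] * 2)
        merged = merge_datasets([d])
        pd.testing.assert_frame_equal(merged.values, d.values.sort_index())

    def test_intersection_and_concatenation(self):
        d1 = _dataset([[1.0, 2.0], [3.0, 4.0]], ["g1", "g2"], ["a", "b"], ["B1"] * 2)
        d2 = _dataset([[5.0, 6.0], [7.0, 8.0]], ["g2", "g3"], ["c", "d"], ["B2"] * 2)
        merged = merge_datasets([d1, d2])
        assert list(merged.gene_ids) == ["g2"]
        assert list(merged.sample_ids) == ["a", "b", "c", "d"]
        assert list(merged.batch) == ["B1", "B1", "B2", "B2"]

    def test_disjoint_gene_sets_raise(self):
        d1 = _dataset([[1.0, 2.0]], ["g1"], ["a", "b"], ["B1"] * 2)
        d2 = _dataset([[1.0, 2.0]], ["g2"], ["c", "d"], ["B2"] * 2)
        with pytest.raises(ValidationError, match="intersection"):
            merge_datasets([d1, d2])

    def test_duplicate_sample_ids_raise(self):
        d1 = _dataset([[1.0, 2.0]], ["g1"], ["a", "b"], ["B1"] * 2)
        d2 = _dataset([[1.0, 2.0]], ["g1"], ["a", "c"], ["B2"] * 2)
        with pytest.raises(ValidationError, match="duplicate sample"):
            merge_datasets([d1, d2])


class TestLog2:
    def test_log_scale_batch_unchanged(self):
        d = _dataset([[15.8, 3.0], [7.0, 9.0]], ["g1", "g2"], ["a", "b"], ["B1"] * 2)
        out = log2_if_needed(d)
        pd.testing.assert_frame_equal(out.values, d.values)

    def test_linear_scale_batch_transformed_and_1023_maps_to_10(self):
        d = _dataset([[20000.0, 1023.0]], ["g1"], ["a", "b"], ["B1"] * 2)
        out = log2_if_needed(d)
        assert out.values.loc["g1", "b"] == pytest.approx(10.0)

    def test_negative_values_in_linear_batch_raise(self):
        d = _dataset([[20000.0, -1.0]], ["g1"], ["a", "b"], ["B1"] * 2)
        with pytest.raises(ValidationError, match="negative"):
            log2_if_needed(d)


class TestStandardize:
    def test_symmetric_row_with_sample_sd(self):
        m = toy_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 6.0]])
        out = standardize(m)
        np.testing.assert_allclose(out.values.loc["g0"], [-1.0, 0.0, 1.0])

    def test_constant_rows_dropped(self):
        m = toy_matrix([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        out = standardize(m)
        assert list(out.gene_ids) == ["g0"]

    def test_postcondition_mean_zero_sd_one(self, study):
        matrix, _ = study
        out = standardize(matrix)
        vals = out.values.to_numpy()
        assert np.abs(vals.mean(axis=1)).max() < 1e-12
        assert np.abs(vals.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_all_constant_raises(self):
        m = toy_matrix([[1.0, 1.0, 1.0]])
        with pytest.raises(ValidationError):
            standardize(m)


class TestCorrectBatch:
    def test_pure_location_shift_recovered_exactly(self):
        # batch-free data with exactly equal per-gene batch means; shifts with
        # (size-weighted) zero mean are removed exactly in the
        # no-shrinkage, location-only configuration
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, size=(20, 12))
        base[:, :6] -= base[:, :6].mean(axis=1, keepdims=True)
        base[:, 6:] -= base[:, 6:].mean(axis=1, keepdims=True)
        shift = rng.normal(0, 2, size=(20, 1))
        x = base.copy()
        x[:, :6] += shift
        x[:, 6:] -= shift
        m = toy_matrix(x, batch=["A"] * 6 + ["B"] * 6, phenotype=[0, 1] * 6)
        out = correct_batch(m, no_eb=True, mean_only=True, protect_phenotype=False)
        np.testing.assert_allclose(out.values.to_numpy(), base, atol=1e-10)

    def test_batch_means_equalised_after_correction(self):
        rng = np.random.default_rng(1)
        x = rng.normal(5, 1, size=(30, 20))
        x[:, 10:] += rng.normal(0, 3, size=(30, 1))  # constant shift per gene
        m = toy_matrix(x, batch=["A"] * 10 + ["B"] * 10, phenotype=[0, 1] * 10)
        out = correct_batch(m, no_eb=True)
        v = out.values.to_numpy()
        np.testing.assert_allclose(v[:, :10].mean(axis=1), v[:, 10:].mean(axis=1), atol=1e-8)

    def test_single_batch_raises(self):
        m = toy_matrix(np.random.default_rng(2).normal(size=(5, 6)))
        with pytest.raises(ValidationError, match="batches"):
            correct_batch(m)

    def test_batch_with_one_sample_raises(self):
        rng = np.random.default_rng(3)
        m = toy_matrix(rng.normal(size=(5, 5)), batch=["A"] * 4 + ["B"],
                       phenotype=[0, 0, 1, 1, 1])
        with pytest.raises(ValidationError, match="B"):
            correct_batch(m)

    def test_shape_and_gene_moments_preserved_approximately(self, study):
        matrix, _ = study
        out = correct_batch(matrix)
        assert out.values.shape == matrix.values.shape
        before = matrix.values.mean(axis=1)
        after = out.values.mean(axis=1)
        np.testing.assert_allclose(after, before, atol=0.05)

    def test_batch_f_test_signal_removed(self, study):
        matrix, _ = study
        frac_pre = (batch_f_test(matrix) < 0.05).mean()
        frac_post = (batch_f_test(correct_batch(matrix)) < 0.05).mean()
        assert frac_pre > 0.5
        assert frac_post < 0.1

    def test_matches_scanpy_combat_cross_check(self):
        """Independent route: scanpy's parametric ComBat on the same small
        matrix (no covariate protection, since scanpy's default corrects
        without one here)."""
        import anndata
        import scanpy

        rng = np.random.default_rng(4)
        x = rng.normal(6, 1, size=(40, 30))
        x[:, 15:] += rng.normal(0.0, 1.0, size=(40, 1))
        x[:, 15:] *= 1.3
        m = toy_matrix(x, batch=["A"] * 15 + ["B"] * 15, phenotype=[0, 1] * 15)
        ours = correct_batch(m, protect_phenotype=False).values.to_numpy()
        ad = anndata.AnnData(
            X=x.T.copy(), obs=pd.DataFrame({"batch": ["A"] * 15 + ["B"] * 15},
                                           index=[f"s{j}" for j in range(30)])
        )
        scanpy.pp.combat(ad, key="batch")
        theirs = ad.X.T
        assert np.abs(ours - theirs).max() < 0.05
        assert np.corrcoef(ours.ravel(), theirs.ravel())[0, 1] > 0.9999

    def test_held_out_batch_correction_ignores_test_data_for_fit(self):
        rng = np.random.default_rng(5)
        x = rng.normal(6, 1, size=(25, 30))
        m = toy_matrix(x, batch=["A"] * 10 + ["B"] * 10 + ["C"] * 10,
                       phenotype=[0, 1] * 15)
        train = m.subset_samples([s for s in m.sample_ids if m.batch[s] != "C"])
        test = m.subset_samples([s for s in m.sample_ids if m.batch[s] == "C"])
        bc = BatchCorrector()
        bc.fit_transform(train)
        out1 = bc.transform_new_batch(test)
        # perturbing the held-out batch must not alter the fitted state
        mean_before = bc.grand_mean_.copy()
        test2 = ExpressionMatrix(test.values + 0.5, test.batch, test.phenotype)
        bc.transform_new_batch(test2)
        np.testing.assert_array_equal(bc.grand_mean_, mean_before)
        assert out1.values.shape == test.values.shape


class TestPcaQc:
    def test_duplicated_samples_have_identical_scores(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 4))
        x = np.hstack([x, x[:, :1]])  # duplicate first sample
        m = toy_matrix(x, phenotype=[0, 0, 1, 1, 0])
        scores = pca_qc(m, n_components=2)
        np.testing.assert_allclose(
            scores.iloc[0][["PC1", "PC2"]].astype(float),
            scores.iloc[4][["PC1", "PC2"]].astype(float),
            atol=1e-10,
        )

    def test_explained_variance_fractions_valid(self, study):
        matrix, _ = study
        scores = pca_qc(matrix, n_components=5)
        evr = scores.attrs["explained_variance_ratio"]
        assert evr.sum() <= 1 + 1e-12
        assert (np.diff(evr) <= 1e-12).all()

    def test_batch_separation_visible_pre_and_gone_post(self, study, corrected_study):
        matrix, _ = study
        corrected, _ = corrected_study

        def centroid_accuracy(m):
            scores = pca_qc(m, n_components=2)
            pcs = scores[["PC1", "PC2"]].to_numpy(dtype=float)
            batches = scores["batch"].to_numpy()
            cents = {b: pcs[batches == b].mean(axis=0) for b in np.unique(batches)}
            pred = [
                min(cents, key=lambda b: np.linalg.norm(p - cents[b])) for p in pcs
            ]
            return (np.array(pred) == batches).mean()

        chance = 1.0 / matrix.batch.nunique()
        assert centroid_accuracy(matrix) > chance + 0.2
        assert centroid_accuracy(corrected) < chance + 0.2

    def test_too_many_components_raise(self):
        m = toy_matrix(np.random.default_rng(7).normal(size=(5, 4)))
        with pytest.raises(ValidationError):
            pca_qc(m, n_components=6)
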