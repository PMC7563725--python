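"""Network construction: soft threshold, TOM, modules, eigengenes, trait."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import toy_matrix
from coexfeat.containers import ValidationError
from coexfeat.network import (
    adjacency_matrix,
    build_network,
    compute_tom,
    detect_modules,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    scale_free_fit,
    scan_soft_thresholds,
    select_key_module,
    select_power,
)


def tom_oracle(a):
    """Triple-loop brute force of the topological overlap."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a0[i, u] * a0[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return tom


sym_adjacency = st.integers(min_value=2, max_value=8).flatmap(
    lambda n: st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=n * (n - 1) // 2,
        max_size=n * (n - 1) // 2,
    ).map(
        lambda vals: _to_sym(n, vals)
    )
)


def _to_sym(n, vals):
    a = np.eye(n)
    iu = np.triu_indices(n, 1)
    a[iu] = vals
    a[(iu[1], iu[0])] = vals
    return a


class TestTom:
    def test_complete_graph_gives_all_ones(self):
        a = np.ones((5, 5))
        np.testing.assert_allclose(compute_tom(a), np.ones((5, 5)))

    def test_empty_graph_gives_zero_overlap(self):
        a = np.eye(6)
        tom = compute_tom(a)
        assert np.allclose(tom - np.eye(6), 0.0)

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.uniform(0, 1, size=(6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            np.testing.assert_allclose(compute_tom(a), tom_oracle(a), atol=1e-12)

    @given(sym_adjacency)
    def test_oracle_equivalence_property(self, a):
        tom = compute_tom(a)
        np.testing.assert_allclose(tom, tom_oracle(a), atol=1e-10)
        assert tom.min() >= -1e-12 and tom.max() <= 1 + 1e-12
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)

    def test_asymmetric_raises(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValidationError, match="symmetric"):
            compute_tom(a)


class TestSoftThreshold:
    def test_power_law_degrees_fit_perfectly(self):
        # exact discrete power law p(k) ~ k^-gamma: R^2 ~ 1, slope ~ -gamma
        gamma = 2.0
        ks = np.arange(1, 101, dtype=float)
        weights = ks ** (-gamma)
        counts = np.round(weights / weights.min()).astype(int)
        k = np.repeat(ks, counts)
        r2, slope, trunc = scale_free_fit(k, n_bins=10)
        assert r2 > 0.97
        assert slope == pytest.approx(-gamma, abs=0.35)

    def test_power_one_equals_abs_correlation(self, corrected_study):
        matrix, _ = corrected_study
        sub = matrix.subset_genes(matrix.gene_ids[:50])
        cor = np.corrcoef(sub.values.to_numpy())
        a = adjacency_matrix(cor, 1.0)
        np.testing.assert_allclose(a, np.abs(cor))

    def test_mean_connectivity_decreases_with_power(self, corrected_study):
        matrix, _ = corrected_study
        sub = matrix.subset_genes(matrix.gene_ids[:300])
        scan = scan_soft_thresholds(sub, powers=(1, 2, 4, 8))
        assert (np.diff(scan["mean.k"]) < 0).all()
        assert (scan["mean.k"] >= 0).all()

    def test_select_smallest_qualifying_power(self):
        scan = pd.DataFrame(
            {
                "Power": [2, 4, 6, 8],
                "SFT.R.sq": [0.3, 0.7, 0.9, 0.95],
                "slope": [-0.5, -1.0, -1.2, -1.3],
            }
        )
        assert select_power(scan, r2_min=0.85) == 6

    def test_fallback_to_argmax_with_warning(self, caplog):
        scan = pd.DataFrame(
            {"Power": [2, 4], "SFT.R.sq": [0.5, 0.6], "slope": [-1.0, -1.1]}
        )
        with caplog.at_level("WARNING"):
            assert select_power(scan, r2_min=0.85) == 4
        assert "falling back" in caplog.text

    def test_positive_slope_powers_not_selected(self):
        scan = pd.DataFrame(
            {"Power": [1, 3], "SFT.R.sq": [0.99, 0.9], "slope": [1.5, -1.0]}
        )
        assert select_power(scan, r2_min=0.85) == 3


class TestDetectModules:
    @staticmethod
    def _two_blocks(n1=50, n2=50):
        n = n1 + n2
        d = np.ones((n, n))
        d[:n1, :n1] = 0.0
        d[n1:, n1:] = 0.0
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_perfect_blocks_found(self):
        labels = detect_modules(self._two_blocks(), min_size=30)
        counts = labels.value_counts()
        assert sorted(counts.values) == [50, 50]
        assert "grey" not in counts.index

    def test_blocks_below_min_size_all_grey(self):
        labels = detect_modules(self._two_blocks(), min_size=60)
        assert (labels == "grey").all()

    def test_min_size_above_n_genes_all_grey(self, caplog):
        with caplog.at_level("WARNING"):
            labels = detect_modules(self._two_blocks(10, 10), min_size=100)
        assert (labels == "grey").all()

    def test_modules_named_by_descending_size(self):
        n1, n2 = 60, 40
        labels = detect_modules(self._two_blocks(n1, n2), min_size=30)
        assert (labels.iloc[:n1] == "turquoise").all()
        assert (labels.iloc[n1:] == "blue").all()

    def test_planted_modules_recovered(self, corrected_study):
        from sklearn.metrics import adjusted_rand_score

        matrix, truth = corrected_study
        power = select_power(scan_soft_thresholds(matrix))
        net = build_network(matrix, power)
        labels = merge_modules(matrix, detect_modules(net.dissimilarity))
        tv = truth.module_assignment.reindex(matrix.gene_ids)
        mask = (tv != "none").to_numpy()
        ari = adjusted_rand_score(tv.to_numpy()[mask], labels.to_numpy()[mask])
        assert ari >= 0.8
        sizes = labels[labels != "grey"].value_counts()
        assert (sizes >= 30).all()


class TestEigengenes:
    def test_identical_rows_give_explained_variance_one(self):
        row = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0])
        m = toy_matrix(np.tile(row, (4, 1)) + np.arange(4)[:, None])
        labels = pd.Series("m1", index=m.gene_ids)
        me, ev = module_eigengenes(m, labels)
        assert ev["MEm1"] == pytest.approx(1.0)
        r = np.corrcoef(me.loc["MEm1"], row)[0, 1]
        assert r == pytest.approx(1.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=(20, 10))
            m = toy_matrix(x)
            labels = pd.Series("m1", index=m.gene_ids)
            me, ev = module_eigengenes(m, labels)
            xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
            u, s, vt = np.linalg.svd(xs, full_matrices=False)
            ref = vt[0]
            got = me.loc["MEm1"].to_numpy()
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-10
            assert ev["MEm1"] == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_orientation_nonnegative_with_module_average(self, corrected_study):
        matrix, truth = corrected_study
        labels = truth.module_assignment.replace("none", "grey")
        me, ev = module_eigengenes(matrix, labels)
        for mod in me.index:
            genes = labels.index[labels == mod[2:]]
            sub = matrix.values.loc[genes]
            avg = ((sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1, ddof=1), axis=0)).mean()
            assert np.corrcoef(me.loc[mod], avg)[0, 1] >= 0
            assert 0 < ev[mod] <= 1


class TestMerge:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=30)
        x = np.vstack(
            [f + 0.05 * rng.normal(size=(10, 30)), f + 0.05 * rng.normal(size=(10, 30))]
        )
        m = toy_matrix(x)
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=m.gene_ids)
        merged = merge_modules(m, labels, threshold=0.8)
        assert merged.nunique() == 1

    def test_uncorrelated_modules_untouched(self):
        rng = np.random.default_rng(3)
        f1, f2 = rng.normal(size=(2, 40))
        x = np.vstack(
            [f1 + 0.1 * rng.normal(size=(8, 40)), f2 + 0.1 * rng.normal(size=(8, 40))]
        )
        m = toy_matrix(x)
        labels = pd.Series(["a"] * 8 + ["b"] * 8, index=m.gene_ids)
        merged = merge_modules(m, labels, threshold=0.8)
        pd.testing.assert_series_equal(merged, labels, check_names=False)

    def test_terminates_with_max_pair_correlation_below_threshold(self):
        rng = np.random.default_rng(4)
        fs = rng.normal(size=(3, 50))
        blocks = [fs[i % 3] + 0.3 * rng.normal(size=(10, 50)) for i in range(6)]
        m = toy_matrix(np.vstack(blocks))
        labels = pd.Series(
            [lab for lab in "abcdef" for _ in range(10)], index=m.gene_ids
        )
        merged = merge_modules(m, labels, threshold=0.8)
        assert merged.nunique() == 3  # one module per distinct latent factor
        me, _ = module_eigengenes(m, merged)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, 0.0)
        assert cor.max() <= 0.8


class TestTraitCorrelation:
    def test_me_equal_to_phenotype(self):
        y = pd.Series([0, 1, 0, 1, 1, 0, 1, 0, 1, 1])
        me = pd.DataFrame([y.to_numpy(dtype=float)], index=["MEa"])
        res = module_trait_correlation(me, y)
        assert res.loc["MEa", "PCC"] == pytest.approx(1.0)
        assert res.loc["MEa", "p.value"] < 1e-10

    def test_orthogonal_me_has_zero_correlation(self):
        y = pd.Series([0, 0, 1, 1])
        me = pd.DataFrame([[1.0, -1.0, 1.0, -1.0]], index=["MEa"])
        res = module_trait_correlation(me, y)
        assert res.loc["MEa", "PCC"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["MEa", "p.value"] == pytest.approx(1.0)

    def test_p_value_closed_form(self):
        # r = 0.5, n = 20 -> t = 0.5*sqrt(18)/sqrt(0.75), p ~ 0.0249
        t = 0.5 * np.sqrt(18) / np.sqrt(1 - 0.25)
        p = 2 * stats.t.sf(t, 18)
        assert p == pytest.approx(0.0249, abs=5e-4)
        rng = np.random.default_rng(5)
        # construct an ME with exactly r=0.5 against a balanced phenotype
        y = np.array([0.0] * 10 + [1.0] * 10)
        z = rng.normal(size=20)
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        zc = z - z.mean()
        zc -= (zc @ yc) * yc
        zc /= np.linalg.norm(zc)
        v = 0.5 * yc + np.sqrt(0.75) * zc
        me = pd.DataFrame([v], index=["MEa"])
        res = module_trait_correlation(me, pd.Series(y.astype(int)))
        assert res.loc["MEa", "PCC"] == pytest.approx(0.5, abs=1e-12)
        assert res.loc["MEa", "p.value"] == pytest.approx(p, rel=1e-10)


class TestKeyModule:
    def test_reported_module_trait_table_selects_strongest(self):
        table = pd.DataFrame(
            {
                "PCC": [-0.1285, -0.3052, -0.9251, -0.7075, -0.2017, 0.3457,
                        -0.4263, -0.5753, 0.0609, 0.5127, 0.2944, 0.3082],
                "p.value": [0.0920, 0.0, 0.0, 0.0, 0.0078, 0.0,
                            0.0, 0.0, 0.4260, 0.0, 0.0, 0.0],
            },
            index=["MEtan", "MEbrown", "MEturquoise", "MEblue", "MEgreen",
                   "MEpurple", "MEblack", "MEmagenta", "MEmidnightblue",
                   "MEred", "MEcyan", "MEgrey60"],
        )
        assert select_key_module(table) == "turquoise"

    def test_single_module_selected(self):
        table = pd.DataFrame({"PCC": [0.4], "p.value": [0.01]}, index=["MEblue"])
        assert select_key_module(table) == "blue"

    def test_magnitude_decides(self):
        table = pd.DataFrame(
            {"PCC": [-0.9, 0.2], "p.value": [1e-5, 0.1]}, index=["MEa", "MEb"]
        )
        assert select_key_module(table) == "a"


def test_adjacency_monotone_in_power(corrected_study):
    matrix, _ = corrected_study
    cor = np.corrcoef(matrix.subset_genes(matrix.gene_ids[:100]).values.to_numpy())
    a2 = adjacency_matrix(cor, 2.0)
    a5 = adjacency_matrix(cor, 5.0)
    off = ~np.eye(100, dtype=bool)
    assert (a5[off] <= a2[off] + 1e-15).all()
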