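"""PCA, Ward clustering, hierarchical k-means and Tukey letters."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from chlorosom.multivariate import (
    CorrelationPCA,
    HKMeans,
    anova_tukey,
    compact_letter_display,
    cut_dendrogram,
    dendrogram_to_newick,
    standardise,
    ward_dendrogram,
)


class TestStandardise:
    def test_z_scores_with_sample_sd(self):
        out = standardise(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["x"], [-1, 0, 1])

    def test_idempotence(self):
        df = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [0.5, -1.0, 0.5]})
        z = standardise(df)
        assert np.allclose(standardise(z).to_numpy(), z.to_numpy(), atol=1e-12)

    def test_constant_column_is_named_in_error(self):
        with pytest.raises(ValueError, match="'flat'"):
            standardise(pd.DataFrame({"x": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestCorrelationPCA:
    def test_eigenvalues_match_independent_eigendecomposition(self, rng):
        X = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        model = CorrelationPCA().fit(X)
        oracle = np.sort(np.linalg.eigvalsh(np.corrcoef(X.T)))[::-1]
        assert np.allclose(model.eigenvalues_, oracle, atol=1e-9)
        assert np.isclose(model.eigenvalues_.sum(), X.shape[1], atol=1e-9)

    def test_rank_one_table_loads_on_first_component(self, rng):
        x = rng.random(10)
        X = pd.DataFrame({"a": x, "b": 3 * x + 1})
        model = CorrelationPCA().fit(X)
        assert model.proportion_variance_[0] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_features_split_variance_evenly(self):
        # exactly zero sample correlation by construction
        X = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0],
                          "b": [1.0, 1.0, -1.0, -1.0]})
        model = CorrelationPCA().fit(X)
        assert np.allclose(model.proportion_variance_, [0.5, 0.5])

    def test_reconstruction_and_score_covariance(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        model = CorrelationPCA().fit(X)
        assert np.allclose(model.inverse_transform(model.scores_),
                           X.to_numpy(), atol=1e-9)
        cov = np.cov(model.scores_, rowvar=False)
        assert np.allclose(cov, np.diag(model.eigenvalues_), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        X = pd.DataFrame(rng.standard_normal((15, 3)))
        model = CorrelationPCA().fit(X)
        for j in range(3):
            col = model.loadings_[:, j]
            assert col[np.argmax(np.abs(col))] > 0


class TestWard:
    def test_separated_pairs_cut_into_two_groups(self):
        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        Z = ward_dendrogram(X)
        labels = cut_dendrogram(Z, k=2)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_tie_broken_by_lowest_index(self):
        # 3 collinear equidistant points: pairs (0,1) and (1,2) tie at
        # distance 1; the first merge must join the lowest-index pair.
        Z = ward_dendrogram(np.array([[0.0], [1.0], [2.0]]))
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_duplicate_sample_merges_at_height_zero(self):
        Z = ward_dendrogram(np.array([[1.0, 2], [1.0, 2], [5.0, 5]]))
        assert Z[0, 2] == 0.0

    def test_heights_non_decreasing(self, rng):
        Z = ward_dendrogram(rng.random((15, 3)))
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_newick_export_parses(self):
        import dendropy

        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        nwk = dendrogram_to_newick(ward_dendrogram(X), ["a", "b", "c", "d"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("abcd")


class TestHKMeans:
    def _blobs(self, rng, centers, n=10, sd=0.05):
        X = np.vstack([c + sd * rng.standard_normal((n, len(c)))
                       for c in centers])
        y = np.repeat(np.arange(len(centers)), n)
        return X, y

    def test_two_blobs_recovered_exactly(self, rng):
        X, y = self._blobs(rng, [(0, 0), (10, 10)])
        km = HKMeans(k=2).fit(X)
        assert len(set(zip(km.labels_, y))) == 2  # one-to-one label map
        assert set(km.labels_) == {1, 2}

    def test_k_equal_n_gives_zero_wss(self, rng):
        X = rng.random((6, 2))
        km = HKMeans(k=6).fit(X)
        assert km.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_wss_non_increasing_in_k(self, rng):
        X = rng.random((30, 3))
        w = [HKMeans(k=k).fit(X).inertia_ for k in (2, 3, 5, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))

    def test_auto_k_and_wss_match_multirestart_oracle(self, rng):
        """Four simulated groups: auto-k finds 4 and the refined WSS matches
        a 50-restart k-means oracle to 1e-6."""
        X, _ = self._blobs(rng, [(0, 0), (6, 0), (0, 6), (6, 6)], n=10, sd=0.3)
        km = HKMeans(k="auto").fit(X)
        assert km.k_ == 4
        oracle = KMeans(n_clusters=4, n_init=50, random_state=0).fit(X)
        assert km.inertia_ == pytest.approx(oracle.inertia_, abs=1e-6)

    def test_k_larger_than_n_is_an_error(self, rng):
        with pytest.raises(ValueError):
            HKMeans(k=10).fit(rng.random((4, 2)))


class TestAnovaTukey:
    def test_null_case_shares_one_letter(self, rng):
        v = np.concatenate([rng.random(10), rng.random(10)])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        cmp_ = anova_tukey(v, labels)
        assert set(cmp_.letters.values()) == {"a"}

    def test_one_outlying_group_gets_own_letter(self, rng):
        v = np.concatenate([0.1 * rng.standard_normal(10),
                            0.1 * rng.standard_normal(10),
                            10 + 0.1 * rng.standard_normal(10)])
        labels = np.repeat(["g1", "g2", "g3"], 10)
        cmp_ = anova_tukey(v, labels)
        # letters in descending-mean order: the high group is 'a'
        assert cmp_.letters["g3"] == "a"
        assert cmp_.letters["g1"] == cmp_.letters["g2"] == "b"

    def test_five_separated_groups_get_five_letters(self, rng):
        means = [45.92, 32.90, 24.76, 17.53, 13.38]
        v = np.concatenate([m + 0.5 * rng.standard_normal(10) for m in means])
        labels = np.repeat([f"g{i}" for i in range(5)], 10)
        cmp_ = anova_tukey(v, labels)
        assert sorted(cmp_.letters.values()) == ["a", "b", "c", "d", "e"]

    def test_letters_consistent_with_adjusted_p(self, rng):
        """Groups share a letter iff their Tukey-adjusted p >= alpha."""
        v = np.concatenate([rng.standard_normal(8) + m for m in (0, 0.5, 3, 3.2)])
        labels = np.repeat(list("wxyz"), 8)
        cmp_ = anova_tukey(v, labels)
        for i, a in enumerate(cmp_.group_order):
            for b in cmp_.group_order[i + 1:]:
                share = set(cmp_.letters[a]) & set(cmp_.letters[b])
                if cmp_.tukey_p[(a, b)] < cmp_.alpha:
                    assert not share, (a, b)
                else:
                    assert share, (a, b)

    def test_small_group_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCompactLetterDisplay:
    def test_insert_and_absorb_chain(self):
        # g1 > g2 > g3 with only the extremes differing: a / ab / b
        letters = compact_letter_display(["g1", "g2", "g3"], {("g1", "g3")})
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}

    def test_all_distinct(self):
        letters = compact_letter_display(
            ["a", "b", "c"], {("a", "b"), ("b", "c"), ("a", "c")})
        assert letters == {"a": "a", "b": "b", "c": "c"}
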