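"""Standardization, PCA, K-means and MCA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bonepmi.ordination import kmeans_components, mca, pca, standardize
from bonepmi.synthetic import SyntheticSpec, generate_study


def frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestStandardize:
    def test_population_z_scores(self):
        z = standardize(frame([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z["v0"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_dropped_with_warning(self):
        t = frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = standardize(t)
        assert list(z.columns) == ["v0"]

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            standardize(frame([[5.0], [5.0]]))

    def test_output_columns_have_zero_mean_unit_sd(self, default_study):
        z = standardize(default_study[0])
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)


class TestPCA:
    def test_perfectly_correlated_variables_give_rank_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        z = standardize(frame(np.column_stack([x, 2 * x + 1])))
        res = pca(z, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_ratios_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(1)
        z = standardize(frame(rng.normal(size=(6, 4))))
        res = pca(z, 4)
        eig = np.sort(np.linalg.eigvalsh(np.cov(z.to_numpy().T, ddof=1)))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eig / eig.sum(), atol=1e-9)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scores_centered_with_diagonal_covariance(self):
        rng = np.random.default_rng(2)
        z = standardize(frame(rng.normal(size=(10, 5))))
        res = pca(z, 4)
        s = res.scores.to_numpy()
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=1e-9)
        cov = np.cov(s.T, ddof=1)
        np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-9)

    def test_too_many_components_rejected(self):
        z = standardize(frame(np.random.default_rng(0).normal(size=(4, 3))))
        with pytest.raises(ValueError, match="n_components"):
            pca(z, 4)

    def test_dominant_bone_effect_recovered_by_kmeans_on_pc1(self):
        # bone effect dwarfs the (absent) PMI effect: PC1 must separate bones
        proteins = [f"P{i}" for i in range(8)]
        spec = SyntheticSpec(
            conditions=[("PMI15", "rib"), ("PMI15", "tibia"),
                        ("PMI20", "rib"), ("PMI20", "tibia")],
            replicates_per_condition=5,
            protein_panel=proteins,
            log10_mean={(p, c): 6.0 for p in proteins
                        for c in ("PMI15", "PMI20")},
            log10_sd=0.1,
            detection_prob={(p, c): 1.0 for p in proteins
                            for c in ("PMI15", "PMI20")},
            bone_effect={(p, "tibia"): 2.0 for p in proteins[:4]},
            seed=5,
        )
        table, meta = generate_study(spec)
        res = pca(standardize(table), 3)
        labels = kmeans_components(res.scores[["PC1"]], 2, seed=0)
        bones = meta.set_index("sample_id")["bone"]
        groups = labels.groupby(bones).nunique()
        assert (groups == 1).all()            # each bone -> one cluster
        assert labels.nunique() == 2


class TestKMeans:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)),
                         rng.normal(10, 0.1, (5, 2))])
        labels = kmeans_components(frame(pts), 2, seed=0)
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(4)
        pts = frame(rng.normal(size=(5, 2)))
        labels = kmeans_components(pts, 5, seed=0)
        assert labels.nunique() == 5

    def test_matches_exhaustive_two_partition_minimum(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(7, 2))
        labels = kmeans_components(frame(pts), 2, seed=0)

        def wcss(assignment):
            total = 0.0
            for g in (0, 1):
                members = pts[np.array(assignment) == g]
                if len(members):
                    total += ((members - members.mean(axis=0)) ** 2).sum()
            return total

        best = min(wcss([int(i in subset) for i in range(7)])
                   for r in range(1, 7)
                   for subset in itertools.combinations(range(7), r))
        assert wcss(labels.to_numpy()) == pytest.approx(best, rel=1e-9)

    def test_row_permutation_only_relabels(self):
        rng = np.random.default_rng(6)
        pts = frame(rng.normal(size=(9, 3)))
        perm = rng.permutation(9)
        l1 = kmeans_components(pts, 2, seed=0)
        l2 = kmeans_components(pts.iloc[perm], 2, seed=0)
        pairs = set(zip(l1.loc[l2.index], l2))
        assert len(pairs) == 2                 # a bijective relabeling

    def test_invalid_k_rejected(self):
        pts = frame(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            kmeans_components(pts, 0, seed=0)
        with pytest.raises(ValueError):
            kmeans_components(pts, 4, seed=0)


class TestMCA:
    def test_identical_samples_flagged_degenerate(self):
        presence = frame(np.ones((4, 3)))
        with pytest.warns(UserWarning, match="single-state"):
            res = mca(presence, 2)
        assert res.degenerate

    def test_disjoint_proteomes_separate_on_dimension_one(self):
        presence = frame(np.vstack([np.tile([1, 1, 0, 0], (4, 1)),
                                    np.tile([0, 0, 1, 1], (4, 1))]))
        res = mca(presence, 2)
        d1 = res.scores["Dim1"].to_numpy()
        assert (np.sign(d1[:4]) == -np.sign(d1[4:])).all()

    def test_inertias_match_direct_svd_recomputation(self):
        rng = np.random.default_rng(7)
        presence = frame((rng.random((8, 5)) < 0.5).astype(float))
        presence = presence.loc[:, presence.nunique(axis=0) > 1]
        res = mca(presence, 3)
        # independent recomputation from the indicator matrix
        Z = np.hstack([presence.to_numpy(), 1 - presence.to_numpy()])
        P = Z / Z.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        sv = np.linalg.svd(S, compute_uv=False)
        expected = (sv ** 2 / (sv ** 2).sum())[:3]
        np.testing.assert_allclose(res.explained_variance_ratio, expected,
                                   atol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mca(pd.DataFrame(), 2)
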