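import numpy as np
import pandas as pd
import pytest

import ptmscope as pt
from ptmscope.descriptors import DESCRIPTOR_NAMES


SITES = [("A", 45), ("A", 59), ("B", 45), ("B", 59)]


def _random_descriptor(rng):
    row = dict(zip(DESCRIPTOR_NAMES, rng.uniform(1.0, 100.0, len(DESCRIPTOR_NAMES))))
    return pt.DescriptorVector.from_row(row)


def _study_matrix(seed=0):
    rng = np.random.default_rng(seed)
    patterns = pt.enumerate_patterns(SITES)
    descriptors = [_random_descriptor(rng) for _ in patterns]
    return pt.assemble_features(descriptors, patterns)


class TestAssembleFeatures:
    def test_sixteen_by_thirteen(self):
        m = _study_matrix()
        assert m.data.shape == (16, 13)
        assert m.indicator_columns == ["A.45", "A.59", "B.45", "B.59"]
        assert list(m.data.columns[:9]) == list(DESCRIPTOR_NAMES)

    def test_unmodified_row_has_zero_indicators(self):
        m = _study_matrix()
        assert (m.data.loc["wt", m.indicator_columns] == 0).all()

    def test_single_site_single_system(self):
        rng = np.random.default_rng(1)
        pattern = pt.enumerate_patterns([("A", 1)])[1]
        m = pt.assemble_features([_random_descriptor(rng)], [pattern])
        assert m.data.shape == (1, 10)

    def test_mismatched_sites_rejected(self):
        rng = np.random.default_rng(2)
        p1 = pt.enumerate_patterns([("A", 1)])[0]
        p2 = pt.enumerate_patterns([("B", 2)])[0]
        with pytest.raises(ValueError, match="site"):
            pt.assemble_features(
                [_random_descriptor(rng), _random_descriptor(rng)], [p1, p2]
            )


class TestAggregateHexamer:
    def test_mean_of_three(self):
        vecs = []
        for v in (1.0, 2.0, 3.0):
            row = {k: v for k in DESCRIPTOR_NAMES}
            vecs.append(pt.DescriptorVector.from_row(row))
        agg = pt.aggregate_hexamer(vecs)
        assert agg.buried_sas == pytest.approx(2.0)

    def test_single_member_identity(self):
        rng = np.random.default_rng(3)
        v = _random_descriptor(rng)
        agg = pt.aggregate_hexamer([v])
        assert agg.as_row() == pytest.approx(v.as_row())

    def test_matches_elementwise_mean(self):
        rng = np.random.default_rng(4)
        vecs = [_random_descriptor(rng) for _ in range(3)]
        agg = pt.aggregate_hexamer(vecs)
        for name in DESCRIPTOR_NAMES:
            expected = np.mean([v.as_row()[name] for v in vecs])
            assert agg.as_row()[name] == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pt.aggregate_hexamer([])


class TestPairwiseNormalize:
    def _pair_matrix(self, values):
        df = pd.DataFrame(
            {"x": values, "P": [0.0, 1.0]}, index=["wt", "mod"]
        )
        return pt.FeatureMatrix(data=df, indicator_columns=["P"])

    def test_example_values(self):
        out = pt.pairwise_normalize(self._pair_matrix([4.0, 6.0]), [("wt", "mod")])
        assert out.data["x"].tolist() == pytest.approx([0.8, 1.2])

    def test_equal_values_map_to_one(self):
        out = pt.pairwise_normalize(self._pair_matrix([7.0, 7.0]), [("wt", "mod")])
        assert out.data["x"].tolist() == pytest.approx([1.0, 1.0])

    def test_pair_sums_to_two_and_ratio_preserved(self):
        m, _, pairs = pt.make_feature_study(n_per_group=4, effect_size=2.0, seed=5)
        out = pt.pairwise_normalize(m, pairs)
        for a, b in pairs:
            for col in m.descriptor_columns:
                na, nb = out.data.at[a, col], out.data.at[b, col]
                assert na + nb == pytest.approx(2.0)
                va, vb = m.data.at[a, col], m.data.at[b, col]
                assert na / nb == pytest.approx(va / vb)

    def test_indicators_untouched(self):
        m, _, pairs = pt.make_feature_study(n_per_group=2, effect_size=2.0, seed=6)
        out = pt.pairwise_normalize(m, pairs)
        pd.testing.assert_frame_equal(
            out.data[m.indicator_columns], m.data[m.indicator_columns]
        )

    def test_zero_mean_guarded(self):
        with pytest.warns(UserWarning, match="zero mean"):
            out = pt.pairwise_normalize(
                self._pair_matrix([2.0, -2.0]), [("wt", "mod")]
            )
        assert out.data["x"].tolist() == [1.0, 1.0]

    def test_overlapping_pairs_rejected(self):
        m = self._pair_matrix([1.0, 2.0])
        with pytest.raises(ValueError, match="more than one"):
            pt.pairwise_normalize(m, [("wt", "mod"), ("wt", "mod")])


class TestRunPCA:
    # the published loading table of the four-site phosphorylation study:
    # each printed column must be a unit vector up to rounding, the same
    # identity the implementation guarantees exactly
    PRINTED_LOADINGS = {
        "PC1": [0.405, 0.316, -0.461, -0.378, 0.451, -0.300, 0.001,
                -0.051, 0.171, 0.130, 0.164, 0.065, -0.068],
        "PC2": [-0.303, -0.347, -0.047, -0.121, 0.060, -0.351, -0.297,
                -0.226, 0.030, 0.128, -0.350, 0.479, -0.364],
        "PC3": [0.003, -0.139, -0.131, -0.199, 0.178, 0.202, 0.549,
                0.157, -0.021, -0.523, -0.349, -0.005, -0.356],
        "PC4": [-0.104, 0.146, -0.163, 0.229, 0.209, -0.130, 0.056,
                -0.628, -0.565, -0.247, -0.062, -0.115, 0.173],
        "PC5": [0.042, 0.282, 0.247, -0.236, -0.203, 0.233, -0.216,
                -0.411, 0.289, -0.485, 0.275, 0.274, -0.132],
    }

    def test_printed_loading_columns_are_unit_vectors(self):
        for name, col in self.PRINTED_LOADINGS.items():
            assert np.linalg.norm(col) == pytest.approx(1.0, abs=0.01), name

    def test_loadings_orthonormal(self):
        pca = pt.run_pca(_study_matrix())
        L = pca.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_rank_one_data_explained_by_pc1(self):
        x = np.linspace(1.0, 2.0, 8)
        df = pd.DataFrame({"a": x, "b": 3 * x})
        m = pt.FeatureMatrix(data=df)
        pca = pt.run_pca(m)
        assert pca.explained_variance[0] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        m = _study_matrix(seed=7)
        pca = pt.run_pca(m, scale=False)
        x = m.data.to_numpy()
        xc = x - x.mean(axis=0)
        svals = np.linalg.svd(xc, compute_uv=False)
        expected = svals**2 / (svals**2).sum()
        assert np.allclose(
            pca.explained_variance[: len(expected)], expected, atol=1e-8
        )

    def test_reconstruction(self):
        m = _study_matrix(seed=8)
        pca = pt.run_pca(m, scale=True)
        x = m.data.to_numpy()
        xc = x - x.mean(axis=0)
        xc = xc / xc.std(axis=0, ddof=1)
        approx = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        assert np.allclose(approx, xc, atol=1e-8)

    def test_constant_column_dropped_under_scaling(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0], "c": [2.0, 1.0, 4.0]}
        )
        m = pt.FeatureMatrix(data=df)
        with pytest.warns(UserWarning, match="constant"):
            pca = pt.run_pca(m, scale=True)
        assert "b" not in pca.loadings.index

    def test_retention_rule(self):
        m = _study_matrix(seed=9)
        pca = pt.run_pca(m)
        assert pca.retained() == int(np.sum(pca.sdev > 1.0))
        assert pca.cumulative_variance[-1] == pytest.approx(1.0)


class TestKMeansOnPCs:
    def test_separated_groups_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        m, truth, _ = pt.make_feature_study(n_per_group=8, effect_size=6.0, seed=10)
        pca = pt.run_pca(m.descriptors_only())
        cl = pt.kmeans_on_pcs(pca, n_pcs=3, k=2, seed=0)
        assert adjusted_rand_score(truth, cl.labels.to_numpy()) == 1.0

    def test_singleton_clusters_have_zero_inertia(self):
        m = _study_matrix(seed=11)
        pca = pt.run_pca(m)
        cl = pt.kmeans_on_pcs(pca, n_pcs=3, k=m.n_systems, seed=0)
        assert cl.inertia == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        m = _study_matrix(seed=12)
        pca = pt.run_pca(m)
        a = pt.kmeans_on_pcs(pca, n_pcs=3, k=4, seed=5)
        b = pt.kmeans_on_pcs(pca, n_pcs=3, k=4, seed=5)
        assert a.labels.tolist() == b.labels.tolist()
        assert a.metadata["algorithm"] == "lloyd"

    def test_k_larger_than_systems_rejected(self):
        m = _study_matrix(seed=13)
        pca = pt.run_pca(m)
        with pytest.raises(ValueError):
            pt.kmeans_on_pcs(pca, n_pcs=3, k=m.n_systems + 1, seed=0)


class TestCorrelatePTM:
    def test_indicator_tracking_descriptor_is_significant(self):
        rng = np.random.default_rng(14)
        ind = rng.integers(0, 2, 16).astype(float)
        df = pd.DataFrame(
            {"Total SAS": ind * 10 + 5, "noise": rng.normal(size=16), "A.45": ind}
        )
        m = pt.FeatureMatrix(data=df, indicator_columns=["A.45"])
        corr = pt.correlate_ptm(m)
        assert corr.r.at["A.45", "Total SAS"] == pytest.approx(1.0)
        assert bool(corr.significant.at["A.45", "Total SAS"])

    def test_mask_is_threshold_consistent(self):
        m, _, _ = pt.make_feature_study(n_per_group=8, effect_size=1.0, seed=15)
        corr = pt.correlate_ptm(m)
        pd.testing.assert_frame_equal(corr.significant, corr.r.abs() > 0.30)

    def test_matches_direct_formula(self):
        m, _, _ = pt.make_feature_study(n_per_group=8, effect_size=2.0, seed=16)
        corr = pt.correlate_ptm(m)
        x = m.data["P"].to_numpy()
        for d in m.descriptor_columns:
            y = m.data[d].to_numpy()
            expected = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            assert corr.r.at["P", d] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_yields_zero(self):
        df = pd.DataFrame(
            {"d": [1.0, 1.0, 1.0, 1.0], "P": [0.0, 1.0, 0.0, 1.0]}
        )
        m = pt.FeatureMatrix(data=df, indicator_columns=["P"])
        with pytest.warns(UserWarning, match="variance"):
            corr = pt.correlate_ptm(m)
        assert corr.r.at["P", "d"] == 0.0
        assert not bool(corr.significant.at["P", "d"])
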