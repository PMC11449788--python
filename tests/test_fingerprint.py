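import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synfp import fingerprint as fp
from synfp.scaffold_shapes import FEATURE_COLUMNS
from synfp.synthgen import gen_feature_clusters


def feature_frame(X):
    return pd.DataFrame(np.asarray(X, dtype=float), columns=FEATURE_COLUMNS)


@pytest.fixture(scope="module")
def blob_embedding():
    """Two well-separated 3-d blobs lifted into the 9-feature space."""
    rng = np.random.default_rng(0)
    a = rng.normal(5.0, 0.3, (60, 9))
    b = rng.normal(9.0, 0.3, (60, 9))
    df = feature_frame(np.vstack([a, b]))
    return df, fp.embed(df)


class TestEmbed:
    def test_roundtrip_reproduces_scores(self, blob_embedding):
        df, emb = blob_embedding
        np.testing.assert_allclose(emb.transform(df), emb.scores, atol=1e-10)

    def test_loadings_orthonormal(self, blob_embedding):
        _, emb = blob_embedding
        np.testing.assert_allclose(emb.loadings.T @ emb.loadings, np.eye(3),
                                   atol=1e-10)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        df = feature_frame(rng.uniform(1, 10, (30, 9)))
        e1 = fp.embed(df)
        e2 = fp.embed(pd.concat([df, df], ignore_index=True))
        # same transform up to component sign
        sign = np.sign(np.sum(e1.loadings * e2.loadings, axis=0))
        np.testing.assert_allclose(e2.scores[:30] * sign, e1.scores, atol=1e-8)

    def test_planar_data_has_no_pc3_variance(self):
        rng = np.random.default_rng(2)
        basis = rng.normal(0, 1, (2, 9))
        coef = rng.normal(0, 1, (50, 2))
        df = feature_frame(10 + coef @ basis)
        emb = fp.embed(df, log=False)
        assert emb.scores[:, 2].std() == pytest.approx(0.0, abs=1e-8)

    def test_zero_variance_feature_named(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(1, 2, (20, 9))
        X[:, 3] = 7.0
        with pytest.raises(ValueError, match=FEATURE_COLUMNS[3]):
            fp.embed(feature_frame(X))

    def test_zero_feature_values_handled_by_eps(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(1, 2, (30, 9))
        X[:5, 2] = 0.0  # volume_ratio can be exactly 0
        emb = fp.embed(feature_frame(X))
        assert np.isfinite(emb.scores).all()


class TestClara:
    def test_two_blobs_forced_k2_exact(self, blob_embedding):
        _, emb = blob_embedding
        assign, med, _ = fp.clara(emb.scores, 2, seed=0)
        truth = np.repeat([0, 1], 60)
        agree = max((assign == truth).mean(), (assign != truth).mean())
        assert agree == 1.0

    def test_medoids_are_data_points(self, blob_embedding):
        _, emb = blob_embedding
        _, med, _ = fp.clara(emb.scores, 3, seed=0)
        assert med.dtype.kind == "i" and len(np.unique(med)) == 3


class TestGapSelection:
    def test_identical_points_select_k1(self):
        scores = np.ones((40, 3)) * 2.5  # all objects coincide in PC space
        emb = fp.Embedding(scores, np.eye(9, 3), list(FEATURE_COLUMNS),
                           np.zeros(9), np.zeros(9), np.ones(9), np.zeros(9))
        model = fp.cluster(emb, range(1, 4), gap_B=10, seed=0, n_subsamples=10)
        assert model.k == 1

    def test_six_planted_clusters_recovered(self):
        df, truth = gen_feature_clusters(2, n_objects=900)
        emb = fp.embed(df, log=False)
        model = fp.cluster(emb, range(1, 9), gap_B=25, seed=2, n_subsamples=30,
                           volumes=df["volume_nm3"].to_numpy())
        assert model.k == 6
        purity = pd.crosstab(truth, model.assignments).max(axis=1).sum() / len(truth)
        assert purity > 0.95

    def test_uniform_null_selects_k1_in_most_runs(self):
        # Gap-statistic null calibration on single-cluster uniform data
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = feature_frame(rng.uniform(0, 1, (200, 9)))
            emb = fp.embed(df, log=False)
            model = fp.cluster(emb, range(1, 5), gap_B=15, seed=seed,
                               n_subsamples=15)
            hits += model.k == 1
        assert hits >= 9

    def test_clusters_ordered_by_medoid_volume(self):
        df, truth = gen_feature_clusters(1, n_objects=600)
        emb = fp.embed(df, log=False)
        vols = np.abs(df["volume_nm3"].to_numpy()) + truth * 100.0  # volume rank = class
        model = fp.cluster(emb, [6], gap_B=5, seed=1, n_subsamples=20,
                           volumes=vols, forced_k=6)
        med_vols = vols[model.medoids]
        assert (np.diff(med_vols) > 0).all()

    def test_k_range_too_large_rejected(self):
        rng = np.random.default_rng(5)
        emb = fp.embed(feature_frame(rng.uniform(1, 2, (12, 9))))
        with pytest.raises(ValueError):
            fp.cluster(emb, range(1, 12), gap_B=5, seed=0)


class TestPseudotime:
    @staticmethod
    def _line_embedding(n=100, seed=0):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 10, n))
        scores = np.column_stack([t, np.zeros(n), np.zeros(n)])
        emb = fp.Embedding(scores, np.eye(9, 3), list(FEATURE_COLUMNS),
                           np.zeros(9), np.zeros(9), np.ones(9), np.zeros(9))
        return t, emb

    def test_collinear_rank_order_preserved(self):
        t, emb = self._line_embedding()
        medoids = np.array([5, 50, 95])
        model = fp.ClusterModel(3, np.ones(len(t), int), medoids,
                                pd.DataFrame(), np.arange(3))
        pt = fp.pseudotime(emb, model)
        assert stats.spearmanr(t, pt.values).statistic == pytest.approx(1.0)

    def test_reversed_cluster_order_negates_pseudotime(self):
        t, emb = self._line_embedding()
        fwd = fp.ClusterModel(3, np.ones(len(t), int), np.array([5, 50, 95]),
                              pd.DataFrame(), np.arange(3))
        rev = fp.ClusterModel(3, np.ones(len(t), int), np.array([95, 50, 5]),
                              pd.DataFrame(), np.arange(3))
        p_fwd = fp.pseudotime(emb, fwd)
        p_rev = fp.pseudotime(emb, rev)
        np.testing.assert_allclose(p_rev.values, -p_fwd.values, atol=1e-8)

    def test_scaling_mean0_sd1(self):
        t, emb = self._line_embedding(seed=3)
        model = fp.ClusterModel(2, np.ones(len(t), int), np.array([5, 95]),
                                pd.DataFrame(), np.arange(2))
        pt = fp.pseudotime(emb, model)
        assert pt.values.mean() == pytest.approx(0.0, abs=1e-10)
        assert pt.values.std() == pytest.approx(1.0)

    def test_planted_continuum_recovered(self):
        # noisy arc in PC space with known arc positions
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 2 * np.pi * 0.75, 400))
        curve = np.column_stack([np.cos(t), np.sin(t), 0.1 * t])
        scores = 5 * curve + rng.normal(0, 0.15, curve.shape)
        emb = fp.Embedding(scores, np.eye(9, 3), list(FEATURE_COLUMNS),
                           np.zeros(9), np.zeros(9), np.ones(9), np.zeros(9))
        med = np.searchsorted(t, np.linspace(t[0] + 0.3, t[-1] - 0.3, 4))
        model = fp.ClusterModel(4, np.ones(len(t), int), med,
                                pd.DataFrame(), np.arange(4))
        pt = fp.pseudotime(emb, model)
        rho = abs(stats.spearmanr(t, pt.values).statistic)
        assert rho > 0.95


class TestEndToEndRecovery:
    def test_scaffold_continuum_classes_and_maturity_order_recovered(self):
        """Template classes planted in a scaffold volume are recovered by the
        segmentation -> features -> PCA -> CLARA chain, and pseudotime rises
        with the planted volume rank."""
        import warnings

        from synfp import scaffold_shapes as ss
        from synfp.synthgen import SimConfig, gen_scaffolds

        cfg = SimConfig(seed=13, n_objects=180, volume_shape=(48, 256, 256))
        vol, gt = gen_scaffolds(cfg)
        mask = ss.threshold_probability(vol, 0.2)
        labels = vol.meta["true_labels"]
        feats, classes, sizes = [], [], []
        for o in ss.segment_objects(mask):
            if o.border or o.voxel_count < 50:
                continue  # skip background speckles
            lab = labels[tuple(o.voxels[0])]
            if lab == 0:
                continue
            row = gt.objects[gt.objects.label == lab].iloc[0]
            feats.append(ss.shape_features(o, vol.voxel_size_nm))
            classes.append(row.template_class)
            sizes.append(row.voxel_count)
        df = pd.DataFrame(feats)
        classes = np.array(classes)

        emb = fp.embed(df)
        model = fp.cluster(emb, [6], forced_k=6, seed=1,
                           volumes=df["volume_nm3"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pt = fp.pseudotime(emb, model)

        tab = pd.crosstab(model.assignments, classes)
        modal = tab.idxmax(axis=1)
        match = np.mean([modal[a] == c
                         for a, c in zip(model.assignments, classes)])
        assert match >= 0.80
        assert stats.spearmanr(pt.values, np.array(sizes)).statistic > 0.9


class TestComposition:
    def test_uniform_counts(self):
        ids = np.tile(np.arange(1, 7), 20)
        groups = np.repeat(["a", "b"], 60)
        tab = fp.composition_table(ids, groups, k=6)
        assert (tab.to_numpy() == 10).all()
        props = tab / tab.sum(axis=0)
        np.testing.assert_allclose(props.sum(axis=0), 1.0)

    def test_zero_cell_retained(self):
        ids = np.array([1, 1, 2, 2, 2, 1])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        tab = fp.composition_table(ids, groups, k=3)
        assert tab.shape == (3, 2)
        assert tab.loc[3].sum() == 0  # empty cluster kept as zero row

    def test_totals_conserved(self):
        rng = np.random.default_rng(8)
        ids = rng.integers(1, 7, 200)
        groups = rng.choice(["a", "b", "c"], 200)
        tab = fp.composition_table(ids, groups, k=6)
        assert tab.to_numpy().sum() == 200

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            fp.composition_table(np.array([1, 2]), pd.Series(["a", None]))
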