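import numpy as np
import pytest

from chemimage.core_io import ValidationError
from chemimage.plsda import (
    cluster_plsda_pipeline,
    pls_embed_image,
    pls_fit,
    pls_predict,
    select_lv,
)
from chemimage.preprocess import preprocess_image
from chemimage.segmentation import double_segmentation
from chemimage.synthetic import SynthConfig, generate_cohort


def _two_class_data(rng, n=40, p=12, sep=4.0, noise=0.3):
    y = np.repeat([0, 1], n // 2)
    direction = np.zeros(p)
    direction[2] = 1.0
    X = rng.standard_normal((n, p)) * noise + sep * y[:, None] * direction
    return X, y


class TestPlsFit:
    def test_rank_one_perfectly_fit_by_one_lv(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(20)
        direction = rng.standard_normal(6)
        X = np.outer(t, direction)
        y = (t > 0).astype(float)
        # y not proportional to t, but X is rank 1: the single score carries
        # all X variance; residual X after one component vanishes
        model = pls_fit(X, y, n_lv=3)
        assert model.n_lv == 1  # extraction stops: X fully deflated
        scores, _ = pls_predict(model, X)
        # fitted values are the best rank-1 linear predictor of y from t
        t_c = t - t.mean()
        beta = (y - y.mean()) @ t_c / (t_c @ t_c)
        np.testing.assert_allclose(scores, y.mean() + beta * t_c, atol=1e-10)

    def test_first_weight_is_dominant_eigenvector(self):
        """First NIPALS weight equals the dominant eigenvector of X'yy'X
        (up to sign), on random 20x10 instances."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            X = rng.standard_normal((20, 10))
            y = rng.integers(0, 2, 20).astype(float)
            if np.unique(y).size < 2:
                continue
            model = pls_fit(X, y, n_lv=2)
            Xc = X - X.mean(0)
            yc = y - y.mean()
            M = np.outer(Xc.T @ yc, yc @ Xc)
            evals, evecs = np.linalg.eigh(M)
            v = evecs[:, -1]
            w = model.weights[:, 0]
            assert min(np.linalg.norm(w - v), np.linalg.norm(w + v)) < 1e-8

    def test_constant_y_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValidationError, match="single class"):
            pls_fit(rng.standard_normal((10, 4)), np.ones(10), n_lv=1)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValidationError):
            pls_fit(np.ones((10, 4)), np.repeat([0.0, 1.0], 5), n_lv=1)

    def test_weights_unit_norm_and_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        X, y = _two_class_data(rng)
        model = pls_fit(X, y, n_lv=6)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-10
        )
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8

    def test_deflation_residual_norm_non_increasing(self):
        rng = np.random.default_rng(4)
        X, y = _two_class_data(rng)
        Xc = X - X.mean(0)
        model = pls_fit(X, y, n_lv=6)
        norms = []
        R = Xc.copy()
        for a in range(model.n_lv):
            norms.append(np.linalg.norm(R))
            R = R - np.outer(model.scores[:, a], model.loadings[:, a])
        norms.append(np.linalg.norm(R))
        assert all(b <= a + 1e-12 for a, b in zip(norms, norms[1:]))

    def test_matches_sklearn_pls_regression(self):
        """Cross-check predictions against the scikit-learn NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X, y = _two_class_data(rng)
        for a in (1, 2, 4):
            model = pls_fit(X, y, n_lv=a)
            ours, _ = pls_predict(model, X, n_lv=a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y.astype(float))
            np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_clamps_excessive_lv(self):
        rng = np.random.default_rng(6)
        X, y = _two_class_data(rng, n=10, p=4)
        with pytest.warns(UserWarning, match="clamping"):
            model = pls_fit(X, y, n_lv=50)
        assert model.lv_max <= 4


class TestPlsPredict:
    def test_training_mean_scores_class_mean(self):
        rng = np.random.default_rng(7)
        X, y = _two_class_data(rng)
        model = pls_fit(X, y, n_lv=3)
        score, label = pls_predict(model, X.mean(0)[None, :])
        assert score[0] == pytest.approx(y.mean(), abs=1e-12)
        assert label[0] == int(y.mean() >= 0.5)

    def test_reproduces_training_fit(self):
        rng = np.random.default_rng(8)
        X, y = _two_class_data(rng)
        model = pls_fit(X, y, n_lv=4)
        s1, _ = pls_predict(model, X)
        s2, _ = pls_predict(model, X)
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        # coefficient-path reconstruction matches a fresh truncated fit
        small = pls_fit(X, y, n_lv=2)
        s_trunc, _ = pls_predict(model, X, n_lv=2)
        s_small, _ = pls_predict(small, X, n_lv=2)
        np.testing.assert_allclose(s_trunc, s_small, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        X, y = _two_class_data(rng)
        model = pls_fit(X, y, n_lv=2)
        with pytest.raises(ValidationError):
            pls_predict(model, X[:, :5])

    def test_separable_classes_reach_f1_one(self):
        rng = np.random.default_rng(10)
        X, y = _two_class_data(rng, sep=8.0, noise=0.1)
        model = pls_fit(X, y, n_lv=2)
        _, labels = pls_predict(model, X)
        assert np.array_equal(labels, y)


class TestSelectLv:
    def test_separable_selects_lv1_with_f1_one(self):
        rng = np.random.default_rng(11)
        X, y = _two_class_data(rng, sep=8.0, noise=0.1)
        Xv, yv = _two_class_data(rng, sep=8.0, noise=0.1)
        model, best, f1s = select_lv(X, y, Xv, yv, lv_max=6)
        assert best == 1 and f1s[0] == 1.0

    def test_signal_in_second_direction_needs_lv2(self):
        """Class signal hidden behind a dominant orthogonal nuisance
        direction: validation F1 only reaches its optimum at LV >= 2, matching
        a brute-force F1 sweep over truncations."""
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(12)
        n, p = 60, 8
        y = np.repeat([0, 1], n // 2).astype(float)
        nuisance = np.zeros(p); nuisance[0] = 1.0
        signal = np.zeros(p); signal[1] = 1.0
        def draw():
            g = 20.0 * rng.standard_normal((n, 1)) * nuisance  # huge, label-free
            s = 3.0 * y[:, None] * signal
            return g + s + 0.2 * rng.standard_normal((n, p))
        X, Xv = draw(), draw()
        model, best, f1s = select_lv(X, y, Xv, y, lv_max=4)
        assert best == 2
        # brute-force sweep: refit at each truncation and score
        for a in (1, 2):
            m = pls_fit(X, y, n_lv=a)
            _, lab = pls_predict(m, Xv)
            assert f1s[a - 1] == pytest.approx(
                f1_score(y, lab, zero_division=0.0), abs=1e-12
            )

    def test_shuffled_labels_do_not_crash(self):
        rng = np.random.default_rng(13)
        X, y = _two_class_data(rng)
        y_shuf = rng.permutation(y)
        model, best, f1s = select_lv(X, y_shuf, X, rng.permutation(y), lv_max=5)
        assert 1 <= best <= 5 and np.all((0 <= f1s) & (f1s <= 1))

    def test_empty_or_single_class_validation_rejected(self):
        rng = np.random.default_rng(14)
        X, y = _two_class_data(rng)
        with pytest.raises(ValidationError):
            select_lv(X, y, X[:0], y[:0])
        with pytest.raises(ValidationError):
            select_lv(X, y, X[:5], np.zeros(5))


class TestEmbedding:
    def _model3lv(self, rng):
        X, y = _two_class_data(rng, n=60, p=24)
        return pls_fit(X, y, n_lv=3), X

    def test_substrate_is_zero_and_mean_maps_to_origin(self, small_axis):
        from chemimage.core_io import HyperspectralImage

        rng = np.random.default_rng(15)
        X, y = _two_class_data(rng, n=60, p=40)
        model = pls_fit(X, y, n_lv=3)
        cube = np.zeros((4, 4, 40))
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = mask[2, 3] = True
        cube[1, 1] = model.x_mean
        cube[2, 2] = X[0]
        cube[2, 3] = X[0]
        img = HyperspectralImage(cube=cube, axis=small_axis, mask=mask)
        emb = pls_embed_image(img, model)
        assert emb.shape == (4, 4, 3)
        np.testing.assert_array_equal(emb[0, 0], 0.0)  # substrate
        np.testing.assert_allclose(emb[1, 1], 0.0, atol=1e-10)  # training mean
        np.testing.assert_array_equal(emb[2, 2], emb[2, 3])  # identical pixels

    def test_scores_match_projection_oracle(self, small_axis):
        """Embedded triples equal the direct matrix-product projection
        (X - mean) W (P'W)^-1 computed independently."""
        from chemimage.core_io import HyperspectralImage

        rng = np.random.default_rng(16)
        X, y = _two_class_data(rng, n=60, p=40)
        model = pls_fit(X, y, n_lv=3)
        spectrum = rng.standard_normal(40)
        cube = np.tile(spectrum, (2, 2, 1))
        img = HyperspectralImage(cube=cube, axis=small_axis, mask=np.ones((2, 2), bool))
        emb = pls_embed_image(img, model)
        W, P = model.weights[:, :3], model.loadings[:, :3]
        oracle = (spectrum - model.x_mean) @ (W @ np.linalg.inv(P.T @ W))
        np.testing.assert_allclose(emb[0, 0], oracle, atol=1e-10)

    def test_wrong_lv_count_rejected(self, small_axis):
        from chemimage.core_io import HyperspectralImage

        rng = np.random.default_rng(17)
        X, y = _two_class_data(rng, n=30, p=40)
        model = pls_fit(X, y, n_lv=2)
        img = HyperspectralImage(cube=np.zeros((2, 2, 40)), axis=small_axis,
                                 mask=np.ones((2, 2), bool))
        with pytest.raises(ValidationError, match="3 latent"):
            pls_embed_image(img, model)


class TestClusterPipeline:
    @pytest.fixture(scope="class")
    def pipeline_inputs(self):
        # effect moderate on the tissue-contrast scale: strong enough for
        # PLSDA, weak enough that segmentation keeps epithelium in one cluster
        cfg = SynthConfig(n_patients=20, rows=24, cols=24, n_channels=24,
                          recurrence_rate=0.3, effect_size=0.3, noise_sd=0.02,
                          baseline_amplitude=0.05, seed=31)
        cohort, images, manifest = generate_cohort(cfg)
        images = [preprocess_image(im, seed=0) for im in images]
        model = double_segmentation(images, subsample=2000, seed=3)
        return cfg, cohort, images, manifest, model

    def test_deterministic_table(self, pipeline_inputs):
        _, cohort, images, _, model = pipeline_inputs
        t1 = cluster_plsda_pipeline(images, cohort, model, n_repeats=1, seed=5,
                                    lv_max=6, cap_per_image=50)
        t2 = cluster_plsda_pipeline(images, cohort, model, n_repeats=1, seed=5,
                                    lv_max=6, cap_per_image=50)
        assert t1.equals(t2)

    def test_effect_cluster_has_highest_auc(self, pipeline_inputs):
        """Only epithelium carries the label effect, so the epithelium-dominated
        composite cluster attains the top patient-level AUC."""
        cfg, cohort, images, manifest, model = pipeline_inputs
        table = cluster_plsda_pipeline(images, cohort, model, n_repeats=4, seed=1,
                                       lv_max=6, cap_per_image=80)
        # identify epithelium-dominated composite clusters from the truth maps
        off = model.composite_offset()
        comp_counts = {c: np.zeros(3) for c in range(model.n_composite)}
        for img in images:
            truth = np.asarray(manifest["regions"][img.image_id])
            amap = model.assignments[img.image_id]
            sel = img.mask & (truth >= 0)
            comp = np.array([off[int(a)] for a in amap[:, :, 0][sel]]) + amap[:, :, 1][sel]
            for t in range(3):
                comp_counts_t = np.bincount(comp[truth[sel] == t],
                                            minlength=model.n_composite)
                for c in range(model.n_composite):
                    comp_counts[c][t] += comp_counts_t[c]
        epi_clusters = {c for c, v in comp_counts.items()
                        if v.sum() > 0 and np.argmax(v) == 0}
        ranked = table.dropna(subset=["auc_mean"]).sort_values(
            "auc_mean", ascending=False
        )
        assert int(ranked.iloc[0]["cluster"]) in epi_clusters
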