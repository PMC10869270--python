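"""Reference fitting, projection bridges, multi-hop traversal, assembly."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from stabmap import (
    Dataset,
    MosaicScenario,
    StabMapConfig,
    apply_bridge,
    fit_bridge,
    fit_reference,
    generate_mosaic,
    make_user_reference,
    project_along_path,
    project_direct,
    reweight_blocks,
    stabmap,
)
from stabmap.mdt import build_mdt, shortest_path

from conftest import make_dataset


def svd_pca_oracle(x, n_dims):
    """Dense-SVD PCA: x is cells x features."""
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    return (u * s)[:, :n_dims], vt.T[:, :n_dims]


def assert_equal_up_to_sign(a, b, atol=1e-8):
    assert a.shape == b.shape
    for j in range(a.shape[1]):
        assert (np.allclose(a[:, j], b[:, j], atol=atol)
                or np.allclose(a[:, j], -b[:, j], atol=atol)), f"column {j}"


class TestFitReference:
    def test_default_requests_50_dims(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(200)],
                         [f"c{i}" for i in range(500)], rng=rng)
        model = fit_reference(d)
        assert model.n_dims == 50
        assert model.scores.shape == (500, 50)

    def test_pca_matches_dense_svd_oracle(self, rng):
        x = rng.normal(size=(100, 30))  # cells x features
        d = make_dataset("ref", [f"f{i}" for i in range(30)],
                         [f"c{i}" for i in range(100)], values=x.T)
        model = fit_reference(d, StabMapConfig(n_dims=10))
        scores_o, loadings_o = svd_pca_oracle(x, 10)
        assert_equal_up_to_sign(model.scores, scores_o)
        assert_equal_up_to_sign(model.loadings, loadings_o)

    def test_rank_one_data_concentrates_variance_in_pc1(self):
        t = np.linspace(-3, 3, 40)
        d = make_dataset("ref", ["x", "y"], [f"c{i}" for i in range(40)],
                         values=np.vstack([t, t]))
        model = fit_reference(d, StabMapConfig(n_dims=2))
        var = model.scores.var(axis=0)
        assert var[0] > 0
        assert var[1] == pytest.approx(0.0, abs=1e-20)

    def test_dims_capped_by_cells_and_features(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(5)],
                         [f"c{i}" for i in range(4)], rng=rng)
        assert fit_reference(d, StabMapConfig(n_dims=50)).n_dims == 3

    def test_zero_variance_matrix_rejected(self):
        d = make_dataset("ref", ["f1", "f2"], ["c1", "c2"],
                         values=np.ones((2, 2)))
        with pytest.raises(ValueError, match="variance"):
            fit_reference(d)

    def test_lda_caps_at_classes_minus_one_and_separates(self, rng):
        n = 90
        labels_arr = np.repeat(["a", "b", "c"], n // 3)
        centers = {"a": 0.0, "b": 4.0, "c": 8.0}
        x = rng.normal(size=(20, n)) * 0.3
        x[0] += [centers[l] for l in labels_arr]
        x[1] += [2 * centers[l] for l in labels_arr]
        cells = [f"c{i}" for i in range(n)]
        d = make_dataset("ref", [f"f{i}" for i in range(20)], cells, values=x)
        labels = dict(zip(cells, labels_arr))
        model = fit_reference(d, StabMapConfig(n_dims=50, labels=labels))
        assert model.mode == "lda"
        assert model.n_dims == 2
        # class means well separated along LD1 relative to within-class spread
        ld1 = model.scores[:, 0]
        mus = [ld1[labels_arr == l].mean() for l in "abc"]
        sds = [ld1[labels_arr == l].std() for l in "abc"]
        assert (max(mus) - min(mus)) > 5 * max(sds)

    def test_lda_subspace_matches_sklearn(self, rng):
        # n >> p so the within-class scatter is well conditioned; compare the
        # spanned discriminant subspace (loadings are scale/sign-free)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        n, p = 300, 8
        labels_arr = rng.choice(["a", "b", "c"], size=n)
        shift = {"a": 0.0, "b": 2.0, "c": 5.0}
        x = rng.normal(size=(n, p))
        x[:, 0] += [shift[l] for l in labels_arr]
        x[:, 1] -= [shift[l] for l in labels_arr]
        cells = [f"c{i}" for i in range(n)]
        d = make_dataset("ref", [f"f{i}" for i in range(p)], cells, values=x.T)
        model = fit_reference(
            d, StabMapConfig(n_dims=2, labels=dict(zip(cells, labels_arr))))
        skl = LinearDiscriminantAnalysis(solver="eigen").fit(x, labels_arr)
        w_skl = skl.scalings_[:, :2]

        def proj(w):
            q, _ = np.linalg.qr(w)
            return q @ q.T
        assert np.linalg.norm(proj(model.loadings) - proj(w_skl)) < 1e-4

    def test_lda_single_class_rejected(self, rng):
        cells = [f"c{i}" for i in range(10)]
        d = make_dataset("ref", ["f1", "f2"], cells, rng=rng)
        with pytest.raises(ValueError, match="classes"):
            fit_reference(d, StabMapConfig(labels={c: "only" for c in cells}))


class TestProjectDirect:
    def test_reference_round_trip(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(30)],
                         [f"c{i}" for i in range(80)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=8))
        np.testing.assert_allclose(project_direct(d, model), model.scores, atol=1e-9)

    def test_cell_at_feature_means_scores_zero(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(12)],
                         [f"c{i}" for i in range(40)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=4))
        q = Dataset("q", list(d.features), ["mean_cell"],
                    model.feature_means[:, None])
        np.testing.assert_allclose(project_direct(q, model), 0.0, atol=1e-12)

    def test_matches_naive_triple_loop(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(10)],
                         [f"c{i}" for i in range(25)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=3))
        q = make_dataset("q", list(d.features), [f"q{i}" for i in range(7)],
                         rng=np.random.default_rng(5))
        got = project_direct(q, model)
        x = q.dense()
        expected = np.zeros((7, 3))
        for c in range(7):
            for j in range(3):
                for f in range(10):
                    expected[c, j] += (x[f, c] - model.feature_means[f]) * model.loadings[f, j]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_missing_features_point_to_bridge(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(10)],
                         [f"c{i}" for i in range(25)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=3))
        q = make_dataset("q", [f"f{i}" for i in range(5)],
                         [f"q{i}" for i in range(4)], rng=rng)
        with pytest.raises(KeyError, match="bridge"):
            project_direct(q, model)


class TestBridge:
    def test_full_panel_bridge_recovers_direct_projection(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(15)],
                         [f"c{i}" for i in range(120)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=5))
        bridge = fit_bridge(model.scores, d, list(d.features))
        q = make_dataset("q", list(d.features), [f"q{i}" for i in range(30)],
                         rng=np.random.default_rng(3))
        np.testing.assert_allclose(
            apply_bridge(bridge, q), project_direct(q, model), atol=1e-7)

    def test_zero_scores_zero_coefficients(self, rng):
        d = make_dataset("src", ["f1", "f2"], [f"c{i}" for i in range(20)], rng=rng)
        bridge = fit_bridge(np.zeros((20, 3)), d, ["f1", "f2"])
        np.testing.assert_allclose(bridge.coefficients, 0.0, atol=1e-12)

    def test_exact_line_fit_recovers_slope_and_intercept(self, rng):
        x = rng.normal(size=(1, 30))
        d = Dataset("src", ["f1"], [f"c{i}" for i in range(30)], x)
        scores = (2.0 * x[0] + 1.0)[:, None]
        bridge = fit_bridge(scores, d, ["f1"])
        np.testing.assert_allclose(bridge.coefficients[:, 0], [1.0, 2.0], atol=1e-10)

    def test_rank_deficient_warns_and_uses_min_norm(self, rng):
        x = rng.normal(size=(1, 20))
        vals = np.vstack([x, 2 * x])  # collinear predictors
        d = Dataset("src", ["f1", "f2"], [f"c{i}" for i in range(20)], vals)
        with pytest.warns(RuntimeWarning, match="minimum-norm"):
            bridge = fit_bridge(rng.normal(size=(20, 2)), d, ["f1", "f2"])
        assert np.all(np.isfinite(bridge.coefficients))

    def test_apply_matches_hand_rolled_arithmetic(self, rng):
        d = make_dataset("src", ["f1", "f2", "f3"],
                         [f"c{i}" for i in range(25)], rng=rng)
        bridge = fit_bridge(rng.normal(size=(25, 4)), d, ["f1", "f3"])
        q = make_dataset("q", ["f3", "f1", "f9"], [f"q{i}" for i in range(6)],
                         rng=np.random.default_rng(9))
        got = apply_bridge(bridge, q)
        xs = q.submatrix(["f1", "f3"]).T
        expected = np.empty((6, 4))
        for c in range(6):
            for j in range(4):
                expected[c, j] = bridge.coefficients[0, j] + sum(
                    xs[c, f] * bridge.coefficients[1 + f, j] for f in range(2))
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestMultiHop:
    def test_path_of_length_one_returns_model_scores(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(10)],
                         [f"c{i}" for i in range(30)], rng=rng)
        model = fit_reference(d, StabMapConfig(n_dims=3))
        got = project_along_path(["ref"], {"ref": d}, model)
        np.testing.assert_allclose(got, model.scores)

    def test_two_hop_matches_direct_on_noiseless_rank2_chain(self):
        # noiseless rank-2 chain A-B-C; C secretly keeps the full panel so
        # direct projection with A's loadings is available as the oracle
        scenario = MosaicScenario(
            n_features=60, latent_dim=2, n_types=2,
            cells_per_dataset=(150, 150, 150),
            feature_panels=[list(range(40)), list(range(20, 60)), list(range(60))],
            noise_sd=0.0, seed=3,
        )
        datasets, _ = generate_mosaic(scenario)
        a, b, c_full = datasets
        c = c_full.subset_features([c_full.features[i] for i in range(30, 60)])
        model = fit_reference(a, StabMapConfig(n_dims=2))
        hops = project_along_path([a.name, b.name, c.name],
                                  {a.name: a, b.name: b, c.name: c}, model)
        oracle = project_direct(c_full, model)
        for j in range(2):
            r = np.corrcoef(hops[:, j], oracle[:, j])[0, 1]
            assert abs(r) > 0.99

    def test_disjoint_consecutive_pair_rejected(self, rng):
        a = make_dataset("A", ["f1", "f2"], ["a1", "a2", "a3"], rng=rng)
        b = make_dataset("B", ["g1", "g2"], ["b1", "b2"], rng=rng)
        model = fit_reference(a, StabMapConfig(n_dims=1))
        with pytest.raises(ValueError, match="share no features"):
            project_along_path(["A", "B"], {"A": a, "B": b}, model)


class TestReweighting:
    def test_equal_weights_equalize_l1_norms(self, rng):
        blocks = [rng.normal(size=(10, 4)), 100 * rng.normal(size=(10, 6))]
        out = reweight_blocks(blocks, [1.0, 1.0])
        assert np.abs(out[0]).sum() == pytest.approx(np.abs(out[1]).sum())

    def test_zero_weight_zeroes_block(self, rng):
        blocks = [rng.normal(size=(5, 2)), rng.normal(size=(5, 2))]
        out = reweight_blocks(blocks, [1.0, 0.0])
        np.testing.assert_allclose(out[1], 0.0)

    def test_half_weight_gives_two_to_one_norm_ratio(self, rng):
        blocks = [rng.normal(size=(8, 3)), rng.normal(size=(8, 3))]
        out = reweight_blocks(blocks, [1.0, 0.5])
        assert np.abs(out[0]).sum() / np.abs(out[1]).sum() == pytest.approx(2.0)

    def test_l2_option_equalizes_frobenius_norms(self, rng):
        blocks = [rng.normal(size=(10, 4)), 50 * rng.normal(size=(10, 6))]
        out = reweight_blocks(blocks, [1.0, 1.0], norm="l2")
        assert np.linalg.norm(out[0]) == pytest.approx(np.linalg.norm(out[1]))

    def test_zero_norm_block_rejected(self):
        with pytest.raises(ValueError, match="zero norm"):
            reweight_blocks([np.zeros((3, 2))], [1.0])


class TestStabmap:
    def test_two_references_50_dims_yield_100_columns(self, small_mosaic):
        datasets, _ = small_mosaic
        emb = stabmap(datasets, StabMapConfig(n_dims=50))
        assert emb.n_dims == 100
        assert emb.n_cells == sum(d.n_cells for d in datasets)
        assert np.all(np.isfinite(emb.values))
        assert emb.block_index[:50] == ["dataset_0"] * 50

    def test_single_dataset_embedding_is_scaled_pca(self, rng):
        d = make_dataset("only", [f"f{i}" for i in range(30)],
                         [f"c{i}" for i in range(60)], rng=rng)
        emb = stabmap([d], StabMapConfig(n_dims=5))
        model = fit_reference(d, StabMapConfig(n_dims=5))
        scale = np.abs(model.scores).sum()
        np.testing.assert_allclose(emb.values, model.scores / scale, atol=1e-10)

    def test_permutation_equivariance(self, small_mosaic, rng):
        datasets, _ = small_mosaic
        emb = stabmap(datasets, StabMapConfig(n_dims=10))
        d0 = datasets[0]
        perm = rng.permutation(d0.n_cells)
        d0p = d0.subset_cells([d0.cells[i] for i in perm])
        emb_p = stabmap([d0p, datasets[1]], StabMapConfig(n_dims=10))
        np.testing.assert_allclose(emb_p.rows(d0.cells), emb.rows(d0.cells), atol=1e-8)
        np.testing.assert_allclose(
            emb_p.rows(datasets[1].cells), emb.rows(datasets[1].cells), atol=1e-8)

    def test_embedding_distances_track_latent_distances(self):
        scenario = MosaicScenario(
            n_features=150, latent_dim=4, n_types=3,
            cells_per_dataset=(150, 150),
            feature_panels=[list(range(100)), list(range(60, 150))],
            noise_sd=0.05, seed=21,
        )
        datasets, truth = generate_mosaic(scenario)
        emb = stabmap(datasets, StabMapConfig(n_dims=10))
        cells = [c for d in datasets for c in d.cells]
        idx = np.random.default_rng(0).permutation(len(cells))[:80]
        pos = emb.rows([cells[i] for i in idx])
        lat = truth.latent[:, idx].T
        d_emb = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1).ravel()
        d_lat = np.linalg.norm(lat[:, None] - lat[None, :], axis=-1).ravel()
        rho = spearmanr(d_emb, d_lat).statistic
        assert rho > 0.8

    def test_disconnected_collection_rejected(self, rng):
        a = make_dataset("A", ["f1", "f2"], ["a1", "a2", "a3"], rng=rng)
        b = make_dataset("B", ["g1", "g2"], ["b1", "b2", "b3"], rng=rng)
        with pytest.raises(ValueError, match="disconnected"):
            stabmap([a, b])

    def test_user_supplied_reference_model_round_trip(self, rng):
        d = make_dataset("ref", [f"f{i}" for i in range(20)],
                         [f"c{i}" for i in range(50)], rng=rng)
        pca_model = fit_reference(d, StabMapConfig(n_dims=4))
        user = make_user_reference(
            "ref", pca_model.feature_names, pca_model.loadings,
            pca_model.feature_means, pca_model.scores, pca_model.cell_ids)
        assert user.mode == "user_supplied"
        np.testing.assert_allclose(project_direct(d, user), pca_model.scores,
                                   atol=1e-9)
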