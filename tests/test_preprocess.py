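import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from probeseq import preprocess as pp


def _toy_adata(counts, gene_prefix="G", origin=None, gene_names=None):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = gene_names or [f"{gene_prefix}{i}" for i in range(n_genes)]
    barcodes = [f"c{i}" for i in range(n_cells)]
    origin = origin or ["vehicle"] * n_cells
    return pp.make_count_matrix(counts, genes, barcodes, origin)


class TestQC:
    def test_gene_bounds_inclusive(self):
        counts = np.zeros((5, 5200))
        for i, n in enumerate((900, 1000, 3000, 5000, 5100)):
            counts[i, :n] = 1
        adata = _toy_adata(counts)
        kept = pp.filter_cells(adata)
        assert list(kept.obs["n_genes"]) == [1000, 3000, 5000]

    def test_mito_bound_strict(self):
        # 2000 detected genes each; second cell has exactly 20% mito UMIs
        genes = [f"MT-{i}" if i < 100 else f"G{i}" for i in range(2000)]
        counts = np.ones((2, 2000))
        counts[1, :100] = 4.75  # 475 mito / 2375 total = 0.20
        adata = _toy_adata(counts, gene_names=genes)
        assert adata.obs["pct_mito"].iloc[1] == pytest.approx(0.20)
        kept = pp.filter_cells(adata, min_genes=100, max_genes=5000, max_mito=0.20)
        assert kept.n_obs == 1

    def test_all_removed_is_error(self):
        adata = _toy_adata(np.ones((3, 50)))
        with pytest.raises(ValueError):
            pp.filter_cells(adata, min_genes=100, max_genes=200, max_mito=0.2)

    def test_origin_required(self):
        with pytest.raises(ValueError):
            pp.make_count_matrix(np.ones((2, 3)), ["a", "b", "c"], ["c0", "c1"], ["x"])


class TestNormalize:
    def test_hand_value(self):
        adata = _toy_adata([[10, 0]])
        pp.normalize_log(adata)
        x = np.asarray(adata.X.todense()).ravel()
        assert x[0] == pytest.approx(np.log(1 + 10_000), rel=1e-6)
        assert x[1] == 0.0

    def test_depth_invariance(self):
        base = np.array([[3, 7, 0, 5]])
        a = _toy_adata(base)
        b = _toy_adata(base * 2)
        pp.normalize_log(a), pp.normalize_log(b)
        np.testing.assert_allclose(
            np.asarray(a.X.todense()), np.asarray(b.X.todense()), rtol=1e-6
        )

    def test_zero_total_cell_rejected(self):
        adata = _toy_adata([[1, 2], [0, 0]])
        with pytest.raises(ValueError):
            pp.normalize_log(adata)

    def test_matches_reference_implementation(self):
        """Cross-check against the scanpy normalize/log1p chain."""
        import scanpy as sc

        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(30, 200))
        counts[:, 0] += 1  # no zero-total cells
        ours = _toy_adata(counts)
        pp.normalize_log(ours)
        ref = _toy_adata(counts)
        sc.pp.normalize_total(ref, target_sum=1e4)
        sc.pp.log1p(ref)
        np.testing.assert_allclose(
            np.asarray(ours.X.todense()), np.asarray(ref.X.todense()), rtol=1e-5
        )


class TestHVG:
    def test_planted_high_dispersion_recovered(self, rng):
        n_cells, n_genes, n_planted = 300, 2000, 50
        # heterogeneous baseline means, as in a real transcriptome
        mean = rng.lognormal(np.log(2.0), 0.8, n_genes)
        counts = rng.poisson(mean, size=(n_cells, n_genes)).astype(float)
        # planted genes: bimodal on/off expression -> high variance at their mean
        on = rng.random((n_cells, n_planted)) < 0.2
        counts[:, :n_planted] = np.where(on, rng.poisson(10.0, (n_cells, n_planted)), 0)
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        hvg = pp.select_hvg(adata, mean_bounds=(0.0, 10.0))
        hits = sum(1 for g in hvg if int(g[1:]) < n_planted)
        assert hits >= 45

    def test_constant_gene_never_selected(self, rng):
        counts = rng.poisson(3.0, size=(100, 100)).astype(float)
        counts[:, 0] = 5.0
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        assert "G0" not in pp.select_hvg(adata, n_bins=5, mean_bounds=(0.0, 10.0))

    def test_infinite_cutoff_selects_nothing(self, rng):
        counts = rng.poisson(3.0, size=(50, 60))
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        assert pp.select_hvg(adata, n_bins=5, z_cutoff=np.inf) == []


class TestScaleRegress:
    def test_no_covariates_is_zscore(self, rng):
        counts = rng.poisson(3.0, size=(40, 20)) + 1
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        Z = pp.scale_and_regress(adata, covariates=())
        X = np.asarray(adata.X.todense(), dtype=np.float64)
        expected = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(Z, expected, atol=1e-5)

    def test_covariate_effect_removed(self, rng):
        n = 200
        covar = rng.uniform(1.0, 3.0, n)
        counts = rng.poisson(np.outer(covar, np.full(30, 2.0))).astype(float)
        adata = _toy_adata(counts + 1)
        pp.normalize_log(adata)
        adata.obs["drive"] = covar
        Z = pp.scale_and_regress(adata, covariates=("drive",))
        corr = np.array([np.corrcoef(Z[:, g], covar)[0, 1] for g in range(Z.shape[1])])
        assert np.nanmax(np.abs(corr)) < 0.01

    def test_clipping(self, rng):
        counts = rng.poisson(2.0, size=(50, 10)) + 1
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        Z = pp.scale_and_regress(adata, covariates=(), clip=1.0)
        assert np.abs(Z).max() <= 1.0


class TestEmbeddings:
    def test_pca_orthogonal_and_ordered(self, rng):
        X = rng.standard_normal((100, 30))
        S = pp.pca_embed(X, n_components=5)
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8
        var = S.var(axis=0)
        assert np.all(np.diff(var) <= 1e-10)

    def test_rank2_recovery(self, rng):
        u = rng.standard_normal((80, 2))
        v = rng.standard_normal((2, 40))
        X = u @ v
        S = pp.pca_embed(X - X.mean(0), n_components=5)
        assert S[:, 2:].var() < 1e-20
        recon_rank = np.linalg.matrix_rank(S, tol=1e-8)
        assert recon_rank == 2

    def test_two_blobs_two_clusters(self, rng):
        X = np.vstack(
            [rng.standard_normal((60, 5)), rng.standard_normal((60, 5)) + 20.0]
        )
        labels = pp.knn_snn_cluster(X, k=15, resolution=0.5, seed=0)
        assert np.unique(labels).size == 2
        assert adjusted_rand_score(labels, [0] * 60 + [1] * 60) == 1.0

    def test_planted_five_clusters(self, rng):
        centers = rng.standard_normal((5, 10)) * 12.0
        X = np.vstack([c + rng.standard_normal((50, 10)) for c in centers])
        truth = np.repeat(np.arange(5), 50)
        labels = pp.knn_snn_cluster(X, k=20, resolution=0.8, seed=0)
        assert adjusted_rand_score(labels, truth) >= 0.9

    def test_k_bound(self, rng):
        with pytest.raises(ValueError):
            pp.knn_snn_cluster(rng.standard_normal((10, 3)), k=10)

    def test_tsne_shape_and_determinism(self, rng):
        X = rng.standard_normal((60, 8))
        a = pp.embed_2d(X, seed=3)
        b = pp.embed_2d(X, seed=3)
        assert a.shape == (60, 2)
        np.testing.assert_array_equal(a, b)

    def test_tsne_preserves_separation(self, rng):
        X = np.vstack(
            [rng.standard_normal((50, 6)), rng.standard_normal((50, 6)) + 25.0]
        )
        coords = pp.embed_2d(X, seed=0)
        assert silhouette_score(coords, [0] * 50 + [1] * 50) > 0.5


class TestCellCycle:
    def _scored_adata(self, rng, planted=True):
        n_cells, n_genes, n_mark = 200, 500, 20
        # heterogeneous baseline so expression bins mix markers with background
        mean = rng.lognormal(np.log(2.0), 0.8, n_genes)
        counts = rng.poisson(mean, size=(n_cells, n_genes)).astype(float)
        s_cells = np.zeros(n_cells, bool)
        s_cells[:60] = True
        if planted:
            counts[np.ix_(s_cells, np.arange(n_mark))] *= 6.0
        adata = _toy_adata(counts)
        pp.normalize_log(adata)
        s_genes = [f"G{i}" for i in range(n_mark)]
        g2m_genes = [f"G{i}" for i in range(n_mark, 2 * n_mark)]
        return adata, s_genes, g2m_genes, s_cells

    def test_background_like_markers_score_near_zero(self, rng):
        adata, s_genes, g2m_genes, _ = self._scored_adata(rng, planted=False)
        scores = pp.cell_cycle_scores(adata, s_genes, g2m_genes, seed=0)
        assert abs(scores.s_score.mean()) < 0.05
        assert abs(scores.g2m_score.mean()) < 0.05

    def test_planted_program_scores_positive(self, rng):
        adata, s_genes, g2m_genes, s_cells = self._scored_adata(rng)
        scores = pp.cell_cycle_scores(adata, s_genes, g2m_genes, seed=0)
        assert (scores.s_score[s_cells] > 0).mean() >= 0.95

    def test_seed_reproducibility(self, rng):
        adata, s_genes, g2m_genes, _ = self._scored_adata(rng)
        a = pp.cell_cycle_scores(adata, s_genes, g2m_genes, seed=7)
        b = pp.cell_cycle_scores(adata, s_genes, g2m_genes, seed=7)
        np.testing.assert_array_equal(a.s_score, b.s_score)
        np.testing.assert_array_equal(a.g2m_score, b.g2m_score)

    def test_missing_markers_warn_and_all_missing_error(self, rng):
        adata, s_genes, g2m_genes, _ = self._scored_adata(rng)
        with pytest.warns(UserWarning):
            pp.cell_cycle_scores(adata, s_genes + ["NOPE"], g2m_genes, seed=0)
        with pytest.raises(ValueError):
            pp.cell_cycle_scores(adata, ["NOPE1", "NOPE2"], g2m_genes, seed=0)


class TestAssignStage:
    @pytest.mark.parametrize(
        "s, g2m, expected",
        [
            (-0.1, -0.2, "G0/G1"),
            (0.5, 0.1, "S"),
            (0.1, 0.5, "G2/M"),
            (0.0, 0.0, "G0/G1"),
            (0.3, 0.3, "S"),      # positive tie goes to S
            (0.2, -0.1, "S"),     # single positive score wins
            (-0.1, 0.2, "G2/M"),
        ],
    )
    def test_rule(self, s, g2m, expected):
        scores = pp.CellCycleScores(np.array([s]), np.array([g2m]))
        assert pp.assign_stage(scores)[0] == expected

    def test_every_cell_assigned_once(self, rng):
        scores = pp.CellCycleScores(rng.standard_normal(500), rng.standard_normal(500))
        stages = pp.assign_stage(scores)
        assert set(stages) <= set(pp.STAGES)
        assert len(stages) == 500
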