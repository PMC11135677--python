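import numpy as np
import pytest

from urbantol.errors import (DegenerateLayerError, ExtentError, MetadataError,
                             ParameterError)
from urbantol.grid import GridSpec, Raster
from urbantol.synthetic import default_grid, generate_environment
from urbantol.urban_intensity import align_layers, composite_pca


def _rand_layers(n_layers, grid, seed=0, corr=None):
    rng = np.random.default_rng(seed)
    if corr is None:
        return [Raster(grid, rng.normal(size=grid.shape), name=f"l{i}")
                for i in range(n_layers)]


@pytest.fixture
def grid9():
    return GridSpec(n_rows=9, n_cols=9, cell_size=1.0, origin=(0.0, 0.0))


class TestAlign:
    def test_layer_already_on_grid_is_identity(self, grid9):
        layer = Raster(grid9, np.arange(81.0).reshape(9, 9))
        out, = align_layers([layer], grid9)
        np.testing.assert_array_equal(out.values, layer.values)

    def test_mean_aggregation_of_2x2_block(self):
        # 2x2 source cells (1,2,3,4) aggregate to a single cell -> 2.5
        src = GridSpec(n_rows=2, n_cols=2, cell_size=1.0, origin=(0.0, 0.0))
        tgt = GridSpec(n_rows=1, n_cols=1, cell_size=2.0, origin=(0.0, 0.0))
        layer = Raster(src, np.array([[1.0, 2.0], [3.0, 4.0]]))
        out, = align_layers([layer], tgt, resampling="mean")
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_constant_finer_layer_stays_constant(self):
        src = GridSpec(n_rows=8, n_cols=8, cell_size=0.5, origin=(0.0, 0.0))
        tgt = GridSpec(n_rows=4, n_cols=4, cell_size=1.0, origin=(0.0, 0.0))
        layer = Raster(src, np.full((8, 8), 7.25))
        out, = align_layers([layer], tgt, resampling="mean")
        np.testing.assert_allclose(out.values, 7.25)

    def test_zero_overlap_raises_extent_error(self, grid9):
        far = GridSpec(n_rows=2, n_cols=2, cell_size=1.0, origin=(100.0, 100.0))
        with pytest.raises(ExtentError):
            align_layers([Raster(far, np.ones((2, 2)))], grid9)

    def test_frame_mismatch_raises_metadata_error(self, grid9):
        other = default_grid(9, 9)  # projected frame, not grid-units
        with pytest.raises(MetadataError):
            align_layers([Raster(other, np.ones((9, 9)))], grid9)


class TestCompositePCA:
    def test_identical_layers_pc1_explains_everything(self, grid9):
        base = np.random.default_rng(0).normal(size=(9, 9))
        stack = [Raster(grid9, 2.0 * base + 1.0, name="a"),
                 Raster(grid9, base, name="b"),
                 Raster(grid9, -3.0 * base, name="c")]
        pc1 = composite_pca(stack, reference_layer="b")
        assert pc1.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_layer_variance_share_is_closed_form(self, grid9, seed):
        """For 2 standardized layers with sample correlation r the 2x2
        correlation matrix has eigenvalues 1 +- r, so PC1's share is (1+|r|)/2."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(9, 9))
        b = 0.6 * a + rng.normal(size=(9, 9))
        stack = [Raster(grid9, a, name="a"), Raster(grid9, b, name="b")]
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        pc1 = composite_pca(stack)
        assert pc1.variance_explained[0] == pytest.approx((1 + abs(r)) / 2, abs=1e-9)

    def test_orientation_is_sign_stable(self, grid9):
        stack = _rand_layers(3, grid9, seed=3)
        ref = stack[1]
        out1 = composite_pca(stack, reference_layer=1)
        out2 = composite_pca([Raster(grid9, -s.values, name=s.name) for s in stack],
                             reference_layer=1)
        # negating every input leaves oriented scores' correlation with the
        # (negated) reference intact: both runs satisfy corr(pc1, ref) >= 0
        v1 = out1.values.ravel()
        assert np.corrcoef(v1, ref.flat)[0, 1] >= 0
        v2 = out2.values.ravel()
        assert np.corrcoef(v2, -ref.flat)[0, 1] >= 0

    def test_layer_permutation_changes_only_loading_order(self, grid9):
        stack = _rand_layers(3, grid9, seed=4)
        out = composite_pca(stack, reference_layer="l1")
        out_perm = composite_pca([stack[2], stack[0], stack[1]],
                                 reference_layer="l1")
        np.testing.assert_allclose(out_perm.values, out.values, atol=1e-9)

    def test_scores_zero_mean_and_eigenvalue_variance(self, grid9):
        stack = _rand_layers(3, grid9, seed=5)
        out = composite_pca(stack)
        scores = out.values.ravel()
        assert scores.mean() == pytest.approx(0.0, abs=1e-10)
        Z = np.column_stack([(s.flat - s.flat.mean()) / s.flat.std() for s in stack])
        lam1 = np.linalg.eigvalsh(Z.T @ Z / len(Z)).max()
        assert scores.var() == pytest.approx(lam1, rel=1e-6)

    def test_svd_matches_eigendecomposition_oracle(self, grid9):
        """Dual route: the SVD-based PC1 equals PC1 from an explicit
        correlation-matrix eigendecomposition to 1e-8."""
        stack = _rand_layers(4, grid9, seed=6)
        out = composite_pca(stack, reference_layer=0)
        Z = np.column_stack([(s.flat - s.flat.mean()) / s.flat.std() for s in stack])
        C = Z.T @ Z / len(Z)
        vals, vecs = np.linalg.eigh(C)
        v1 = vecs[:, np.argmax(vals)]
        scores = Z @ v1
        if np.dot(scores, Z[:, 0]) < 0:
            scores = -scores
        np.testing.assert_allclose(out.values.ravel(), scores, atol=1e-8)
        assert out.variance_explained[0] == pytest.approx(
            vals.max() / vals.sum(), abs=1e-10)

    def test_constant_layer_is_named_in_error(self, grid9):
        stack = [Raster(grid9, np.random.default_rng(1).normal(size=(9, 9)), name="ok"),
                 Raster(grid9, np.full((9, 9), 3.0), name="flatliner")]
        with pytest.raises(DegenerateLayerError, match="flatliner"):
            composite_pca(stack)

    def test_missing_cells_excluded_and_flagged(self, grid9):
        stack = _rand_layers(2, grid9, seed=7)
        stack[0].values[0, 0] = np.nan
        out = composite_pca(stack)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values.ravel()).sum() == 80

    def test_retention_check_warns_not_fails(self, grid9, caplog):
        stack = _rand_layers(3, grid9, seed=8)  # nearly uncorrelated layers
        with caplog.at_level("WARNING"):
            out = composite_pca(stack)
        assert not out.retained_ok
        assert any("PC1 explains" in m for m in caplog.messages)


class TestGeneratedEnvironment:
    def test_degenerate_correlation_gives_affine_layers(self):
        grid = default_grid(20, 20)
        layers = generate_environment(grid, n_layers=3, correlation=1.0, seed=0)
        pc1 = composite_pca(layers)
        assert pc1.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        # affine: perfect pairwise correlation
        r = np.corrcoef(layers[0].flat, layers[2].flat)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_layers_split_variance(self):
        grid = default_grid(80, 80)
        layers = generate_environment(grid, n_layers=2, correlation=0.0, seed=0)
        pc1 = composite_pca(layers)
        r = abs(np.corrcoef(layers[0].flat, layers[1].flat)[0, 1])
        assert pc1.variance_explained[0] == pytest.approx((1 + r) / 2, abs=1e-9)
        assert pc1.variance_explained[0] < 0.65  # near 1/2 up to sampling noise

    def test_generator_is_deterministic(self):
        grid = default_grid(15, 15)
        a = generate_environment(grid, 3, 0.8, seed=42)
        b = generate_environment(grid, 3, 0.8, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)

    def test_invalid_correlation_rejected(self):
        grid = default_grid(5, 5)
        with pytest.raises(ParameterError):
            generate_environment(grid, 3, correlation=1.5, seed=0)
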