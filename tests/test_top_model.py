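"""Stage 3: design-matrix plumbing, OPLS-DA, prediction, leukocyte map."""

import numpy as np
import pytest

from damacy import (
    filter_low_variance_bins,
    fit_oplsda,
    predict_scores,
    refold_weights,
    vectorize_histograms,
)
from damacy.histogram import BinGrid, SampleHistogram, build_histogram, smooth_histogram
from damacy.top_model import DegenerateDesignError, HistogramDesignMatrix, refold_vector
from damacy import preprocess as pp
from damacy import base_model as bm


def _hist(values, grid=None):
    values = np.asarray(values, dtype=float)
    return SampleHistogram(values=values, individual_id="x", n_cells=1, grid=grid)


def _design(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return HistogramDesignMatrix(
        matrix=matrix,
        bin_mask=np.ones(matrix.shape[1], dtype=bool),
        grid_shape=(matrix.shape[1],),
    )


class TestVectorize:
    def test_round_trip_restores_position(self):
        h = np.zeros((3, 3))
        h[1, 2] = 1.0  # row 2, col 3 in one-based terms
        design = vectorize_histograms([_hist(h)])
        assert design.matrix[0, 1 * 3 + 2] == 1.0  # C order position
        refolded = refold_vector(design.matrix[0], design.bin_mask, (3, 3))
        np.testing.assert_array_equal(refolded, h)

    def test_rows_keep_unit_mass(self):
        rng = np.random.default_rng(0)
        grid = BinGrid(f_bins=8, anchor=(0.0, 0.0), delta=(1.0, 1.0))
        hists = [
            smooth_histogram(build_histogram(rng.uniform(0, 8, (50, 2)), grid), 2.0)
            for _ in range(5)
        ]
        design = vectorize_histograms(hists)
        np.testing.assert_allclose(design.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_round_trip_under_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mask = rng.uniform(size=12) > 0.4
            mask[0] = True
            vec = rng.normal(size=int(mask.sum()))
            grid_shape = (3, 4)
            refolded = refold_vector(vec, mask, grid_shape)
            np.testing.assert_array_equal(refolded.ravel(order="C")[mask], vec)
            assert np.all(refolded.ravel(order="C")[~mask] == 0)

    def test_grid_mismatch_rejected(self):
        g1 = BinGrid(f_bins=4, anchor=(0.0,), delta=(1.0,))
        g2 = BinGrid(f_bins=4, anchor=(1.0,), delta=(1.0,))
        with pytest.raises(ValueError, match="grid"):
            vectorize_histograms([_hist(np.ones(4) / 4, g1), _hist(np.ones(4) / 4, g2)])


class TestVarianceFilter:
    def test_constant_zero_bin_removed_varying_bin_kept(self):
        c = np.array([[0.0, 0.0, 0.3], [0.0, 0.5, 0.4], [0.0, 0.0, 0.5], [0.0, 0.5, 0.6]])
        filtered = filter_low_variance_bins(_design(c), threshold=1e-6)
        np.testing.assert_array_equal(filtered.bin_mask, [False, True, True])
        assert filtered.matrix.shape == (4, 2)

    def test_survivor_count_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(size=(6, 40))
        c[:, 10:20] = 0.123  # planted constant region
        c[:, 25] = c[0, 25]  # another constant column
        threshold = 1e-6
        expected = sum(
            1 for j in range(40)
            if np.mean((c[:, j] - c[:, j].mean()) ** 2) >= threshold
        )
        filtered = filter_low_variance_bins(_design(c), threshold)
        assert filtered.matrix.shape[1] == expected == 29

    def test_all_columns_removed_is_degenerate(self):
        c = np.tile([0.25, 0.25, 0.5, 0.0], (4, 1))
        with pytest.raises(DegenerateDesignError):
            filter_low_variance_bins(_design(c), threshold=1e-6)


class TestOplsda:
    def _separated_design(self, rng, n=12, p=30, delta=0.3):
        y = np.repeat([1, 2], n // 2)
        c = rng.uniform(0.1, 0.2, size=(n, p))
        c[y == 2, 1] += delta  # group 2 high in bin 2
        c /= c.sum(axis=1, keepdims=True)
        return _design(c), y

    def test_weight_sign_follows_coding(self):
        rng = np.random.default_rng(3)
        design, y = self._separated_design(rng)
        model = fit_oplsda(design, y, n_ortho=0)
        assert model.w_top[1] > 0  # challenged-enriched bin gets positive weight
        assert np.all(model.t_top[y == 2] > model.t_top[y == 1].max())

    def test_zero_ortho_matches_nipals_pls1_oracle(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        design, y = self._separated_design(rng, n=16, p=50, delta=0.1)
        model = fit_oplsda(design, y, n_ortho=0)
        oracle = PLSRegression(n_components=1, scale=False)
        oracle.fit(design.matrix, np.where(y == 1, -1.0, 1.0))
        t_oracle = oracle.x_scores_[:, 0]
        corr = np.corrcoef(model.t_top, t_oracle)[0, 1]
        assert abs(corr) >= 1.0 - 1e-8

    def test_orthogonal_scores_uncorrelated_with_y_and_t(self):
        rng = np.random.default_rng(5)
        design, y = self._separated_design(rng, n=14, p=40)
        model = fit_oplsda(design, y, n_ortho=2)
        y_signed = np.where(y == 1, -1.0, 1.0)
        for j in range(2):
            assert abs(np.cov(model.t_ortho[:, j], y_signed)[0, 1]) < 1e-8
            assert abs(model.t_top @ model.t_ortho[:, j]) < 1e-8

    def test_osc_filter_removes_added_back_components(self):
        """Training predictions are invariant to re-adding T_o P_o^T."""
        rng = np.random.default_rng(6)
        design, y = self._separated_design(rng, n=14, p=40)
        model = fit_oplsda(design, y, n_ortho=1)
        # raw training rows (never deflated) score exactly t_top
        np.testing.assert_allclose(predict_scores(model, design.matrix), model.t_top, atol=1e-10)
        # explicitly re-add the orthogonal structure to the deflated matrix
        xc_def = (design.matrix - model.column_center)
        for j in range(model.n_ortho):
            t_o = xc_def @ model.w_ortho[:, j]
            xc_def = xc_def - np.outer(t_o, model.p_ortho[:, j])
        back = xc_def + model.t_ortho @ model.p_ortho.T + model.column_center
        np.testing.assert_allclose(predict_scores(model, back), model.t_top, atol=1e-10)

    def test_label_swap_negates_weights_and_scores(self):
        rng = np.random.default_rng(7)
        design, y = self._separated_design(rng)
        m1 = fit_oplsda(design, y, n_ortho=1)
        m2 = fit_oplsda(design, 3 - y, n_ortho=1)  # swap groups 1 <-> 2
        np.testing.assert_allclose(m1.w_top, -m2.w_top, atol=1e-10)
        np.testing.assert_allclose(m1.t_top, -m2.t_top, atol=1e-10)

    def test_single_class_and_excessive_n_ortho_rejected(self):
        rng = np.random.default_rng(8)
        design, y = self._separated_design(rng, n=6)
        with pytest.raises(ValueError, match="2 classes"):
            fit_oplsda(design, np.ones_like(y))
        with pytest.raises(ValueError, match="n_ortho"):
            fit_oplsda(design, y, n_ortho=5)

    def test_mean_histogram_scores_zero_and_affinity(self):
        rng = np.random.default_rng(9)
        design, y = self._separated_design(rng, n=12, p=20)
        model = fit_oplsda(design, y, n_ortho=1)
        mean_row = design.matrix.mean(axis=0)
        assert abs(predict_scores(model, mean_row)[0]) < 1e-12
        # score is affine in the histogram: s(a*h1 + (1-a)*h2) = a*s1 + (1-a)*s2
        h1, h2 = design.matrix[0], design.matrix[-1]
        a = 0.3
        s = predict_scores(model, np.vstack([h1, h2, a * h1 + (1 - a) * h2]))
        assert s[2] == pytest.approx(a * s[0] + (1 - a) * s[1], abs=1e-12)


class TestLeukocyteMap:
    def test_refold_round_trip_and_masked_zeros(self):
        rng = np.random.default_rng(10)
        c = rng.uniform(size=(8, 16))
        design = HistogramDesignMatrix(
            matrix=c, bin_mask=np.ones(16, dtype=bool), grid_shape=(4, 4)
        )
        design = filter_low_variance_bins(design, threshold=0.0)
        y = np.repeat([1, 2], 4)
        model = fit_oplsda(design, y, n_ortho=0)
        lmap = refold_weights(model)
        np.testing.assert_array_equal(
            lmap.weights.ravel(order="C")[model.bin_mask], model.w_top
        )
        assert np.all(lmap.weights.ravel(order="C")[~model.bin_mask] == 0)

    def test_non_2d_grid_rejected(self):
        rng = np.random.default_rng(11)
        c = rng.uniform(size=(6, 8))
        design = HistogramDesignMatrix(
            matrix=c, bin_mask=np.ones(8, dtype=bool), grid_shape=(8,)
        )
        model = fit_oplsda(design, np.repeat([1, 2], 3), n_ortho=0)
        with pytest.raises(ValueError, match="2-component"):
            refold_weights(model)

    def test_max_weight_bin_sits_on_planted_population(self, lps_cohort, lps_model):
        """The strongest map weight marks where the group-specific cells live."""
        dataset, truth = lps_cohort
        model = lps_model
        x_cs = pp.apply_preprocess(dataset, model.preprocess)
        comps = list(model.config.histogram_components())
        scores = bm.project_cells(x_cs, model.base)[:, comps]
        planted = truth.cell_population == truth.population_names.index("planted_gradient")
        dens = smooth_histogram(
            build_histogram(scores[planted], model.grid), model.config.smoothing_factor
        ).values.ravel()
        order = np.argsort(dens)[::-1]
        region = np.zeros(dens.size, bool)
        region[order[: np.searchsorted(np.cumsum(dens[order]), 0.95) + 1]] = True
        w = model.leukocyte_map().weights.ravel(order="C")
        assert region[np.argmax(np.abs(w))]
        assert w[np.argmax(np.abs(w))] > 0  # challenged-enriched
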