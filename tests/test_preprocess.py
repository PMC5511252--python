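"""Stage 1: log transform and multiset centring/scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damacy import MFCDataset, apply_preprocess, fit_preprocess, log_transform
from damacy.preprocess import (
    DegenerateMarkerError,
    apply_centring,
    apply_scaling,
    fit_centring,
    fit_scaling,
)

from conftest import make_dataset


class TestLogTransform:
    def test_powers_of_ten(self):
        ds = make_dataset([[[1.0], [10.0], [100.0], [1000.0]]], groups=[1])
        logged, shift = log_transform(ds)
        assert shift == 0.0
        np.testing.assert_allclose(logged.values.ravel(), [0, 1, 2, 3])

    def test_negative_minimum_triggers_shift(self):
        ds = make_dataset([[[-9.0], [91.0]]], groups=[1])
        logged, shift = log_transform(ds)
        assert shift == 10.0
        np.testing.assert_allclose(logged.values.ravel(), [0.0, np.log10(101.0)])

    def test_monotone_and_identity_shift_for_data_above_one(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1.0, 1e4, size=(50, 2))
        ds = make_dataset([vals], groups=[1])
        logged, shift = log_transform(ds)
        assert shift == 0.0
        for j in range(2):
            order = np.argsort(vals[:, j])
            assert np.all(np.diff(logged.values[order, j]) >= 0)

    def test_non_finite_rejected(self):
        ds = make_dataset([[[1.0], [2.0]]], groups=[1])
        ds.values[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            log_transform(ds)


class TestCentring:
    def test_overall_center_is_unweighted_over_individuals(self, two_individual_dataset):
        model = fit_centring(two_individual_dataset, "overall")
        # 10-cell and 1000-cell individuals weigh equally
        np.testing.assert_allclose(model.overall_center, [1.0, 3.0], atol=1e-12)

    def test_single_individual_center_is_its_mean(self):
        rng = np.random.default_rng(4)
        block = rng.normal(size=(20, 3))
        ds = make_dataset([block], groups=[1])
        model = fit_centring(ds)
        np.testing.assert_allclose(model.overall_center, block.mean(axis=0))

    def test_matches_explicit_two_step_loop(self):
        rng = np.random.default_rng(5)
        blocks = [rng.normal(size=(n, 3)) for n in (5, 17, 40)]
        ds = make_dataset(blocks, groups=[1, 1, 2])
        model = fit_centring(ds)
        expected = np.zeros(3)
        for j in range(3):
            acc = 0.0
            for b in blocks:
                acc += sum(row[j] for row in b) / len(b)
            expected[j] = acc / len(blocks)
        np.testing.assert_allclose(model.overall_center, expected, atol=1e-12)

    def test_centred_individual_means(self, two_individual_dataset):
        model = fit_centring(two_individual_dataset)
        centred = apply_centring(two_individual_dataset, model)
        means = np.array([centred.cells_of(i).mean(axis=0) for i in range(2)])
        np.testing.assert_allclose(means, [[-1, -1], [1, 1]], atol=1e-12)
        # overall-mode invariant: centred per-individual means average to zero
        np.testing.assert_allclose(means.mean(axis=0), 0.0, atol=1e-10)

    def test_per_individual_mode_self_centres(self, two_individual_dataset):
        model = fit_centring(two_individual_dataset, "per_individual")
        centred = apply_centring(two_individual_dataset, model)
        for i in range(2):
            np.testing.assert_allclose(centred.cells_of(i).mean(axis=0), 0.0, atol=1e-12)

    def test_apply_twice_shifts_by_two_centres(self, two_individual_dataset):
        model = fit_centring(two_individual_dataset)
        twice = apply_centring(apply_centring(two_individual_dataset, model), model)
        np.testing.assert_allclose(
            twice.values, two_individual_dataset.values - 2 * model.overall_center
        )

    def test_median_mode_uses_medians_at_both_levels(self):
        blocks = [np.array([[0.0], [0.0], [10.0]]), np.array([[4.0], [5.0], [6.0]])]
        ds = make_dataset(blocks, groups=[1, 2])
        model = fit_centring(ds, "median_overall")
        # per-individual medians 0 and 5, median across individuals = 2.5
        np.testing.assert_allclose(model.overall_center, [2.5])


class TestScaling:
    def test_mean_variance_over_individuals(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(200, 1))
        b = rng.normal(size=(300, 1))
        a = (a - a.mean()) / a.std() * 1.0  # variance exactly 1
        b = (b - b.mean()) / b.std() * np.sqrt(3.0)  # variance exactly 3
        ds = make_dataset([a, b], groups=[1, 2])
        model = fit_scaling(ds)
        np.testing.assert_allclose(model.scale_s, [np.sqrt(2.0)], atol=1e-12)

    def test_degenerate_marker_named(self):
        ds = make_dataset([np.ones((5, 2)) * [3.0, 1.0]], groups=[1])
        ds.values[:, 0] += np.arange(5)  # marker M1 varies, M2 constant
        with pytest.raises(DegenerateMarkerError, match="M2"):
            fit_scaling(ds)

    def test_apply_divides_by_scale(self):
        ds = make_dataset([[[-2.0], [2.0]]], groups=[1])
        model = fit_scaling(ds)
        model.scale_s = np.array([2.0])
        scaled = apply_scaling(ds, model)
        np.testing.assert_allclose(scaled.values.ravel(), [-1.0, 1.0])

    def test_pooled_scale_of_scaled_training_data_is_one(self, two_individual_dataset):
        model = fit_centring(two_individual_dataset)
        centred = apply_centring(two_individual_dataset, model)
        fit_scaling(centred, "pooled", model=model)
        scaled = apply_scaling(centred, model)
        recheck = fit_scaling(scaled)
        np.testing.assert_allclose(recheck.scale_s, 1.0, atol=1e-10)

    def test_scale_mode_none_is_identity(self, two_individual_dataset):
        model = fit_scaling(two_individual_dataset, "none")
        scaled = apply_scaling(two_individual_dataset, model)
        np.testing.assert_array_equal(scaled.values, two_individual_dataset.values)


class TestMultisetInvariants:
    def test_replicating_one_individual_changes_nothing(self):
        """Equal weighting: r-fold cell replication leaves m and s alone."""
        rng = np.random.default_rng(8)
        blocks = [rng.normal(size=(n, 3)) for n in (12, 30)]
        ds = make_dataset(blocks, groups=[1, 2])
        rep = make_dataset([np.tile(blocks[0], (3, 1)), blocks[1]], groups=[1, 2])
        m1, m2 = fit_centring(ds), fit_centring(rep)
        np.testing.assert_allclose(m1.overall_center, m2.overall_center, atol=1e-12)
        s1 = fit_scaling(apply_centring(ds, m1))
        s2 = fit_scaling(apply_centring(rep, m2))
        np.testing.assert_allclose(s1.scale_s, s2.scale_s, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), perm_seed=st.integers(0, 10_000))
    def test_commutes_with_marker_permutation(self, seed, perm_seed):
        rng = np.random.default_rng(seed)
        blocks = [10 ** rng.normal(2.0, 0.4, size=(n, 4)) for n in (8, 15)]
        ds = make_dataset(blocks, groups=[1, 2])
        perm = np.random.default_rng(perm_seed).permutation(4)
        ds_p = make_dataset(
            [b[:, perm] for b in blocks],
            groups=[1, 2],
            marker_names=[ds.marker_names[p] for p in perm],
        )
        x1, _ = fit_preprocess(ds)
        x2, _ = fit_preprocess(ds_p)
        np.testing.assert_allclose(x1.values[:, perm], x2.values, atol=1e-10)

    def test_held_out_sample_identical_to_training_transforms_identically(self):
        rng = np.random.default_rng(9)
        blocks = [10 ** rng.normal(2.0, 0.3, size=(20, 3)) for _ in range(4)]
        ds = make_dataset(blocks, groups=[1, 1, 2, 2])
        x_cs, model = fit_preprocess(ds)
        held_out = make_dataset([blocks[2]], groups=[2], ids=["new"])
        transformed = apply_preprocess(held_out, model)
        np.testing.assert_allclose(
            transformed.values, x_cs.values[ds.cell_to_individual == 2], atol=1e-12
        )
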