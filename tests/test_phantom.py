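"""Synthetic phantom: atlas geometry, embeddings, extraction and Pearson FC."""

import numpy as np
import pytest

from atatnet import (PhantomSpec, block_covariance, extract_empirical_series,
                     hub_covariance, make_atlas, normalize_embeddings, pearson_fc,
                     simulate_phantom)
from atatnet.phantom import Atlas, GeometryError, InvalidAtlasError

import pandas as pd


class TestNormalizeEmbeddings:
    def _atlas_from_centers(self, centers, volumes=None):
        n = len(centers)
        volumes = volumes or [10] * n
        table = pd.DataFrame({
            "index": range(1, n + 1), "name": [f"ROI{i}" for i in range(1, n + 1)],
            "cx": [c[0] for c in centers], "cy": [c[1] for c in centers],
            "cz": [c[2] for c in centers], "volume": volumes})
        return Atlas(table, [])

    def test_min_max_identity_on_three_centers(self):
        atlas = self._atlas_from_centers([(10, 0, 0), (20, 0, 0), (30, 0, 0)])
        emb = normalize_embeddings(atlas)
        assert np.allclose(emb[:, 0], [0.0, 0.5, 1.0])

    def test_constant_component_maps_to_half(self):
        atlas = self._atlas_from_centers([(1, 2, 3), (4, 5, 6)], volumes=[7, 7])
        emb = normalize_embeddings(atlas)
        assert np.allclose(emb[:, 3], 0.5)

    def test_hand_computed_min_max(self):
        # x = (3, 7, 5, 9): (x - 3) / 6 -> (0, 2/3, 1/3, 1)
        atlas = self._atlas_from_centers([(3, 0, 0), (7, 0, 0), (5, 0, 0), (9, 0, 0)])
        emb = normalize_embeddings(atlas)
        assert np.allclose(emb[:, 0], [0.0, 2 / 3, 1 / 3, 1.0])

    def test_rejects_single_roi(self):
        atlas = self._atlas_from_centers([(1, 1, 1)])
        with pytest.raises(InvalidAtlasError):
            normalize_embeddings(atlas)

    def test_all_components_in_unit_interval(self, tiny_cohort):
        emb = tiny_cohort[0].embeddings
        assert emb.min() >= 0.0 and emb.max() <= 1.0


class TestAtlasGeometry:
    def test_masks_are_pairwise_disjoint_with_exact_volumes(self):
        atlas = make_atlas((16, 16, 16), 8, 2)
        total = np.zeros((16, 16, 16), dtype=int)
        for mask, vol in zip(atlas.masks, atlas.table["volume"]):
            assert mask.sum() == vol >= 1
            total += mask
        assert total.max() == 1

    def test_too_many_rois_raise_geometry_error(self):
        with pytest.raises(GeometryError):
            make_atlas((8, 8, 8), 100, 2)


class TestSimulatePhantom:
    def test_same_seed_is_bit_identical(self, tiny_spec):
        v1, _, g1 = simulate_phantom(tiny_spec, 0, seed=42)
        v2, _, g2 = simulate_phantom(tiny_spec, 0, seed=42)
        assert np.array_equal(v1, v2) and np.array_equal(g1, g2)

    def test_zero_noise_voxels_carry_exact_roi_series(self, tiny_spec):
        spec = PhantomSpec(**{**tiny_spec.__dict__, "noise_sd": 0.0})
        vol, atlas, gt = simulate_phantom(spec, 0, seed=5)
        for i, mask in enumerate(atlas.masks):
            assert np.allclose(vol[mask, :], gt[i], atol=0)
        out_of_roi = ~np.logical_or.reduce(atlas.masks)
        assert np.all(vol[out_of_roi, :] == 0)

    def test_non_psd_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        spec = PhantomSpec(grid_shape=(8, 8, 8), n_rois=2, n_timepoints=8,
                           roi_radius=1, class_covariances={0: bad})
        with pytest.raises(ValueError, match="positive semidefinite"):
            spec.validate()

    def test_planted_block_correlation_recovered_at_q200(self):
        # two 4-ROI communities at r = 0.8; sample correlation of the latent
        # series should fall in [0.7, 0.9] for >= 90% of within-block pairs
        cov = block_covariance(8, [[0, 1, 2, 3], [4, 5, 6, 7]], 0.8)
        spec = PhantomSpec(grid_shape=(32, 32, 32), n_rois=8, n_timepoints=200,
                           roi_radius=2, class_covariances={0: cov}, noise_sd=0.0)
        hits = total = 0
        for seed in range(5):
            _, _, gt = simulate_phantom(spec, 0, seed=seed)
            corr = pearson_fc(gt)
            for block in ([0, 1, 2, 3], [4, 5, 6, 7]):
                for a in block:
                    for b in block:
                        if a < b:
                            total += 1
                            hits += 0.7 <= corr[a, b] <= 0.9
        assert hits / total >= 0.9


class TestExtractEmpiricalSeries:
    def test_zero_noise_extraction_recovers_standardized_truth(self, tiny_spec):
        spec = PhantomSpec(**{**tiny_spec.__dict__, "noise_sd": 0.0})
        vol, atlas, gt = simulate_phantom(spec, 1, seed=9)
        fe = extract_empirical_series(vol, atlas)
        z = (gt - gt.mean(axis=1, keepdims=True)) / gt.std(axis=1, keepdims=True)
        assert np.allclose(fe, z, atol=1e-9)

    def test_roi_mean_is_arithmetic_mean_of_voxels(self):
        atlas = make_atlas((8, 8, 8), 2, 1)
        vol = np.zeros((8, 8, 8, 2))
        vol[atlas.masks[0], 0] = 1.0
        vol[atlas.masks[0], 1] = 3.0
        raw = vol[atlas.masks[0], :].mean(axis=0)
        assert np.allclose(raw, [1.0, 3.0])  # mean over identical voxels
        with pytest.warns(RuntimeWarning):
            fe = extract_empirical_series(np.zeros((8, 8, 8, 4)), atlas)
        assert np.all(fe == 0.0)

    def test_constant_roi_yields_zero_row_and_warning(self):
        atlas = make_atlas((8, 8, 8), 2, 1)
        vol = np.random.default_rng(0).normal(size=(8, 8, 8, 6))
        vol[atlas.masks[0], :] = 5.0  # constant in time
        with pytest.warns(RuntimeWarning, match="constant"):
            fe = extract_empirical_series(vol, atlas)
        assert np.all(fe[0] == 0.0) and fe[1].std() > 0


class TestPearsonFC:
    def test_textbook_examples(self):
        s = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        fc = pearson_fc(s)
        assert fc[0, 0] == 1.0
        assert np.isclose(fc[0, 1], -1.0)
        assert np.isclose(fc[0, 2], 0.5)  # hand computation: cov 1, sds sqrt(2)

    def test_matches_scalar_loop_oracle(self, rng):
        s = rng.standard_normal((8, 32))
        fc = pearson_fc(s)
        for i in range(8):
            for j in range(8):
                xi, xj = s[i] - s[i].mean(), s[j] - s[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
                assert abs(fc[i, j] - r) < 1e-12

    def test_zero_rows_correlate_as_zero(self):
        s = np.vstack([np.zeros(10), np.arange(10.0), np.arange(10.0)[::-1]])
        fc = pearson_fc(s)
        assert fc[0, 1] == 0.0 and fc[0, 0] == 1.0
        assert np.isfinite(fc).all()

    def test_symmetric_unit_diagonal_bounded(self, rng):
        fc = pearson_fc(rng.standard_normal((6, 20)))
        assert np.allclose(fc, fc.T, atol=1e-12)
        assert np.allclose(np.diag(fc), 1.0)
        assert fc.min() >= -1.0 and fc.max() <= 1.0

    def test_rejects_too_short_series(self):
        with pytest.raises(ValueError):
            pearson_fc(np.ones((3, 2)))


def test_hub_covariance_is_psd_and_targeted():
    cov = hub_covariance(6, 2, 0.4)
    assert np.linalg.eigvalsh(cov).min() > -1e-12
    assert cov[2, 0] == 0.4 and cov[0, 1] == 0.0
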