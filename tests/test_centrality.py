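import numpy as np
import pytest

from cogplast.centrality import (degree_centrality, eigenvector_centrality,
                                 parcellate_zmap, sbca)
from cogplast.volgrid import Mask, Timeseries4D, VolumeGrid

from conftest import pearson_matrix


def ts_from_rows(rows, shape):
    rows = np.asarray(rows, dtype=float)
    return Timeseries4D(values=rows.reshape(shape + (rows.shape[1],)))


class TestEigenvectorCentrality:
    def test_identical_timeseries_give_uniform_ec(self, rng):
        base = rng.normal(size=50)
        shape = (2, 2, 2)
        rows = np.tile(base, (8, 1)) * rng.uniform(0.5, 2.0, size=(8, 1))
        ec = eigenvector_centrality(ts_from_rows(rows, shape), Mask(np.ones(shape, bool)))
        np.testing.assert_allclose(ec.values.ravel(), 1 / np.sqrt(8), atol=1e-6)

    def test_exchangeable_correlation_gives_uniform_ec(self, rng):
        # 3 voxels sharing one latent equally: r_ij identical for all pairs
        g = rng.normal(size=4000)
        rows = g[None, :] + rng.normal(size=(3, 4000))
        shape = (3, 1, 1)
        ec = eigenvector_centrality(ts_from_rows(rows, shape), Mask(np.ones(shape, bool)))
        np.testing.assert_allclose(ec.values.ravel(), 1 / np.sqrt(3), atol=0.02)

    def test_matches_explicit_eigendecomposition(self, rng):
        shape = (4, 4, 4)
        rows = rng.normal(size=(64, 120))
        mask = Mask(np.ones(shape, bool))
        ec = eigenvector_centrality(ts_from_rows(rows, shape), mask)
        A = (pearson_matrix(rows) + 1) / 2
        w, v = np.linalg.eigh(A)
        vec = v[:, -1] * np.sign(v[:, -1].sum())
        assert np.max(np.abs(ec.values[mask.membership] - vec)) <= 1e-6

    def test_unit_norm_and_nonnegative(self, random_timeseries, rng):
        mask = Mask(np.ones((4, 4, 4), bool))
        ec = eigenvector_centrality(random_timeseries, mask)
        vals = ec.values[mask.membership]
        assert np.all(vals >= 0)
        assert np.linalg.norm(vals) == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_reordering_and_affine_signal_transforms(self, rng):
        shape = (3, 3, 3)
        rows = rng.normal(size=(27, 90))
        mask = Mask(np.ones(shape, bool))
        base = eigenvector_centrality(ts_from_rows(rows, shape), mask).values.ravel()
        scaled = eigenvector_centrality(ts_from_rows(5.0 * rows + 2.0, shape), mask).values.ravel()
        np.testing.assert_allclose(base, scaled, atol=1e-6)
        perm = rng.permutation(27)
        permuted = eigenvector_centrality(ts_from_rows(rows[perm], shape), mask).values.ravel()
        np.testing.assert_allclose(permuted, base[perm], atol=1e-6)

    def test_zero_variance_voxel_reported(self, rng):
        shape = (2, 2, 2)
        rows = rng.normal(size=(8, 40))
        rows[3] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            eigenvector_centrality(ts_from_rows(rows, shape), Mask(np.ones(shape, bool)))


class TestDegreeCentrality:
    def test_identical_series_give_n_minus_1(self, rng):
        base = rng.normal(size=60)
        shape = (2, 2, 2)
        rows = np.tile(base, (8, 1))
        dc = degree_centrality(ts_from_rows(rows, shape), Mask(np.ones(shape, bool)))
        np.testing.assert_allclose(dc.values.ravel(), 7.0, atol=1e-8)

    def test_anticorrelated_pair_excluded_at_tau_zero(self, rng):
        x = rng.normal(size=50)
        rows = np.vstack([x, -x])
        shape = (2, 1, 1)
        dc = degree_centrality(ts_from_rows(rows, shape), Mask(np.ones(shape, bool)), tau=0.0)
        np.testing.assert_allclose(dc.values.ravel(), 0.0, atol=1e-12)

    def test_matches_row_sum_oracle(self, rng):
        shape = (4, 4, 4)
        rows = rng.normal(size=(64, 100))
        mask = Mask(np.ones(shape, bool))
        dc = degree_centrality(ts_from_rows(rows, shape), mask, tau=0.0, block_size=7)
        R = pearson_matrix(rows)
        np.fill_diagonal(R, 0.0)
        oracle = np.where(R > 0, R, 0.0).sum(axis=1)
        assert np.max(np.abs(dc.values[mask.membership] - oracle)) <= 1e-8

    def test_tau_minus_one_gives_plain_row_sum(self, rng):
        shape = (3, 3, 3)
        rows = rng.normal(size=(27, 80))
        mask = Mask(np.ones(shape, bool))
        dc = degree_centrality(ts_from_rows(rows, shape), mask, tau=-1.0)
        R = pearson_matrix(rows)
        np.fill_diagonal(R, 0.0)
        assert np.max(np.abs(dc.values[mask.membership] - R.sum(axis=1))) <= 1e-8


class TestSBCA:
    def test_known_correlation_recovers_fisher_z(self, rng):
        # build two series with exact sample correlation 0.6
        t = 400
        x = rng.normal(size=t)
        y = rng.normal(size=t)
        x = (x - x.mean()) / x.std()
        y = y - y.mean()
        y -= (y @ x) / (x @ x) * x  # orthogonalize
        y /= y.std()
        target = 0.6
        v2 = target * x + np.sqrt(1 - target ** 2) * y
        shape = (2, 1, 1)
        ts = ts_from_rows(np.vstack([x, v2]), shape)
        seed = Mask(np.array([[[True]], [[False]]]))
        res = sbca([ts], seed, Mask(np.ones(shape, bool)))
        assert res.z_map.values[1, 0, 0] == pytest.approx(np.arctanh(0.6), abs=1e-10)

    def test_seed_voxel_capped_and_flagged(self, rng):
        shape = (2, 1, 1)
        x = rng.normal(size=100)
        ts = ts_from_rows(np.vstack([x, rng.normal(size=100)]), shape)
        seed = Mask(np.array([[[True]], [[False]]]))
        res = sbca([ts], seed, Mask(np.ones(shape, bool)))
        assert res.z_map.values[0, 0, 0] == pytest.approx(np.arctanh(1 - 1e-7))
        assert res.capped_fraction > 0

    def test_independent_voxel_z_near_zero(self, rng):
        t = 800
        shape = (2, 1, 1)
        ts = ts_from_rows(rng.normal(size=(2, t)), shape)
        seed = Mask(np.array([[[True]], [[False]]]))
        res = sbca([ts], seed, Mask(np.ones(shape, bool)))
        assert abs(res.z_map.values[1, 0, 0]) < 3 / np.sqrt(t - 3)


class TestParcellation:
    def test_constant_map_has_no_clusters(self):
        labels = parcellate_zmap(VolumeGrid(np.ones((5, 5, 5))),
                                 Mask(np.ones((5, 5, 5), bool)))
        assert labels.max() == 0

    def test_single_high_voxel_forms_one_cluster(self, rng):
        vals = rng.normal(0, 0.1, size=(6, 6, 6))
        vals[3, 3, 3] = vals.mean() + 10 * vals.std()
        labels = parcellate_zmap(VolumeGrid(vals), Mask(np.ones((6, 6, 6), bool)), k_sd=3)
        assert labels[3, 3, 3] == 1
        assert (labels > 0).sum() == 1

    def test_two_blobs_match_flood_fill_oracle(self, rng):
        from scipy import ndimage

        vals = rng.normal(0, 0.05, size=(10, 10, 10))
        vals[1:3, 1:3, 1:3] += 5.0
        vals[7:9, 7:9, 7:9] += 5.0
        mask = Mask(np.ones((10, 10, 10), bool))
        labels = parcellate_zmap(VolumeGrid(vals), mask, k_sd=2)
        thr = vals.mean() + 2 * vals.std()
        oracle, n = ndimage.label(vals > thr, structure=np.ones((3, 3, 3)))
        assert n == 2
        assert set(np.unique(labels)) == {0, 1, 2}
        for lab in (1, 2):
            sel = labels == lab
            assert len(np.unique(oracle[sel])) == 1
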