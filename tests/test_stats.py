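"""Smoothing, TFCE, permutation tests, ROI summaries, ratio test, PCA."""

import numpy as np
import pytest

from cohorttrf.stats import (
    SourceGeometry,
    StatMap,
    chain_adjacency,
    cohens_d,
    paired_permutation_test,
    ratio_interaction_test,
    roi_summary,
    signflip_test,
    smooth_map,
    tfce,
    trf_pca_align,
)


def tfce_oracle(stat, edges, E, H, dh):
    """Independent fine-step oracle using explicit component search."""
    import networkx as nx

    stat = np.asarray(stat, float)
    out = np.zeros_like(stat)
    for sign in (1.0, -1.0):
        s = np.maximum(sign * stat, 0.0)
        m = s.max()
        if m <= 0:
            continue
        n_steps = int(np.floor(m / dh + 1e-9))
        for k in range(1, n_steps + 1):
            h = k * dh
            above = np.flatnonzero(s >= h)
            g = nx.Graph()
            g.add_nodes_from(above.tolist())
            g.add_edges_from(
                (a, b) for a, b in edges if s[a] >= h and s[b] >= h
            )
            for comp in nx.connected_components(g):
                val = len(comp) ** E * h**H * dh
                for v in comp:
                    out[v] += sign * val
    return out


@pytest.fixture
def grid():
    return SourceGeometry.grid(4, 4, spacing=5.0, roi=(1, 2, 1, 2),
                               split_hemispheres=True)


class TestGeometry:
    def test_grid_structure(self, grid):
        assert grid.n_sources == 16
        assert grid.roi_mask.sum() == 4
        assert len(grid.edges) == 2 * 4 * 3
        assert set(grid.hemisphere) == {0, 1}

    def test_orientation_norms_enforced(self):
        with pytest.raises(ValueError, match="unit"):
            SourceGeometry(np.zeros((2, 3)), np.array([[0, 1]]),
                           orientations=np.ones((2, 3)))


class TestSmoothing:
    def test_constant_map_unchanged(self, grid):
        out = smooth_map(np.full((3, 16), 2.5), grid, sd=5.0)
        np.testing.assert_allclose(out, 2.5, atol=1e-12)

    def test_impulse_spreads_gaussian_weights(self, grid):
        x = np.zeros(16)
        x[5] = 1.0
        out = smooth_map(x, grid, sd=5.0)
        d2 = ((grid.coordinates - grid.coordinates[5]) ** 2).sum(1)
        w = np.exp(-d2 / 50.0)
        w[d2 > (3 * 5.0) ** 2] = 0.0
        # row-normalized weights: out[v] = w[v] / sum_u w_vu
        norm = np.array([
            np.exp(-((grid.coordinates[v] - grid.coordinates) ** 2).sum(1) / 50.0)[
                ((grid.coordinates[v] - grid.coordinates) ** 2).sum(1) <= 225.0
            ].sum()
            for v in range(16)
        ])
        np.testing.assert_allclose(out, w / norm, atol=1e-12)
        assert out.sum() == pytest.approx((w / norm).sum())

    def test_tiny_sd_is_identity(self, grid):
        rng = np.random.default_rng(0)
        x = rng.normal(size=16)
        np.testing.assert_allclose(smooth_map(x, grid, sd=0.5), x, atol=1e-12)

    def test_nonpositive_sd_rejected(self, grid):
        with pytest.raises(ValueError):
            smooth_map(np.zeros(16), grid, sd=0.0)


class TestTFCE:
    def test_zero_map(self, grid):
        assert np.abs(tfce(np.zeros(16), grid.edges)).max() == 0.0

    def test_plateau_closed_form(self):
        # chain of 6, plateau of 4 at height 1: integral -> 4^0.5 / 3
        stat = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 0.0])
        out = tfce(stat, chain_adjacency(6), dh=1e-3)
        assert out[1] == pytest.approx(2.0 / 3.0, rel=5e-3)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_fine_step_oracle(self, seed, grid):
        rng = np.random.default_rng(seed)
        stat = rng.normal(size=16)
        dh = np.abs(stat).max() / 1000.0
        ours = tfce(stat, grid.edges, dh=dh)
        oracle = tfce_oracle(stat, grid.edges, 0.5, 2.0, dh)
        np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_scaling_monotonicity(self, grid):
        rng = np.random.default_rng(1)
        stat = np.abs(rng.normal(size=16))
        a = tfce(stat, grid.edges, dh=stat.max() / 200)
        b = tfce(3.0 * stat, grid.edges, dh=3 * stat.max() / 200)
        nz = a > 0
        assert (b[nz] > a[nz]).all()

    def test_negative_values_antisymmetric(self, grid):
        rng = np.random.default_rng(2)
        stat = rng.normal(size=16)
        np.testing.assert_allclose(
            tfce(-stat, grid.edges), -tfce(stat, grid.edges), atol=1e-12
        )


class TestPairedPermutation:
    def test_identical_conditions_p_one(self, grid):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 16))
        res = paired_permutation_test(a, a.copy(), grid.edges, n_perm=100, seed=1)
        assert (res.statistic == 0).all()
        assert (res.p == 1.0).all()

    def test_exhaustive_enumeration_one_sided(self, grid):
        # 3 subjects, all differences equal and positive: the identity flip
        # is the unique maximum -> one-sided p = 1/8 at every ROI source
        a = np.full((3, 16), 1.0)
        b = np.zeros((3, 16))
        res = paired_permutation_test(
            a, b, grid.edges, n_perm=8, tail="greater", exhaustive=True
        )
        np.testing.assert_allclose(res.p, 1.0 / 8.0)

    def test_subject_relabeling_invariance(self, grid):
        """With exhaustive enumeration, p-values are exactly invariant to any
        relabeling of subjects (exchangeability of the sign-flip orbit)."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 16))
        b = rng.normal(size=(6, 16))
        r1 = paired_permutation_test(a, b, grid.edges, n_perm=64, exhaustive=True)
        perm = rng.permutation(6)
        r2 = paired_permutation_test(
            a[perm], b[perm], grid.edges, n_perm=64, exhaustive=True
        )
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)

    def test_too_few_subjects_rejected(self, grid):
        with pytest.raises(ValueError, match="2 subjects"):
            paired_permutation_test(
                np.ones((1, 16)), np.zeros((1, 16)), grid.edges, n_perm=10
            )

    def test_strong_effect_detected(self, grid):
        # with 8 subjects and random sign flips, the two-tailed null revisits
        # the identity/mirror patterns ~2/256 of the time, so the attainable
        # p floor is about 0.008; assert clearly past the 0.05 level instead
        rng = np.random.default_rng(4)
        b = rng.normal(size=(8, 16))
        a = b + 1.0 + rng.normal(0, 0.1, size=(8, 16))
        res = paired_permutation_test(a, b, grid.edges, n_perm=500, seed=0)
        assert res.p.min() <= 0.02


class TestSignFlip:
    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            signflip_test(np.zeros((5, 20)), n_perm=10)

    def test_deflection_detected(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=(10, 60))
            x[:, 20:30] += 3.0
            res = signflip_test(x, n_perm=300, seed=rep)
            covered = (res.p[20:30] <= 0.05).mean() >= 0.8
            spared = (res.p[:15] > 0.05).all() and (res.p[40:] > 0.05).all()
            hits += covered and spared
        assert hits >= 9

    def test_null_pvalues_not_extreme(self):
        rng = np.random.default_rng(7)
        rejections = 0
        for rep in range(40):
            x = rng.normal(size=(8, 30))
            res = signflip_test(x, n_perm=200, seed=rep)
            rejections += (res.p <= 0.05).any()
        # family-wise error should be near 5%: allow generous binomial slack
        assert rejections <= 8


class TestROISummary:
    def test_constant_map(self, grid):
        maps = np.full((4, 16), 3.0)
        with pytest.raises(ValueError, match="Cohen"):
            roi_summary(StatMap(maps, grid))  # zero SD -> d undefined

    def test_hand_case(self):
        maps = np.array([[0.5, 0.5], [1.5, 1.5]])
        s = roi_summary(maps)
        assert s.mean == pytest.approx(1.0)
        assert s.d == pytest.approx(1.0 / np.sqrt(0.5), abs=1e-6)

    def test_empty_mask_rejected(self, grid):
        with pytest.raises(ValueError, match="empty"):
            roi_summary(np.ones((3, 16)), roi_mask=np.zeros(16, bool))

    def test_hemisphere_averaging_logic(self, grid):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(6, 16))
        s = roi_summary(StatMap(maps, grid), test_hemispheres=True)
        assert s.hemisphere_p is not None
        assert s.per_hemisphere.shape == (6, 2)


class TestRatioInteraction:
    def test_identical_groups(self):
        t, df, p = ratio_interaction_test(
            [0.2, 0.4], [1.0, 1.0], [0.2, 0.4], [1.0, 1.0]
        )
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_t(self):
        t, df, p = ratio_interaction_test(
            [0.6, 0.8], [1.0, 1.0], [0.1, 0.3], [1.0, 1.0]
        )
        assert df == 2
        assert t == pytest.approx(3.5355, abs=1e-3)

    def test_zero_surprisal_delta_names_subject(self):
        with pytest.raises(ValueError, match="group 2 subject"):
            ratio_interaction_test([1, 1], [1, 1], [1, 1], [1, 0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ratio_interaction_test([1], [1], [1, 2], [1, 1])

    def test_null_calibration_on_equal_gain_structure(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            e1, s1 = rng.normal(1, 0.3, 8), rng.normal(2, 0.3, 8)
            e2, s2 = rng.normal(1, 0.3, 8), rng.normal(2, 0.3, 8)
            _, _, p = ratio_interaction_test(e1, s1, e2, s2)
            rejections += p < 0.05
        # 95% binomial interval around 0.05 for 400 draws: [11, 30]
        assert 11 <= rejections <= 30


class TestCohenD:
    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(np.array([1.0, 1.0, 1.0]))


class TestPCAAlign:
    def _rank1_trfs(self, grid, rng, n_subj=4, flip_subject=None):
        V, T = grid.n_sources, 50
        spatial = np.abs(rng.normal(size=V)) * grid.roi_mask
        t = np.linspace(0, 1, T)
        course = np.exp(-((t - 0.2) ** 2) / 0.005) - 0.7 * np.exp(
            -((t - 0.6) ** 2) / 0.005
        )
        trfs = np.array(
            [
                np.outer(spatial, course) + rng.normal(0, 1e-3, (V, T))
                for _ in range(n_subj)
            ]
        )
        if flip_subject is not None:
            trfs[flip_subject] *= -1
        return trfs, course

    def test_recovers_time_course(self, grid):
        rng = np.random.default_rng(0)
        trfs, course = self._rank1_trfs(grid, rng)
        maps, courses = trf_pca_align(trfs, grid)
        for c in courses:
            r = np.corrcoef(c, course)[0, 1]
            assert abs(r) >= 0.99

    def test_sign_alignment_invariance(self, grid):
        """Negating a subject's TRF cannot change the aligned spatial map:
        the upward rule pins the map's sign.  The time course must then
        carry the negation (map x course reconstructs the TRF), so its
        magnitude is unchanged and only its sign flips."""
        rng = np.random.default_rng(1)
        trfs, _ = self._rank1_trfs(grid, rng)
        flipped = trfs.copy()
        flipped[2] *= -1
        m1, c1 = trf_pca_align(trfs, grid)
        m2, c2 = trf_pca_align(flipped, grid)
        np.testing.assert_allclose(m1[2], m2[2], atol=1e-12)
        np.testing.assert_allclose(c1[2], -c2[2], atol=1e-12)

    def test_unit_norm_maps(self, grid):
        rng = np.random.default_rng(2)
        trfs, _ = self._rank1_trfs(grid, rng)
        maps, _ = trf_pca_align(trfs, grid)
        np.testing.assert_allclose(np.linalg.norm(maps, axis=1), 1.0, atol=1e-9)

    def test_zero_trf_rejected(self, grid):
        with pytest.raises(ValueError, match="zero"):
            trf_pca_align(np.zeros((1, grid.n_sources, 10)), grid)
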