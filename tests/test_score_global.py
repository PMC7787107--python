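"""Whole-map scores: identities, brute-force oracles and degradation trends."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from emfitkit import (
    DensityMap,
    GlobalScoreConfig,
    RigidTransform,
    UndefinedScoreError,
    ccc,
    chamfer_distance,
    entropy_bits,
    envelope_score,
    lsf,
    mutual_information,
    normal_vector_score,
    score_model,
    simulate_map,
    transform_map_onto,
)
from emfitkit.fixtures import FixtureSpec, make_blob_map


# -- independent oracles ----------------------------------------------------

def pearson_oracle(x, y):
    x, y = x.ravel(), y.ravel()
    dx, dy = x - x.mean(), y - y.mean()
    return (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())


def mi_oracle(x, y, bins):
    """Direct double summation over the joint histogram."""
    joint, _, _ = np.histogram2d(x.ravel(), y.ravel(), bins=bins)
    n = joint.sum()
    mi = 0.0
    for i, j in itertools.product(range(bins), range(bins)):
        pij = joint[i, j] / n
        if pij == 0:
            continue
        pi = joint[i, :].sum() / n
        qj = joint[:, j].sum() / n
        mi += pij * np.log2(pij / (pi * qj))
    return mi


def chamfer_oracle(points_a, points_b):
    total = 0.0
    for p in points_a:
        total += min(np.linalg.norm(p - q) for q in points_b)
    return total / len(points_a)


class TestIdentities:
    def test_self_scores(self, blob_map):
        assert ccc(blob_map, blob_map) == pytest.approx(1.0)
        assert lsf(blob_map, blob_map) == 0.0
        assert normal_vector_score(blob_map, blob_map) == pytest.approx(0.0, abs=1e-6)
        assert chamfer_distance(blob_map, blob_map) == 0.0
        assert envelope_score(blob_map, blob_map) == pytest.approx(1.0)

    def test_negation(self, blob_map):
        neg = blob_map.with_grid(-blob_map.grid.astype(float))
        assert ccc(blob_map, neg) == pytest.approx(-1.0)
        assert normal_vector_score(blob_map, neg) == pytest.approx(np.pi, abs=1e-6)

    def test_zero_variance_raises(self, blob_map):
        flat = blob_map.with_grid(np.full(blob_map.shape, 1.0))
        with pytest.raises(UndefinedScoreError):
            ccc(blob_map, flat)

    def test_mi_of_self_is_entropy(self):
        # 4 equally frequent values, 4 bins -> H = 2 bits
        g = np.repeat(np.arange(4.0), 16).reshape(4, 4, 4)
        m = DensityMap(g)
        cfg = GlobalScoreConfig(mi_bins=4)
        assert mutual_information(m, m, cfg) == pytest.approx(2.0)
        assert entropy_bits(m, bins=4) == pytest.approx(2.0)

    def test_mi_constant_is_zero(self, blob_map):
        const = blob_map.with_grid(np.full(blob_map.shape, 3.0))
        assert mutual_information(blob_map, const) == pytest.approx(0.0, abs=1e-12)

    def test_mi_nonnegative_and_bounded(self, rng):
        cfg = GlobalScoreConfig(mi_bins=8)
        for _ in range(10):
            a = DensityMap(rng.random((5, 5, 5)))
            b = DensityMap(rng.random((5, 5, 5)))
            mi = mutual_information(a, b, cfg)
            bound = min(entropy_bits(a, 8), entropy_bits(b, 8))
            assert -1e-12 <= mi <= bound + 1e-9


class TestOracles:
    def test_ccc_matches_pearson(self, rng):
        a = DensityMap(rng.random((3, 3, 3)))
        b = DensityMap(rng.random((3, 3, 3)))
        assert ccc(a, b) == pytest.approx(pearson_oracle(a.grid, b.grid), abs=1e-12)

    def test_lsf_matches_direct_sum(self, rng):
        a = DensityMap(rng.random((3, 3, 3)))
        b = DensityMap(rng.random((3, 3, 3)))
        assert lsf(a, b) == pytest.approx(((a.grid - b.grid) ** 2).sum(), abs=1e-12)
        c = a.with_grid(a.grid + 0.25)
        assert lsf(a, c) == pytest.approx(27 * 0.25**2, abs=1e-12)

    def test_mi_matches_brute_force(self, rng):
        a = DensityMap(rng.random((3, 3, 3)))
        b = DensityMap(rng.random((3, 3, 3)))
        cfg = GlobalScoreConfig(mi_bins=3)
        assert mutual_information(a, b, cfg) == pytest.approx(
            mi_oracle(a.grid, b.grid, 3), abs=1e-9
        )

    def test_chamfer_matches_all_pairs(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[1, 1, 1] = a[4, 4, 1] = 1.0
        b[1, 4, 1] = b[2, 2, 3] = 1.0
        ma, mb = DensityMap(a), DensityMap(b)
        cfg = GlobalScoreConfig(threshold_a=0.5, threshold_b=0.5)
        pa = [np.array(p, float) for p in [(1, 1, 1), (4, 4, 1)]]
        pb = [np.array(p, float) for p in [(1, 4, 1), (2, 2, 3)]]
        assert chamfer_distance(ma, mb, cfg) == pytest.approx(chamfer_oracle(pa, pb))
        sym = GlobalScoreConfig(threshold_a=0.5, threshold_b=0.5, cd_mode="symmetric")
        expected = 0.5 * (chamfer_oracle(pa, pb) + chamfer_oracle(pb, pa))
        assert chamfer_distance(ma, mb, sym) == pytest.approx(expected)
        assert chamfer_distance(ma, mb, sym) == pytest.approx(
            chamfer_distance(mb, ma, sym)
        )

    def test_chamfer_two_voxels_distance(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[2, 2, 2] = 1.0
        b[2, 2, 6] = 1.0
        cfg = GlobalScoreConfig(threshold_a=0.5, threshold_b=0.5)
        d = chamfer_distance(DensityMap(a), DensityMap(b), cfg)
        assert d == pytest.approx(4.0)

    def test_nv_matches_arccos_oracle(self):
        # two offset spherical blobs; compare against per-voxel brute force
        from emfitkit.map_core import _sobel_gradient, binarize, surface_points

        n = 17
        ax = np.arange(n) - 8.0
        r2a = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        a = DensityMap(np.exp(-r2a / 12.0))
        bx = ax - 1.5
        r2b = bx[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        b = DensityMap(np.exp(-r2b / 12.0))
        cfg = GlobalScoreConfig(threshold_a=0.3)
        got = normal_vector_score(a, b, cfg)

        env = binarize(a, 0.3)
        pts = surface_points(env)
        idx = np.round(a.world_to_index(pts)).astype(int)
        ga = _sobel_gradient(a.grid, a.voxel_size)
        gb = _sobel_gradient(b.grid, b.voxel_size)
        angles = []
        for i, j, k in idx:
            va, vb = -ga[i, j, k], -gb[i, j, k]
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na < 1e-12 or nb < 1e-12:
                continue
            angles.append(np.arccos(np.clip(va @ vb / (na * nb), -1, 1)))
        assert got == pytest.approx(np.mean(angles), abs=1e-12)


class TestEnvelope:
    def test_disjoint_equal_size(self):
        a = np.zeros((6, 6, 6))
        b = np.zeros((6, 6, 6))
        a[:2] = 1.0
        b[4:] = 1.0
        cfg = GlobalScoreConfig(threshold_a=0.5, threshold_b=0.5, env_penalty=2.0)
        assert envelope_score(DensityMap(a), DensityMap(b), cfg) == pytest.approx(-2.0)

    def test_half_overlap_formula(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[:2] = 1.0  # 32 target voxels
        b[1:3] = 1.0  # 32 probe voxels, 16 overlap, 16 outside
        cfg = GlobalScoreConfig(threshold_a=0.5, threshold_b=0.5, env_penalty=2.0)
        expected = (16 - 2.0 * 16) / 32
        assert envelope_score(DensityMap(a), DensityMap(b), cfg) == pytest.approx(expected)

    def test_empty_target_raises(self):
        m = DensityMap(np.zeros((4, 4, 4)))
        cfg = GlobalScoreConfig(threshold_a=1.0, threshold_b=1.0)
        with pytest.raises(UndefinedScoreError):
            envelope_score(m, m, cfg)


class TestInvariances:
    def test_ccc_affine_invariant(self, blob_map, rng):
        other = DensityMap(rng.random(blob_map.shape))
        base = ccc(blob_map, other)
        scaled = blob_map.with_grid(3.0 * blob_map.grid.astype(float) + 5.0)
        assert ccc(scaled, other) == pytest.approx(base, abs=1e-12)

    def test_mi_affine_invariant(self, blob_map, rng):
        other = DensityMap(rng.random(blob_map.shape))
        cfg = GlobalScoreConfig(mi_bins=10)
        base = mutual_information(blob_map, other, cfg)
        scaled = blob_map.with_grid(3.0 * blob_map.grid.astype(float) + 5.0)
        # bin edges rescale with the data, so the joint histogram is identical
        assert mutual_information(scaled, other, cfg) == pytest.approx(base, abs=1e-12)

    def test_degradation_monotone_over_offsets(self, helix, sim_params):
        reference = simulate_map(helix, sim_params)
        cccs, lsfs = [], []
        for off in [0.0, 1.0, 2.0, 4.0, 8.0]:
            t = RigidTransform(np.eye(3), [off, 0.0, 0.0])
            moved = transform_map_onto(reference, t, reference)
            cccs.append(ccc(reference, moved))
            lsfs.append(lsf(reference, moved))
        assert all(b <= a + 1e-12 for a, b in zip(cccs, cccs[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(lsfs, lsfs[1:]))


class TestScoreModel:
    def test_dispatch_and_self_fit(self, helix, sim_params, helix_map):
        assert score_model(helix, helix_map, "ccc", sim_params) == pytest.approx(1.0)
        assert score_model(helix, helix_map, "lsf", sim_params) == pytest.approx(0.0)
        moved = helix.with_coords(helix.coords + np.array([5.0, 0.0, 0.0]))
        assert score_model(moved, helix_map, "ccc", sim_params) < 1.0
        with pytest.raises(ValueError):
            score_model(helix, helix_map, "nope", sim_params)


class TestScoreCorrelationHarness:
    def test_rank_correlation_matrix_on_decoys(self, helix, sim_params):
        """All six scores ranked over a ladder of synthetic decoy fits."""
        reference = simulate_map(helix, sim_params)
        rng = np.random.default_rng(0)
        ta = float(reference.grid.mean() + reference.grid.std())
        # NV's threshold pair bounds an intensity band on the first map;
        # CD/ENV's threshold_b contours the second map
        nv_cfg = GlobalScoreConfig(threshold_a=ta)
        pair_cfg = GlobalScoreConfig(threshold_a=ta, threshold_b=ta)
        rows = []
        for _ in range(50):
            off = rng.normal(0, 3.0, size=3)
            moved = transform_map_onto(
                reference, RigidTransform(np.eye(3), off), reference
            )
            rows.append(
                [
                    ccc(reference, moved),
                    mutual_information(reference, moved),
                    -lsf(reference, moved),
                    -normal_vector_score(reference, moved, nv_cfg),
                    -chamfer_distance(reference, moved, pair_cfg),
                    envelope_score(reference, moved, pair_cfg),
                ]
            )
        table = np.array(rows)
        corr = spearmanr(table).statistic
        assert corr.shape == (6, 6)
        assert np.allclose(np.diag(corr), 1.0)
        # all scores orientated better-is-higher: positively rank-correlated
        assert (corr > 0.2).all()
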