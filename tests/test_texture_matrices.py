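"""Texture matrices: hand-enumerated examples and brute-force oracle equality."""

import numpy as np
import pytest

from fishrad.features.matrices import (
    GLCM_OFFSETS,
    build_glcm,
    build_gldm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    _glcm_features_single,
    _present_levels,
)

import oracles


def _random_levels(rng, max_side=12, max_levels=5):
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    levels = rng.integers(0, max_levels + 1, size=(h, w))
    if not (levels > 0).any():
        levels[rng.integers(h), rng.integers(w)] = 1
    return levels


class TestGLCM:
    def test_pair_enumeration_2x2(self):
        levels = np.array([[1, 1], [1, 2]])
        counts = build_glcm(levels, (0, 1))
        # pairs (1,1) and (1,2); symmetrized
        g = _present_levels(levels)
        assert g.tolist() == [1, 2]
        assert counts.tolist() == [[2, 1], [1, 0]]
        feats = _glcm_features_single(counts, g)
        assert feats["Contrast"] == pytest.approx(0.5)

    def test_checkerboard_horizontal(self):
        rows, cols = np.indices((6, 6))
        levels = ((rows + cols) % 2) + 1
        counts = build_glcm(levels, (0, 1))
        p = counts / counts.sum()
        feats = _glcm_features_single(counts, _present_levels(levels))
        assert feats["MaximumProbability"] == pytest.approx(0.5)
        assert feats["Contrast"] == pytest.approx(1.0)
        assert p[0, 0] == 0.0 and p[1, 1] == 0.0

    def test_constant_region_degenerate_values(self):
        levels = np.ones((4, 4), dtype=int)
        feats = glcm_features(levels)
        assert feats["MaximumProbability"] == 1.0
        assert feats["Contrast"] == 0.0
        assert feats["JointEntropy"] == pytest.approx(0.0, abs=1e-9)
        assert feats["JointEnergy"] == 1.0
        assert feats["Correlation"] == 1.0
        assert feats["Imc1"] == 0.0 and feats["Imc2"] == 0.0

    def test_single_pixel_fallback(self):
        levels = np.array([[3]])
        feats = glcm_features(levels)
        assert feats["Correlation"] == 1.0
        assert feats["MaximumProbability"] == 1.0

    def test_symmetry_and_normalization_properties(self, rng):
        for _ in range(20):
            levels = _random_levels(rng)
            for off in GLCM_OFFSETS:
                counts = build_glcm(levels, off)
                assert np.array_equal(counts, counts.T)
                if counts.sum():
                    assert (counts / counts.sum()).sum() == pytest.approx(1.0)


class TestGLRLM:
    def test_single_row_single_run(self):
        levels = np.ones((1, 5), dtype=int)
        counts = build_glrlm(levels, (0, 1))
        assert counts[0, 4] == 1 and counts.sum() == 1
        feats = glrlm_features(levels)
        # horizontal: one run of 5; the other three directions: 5 runs of 1
        # LongRunEmphasis mean over angles: (25 + 1 + 1 + 1) / 4
        assert feats["LongRunEmphasis"] == pytest.approx((25 + 3) / 4)
        assert feats["RunPercentage"] == pytest.approx((0.2 + 3.0) / 4)

    def test_alternating_row_all_unit_runs(self):
        levels = np.array([[1, 2, 1, 2, 1, 2]])
        feats = glrlm_features(levels)
        assert feats["ShortRunEmphasis"] == pytest.approx(1.0)
        assert feats["LongRunEmphasis"] == pytest.approx(1.0)

    def test_run_length_nonuniformity_enumeration(self):
        levels = np.array([[1, 1, 2, 2, 2]])
        counts = build_glrlm(levels, (0, 1))
        # runs: (1, len 2) and (2, len 3)
        assert counts[0, 1] == 1 and counts[1, 2] == 1
        nr = counts.sum()
        rln = (counts.sum(axis=0) ** 2).sum() / nr
        assert rln == pytest.approx(1.0)


class TestGLSZM:
    def test_constant_region_single_zone(self):
        levels = np.ones((3, 4), dtype=int)
        feats = glszm_features(levels)
        assert feats["LargeAreaEmphasis"] == pytest.approx(144.0)
        assert feats["ZoneVariance"] == pytest.approx(0.0)
        assert feats["ZonePercentage"] == pytest.approx(1 / 12)

    def test_two_disjoint_blobs_zone_variance(self):
        levels = np.zeros((5, 9), dtype=int)
        levels[0, :2] = 4  # size-2 zone
        levels[4, 5:8] = 4  # size-3 zone
        feats = glszm_features(levels)
        assert feats["ZoneVariance"] == pytest.approx(0.25)  # var of {2, 3}

    def test_checkerboard_zones_under_8_connectivity(self):
        # diagonal equal-level cells are connected, so a 2-level
        # checkerboard collapses into exactly two zones
        rows, cols = np.indices((4, 4))
        levels = ((rows + cols) % 2) + 1
        counts = build_glszm(levels)
        assert counts.sum() == 2
        assert counts[0, 7] == 1 and counts[1, 7] == 1  # two zones of size 8

    def test_stripes_give_singleton_free_zones(self):
        # vertical stripes of distinct levels: one zone per stripe
        levels = np.tile(np.array([[1, 2, 3, 4]]), (3, 1))
        feats = glszm_features(levels)
        assert feats["ZonePercentage"] == pytest.approx(4 / 12)
        assert feats["ZoneVariance"] == pytest.approx(0.0)  # all zones size 3

    def test_diagonal_cells_join_by_8_connectivity(self):
        levels = np.array([[1, 2], [2, 1]])
        counts = build_glszm(levels)
        # both 1s touch diagonally -> one zone of size 2; same for 2s
        assert counts[0, 1] == 1 and counts[1, 1] == 1
        assert counts.sum() == 2


class TestGLDM:
    def test_constant_3x3_dependence_counts(self):
        levels = np.ones((3, 3), dtype=int)
        counts = build_gldm(levels, alpha=0)
        # corners have 3 dependent neighbors, edges 5, the center 8
        assert counts[0, 3] == 4
        assert counts[0, 5] == 4
        assert counts[0, 8] == 1

    def test_all_distinct_levels_zero_dependence(self):
        # every Chebyshev-1 neighbor differs -> dependence 0 everywhere
        levels = np.arange(1, 17).reshape(4, 4)
        feats = gldm_features(levels, alpha=0)
        assert feats["SmallDependenceEmphasis"] == pytest.approx(1.0)
        assert feats["LargeDependenceEmphasis"] == pytest.approx(1.0)

    def test_checkerboard_diagonals_count_as_dependent(self):
        # with the 8-neighborhood a 2-level checkerboard is NOT
        # dependence-free: diagonal cells share the level
        rows, cols = np.indices((5, 5))
        levels = ((rows + cols) % 2) + 1
        counts = build_gldm(levels, alpha=0)
        assert counts[:, 0].sum() == 0  # no pixel has zero dependence

    def test_single_pixel(self):
        levels = np.array([[2]])
        feats = gldm_features(levels)
        assert feats["DependenceVariance"] == 0.0
        assert feats["SmallDependenceEmphasis"] == 1.0


class TestNGTDM:
    def test_constant_region(self):
        levels = np.ones((4, 4), dtype=int)
        feats = ngtdm_features(levels)
        assert feats["Coarseness"] == 1e6
        assert feats["Contrast"] == 0.0

    def test_two_level_row_hand_oracle(self):
        levels = np.array([[1, 1, 2, 2]])
        n_i, p_i, s_i = build_ngtdm(levels)
        assert n_i.tolist() == [2, 2]
        assert s_i == pytest.approx([0.5, 0.5])
        feats = ngtdm_features(levels)
        assert feats["Coarseness"] == pytest.approx(2.0)
        assert feats["Contrast"] == pytest.approx(0.0625)
        assert feats["Busyness"] == pytest.approx(0.5)
        assert feats["Complexity"] == pytest.approx(0.25)
        assert feats["Strength"] == pytest.approx(2.0)

    def test_single_pixel_conventions(self):
        levels = np.array([[5]])
        feats = ngtdm_features(levels)
        assert feats["Strength"] == 0.0
        assert feats["Coarseness"] == 1e6


class TestBruteForceOracleEquality:
    """Exact count agreement with independent enumeration on random grids."""

    @pytest.mark.parametrize("seed", range(25))
    def test_all_five_families(self, seed):
        rng = np.random.default_rng(1000 + seed)
        levels = _random_levels(rng)
        assert_matrices_match_oracle(levels)


def assert_matrices_match_oracle(levels: np.ndarray) -> None:
    g = oracles.present_levels(levels)
    garr = _present_levels(levels)
    assert garr.tolist() == g

    for off in GLCM_OFFSETS:
        got = oracles.glcm_matrix_to_dict(build_glcm(levels, off, garr), garr)
        assert got == oracles.brute_glcm(levels, off), f"glcm offset {off}"

    for direction in GLCM_OFFSETS:
        got = oracles.indexed_matrix_to_dict(
            build_glrlm(levels, direction, garr), garr, col_offset=1
        )
        assert got == oracles.brute_glrlm(levels, direction), f"glrlm {direction}"

    got = oracles.indexed_matrix_to_dict(build_glszm(levels, garr), garr, col_offset=1)
    assert got == oracles.brute_glszm(levels)

    got = oracles.indexed_matrix_to_dict(build_gldm(levels, 0, garr), garr, col_offset=0)
    assert got == oracles.brute_gldm(levels)

    n_i, p_i, s_i = build_ngtdm(levels, garr)
    expected = oracles.brute_ngtdm(levels)
    got_ngtdm = {
        int(v): (int(n), float(s))
        for v, n, s in zip(garr, n_i, s_i)
        if n > 0
    }
    assert set(got_ngtdm) == set(expected)
    for v in expected:
        assert got_ngtdm[v][0] == expected[v][0]
        assert got_ngtdm[v][1] == pytest.approx(expected[v][1], abs=1e-9)
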