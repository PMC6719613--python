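import numpy as np
import pytest

from conftest import make_disc, random_disc
from oracles import scan_runs, unionfind_zones

from radbcr.imaging import ROIMask
from radbcr.texture import (
    DIRECTIONS_13,
    GLSZM,
    GLRLM,
    build_glcm,
    build_glrlm,
    build_glszm,
    expected_row_length,
    extract_all,
    first_order_features,
    glcm_features,
    hgre,
    label_zones,
    make_key,
    parse_key,
    shape_features,
    sze,
    szlge,
)
from radbcr.wavelets import decompose

# the 3x3x1 worked example: rows [1 2 2 / 1 1 2 / 3 3 3]
WORKED = np.array([[1, 2, 2], [1, 1, 2], [3, 3, 3]])


class TestZones:
    def test_uniform_roi_single_zone(self):
        disc = make_disc(np.ones((3, 4, 2)))
        assert label_zones(disc, 26) == [(1, 24)]

    def test_worked_example_zones(self):
        disc = make_disc(WORKED)
        assert sorted(label_zones(disc, 26)) == [(1, 3), (2, 3), (3, 3)]

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_unionfind_oracle(self, rng, connectivity):
        for _ in range(20):
            disc = random_disc(rng, (4, 4, 4), n_levels=3)
            assert sorted(label_zones(disc, connectivity)) == \
                unionfind_zones(disc.levels, connectivity)

    def test_26_connectivity_merges_zones(self, rng):
        for _ in range(10):
            disc = random_disc(rng, (5, 5, 5), n_levels=2)
            assert build_glszm(disc, 26).n_zones <= build_glszm(disc, 6).n_zones


class TestGLSZM:
    def test_uniform_roi_matrix(self):
        disc = make_disc(np.ones((2, 3, 4)))
        m = build_glszm(disc)
        assert m.counts[0, 23] == 1
        assert m.counts.sum() == 1

    def test_worked_example_matrix(self):
        m = build_glszm(make_disc(WORKED))
        assert m.counts[0, 2] == m.counts[1, 2] == m.counts[2, 2] == 1
        assert m.n_zones == 3

    def test_voxel_conservation(self, rng):
        for _ in range(10):
            disc = random_disc(rng, (5, 5, 5), n_levels=4)
            m = build_glszm(disc)
            assert (m.counts * m.sizes[None, :]).sum() == disc.n_voxels


class TestSZEFamilies:
    def test_singleton_zones_give_sze_one(self):
        m = GLSZM(np.array([[3], [2]]), n_voxels=5)
        assert sze(m) == 1.0

    def test_single_zone_closed_form(self):
        counts = np.zeros((1, 24), dtype=int)
        counts[0, 23] = 1
        assert sze(GLSZM(counts, 24)) == pytest.approx(1 / 24**2, rel=1e-14)

    def test_worked_example_sze(self):
        m = build_glszm(make_disc(WORKED))
        assert sze(m) == pytest.approx(1 / 9, rel=1e-14)

    def test_worked_example_szlge(self):
        m = build_glszm(make_disc(WORKED))
        assert szlge(m) == pytest.approx(49 / 972, rel=1e-14)

    def test_szlge_single_zone_closed_forms(self):
        counts = np.zeros((2, 3), dtype=int)
        counts[1, 2] = 1   # level 2, size 3
        assert szlge(GLSZM(counts, 3)) == pytest.approx(1 / 36, rel=1e-14)
        assert szlge(GLSZM(np.array([[1]]), 1)) == 1.0

    def test_splitting_a_zone_raises_sze(self):
        # zones weight as 1/size^2, so fragmenting one zone into smaller
        # pieces of the same total size increases small-zone emphasis
        one = np.zeros((1, 6), dtype=int)
        one[0, 5] = 1
        split = np.zeros((1, 6), dtype=int)
        split[0, 2] = 2    # two zones of size 3
        assert sze(GLSZM(split, 6)) > sze(GLSZM(one, 6))

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            sze(GLSZM(np.zeros((2, 2), dtype=int), 0))


class TestGLRLM:
    def test_line_roi_runs(self):
        disc = make_disc(np.ones((1, 1, 5), dtype=int))
        m = build_glrlm(disc)
        # one run of length 5 along the line axis, 5 singleton runs in
        # each of the 12 other directions
        assert m.counts[0, 4] == 1
        assert m.counts[0, 0] == 12 * 5
        assert m.n_runs == 1 + 60

    def test_all_distinct_levels_all_singletons(self):
        levels = np.arange(1, 9).reshape(2, 2, 2)
        m = build_glrlm(make_disc(levels))
        assert m.counts[:, 0].sum() == m.n_runs == 13 * 8

    def test_hgre_closed_forms(self):
        counts = np.zeros((3, 2), dtype=int)
        counts[0, 0] = 4
        assert hgre(GLRLM(counts, 4)) == 1.0
        counts = np.zeros((3, 2), dtype=int)
        counts[2, 1] = 1
        assert hgre(GLRLM(counts, 2)) == 9.0

    def test_matches_run_scan_oracle(self, rng):
        for _ in range(10):
            disc = random_disc(rng, (4, 4, 4), n_levels=3)
            expected = np.zeros_like(build_glrlm(disc).counts)
            for d in DIRECTIONS_13:
                for lvl, length in scan_runs(disc.levels, d):
                    expected[lvl - 1, length - 1] += 1
            np.testing.assert_array_equal(build_glrlm(disc).counts, expected)

    def test_per_direction_voxel_conservation(self, rng):
        disc = random_disc(rng, (5, 5, 5), n_levels=4)
        for d in DIRECTIONS_13:
            runs = scan_runs(disc.levels, d)
            assert sum(length for _, length in runs) == disc.n_voxels


class TestGLCM:
    def test_probabilities_sum_to_one_and_symmetric(self, rng):
        disc = random_disc(rng, (5, 5, 5), n_levels=4)
        m = build_glcm(disc)
        p = m.probabilities
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)

    def test_degenerate_single_level_correlation_is_missing(self):
        m = build_glcm(make_disc(np.ones((3, 3, 3))))
        feats = glcm_features(m)
        assert np.isnan(feats["Correlation"])
        assert feats["Contrast"] == 0.0


class TestFirstOrder:
    def test_constant_input(self):
        f = first_order_features(np.full(10, 2.0))
        assert f["Variance"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0

    def test_worked_example(self):
        f = first_order_features(np.array([1.0, 2, 3, 4]))
        assert f["Mean"] == 2.5
        assert f["Variance"] == 1.25

    def test_order_statistics_consistent(self, rng):
        f = first_order_features(rng.normal(size=100))
        assert f["Min"] <= f["Median"] <= f["Max"]
        assert f["P10"] <= f["P90"]


class TestShape:
    def test_single_voxel_volume(self):
        mask = np.zeros((3, 3, 3))
        mask[1, 1, 1] = 1
        f = shape_features(ROIMask(mask), (1, 1, 1))
        assert f["VolumeMm3"] == 1.0
        assert f["MaxDiameterMm"] == 0.0

    def test_cube_volume_and_diameter(self):
        mask = np.zeros((4, 4, 4))
        mask[1:3, 1:3, 1:3] = 1
        f = shape_features(ROIMask(mask), (1, 1, 1))
        assert f["VolumeMm3"] == 8.0
        assert f["MaxDiameterMm"] == pytest.approx(np.sqrt(3), rel=1e-12)

    def test_ball_rounder_than_slab(self):
        size = (13, 13, 13)
        grids = np.indices(size)
        ball = (((grids - 6) ** 2).sum(axis=0)) <= 25
        slab = np.zeros(size, dtype=bool)
        slab[6, :, :] = True
        f_ball = shape_features(ROIMask(ball), (1, 1, 1))
        f_slab = shape_features(ROIMask(slab), (1, 1, 1))
        assert f_ball["Sphericity"] > f_slab["Sphericity"]


class TestExtractAll:
    def _setup(self, rng, shape=(12, 12, 12)):
        from radbcr.imaging import DiscretizationScheme

        banks = {
            "ADC": decompose(rng.normal(size=shape)),
            "T2": decompose(rng.normal(size=shape)),
        }
        mask = np.zeros(shape)
        mask[3:9, 3:9, 3:9] = 1
        schemes = [DiscretizationScheme.fbn(8), DiscretizationScheme.fbn(16)]
        return banks, ROIMask(mask), schemes

    def test_row_length_matches_closed_form(self, rng):
        banks, mask, schemes = self._setup(rng)
        row = extract_all(banks, mask, schemes)
        assert len(row) == expected_row_length(2, 2)

    def test_deterministic(self, rng):
        banks, mask, schemes = self._setup(rng)
        assert extract_all(banks, mask, schemes) == extract_all(banks, mask, schemes)

    def test_scheme_order_invariance(self, rng):
        banks, mask, schemes = self._setup(rng)
        fwd = extract_all(banks, mask, schemes)
        rev = extract_all(banks, mask, schemes[::-1])
        assert list(fwd) == list(rev)
        assert fwd == rev

    def test_key_round_trip(self):
        key = make_key("ADC", "LLL", "FBN32", "SZE")
        assert key == "ADC|LLL|FBN32|SZE"
        assert parse_key(key) == ("ADC", "LLL", "FBN32", "SZE")
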