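"""The 33-feature extractor against brute-force oracles and analytic shapes."""

import numpy as np
import pytest

from nucleomorph.features import (
    DIRECTIONS,
    directional_distances,
    directional_features,
    extract_features,
    extract_regions,
    geometric_features,
    intensity_features,
)

from _oracles import digital_disk, digital_ellipse, region_quantities
from conftest import random_label_map


def square_map(side, pad=2):
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=np.int32)
    m[pad : pad + side, pad : pad + side] = 1
    return m


class TestExtractRegions:
    def test_three_by_three_square(self):
        regions = extract_regions(square_map(3), np.zeros((7, 7)))
        (r,) = regions
        assert r.x_k == 9
        assert r.P_k == 8  # all but the center pixel touch the outside
        assert r.centroid == (3.0, 3.0)

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.int32)
        m[2, 2] = 1
        (r,) = extract_regions(m, np.full((5, 5), 7.0))
        assert r.x_k == r.P_k == 1
        assert r.centroid == (2.0, 2.0)
        assert np.all(r.d_Dk == 0)

    def test_two_labels_partition(self):
        m = np.zeros((6, 10), dtype=np.int32)
        m[1:3, 1:3] = 1
        m[3:5, 6:9] = 2
        regions = extract_regions(m, np.zeros(m.shape))
        assert [r.label for r in regions] == [1, 2]
        a = set(map(tuple, regions[0].pixels))
        b = set(map(tuple, regions[1].pixels))
        assert not a & b

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            extract_regions(np.zeros((4, 4), dtype=int), np.zeros((5, 5)))

    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_random_masks(self, seed):
        """Pixel-enumeration oracle reproduces every per-region quantity."""
        rng = np.random.default_rng(seed)
        lmap = random_label_map(rng)
        gray = np.round(rng.uniform(0, 255, size=lmap.shape), 3)
        regions = extract_regions(lmap, gray)
        assert len(regions) == lmap.max()
        for reg in regions:
            ref = region_quantities(lmap == reg.label, gray)
            assert reg.x_k == ref["x_k"]
            assert reg.P_k == ref["P_k"]
            assert reg.centroid == pytest.approx(ref["centroid"], abs=0)
            assert reg.d_Dk.tolist() == pytest.approx(ref["d_Dk"], abs=0)
            assert reg.AR_k == ref["AR_k"]
            assert reg.I_k == pytest.approx(ref["I_k"], rel=1e-12)
            assert reg.sigma_Ik == pytest.approx(ref["sigma_Ik"], rel=1e-9, abs=1e-9)
            assert reg.RI_k == pytest.approx(ref["RI_k"], abs=0)


class TestGeometricFeatures:
    def test_square_hand_arithmetic(self):
        f = geometric_features(extract_regions(square_map(3), np.zeros((7, 7))))
        assert f.tolist() == pytest.approx([1, 9, 8, 1.125, 36 * np.pi / 64])

    def test_two_nuclei_means(self):
        m = np.zeros((10, 20), dtype=np.int32)
        m[2:5, 2:5] = 1          # 3x3: area 9, perimeter 8
        m[2:5, 10:14] = 2        # 3x4: area 12, perimeter 10
        f = geometric_features(extract_regions(m, np.zeros(m.shape)))
        assert f[0] == 2
        assert f[1] == pytest.approx((9 + 12) / 2)
        assert f[2] == pytest.approx((8 + 10) / 2)
        assert f[3] == pytest.approx(f[1] / f[2])

    def test_disk_rounder_than_square(self):
        disk = digital_disk(30).astype(np.int32)
        side = int(round(np.sqrt(disk.sum())))
        square = square_map(side)
        f_disk = geometric_features(extract_regions(disk, np.zeros(disk.shape)))
        f_square = geometric_features(extract_regions(square, np.zeros(square.shape)))
        assert f_disk[4] > f_square[4]

    def test_empty_gives_zeros(self, caplog):
        f = geometric_features([])
        assert np.all(f == 0)


class TestDirectionalDistances:
    def test_centered_disk(self):
        d = directional_distances(digital_disk(20))
        assert np.all(np.abs(d - 20) <= 1.5)

    def test_axis_aligned_ellipse(self):
        # semi-axes: 20 along E-W (columns), 10 along N-S (rows)
        d = dict(zip(DIRECTIONS, directional_distances(digital_ellipse(20, 10))))
        assert d["E"] == pytest.approx(20, abs=1.0)
        assert d["W"] == pytest.approx(20, abs=1.0)
        assert d["N"] == pytest.approx(10, abs=1.0)
        assert d["S"] == pytest.approx(10, abs=1.0)

    def test_diagonals_are_euclidean(self):
        # a filled square reaches its corner along diagonals: distance s*sqrt(2)
        m = square_map(21)
        d = dict(zip(DIRECTIONS, directional_distances(m > 0)))
        assert d["NE"] == pytest.approx(10 * np.sqrt(2))
        assert d["N"] == pytest.approx(10)


class TestDirectionalFeatures:
    def test_single_nucleus_zero_spread(self):
        regions = extract_regions(square_map(5), np.zeros((9, 9)))
        f = directional_features(regions)
        assert np.all(f[8:16] == 0)  # stds
        assert np.all(f[16:24] == 0)  # ranges

    def test_two_disks_mean_std_range(self):
        m = np.zeros((60, 120), dtype=np.int32)
        d5 = digital_disk(5)
        d10 = digital_disk(10)
        m[10 : 10 + d5.shape[0], 10 : 10 + d5.shape[1]] = d5
        m[10 : 10 + d10.shape[0], 60 : 60 + d10.shape[1]] = 2 * d10
        f = directional_features(extract_regions(m, np.zeros(m.shape)))
        assert f[0] == pytest.approx(7.5, abs=0.5)   # mean of N distances 5, 10
        assert f[8] == pytest.approx(2.5, abs=0.5)   # population std
        assert f[16] == pytest.approx(5.0, abs=0.8)  # range

    def test_rectangle_fills_its_bounding_box(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[3:9, 4:15] = 1
        f = directional_features(extract_regions(m, np.zeros(m.shape)))
        assert f[24] == 1.0

    def test_disk_fill_ratio_approaches_pi_over_4(self):
        disk = digital_disk(40).astype(np.int32)
        f = directional_features(extract_regions(disk, np.zeros(disk.shape)))
        assert f[24] == pytest.approx(np.pi / 4, abs=0.03)


class TestIntensityFeatures:
    def test_constant_nuclei(self):
        m = square_map(4)
        f = intensity_features(extract_regions(m, np.full(m.shape, 100.0)))
        assert f.tolist() == [100.0, 0.0, 0.0]

    def test_mean_of_two_nuclei(self):
        m = np.zeros((10, 20), dtype=np.int32)
        m[2:5, 2:5] = 1
        m[2:5, 10:13] = 2
        gray = np.zeros(m.shape)
        gray[m == 1] = 80.0
        gray[m == 2] = 120.0
        f = intensity_features(extract_regions(m, gray))
        assert f[0] == 100.0

    def test_two_pixel_extremes(self):
        m = np.zeros((3, 4), dtype=np.int32)
        m[1, 1:3] = 1
        gray = np.zeros(m.shape)
        gray[1, 2] = 255.0
        f = intensity_features(extract_regions(m, gray))
        assert f.tolist() == [127.5, 127.5, 255.0]


ROT90_CW = {"N": "E", "E": "S", "S": "W", "W": "N",
            "NW": "NE", "NE": "SE", "SE": "SW", "SW": "NW"}


class TestExtractFeatures:
    def test_exactly_33_features(self, small_dataset):
        vec = extract_features(small_dataset.images[0], small_dataset.label_maps[0])
        assert vec.shape == (33,)

    def test_translation_invariance(self, small_dataset):
        img = small_dataset.images[0]
        lmap = small_dataset.label_maps[0]
        rows, cols = lmap.shape
        big_img = np.full((rows + 20, cols + 20, 3), 255, dtype=img.dtype)
        big_map = np.zeros((rows + 20, cols + 20), dtype=lmap.dtype)
        big_img[10 : 10 + rows, 10 : 10 + cols] = img
        big_map[10 : 10 + rows, 10 : 10 + cols] = lmap
        a = extract_features(img, lmap)
        b = extract_features(big_img, big_map)
        assert a.tolist() == pytest.approx(b.tolist(), rel=1e-12)

    def test_rotation_permutes_directions(self, small_dataset):
        """90 deg clockwise rotation cycles N->E->S->W (and NW->NE->SE->SW)."""
        img = small_dataset.images[0]
        lmap = small_dataset.label_maps[0]
        a = extract_features(img, lmap)
        b = extract_features(np.rot90(img, k=-1), np.rot90(lmap, k=-1))

        def block(vec, offset):
            return dict(zip(DIRECTIONS, vec[offset : offset + 8]))

        for offset in (5, 13, 21):  # means, stds, ranges
            orig = block(a, offset)
            rot = block(b, offset)
            for D in DIRECTIONS:
                ref = orig[D]
                got = rot[ROT90_CW[D]]
                assert got == pytest.approx(ref, rel=0.02, abs=0.5)
        invariant = np.r_[a[:5], a[29:]]
        rotated = np.r_[b[:5], b[29:]]
        assert rotated.tolist() == pytest.approx(invariant.tolist(), rel=0.02)

    def test_identities_on_random_masks(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            lmap = random_label_map(rng, shape=(30, 30))
            if lmap.max() == 0:
                continue
            gray = rng.uniform(0, 255, size=lmap.shape)
            img = np.repeat(gray[..., None], 3, axis=2).astype(np.uint8)
            f = extract_features(img, lmap)
            if f[2] > 0:
                assert f[3] * f[2] == pytest.approx(f[1], abs=1e-9)
                assert f[4] == pytest.approx(4 * np.pi * f[1] / f[2] ** 2, abs=1e-9)
            assert np.all(f[13:29] >= 0)
            assert 0 < f[29] <= 1
            assert 0 <= f[30] <= 255

    def test_empty_label_map_yields_zero_vector(self, small_dataset):
        img = small_dataset.images[0]
        vec = extract_features(img, np.zeros(img.shape[:2], dtype=np.int32))
        assert np.all(vec == 0)
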