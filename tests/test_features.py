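import numpy as np
import pytest

from petrad.features import (
    FEATURE_NAMES,
    DiscretizationSpec,
    RadiomicsExtractor,
    conventional_features,
    direction_set,
    discretize,
    extract_all,
    glcm,
    glrlm,
    glrlm_features,
    glzlm,
    suv_peak,
    texture_features,
)
from petrad.segmentation import sphere_radius_mm
from petrad.volumes import PETVolume, VOIMask

from ._oracles import bf_glcm, bf_glrlm, bf_glzlm, bf_texture_features
from .conftest import make_discretized, random_discretized


def _vol_mask(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return PETVolume(values, spacing), VOIMask(np.ones(values.shape, bool), spacing)


class TestDiscretize:
    @pytest.mark.parametrize(
        "x,expected",
        [(20.0, 64), (0.0, 0), (40.0, 128), (55.0, 128), (40 / 256, 1), (19.9, 64)],
    )
    def test_absolute_binning(self, x, expected):
        vol, mask = _vol_mask(np.full((1, 1, 2), x))
        d = discretize(vol, mask, DiscretizationSpec(128, 0.0, 40.0))
        assert d.levels[0, 0, 0] == expected

    def test_bin_width(self):
        assert DiscretizationSpec(128, 0.0, 40.0).bin_width == pytest.approx(0.3125)

    def test_negative_values_clamped_with_warning(self):
        vol, mask = _vol_mask(np.array([[[-0.5, 2.0]]]))
        with pytest.warns(UserWarning, match="clamped"):
            d = discretize(vol, mask)
        assert d.levels[0, 0, 0] == 0

    def test_out_of_mask_sentinel(self):
        vol = PETVolume(np.full((2, 2, 2), 10.0), (1, 1, 1))
        mdat = np.zeros((2, 2, 2), bool)
        mdat[0, 0, 0] = True
        d = discretize(vol, VOIMask(mdat, (1, 1, 1)))
        assert d.levels[0, 0, 0] == 32
        assert (d.levels[~mdat] == -1).all()


class TestDirectionSet:
    def test_thirteen_sign_unique_offsets(self):
        dirs = direction_set()
        assert len(dirs) == 13
        assert all(d != (0, 0, 0) for d in dirs)
        assert all(set(d) <= {-1, 0, 1} for d in dirs)
        for a in dirs:
            for b in dirs:
                assert b != tuple(-c for c in a)

    def test_contains_axes_and_diagonal(self):
        dirs = set(direction_set())
        assert {(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)} <= dirs

    def test_closed_under_axis_permutation(self):
        # a permuted direction or its negation is always in the set
        dirs = set(direction_set())
        for d in dirs:
            for perm in ((1, 0, 2), (2, 1, 0), (0, 2, 1), (1, 2, 0), (2, 0, 1)):
                p = tuple(d[i] for i in perm)
                assert p in dirs or tuple(-c for c in p) in dirs


class TestMatrices:
    def test_glcm_two_voxel_pair(self):
        d = make_discretized(np.array([[[5, 7]]]), n_bins=8)
        m = glcm(d, (0, 0, 1))
        assert m.counts[5, 7] == 1 and m.counts[7, 5] == 1
        assert m.total == 2

    def test_glcm_constant_on_diagonal(self):
        d = make_discretized(np.full((3, 3, 3), 4), n_bins=8)
        for off in direction_set():
            m = glcm(d, off)
            assert m.counts[4, 4] == m.total > 0

    def test_glcm_single_voxel_empty(self):
        d = make_discretized(np.array([[[3]]]), n_bins=4)
        assert glcm(d, (0, 0, 1)).total == 0

    def test_glrlm_run_scan(self):
        d = make_discretized(np.array([[[3, 3, 3, 9]]]), n_bins=10)
        m = glrlm(d, (0, 0, 1))
        assert m.counts[3, 3] == 1 and m.counts[9, 1] == 1
        assert m.total == 2

    def test_glrlm_constant_line_single_run(self):
        d = make_discretized(np.full((1, 1, 7), 2), n_bins=4)
        m = glrlm(d, (0, 0, 1))
        assert m.counts[2, 7] == 1 and m.total == 1

    def test_glrlm_alternating_levels(self):
        d = make_discretized(np.array([[[1, 2, 1, 2]]]), n_bins=4)
        m = glrlm(d, (0, 0, 1))
        assert m.counts[1, 1] == 2 and m.counts[2, 1] == 2 and m.total == 4

    def test_glrlm_orientation_free(self, rng):
        d = random_discretized(rng)
        for off in direction_set():
            a = glrlm(d, off).counts
            b = glrlm(d, tuple(-c for c in off)).counts
            np.testing.assert_array_equal(a, b)

    def test_glzlm_two_separated_voxels(self):
        lv = np.full((5, 5, 1), -1)
        lv[0, 0, 0] = 4
        lv[3, 3, 0] = 4
        m = glzlm(make_discretized(lv, n_bins=6))
        assert m.counts[4, 1] == 2

    def test_glzlm_constant_mask_one_zone(self):
        d = make_discretized(np.full((3, 3, 2), 5), n_bins=6)
        m = glzlm(d)
        assert m.counts[5, 18] == 1 and m.total == 1

    def test_glzlm_diagonal_touch_is_one_zone(self):
        lv = np.full((4, 4, 1), -1)
        lv[0:2, 0:2, 0] = 6  # 2x2 block
        lv[2, 2, 0] = 6      # touches only diagonally
        m = glzlm(make_discretized(lv, n_bins=8))
        assert m.counts[6, 5] == 1

    def test_matrices_match_bruteforce_on_random_vois(self, rng):
        for _ in range(8):
            d = random_discretized(rng)
            n = d.n_levels
            for off in direction_set():
                np.testing.assert_array_equal(
                    glcm(d, off).counts, bf_glcm(d.levels, off, n)
                )
                ours = glrlm(d, off).counts
                ref = bf_glrlm(d.levels, off, n)
                w = max(ours.shape[1], ref.shape[1])
                np.testing.assert_array_equal(
                    np.pad(ours, ((0, 0), (0, w - ours.shape[1]))),
                    np.pad(ref, ((0, 0), (0, w - ref.shape[1]))),
                )
            zo = glzlm(d).counts
            zr = bf_glzlm(d.levels, n)
            w = max(zo.shape[1], zr.shape[1])
            np.testing.assert_array_equal(
                np.pad(zo, ((0, 0), (0, w - zo.shape[1]))),
                np.pad(zr, ((0, 0), (0, w - zr.shape[1]))),
            )


class TestTextureFeatures:
    def test_constant_voi_limits(self):
        d = make_discretized(np.full((4, 4, 4), 7), n_bins=10)
        f = texture_features(d)
        assert f["Homogeneity"] == pytest.approx(1.0)
        assert f["Entropy"] == pytest.approx(0.0, abs=1e-12)
        assert f["HGZE"] == pytest.approx(49.0)
        assert f["LGZE"] == pytest.approx(1 / 49.0)

    def test_hand_built_pattern_matches_independent_oracle(self):
        lv = np.array([[[1, 2, 1], [2, 3, 2], [1, 2, 1]]]).transpose(1, 2, 0)
        d = make_discretized(lv, n_bins=4)
        ours = texture_features(d)
        ref = bf_texture_features(d.levels, d.n_levels)
        for k, v in ref.items():
            assert ours[k] == pytest.approx(v, abs=1e-12), k

    def test_random_vois_match_oracle(self, rng):
        for _ in range(5):
            d = random_discretized(rng, shape=(4, 4, 3))
            ours = texture_features(d)
            ref = bf_texture_features(d.levels, d.n_levels)
            for k, v in ref.items():
                assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_sre_lre_bounds(self, rng):
        for _ in range(10):
            d = random_discretized(rng)
            f = texture_features(d)
            assert 0 < f["SRE"] <= 1.0 + 1e-12
            assert f["LRE"] >= 1.0 - 1e-12
            assert 0 < f["Homogeneity"] <= 1.0 + 1e-12
            assert f["Entropy"] >= 0

    def test_entropy_bounded_by_occupied_cells(self, rng):
        for _ in range(5):
            d = random_discretized(rng)
            for off in direction_set():
                m = glcm(d, off)
                if m.total == 0:
                    continue
                from petrad.features import glcm_features

                occ = np.count_nonzero(m.counts)
                assert glcm_features(m)["Entropy"] <= np.log2(occ) + 1e-12

    def test_coarser_bins_never_increase_entropy(self, rng):
        vol = PETVolume(rng.uniform(0, 30, (6, 6, 6)), (1, 1, 1))
        mask = VOIMask(np.ones((6, 6, 6), bool), (1, 1, 1))
        prev = None
        for n_bins in (128, 64, 32, 16, 8):
            f = texture_features(discretize(vol, mask, DiscretizationSpec(n_bins, 0, 40)))
            if prev is not None:
                assert f["Entropy"] <= prev + 1e-9
            prev = f["Entropy"]

    def test_degenerate_voi_raises(self):
        with pytest.raises(ValueError):
            texture_features(make_discretized(np.array([[[3]]]), n_bins=4))


class TestConventionalFeatures:
    def test_constant_cube(self):
        vol, mask = _vol_mask(np.full((10, 10, 10), 5.0))
        f = conventional_features(vol, mask)
        assert f["SUVmean"] == pytest.approx(5.0)
        assert f["SUVmax"] == pytest.approx(5.0)
        assert f["MV"] == pytest.approx(1.0)
        assert f["TLG"] == pytest.approx(5.0)

    def test_single_hot_voxel_peak_is_average(self):
        data = np.ones((11, 11, 11))
        data[5, 5, 5] = 20.0
        vol, mask = _vol_mask(data, spacing=(2.0, 2.0, 2.0))
        f = conventional_features(vol, mask)
        assert 1.0 < f["SUVpeak"] < 20.0

    def test_peak_equals_exhaustive_center_scan(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (7, 7, 7)), (2.0, 2.0, 2.0))
        mask = VOIMask(rng.uniform(size=(7, 7, 7)) > 0.4, (2.0, 2.0, 2.0))
        r = sphere_radius_mm(1.0)
        best = -np.inf
        for c in np.argwhere(mask.data):
            vals = []
            for v in np.ndindex(7, 7, 7):
                if np.sum(((np.array(v) - c) * 2.0) ** 2) <= r * r:
                    vals.append(vol.data[v])
            best = max(best, np.mean(vals))
        assert suv_peak(vol, mask) == pytest.approx(best, rel=1e-9)

    def test_tlg_identity(self, rng):
        vol = PETVolume(rng.uniform(0, 10, (8, 8, 8)), (1.5, 1.5, 2.0))
        mask = VOIMask(rng.uniform(size=(8, 8, 8)) > 0.5, (1.5, 1.5, 2.0))
        f = conventional_features(vol, mask)
        assert f["TLG"] == pytest.approx(f["SUVmean"] * f["MV"])


class TestExtractAll:
    def test_deterministic_and_complete(self, rng):
        vol = PETVolume(rng.uniform(0, 15, (8, 8, 8)), (2, 2, 2))
        mask = VOIMask(rng.uniform(size=(8, 8, 8)) > 0.3, (2, 2, 2))
        a = extract_all(vol, mask)
        b = extract_all(vol, mask)
        assert tuple(a) == FEATURE_NAMES
        assert a == b

    def test_translation_invariance(self, rng):
        # keep the 1 mL peak sphere (r ~ 6.2 mm -> 5 voxels at 1.5 mm) away
        # from the grid edge in both placements
        data = rng.uniform(0, 15, (6, 6, 6))
        big = np.zeros((18, 18, 18))
        mask_big = np.zeros((18, 18, 18), bool)
        big[5:11, 5:11, 5:11] = data
        mask_big[5:11, 5:11, 5:11] = True
        shifted = np.zeros((18, 18, 18))
        mask_shift = np.zeros((18, 18, 18), bool)
        shifted[7:13, 6:12, 5:11] = data
        mask_shift[7:13, 6:12, 5:11] = True
        sp = (1.5, 1.5, 2.0)
        a = extract_all(PETVolume(big, sp), VOIMask(mask_big, sp))
        b = extract_all(PETVolume(shifted, sp), VOIMask(mask_shift, sp))
        for k in FEATURE_NAMES:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_axis_permutation_invariance_of_texture(self, rng):
        data = rng.uniform(0, 15, (6, 7, 8))
        mask = rng.uniform(size=(6, 7, 8)) > 0.3
        sp = (1.0, 1.0, 1.0)
        a = extract_all(PETVolume(data, sp), VOIMask(mask, sp), names=tuple(
            n for n in FEATURE_NAMES if n not in ("SUVpeak",)
        ))
        perm = (2, 0, 1)
        b = extract_all(
            PETVolume(np.transpose(data, perm), sp),
            VOIMask(np.transpose(mask, perm), sp),
            names=tuple(n for n in FEATURE_NAMES if n not in ("SUVpeak",)),
        )
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_subset_extraction(self, rng):
        vol = PETVolume(rng.uniform(0, 15, (6, 6, 6)), (1, 1, 1))
        mask = VOIMask(np.ones((6, 6, 6), bool), (1, 1, 1))
        sub = extract_all(vol, mask, names=("Entropy", "SUVmax"))
        full = extract_all(vol, mask)
        assert sub["Entropy"] == pytest.approx(full["Entropy"])
        assert sub["SUVmax"] == full["SUVmax"]
        with pytest.raises(ValueError, match="unknown"):
            extract_all(vol, mask, names=("Kurtosis",))

    def test_transformer_interface(self, rng):
        vol = PETVolume(rng.uniform(0, 15, (6, 6, 6)), (1, 1, 1))
        mask = VOIMask(np.ones((6, 6, 6), bool), (1, 1, 1))
        df = RadiomicsExtractor().fit().transform([(vol, mask), (vol, mask)])
        assert list(df.columns) == list(FEATURE_NAMES)
        assert len(df) == 2
        params = RadiomicsExtractor(n_bins=64).get_params()
        assert params["n_bins"] == 64
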