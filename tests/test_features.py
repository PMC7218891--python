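import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kflbpcm import (
    FeatureVector,
    FusionParams,
    InvalidInputError,
    LBPConfig,
    LBPHistogramSet,
    StateError,
    compute_lbp_codes,
    extract_cmask_features,
    extract_combined_features,
    extract_pass_features,
    features_from_csv,
    features_to_csv,
    filter_dominant_bins,
    fuse_features,
    lbp_histogram,
)

from ._oracle import brute_force_riu2
from .conftest import make_image

OPERATORS = ((8, 1), (16, 2), (24, 3))


class TestLBPCodes:
    @pytest.mark.parametrize("P,R", OPERATORS)
    def test_matches_brute_force_oracle(self, rng, P, R):
        for _ in range(10):
            g = rng.integers(0, 256, (16, 16)).astype(float)
            assert np.array_equal(compute_lbp_codes(g, P, R),
                                  brute_force_riu2(g, P, R))

    @pytest.mark.parametrize("P,R", OPERATORS)
    def test_constant_raster_codes_all_P(self, P, R):
        # ties count as 1 → P set bits → uniform → code P
        codes = compute_lbp_codes(np.full((12, 12), 7.0), P, R)
        interior = codes[R:-R, R:-R]
        assert np.all(interior == P)
        assert np.all(codes[:R, :] == -1)

    def test_three_by_three_worked_example(self):
        # center's 3 brighter neighbors sit in one run → uniform, code 3
        g = np.array([[9, 9, 9], [0, 5, 0], [0, 0, 0]], dtype=float)
        assert compute_lbp_codes(g, 8, 1)[1, 1] == 3

    def test_rotation_preserves_code_multiset(self, rng):
        g = rng.integers(0, 256, (16, 16)).astype(float)
        for P, R in OPERATORS:
            a = compute_lbp_codes(g, P, R)[R:-R, R:-R]
            b = compute_lbp_codes(np.rot90(g), P, R)[R:-R, R:-R]
            assert np.array_equal(np.sort(a.ravel()), np.sort(b.ravel()))

    def test_too_small_raster_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_lbp_codes(np.zeros((4, 4)), 16, 2)


class TestHistogram:
    def test_conservation_and_constant_example(self):
        codes = compute_lbp_codes(np.full((10, 10), 3.0), 8, 1)
        hist = lbp_histogram(codes, None, 8)
        assert hist[8] == 64 and hist.sum() == 64  # 8×8 interior

    def test_sum_equals_interior_count(self, rng):
        g = rng.integers(0, 256, (20, 14)).astype(float)
        for P, R in OPERATORS:
            hist = lbp_histogram(compute_lbp_codes(g, P, R), None, P)
            assert hist.sum() == (20 - 2 * R) * (14 - 2 * R)

    def test_region_restriction(self, rng):
        g = rng.integers(0, 256, (16, 16)).astype(float)
        codes = compute_lbp_codes(g, 8, 1)
        empty = lbp_histogram(codes, np.zeros((16, 16), bool), 8)
        assert empty.sum() == 0
        full = lbp_histogram(codes, np.ones((16, 16), bool), 8)
        assert np.array_equal(full, lbp_histogram(codes, None, 8))

    def test_region_shape_mismatch(self):
        codes = compute_lbp_codes(np.zeros((16, 16)), 8, 1)
        with pytest.raises(InvalidInputError):
            lbp_histogram(codes, np.zeros((8, 8), bool), 8)


class TestFilterDominantBins:
    def _set(self, hist):
        h = np.asarray(hist, dtype=np.int64)
        return LBPHistogramSet([np.pad(h, (0, 10 - h.size))], ((8, 1),), [int(h.sum())])

    def test_zeroes_max_bin(self):
        out = filter_dominant_bins(self._set([5, 9, 3]))
        assert list(out.histograms[0][:3]) == [5, 0, 3]
        assert out.filtered and out.removed_counts == [9]

    def test_tie_breaks_to_lowest_index(self):
        out = filter_dominant_bins(self._set([7, 7, 1]))
        assert list(out.histograms[0][:3]) == [0, 7, 1]

    def test_all_zero_histogram_noop(self):
        out = filter_dominant_bins(self._set([0, 0, 0]))
        assert out.histograms[0].sum() == 0

    def test_double_filtering_rejected(self):
        out = filter_dominant_bins(self._set([5, 9, 3]))
        with pytest.raises(StateError):
            filter_dominant_bins(out)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=10, max_size=10))
    def test_sum_drops_by_exactly_max(self, counts):
        hset = self._set(counts)
        out = filter_dominant_bins(hset)
        assert out.histograms[0].sum() == sum(counts) - max(counts)


class TestBranches:
    def test_constant_image_gives_zero_vector(self):
        img = make_image(np.full((20, 20, 3), 77, dtype=np.uint8))
        fv = extract_pass_features(img)
        assert fv.branch == "pass"
        assert np.all(fv.values == 0)  # the only occupied bin was dominant

    def test_pass_deterministic(self, small_plant_images):
        img = small_plant_images[0]
        a = extract_pass_features(img).values
        b = extract_pass_features(img).values
        assert np.array_equal(a, b)

    def test_pass_rotation_invariant(self, rng):
        px = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        img = make_image(px)
        base = extract_pass_features(img).values
        for k in (1, 2, 3):
            rot = make_image(np.rot90(px, k))
            assert np.array_equal(extract_pass_features(rot).values, base)

    def test_no_vegetation_gives_zero_cmask(self):
        img = make_image(np.full((32, 32, 3), (140, 90, 60), dtype=np.uint8))
        fv = extract_cmask_features(img)
        assert fv.branch == "cmask"
        assert np.all(fv.values == 0)

    def _green_shape_image(self, mask):
        px = np.zeros(mask.shape + (3,), dtype=np.uint8)
        px[...] = (120, 70, 40)        # soil
        px[mask] = (40, 160, 40)       # leaf green
        return make_image(px)

    def test_disk_and_square_have_different_cmask(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2
        square = np.zeros((64, 64), bool)
        square[14:50, 14:50] = True  # similar area (1296 vs ~1257)
        fd = extract_cmask_features(self._green_shape_image(disk)).values
        fs = extract_cmask_features(self._green_shape_image(square)).values
        assert not np.allclose(fd, fs)

    def test_cmask_similarity_higher_within_shape_across_scale(self):
        # the scale-transfer premise: same boundary style at two sizes is
        # closer than different boundary styles at the same size
        yy, xx = np.mgrid[0:64, 0:64]
        disk_big = (yy - 32) ** 2 + (xx - 32) ** 2 <= 24 ** 2
        disk_small = (yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2
        square = np.zeros((64, 64), bool)
        square[8:56, 8:56] = True

        def cos(a, b):
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

        f_big = extract_cmask_features(self._green_shape_image(disk_big)).values
        f_small = extract_cmask_features(self._green_shape_image(disk_small)).values
        f_square = extract_cmask_features(self._green_shape_image(square)).values
        assert cos(f_big, f_small) > cos(f_big, f_square)

    def test_branch_dims_equal(self, small_plant_images):
        img = small_plant_images[0]
        lbp = LBPConfig()
        p = extract_pass_features(img, lbp)
        c = extract_cmask_features(img, lbp)
        combined = extract_combined_features(img, lbp)
        assert p.dim == c.dim == combined.dim == sum(P + 2 for P, _ in lbp.operators)


class TestFusion:
    def _fv(self, values, branch):
        return FeatureVector(np.asarray(values, float), branch)

    def test_k_zero_equals_cmask(self):
        p, c = self._fv([1, 2, 3], "pass"), self._fv([4, 5, 6], "cmask")
        out = fuse_features(p, c, FusionParams(k=0.0))
        assert np.array_equal(out.values, c.values) and out.branch == "combined"

    def test_k_one_equal_branches_doubles(self):
        v = np.array([0.5, 0.25, 0.25])
        out = fuse_features(self._fv(v, "pass"), self._fv(v, "cmask"), FusionParams(k=1.0))
        assert np.allclose(out.values, 2 * v)

    def test_worked_example(self):
        out = fuse_features(self._fv([10, 0], "pass"), self._fv([1, 2], "cmask"),
                            FusionParams(k=0.2))
        assert np.allclose(out.values, [3, 2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0, 10, allow_nan=False), k=st.floats(0, 5, allow_nan=False))
    def test_fusion_homogeneous(self, a, k):
        p = np.array([1.0, 2.0, 0.5])
        c = np.array([0.25, 0.0, 3.0])
        scaled = fuse_features(self._fv(a * p, "pass"), self._fv(a * c, "cmask"),
                               FusionParams(k=k)).values
        base = fuse_features(self._fv(p, "pass"), self._fv(c, "cmask"),
                             FusionParams(k=k)).values
        assert np.allclose(scaled, a * base)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            fuse_features(self._fv([1, 2], "pass"), self._fv([1, 2, 3], "cmask"))

    def test_branch_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            fuse_features(self._fv([1], "cmask"), self._fv([1], "pass"))


class TestCSVExchange:
    def test_roundtrip(self, tmp_path, small_plant_images):
        imgs = small_plant_images[:3]
        vectors = [extract_combined_features(im) for im in imgs]
        path = tmp_path / "features.csv"
        df = features_to_csv(path, vectors, imgs)
        assert list(df.columns[:3]) == ["path", "label", "stage"]
        X, y, frame = features_from_csv(path)
        assert X.shape == (3, vectors[0].dim)
        assert np.allclose(X, np.vstack([v.values for v in vectors]))
        assert list(y) == [im.label for im in imgs]
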