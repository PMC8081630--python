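"""High-pass rule: score/feature maps, guided filter vs oracle, weighted fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sistfuse.cnn_model import CNNConfig, build_model
from sistfuse.errors import ConfigurationError, InputError, StructureError
from sistfuse.highpass_rule import (
    GuidedFilterParams,
    ScoreMap,
    binarize,
    compute_score_map,
    fuse_highpass,
    guided_filter,
    refine_decision,
    score_to_feature_map,
)
from sistfuse.phantoms import PhantomSpec, make_complementary_blur_pair
from sistfuse.sist import SISTConfig, sist_decompose


class TestScoreMap:
    def test_equal_planes_score_exactly_half(self):
        model = build_model(CNNConfig(seed=0))
        plane = np.random.default_rng(0).standard_normal((32, 32))
        smap = compute_score_map(model, plane, plane.copy(), stride=4)
        assert np.all(smap.values == 0.5)

    @pytest.mark.parametrize(
        "size,stride", [((256, 256), 2), ((64, 64), 4), ((48, 40), 8)]
    )
    def test_sliding_window_grid_arithmetic(self, size, stride):
        model = build_model(CNNConfig(seed=0))
        plane = np.zeros(size)
        smap = compute_score_map(model, plane, plane, stride=stride)
        expected = tuple((s - 16) // stride + 1 for s in size)
        assert smap.values.shape == expected

    def test_sharp_half_scores_above_blurred_half(self, trained_model):
        a, b, _ = make_complementary_blur_pair(PhantomSpec(size=(128, 128), seed=5))
        cfg = SISTConfig(levels=2, directions_per_level=(8, 8))
        pa = sist_decompose(a, cfg)
        pb = sist_decompose(b, cfg)
        agg_a = sum(pa.highpass[0])
        agg_b = sum(pb.highpass[0])
        smap = compute_score_map(trained_model, agg_a, agg_b, stride=4)
        mid = smap.values.shape[1] // 2
        # A is sharp on the left, B on the right
        assert smap.values[:, :mid].mean() > smap.values[:, mid:].mean()

    def test_shape_mismatch_and_small_plane_rejected(self):
        model = build_model(CNNConfig(seed=0))
        with pytest.raises(InputError):
            compute_score_map(model, np.zeros((32, 32)), np.zeros((32, 16)))
        with pytest.raises(InputError):
            compute_score_map(model, np.zeros((8, 8)), np.zeros((8, 8)))


class TestFeatureMap:
    def test_constant_scores_give_constant_map(self):
        smap = ScoreMap(values=np.full((9, 9), 0.3), stride=2, patch_size=16)
        m = score_to_feature_map(smap, (32, 32))
        assert np.allclose(m, 0.3)

    def test_single_window_fills_whole_map(self):
        smap = ScoreMap(values=np.full((1, 1), 0.7), stride=1, patch_size=16)
        m = score_to_feature_map(smap, (16, 16))
        assert m.shape == (16, 16)
        assert np.all(m == 0.7)

    def test_overlap_pixels_average_covering_windows(self):
        # two windows at x=0 and x=8: columns 8..15 are covered by both
        smap = ScoreMap(values=np.array([[0.2, 0.8]]), stride=8, patch_size=16)
        m = score_to_feature_map(smap, (16, 24))
        assert np.allclose(m[:, :8], 0.2)
        assert np.allclose(m[:, 8:16], 0.5)
        assert np.allclose(m[:, 16:], 0.8)

    def test_inconsistent_geometry_rejected(self):
        smap = ScoreMap(values=np.zeros((3, 3)), stride=2, patch_size=16)
        with pytest.raises(StructureError):
            score_to_feature_map(smap, (64, 64))


class TestBinarize:
    def test_strict_threshold(self):
        m = np.array([[0.6, 0.5], [0.4, 0.500001]])
        t = binarize(m, 0.5)
        assert t.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_all_zero_map_stays_zero(self):
        assert not binarize(np.zeros((4, 4))).any()

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_outside_open_interval_rejected(self, tau):
        with pytest.raises(ConfigurationError):
            binarize(np.zeros((2, 2)), tau)


def _guided_filter_oracle(guide, src, r, eps):
    """Brute-force per-window linear regression, windows clipped at borders."""
    h, w = guide.shape
    a = np.zeros((h, w))
    b = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            win_i = guide[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            win_p = src[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            var = win_i.var()
            cov = (win_i * win_p).mean() - win_i.mean() * win_p.mean()
            a[i, j] = cov / (var + eps)
            b[i, j] = win_p.mean() - a[i, j] * win_i.mean()
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            wa = a[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            wb = b[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1]
            out[i, j] = wa.mean() * guide[i, j] + wb.mean()
    return out


def _double_box_mean(x, r):
    """Independent double box-mean with border-clipped windows."""
    def box(y):
        h, w = y.shape
        out = np.zeros_like(y)
        for i in range(h):
            for j in range(w):
                out[i, j] = y[max(0, i - r) : i + r + 1, max(0, j - r) : j + r + 1].mean()
        return out
    return box(box(x))


class TestGuidedFilter:
    def test_constant_input_is_fixed_point(self, rng):
        guide = rng.random((24, 24))
        out = guided_filter(guide, np.full((24, 24), 0.4), GuidedFilterParams(3, 0.1))
        assert np.abs(out - 0.4).max() < 1e-10

    def test_large_eps_limit_is_double_box_mean(self, rng):
        guide = rng.random((24, 24))
        src = rng.random((24, 24))
        out = guided_filter(guide, src, GuidedFilterParams(radius=3, eps=1e6))
        assert np.abs(out - _double_box_mean(src, 3)).max() < 1e-4

    @pytest.mark.parametrize("r", [2, 3, 4])
    def test_matches_brute_force_regression_oracle(self, r, rng):
        guide = rng.random((32, 32))
        src = rng.random((32, 32))
        params = GuidedFilterParams(radius=r, eps=0.1)
        assert np.abs(
            guided_filter(guide, src, params) - _guided_filter_oracle(guide, src, r, 0.1)
        ).max() < 1e-8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            guided_filter(np.zeros((8, 8)), np.zeros((8, 9)))


class TestRefineDecision:
    def test_all_ones_and_all_zeros_are_fixed_points(self, rng):
        guide = rng.random((32, 32))
        assert np.abs(refine_decision(np.ones((32, 32)), guide) - 1.0).max() < 1e-10
        assert np.abs(refine_decision(np.zeros((32, 32)), guide)).max() < 1e-10

    def test_checkerboard_smoothed_into_open_interval(self):
        t = np.indices((32, 32)).sum(axis=0) % 2.0
        d = refine_decision(t, np.full((32, 32), 0.5), GuidedFilterParams(2, 0.1))
        interior = d[4:-4, 4:-4]
        assert np.all(interior > 0.0) and np.all(interior < 1.0)


class TestFuseHighpass:
    def test_decision_endpoints_select_sources_exactly(self, rng):
        a, b = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
        assert np.array_equal(fuse_highpass(a, b, np.ones_like(a)), a)
        assert np.array_equal(fuse_highpass(a, b, np.zeros_like(a)), b)

    def test_halfway_decision_on_constants(self):
        a = np.full((8, 8), 2.0)
        b = np.full((8, 8), 4.0)
        assert np.allclose(fuse_highpass(a, b, np.full((8, 8), 0.5)), 3.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            fuse_highpass(np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 5)))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        data=hnp.arrays(np.float64, (6, 6), elements=st.floats(-10, 10)),
        weights=hnp.arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
        offset=hnp.arrays(np.float64, (6, 6), elements=st.floats(-10, 10)),
    )
    def test_convexity_symmetry_idempotence(self, data, weights, offset):
        a, b, d = data, data + offset, weights
        fused = fuse_highpass(a, b, d)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        assert np.all(fused >= lo - 1e-9) and np.all(fused <= hi + 1e-9)
        assert np.allclose(fuse_highpass(b, a, 1.0 - d), fused)
        # idempotence up to one rounding of the convex combination
        assert np.abs(fuse_highpass(a, a, d) - a).max() < 1e-12
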