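import numpy as np
import pytest

from msiqc.core import DegenerateInputError, IonImage, TissueMask, extract_ion_image
from msiqc.resolution import (
    PixelLabel,
    classify_pixels,
    clip_channel,
    spatial_resolution_score,
)
from conftest import small_phantom_spec
from msiqc.phantom import (
    Droplet,
    generate_phantom,
    truth_channel_map,
)


def _image(values, valid=None):
    values = np.asarray(values, dtype=np.float64)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return IonImage(values, valid, mz_center=0.0, mz_tol=0.0)


def sort_percentile(values, pct):
    """Independent linear-interpolation percentile from a plain sort."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * pct / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def brute_force_classify(a, b, on, ratio):
    """Per-pixel reference classifier, deliberately loop-based."""
    labels = np.full(a.shape, PixelLabel.EXCLUDED, dtype=np.int8)
    ny, nx = a.shape
    for r in range(ny):
        for c in range(nx):
            if not on[r, c]:
                continue
            x, y = a[r, c], b[r, c]
            lo, hi = min(x, y), max(x, y)
            if lo >= ratio * hi:
                labels[r, c] = PixelLabel.YELLOW
            elif x > y:
                labels[r, c] = PixelLabel.RED
            else:
                labels[r, c] = PixelLabel.GREEN
    return labels


class TestClipChannel:
    def test_definition_on_1_to_100(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        mask = TissueMask(np.ones((10, 10), bool))
        out = clip_channel(_image(vals), mask, 3, 97)
        assert out.values.min() == pytest.approx(np.percentile(vals, 3))
        assert out.values.max() == pytest.approx(np.percentile(vals, 97))

    def test_interior_values_unchanged(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 20, size=(8, 8))
        mask = TissueMask(np.ones((8, 8), bool))
        out = clip_channel(_image(vals), mask, 3, 97)
        p3, p97 = np.percentile(vals, [3, 97])
        interior = (vals >= p3) & (vals <= p97)
        np.testing.assert_array_equal(out.values[interior], vals[interior])

    def test_matches_sort_based_percentile_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 1, size=(12, 12))
        on = rng.random((12, 12)) > 0.3
        mask = TissueMask(on)
        out = clip_channel(_image(vals), mask, 3, 97)
        assert out.values[on].min() == pytest.approx(sort_percentile(vals[on], 3))
        assert out.values[on].max() == pytest.approx(sort_percentile(vals[on], 97))

    def test_off_tissue_untouched(self):
        vals = np.arange(1.0, 26.0).reshape(5, 5)
        on = np.zeros((5, 5), bool)
        on[:, :3] = True
        out = clip_channel(_image(vals), TissueMask(on), 3, 97)
        np.testing.assert_array_equal(out.values[~on], vals[~on])

    def test_percentiles_over_on_tissue_only(self):
        # background zeros outside the mask must not set the floor
        vals = np.zeros((6, 6))
        on = np.zeros((6, 6), bool)
        on[2:5, 2:5] = True
        vals[on] = np.arange(1.0, 10.0)
        out = clip_channel(_image(vals), TissueMask(on), 10, 90)
        assert out.values[on].min() >= sort_percentile(np.arange(1.0, 10.0), 10)

    def test_degenerate_inputs(self):
        mask = TissueMask(np.zeros((4, 4), bool))
        with pytest.raises(DegenerateInputError):
            clip_channel(_image(np.ones((4, 4))), mask, 3, 97)
        full = TissueMask(np.ones((4, 4), bool))
        with pytest.warns(UserWarning, match="constant"):
            out = clip_channel(_image(np.ones((4, 4))), full, 3, 97)
        assert np.all(out.values == 1.0)


class TestClassifyPixels:
    def test_tie_is_yellow_and_score_100(self):
        a = np.full((5, 5), 2.0)
        mask = TissueMask(np.ones((5, 5), bool))
        res = classify_pixels(_image(a), _image(a.copy()), mask, 0.7)
        assert np.all(res.labels == PixelLabel.YELLOW)
        assert res.score_percent == 100.0

    def test_ratio_arithmetic(self):
        red = _image([[1.0]])
        green = _image([[0.5]])
        mask = TissueMask([[True]])
        res = classify_pixels(red, green, mask, 0.7)
        assert res.labels[0, 0] == PixelLabel.RED

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.uniform(0, 10, size=(6, 6))
            b = rng.uniform(0, 10, size=(6, 6))
            on = rng.random((6, 6)) > 0.2
            if not on.any():
                continue
            res = classify_pixels(_image(a), _image(b), TissueMask(on), 0.7)
            expected = brute_force_classify(a, b, on, 0.7)
            np.testing.assert_array_equal(res.labels, expected)

    def test_swap_invariance_of_score(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 5, size=(7, 7))
        b = rng.uniform(0, 5, size=(7, 7))
        mask = TissueMask(np.ones((7, 7), bool))
        s1 = classify_pixels(_image(a), _image(b), mask).score_percent
        s2 = classify_pixels(_image(b), _image(a), mask).score_percent
        assert s1 == s2

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        a = rng.uniform(0.1, 5, size=(6, 6))
        b = rng.uniform(0.1, 5, size=(6, 6))
        mask = TissueMask(np.ones((6, 6), bool))
        base = classify_pixels(_image(a), _image(b), mask)
        scaled = classify_pixels(_image(a * 17.0), _image(b), mask)
        # ratio rule compares within-pixel min/max: scaling one channel can
        # flip colors, but scaling BOTH cannot
        both = classify_pixels(_image(a * 17.0), _image(b * 17.0), mask)
        np.testing.assert_array_equal(base.labels, both.labels)
        assert base.score_percent == both.score_percent

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_pixels(
                _image(np.ones((3, 3))), _image(np.ones((4, 4))),
                TissueMask(np.ones((3, 3), bool)),
            )

    def test_excluded_exactly_off_mask_or_unmeasured(self):
        a = np.ones((4, 4))
        valid = np.ones((4, 4), bool)
        valid[0, 0] = False
        on = np.ones((4, 4), bool)
        on[3, 3] = False
        res = classify_pixels(
            IonImage(a, valid, 0, 0), IonImage(a.copy(), valid.copy(), 0, 0),
            TissueMask(on),
        )
        excluded = res.labels == PixelLabel.EXCLUDED
        np.testing.assert_array_equal(excluded, ~(on & valid))


class TestSpatialResolutionScore:
    def test_identical_channels_score_100(self, small_phantom):
        dataset, truth = small_phantom
        res = spatial_resolution_score(dataset, truth.mask, 944.6, 944.6)
        assert res.score_percent == 100.0

    def test_hard_edges_no_noise_yellow_equals_truth_boundary(self):
        spec = small_phantom_spec(baseline_sigma=0.0, jitter_sigma_ln=0.0, seed=2)
        dataset, truth = generate_phantom(spec)
        res = spatial_resolution_score(dataset, truth.mask, 944.6, 1105.6)
        red_t = truth_channel_map(truth, 944.6, 0.25)
        green_t = truth_channel_map(truth, 1105.6, 0.25)
        boundary = (red_t > 0) & (green_t > 0) & truth.mask.grid
        yellow = res.labels == PixelLabel.YELLOW
        np.testing.assert_array_equal(yellow, boundary)

    def test_blurred_boundary_turns_yellow(self):
        spec = small_phantom_spec(baseline_sigma=0.0, jitter_sigma_ln=0.0,
                                  blur_sigma_px=2.0, seed=2)
        dataset, truth = generate_phantom(spec)
        res = spatial_resolution_score(dataset, truth.mask, 944.6, 1105.6)
        red_t = truth_channel_map(truth, 944.6, 0.25)
        green_t = truth_channel_map(truth, 1105.6, 0.25)
        boundary = (red_t > 0) & (green_t > 0) & truth.mask.grid
        yellow = res.labels == PixelLabel.YELLOW
        assert 0 < yellow.sum() <= boundary.sum()
        assert np.all(boundary[yellow])  # yellow only where both analytes land

    def test_droplet_increases_score(self):
        spec = small_phantom_spec(seed=3)
        clean, truth = generate_phantom(spec)
        base = spatial_resolution_score(clean, truth.mask, 944.6, 1105.6).score_percent
        # droplet straddling the villi/muscle boundary mixes both markers
        spec_d = small_phantom_spec(seed=3, droplets=[Droplet((16, 9), 4.0, 1.0)])
        corrupted, truth_d = generate_phantom(spec_d)
        high = spatial_resolution_score(corrupted, truth_d.mask, 944.6, 1105.6).score_percent
        assert high > base

    def test_params_recorded(self, small_phantom):
        dataset, truth = small_phantom
        res = spatial_resolution_score(dataset, truth.mask, 944.6, 1105.6, ratio=0.8)
        assert res.params["ratio"] == 0.8
        assert res.params["red_mz"] == 944.6
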