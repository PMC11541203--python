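"""Segmentation chain: smoothing, graph merging, background logic, masks."""

import numpy as np
import pytest
from scipy import ndimage

from organoid_morph import (
    GrayImage,
    NoOrganoidFoundError,
    PhantomSpec,
    SegmentationParams,
    ValidationError,
    classify_background,
    extract_largest_organoid,
    felzenszwalb_segment,
    gaussian_smooth,
    generate_phantom,
    jaccard_index,
    segment_organoid,
)
from organoid_morph.segmentation import SegmentLabelMap, _grid_edges


def brute_force_felzenszwalb(pixels, k, min_size, connectivity):
    """Naive reference: same sorted edge sequence, components as sets."""
    h, w = pixels.shape
    flat = pixels.ravel()
    a, b = _grid_edges(h, w, connectivity)
    weights = np.abs(flat[a] - flat[b])
    order = np.argsort(weights, kind="stable")
    edges = [(int(a[i]), int(b[i]), float(weights[i])) for i in order]

    comps = [{i} for i in range(h * w)]
    internal = [0.0 for _ in range(h * w)]

    def comp_of(px):
        for ci, c in enumerate(comps):
            if px in c:
                return ci
        raise AssertionError

    for pa, pb, wgt in edges:
        ca, cb = comp_of(pa), comp_of(pb)
        if ca == cb:
            continue
        if wgt <= min(internal[ca] + k / len(comps[ca]), internal[cb] + k / len(comps[cb])):
            comps[ca] |= comps[cb]
            internal[ca] = wgt
            del comps[cb], internal[cb]
    for pa, pb, wgt in edges:
        ca, cb = comp_of(pa), comp_of(pb)
        if ca == cb:
            continue
        if len(comps[ca]) < min_size or len(comps[cb]) < min_size:
            comps[ca] |= comps[cb]
            del comps[cb], internal[cb]
    return frozenset(frozenset(c) for c in comps)


def partition_of(labels: np.ndarray) -> frozenset:
    return frozenset(
        frozenset(np.nonzero(labels.ravel() == lab)[0].tolist())
        for lab in np.unique(labels)
    )


class TestGaussianSmooth:
    def test_constant_image_preserved(self):
        img = GrayImage(np.full((32, 32), 90.0))
        out = gaussian_smooth(img, 6.0)
        assert np.allclose(out.pixels, 90.0)

    def test_center_value_matches_dense_convolution(self):
        """Single bright pixel vs a brute-force dense Gaussian convolution."""
        n = 31
        pixels = np.zeros((n, n))
        pixels[n // 2, n // 2] = 255.0
        out = gaussian_smooth(GrayImage(pixels), 1.0)
        # independent oracle: explicit normalized kernel (4-sigma support,
        # matching the filter's truncation), direct sum
        half = 4
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(yy**2 + xx**2) / 2.0)
        kernel /= kernel.sum()
        expected_center = 255.0 * kernel[half, half]
        assert out.pixels[n // 2, n // 2] == pytest.approx(expected_center, abs=1e-6)

    def test_intensity_sum_conserved_away_from_borders(self):
        rng = np.random.default_rng(5)
        pixels = rng.uniform(50, 200, size=(96, 96))
        out = gaussian_smooth(GrayImage(pixels), 6.0)
        inner = slice(24, -24)
        assert out.pixels[inner, inner].sum() == pytest.approx(
            ndimage.uniform_filter(pixels, 1)[inner, inner].sum(), rel=5e-3
        )

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(GrayImage(np.zeros((10, 10))), 0.0)


class TestFelzenszwalb:
    def test_two_flat_halves_give_two_segments(self):
        pixels = np.full((20, 20), 40.0)
        pixels[:, 10:] = 200.0
        params = SegmentationParams(merge_scale_k=100.0)
        lab = felzenszwalb_segment(GrayImage(pixels), params)
        assert lab.n_segments == 2
        assert len(np.unique(lab.labels[:, :10])) == 1
        assert len(np.unique(lab.labels[:, 10:])) == 1

    def test_constant_image_single_segment(self):
        lab = felzenszwalb_segment(GrayImage(np.full((16, 16), 90.0)), SegmentationParams())
        assert lab.n_segments == 1

    def test_labels_partition_and_are_consecutive(self):
        rng = np.random.default_rng(2)
        pixels = rng.uniform(0, 255, size=(24, 24))
        lab = felzenszwalb_segment(GrayImage(pixels), SegmentationParams())
        assert set(np.unique(lab.labels)) == set(range(lab.n_segments))

    @pytest.mark.parametrize("seed", range(4))
    def test_min_size_postcondition(self, seed):
        rng = np.random.default_rng(seed)
        pixels = rng.uniform(0, 255, size=(20, 20))
        lab = felzenszwalb_segment(GrayImage(pixels), SegmentationParams(min_size_px=3))
        assert lab.sizes().min() >= 3

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("seed", range(5))
    def test_union_find_matches_brute_force_on_small_images(self, seed, connectivity):
        """The union-find partition equals a naive set-based replay of the
        same sorted edge sequence on images up to 12x12."""
        rng = np.random.default_rng(seed)
        size = rng.integers(8, 13)
        pixels = np.round(rng.uniform(0, 255, size=(size, size)), 1)
        params = SegmentationParams(
            merge_scale_k=float(rng.choice([2.0, 20.0, 100.0])),
            connectivity=connectivity,
        )
        lab = felzenszwalb_segment(GrayImage(pixels), params)
        expected = brute_force_felzenszwalb(
            pixels, params.merge_scale_k, params.min_size_px, connectivity
        )
        assert partition_of(lab.labels) == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_segment_count_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        pixels = ndimage.gaussian_filter(rng.uniform(0, 255, size=(20, 20)), 1.5)
        img = GrayImage(np.clip(pixels, 0, 255))
        counts = [
            felzenszwalb_segment(img, SegmentationParams(merge_scale_k=k)).n_segments
            for k in (1.0, 5.0, 20.0, 100.0, 500.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_mirror_image_gives_mirrored_partition(self):
        spec = PhantomSpec(radius_px=25, irregularity_amplitude=0.1, image_size_px=80, seed=3)
        image, _ = generate_phantom(spec)
        smoothed = gaussian_smooth(image, 6.0)
        params = SegmentationParams()
        lab = felzenszwalb_segment(smoothed, params)
        mirrored = GrayImage(smoothed.pixels[:, ::-1].copy())
        lab_m = felzenszwalb_segment(mirrored, params)
        assert partition_of(lab.labels[:, ::-1]) == partition_of(lab_m.labels)

    def test_deterministic(self, disk_phantom):
        image, _ = disk_phantom
        smoothed = gaussian_smooth(image, 6.0)
        l1 = felzenszwalb_segment(smoothed, SegmentationParams())
        l2 = felzenszwalb_segment(smoothed, SegmentationParams())
        assert np.array_equal(l1.labels, l2.labels)


class TestClassifyBackground:
    def _two_segment_map(self):
        labels = np.zeros((10, 10), dtype=np.int64)
        labels[:, 5:] = 1
        pixels = np.full((10, 10), 40.0)
        pixels[:, 5:] = 200.0
        return SegmentLabelMap(labels, 2), GrayImage(pixels)

    def test_bright_segment_is_background_at_90(self):
        lab, img = self._two_segment_map()
        assert classify_background(lab, img, 90.0) == {1}

    def test_all_dark_segments_empty_background(self):
        lab, img = self._two_segment_map()
        dark = GrayImage(np.clip(img.pixels, 0, 85))
        assert classify_background(lab, dark, 90.0) == set()

    def test_mean_exactly_at_threshold_is_not_background(self):
        labels = SegmentLabelMap(np.zeros((10, 10), dtype=np.int64), 1)
        img = GrayImage(np.full((10, 10), 90.0))
        assert classify_background(labels, img, 90.0) == set()

    def test_inverted_polarity_flips_classification(self):
        lab, img = self._two_segment_map()
        assert classify_background(lab, img, 90.0, invert_polarity=True) == {0}

    def test_shape_mismatch_rejected(self):
        lab, _ = self._two_segment_map()
        with pytest.raises(ValidationError):
            classify_background(lab, GrayImage(np.zeros((8, 8))), 90.0)


class TestExtractLargest:
    def _label_map(self, sizes):
        """1-D stripe label map with given segment sizes."""
        total = sum(sizes)
        rows = int(np.ceil(total / 32))
        arr = np.zeros(rows * 32, dtype=np.int64)
        pos = 0
        for lab, s in enumerate(sizes):
            arr[pos : pos + s] = lab
            pos += s
        arr[pos:] = len(sizes) - 1
        return SegmentLabelMap(arr.reshape(rows, 32), len(sizes))

    def test_largest_nonbackground_wins(self):
        lab = self._label_map([500, 120, 80])
        mask = extract_largest_organoid(lab, background={0})
        assert mask.n_foreground_px == 120
        assert np.array_equal(mask.mask, lab.labels == 1)

    def test_single_candidate_returned_exactly(self):
        lab = self._label_map([500, 120])
        mask = extract_largest_organoid(lab, background={0})
        assert np.array_equal(mask.mask, lab.labels == 1)

    def test_all_background_raises(self):
        lab = self._label_map([500, 120])
        with pytest.raises(NoOrganoidFoundError):
            extract_largest_organoid(lab, background={0, 1})

    def test_size_tie_resolves_to_lowest_label(self):
        lab = self._label_map([100, 100, 120])
        mask = extract_largest_organoid(lab, background={2})
        assert np.array_equal(mask.mask, lab.labels == 0)


class TestSegmentOrganoid:
    def test_recovers_synthetic_disk(self, disk_phantom):
        image, truth = disk_phantom
        mask = segment_organoid(image)
        assert jaccard_index(mask, truth) >= 0.95

    def test_uniformly_bright_image_raises(self):
        img = GrayImage(np.full((64, 64), 200.0))
        with pytest.raises(NoOrganoidFoundError):
            segment_organoid(img)

    def test_bit_identical_on_repeat(self, disk_phantom):
        image, _ = disk_phantom
        m1 = segment_organoid(image)
        m2 = segment_organoid(image)
        assert np.array_equal(m1.mask, m2.mask)

    def test_mask_is_single_connected_component(self, disk_phantom):
        image, _ = disk_phantom
        mask = segment_organoid(image)
        _, ncomp = ndimage.label(mask.mask, structure=np.ones((3, 3), bool))
        assert ncomp == 1
        assert mask.n_foreground_px >= 1


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"smoothing_sd_px": 0.0},
            {"min_size_px": 0},
            {"merge_scale_k": -1.0},
            {"background_threshold": 300.0},
            {"connectivity": 6},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SegmentationParams(**kwargs)
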