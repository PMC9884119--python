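"""Detector and linker contracts, with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from embryoquant import (Calibration, Detection2D, SegmentationParams,
                         detect_nuclei_2d, link_z, normalize_percentiles,
                         segment_stack, tracks_to_labels, unsharp_mask)
from embryoquant.synthetic import SyntheticEmbryoSpec, render_stack

CAL = Calibration(pixel_size_um=0.5, z_step_um=2.0)


def brute_force_unsharp(image, radius_px, weight):
    """Direct evaluation of (I - w*G(I)) / (1-w) with an explicit Gaussian
    kernel (truncated at 4 sigma, reflect boundary), then clipping."""
    from scipy.signal import convolve2d

    sigma = radius_px
    r = int(4 * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    blurred = convolve2d(image, kernel, mode="same", boundary="symm")
    out = (image - weight * blurred) / (1 - weight)
    return np.clip(out, image.min(), image.max())


class TestUnsharpMask:
    @given(st.floats(min_value=0.0, max_value=255.0))
    def test_constant_image_is_fixed_point(self, c):
        img = np.full((32, 32), c)
        out = unsharp_mask(img, radius_px=15, weight=0.6)
        assert np.allclose(out, c)

    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (24, 24))
        assert np.allclose(unsharp_mask(img, 3, 0.0), img)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 200, (41, 41))
        expected = brute_force_unsharp(img, radius_px=2, weight=0.6)
        out = unsharp_mask(img, radius_px=2, weight=0.6)
        # interior only: boundary handling differs in the last ulps
        assert np.allclose(out[10:-10, 10:-10], expected[10:-10, 10:-10],
                           rtol=1e-4, atol=1e-3)

    def test_impulse_center_matches_formula(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = unsharp_mask(img, radius_px=2, weight=0.6)
        expected = brute_force_unsharp(img, radius_px=2, weight=0.6)
        assert out[16, 16] == pytest.approx(expected[16, 16], abs=1e-6)

    def test_degenerate_weight_rejected(self):
        with pytest.raises(ValueError):
            unsharp_mask(np.zeros((4, 4)), 2, 1.0)


class TestNormalizePercentiles:
    def test_full_range_ramp_maps_to_unit_interval(self):
        ramp = np.tile(np.arange(256, dtype=float), (4, 1))
        out = normalize_percentiles(ramp, 0, 100)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.allclose(out, ramp / 255.0)

    def test_constant_image_maps_to_zeros(self):
        assert np.array_equal(normalize_percentiles(np.full((8, 8), 7.0), 1, 99.9),
                              np.zeros((8, 8)))

    def test_clipping_at_percentiles_matches_sorting_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (50, 50))
        p_low, p_high = 1.0, 99.9
        lo, hi = np.percentile(np.sort(img.ravel()), [p_low, p_high])
        out = normalize_percentiles(img, p_low, p_high)
        assert np.all(out[img <= lo] == 0.0)
        assert np.all(out[img >= hi] == 1.0)
        mid = (img > lo) & (img < hi)
        assert np.allclose(out[mid], (img[mid] - lo) / (hi - lo))

    @given(st.integers(0, 2**31 - 1))
    def test_output_always_in_unit_interval(self, seed):
        img = np.random.default_rng(seed).uniform(-5, 300, (16, 16))
        out = normalize_percentiles(img, 1.0, 99.9)
        assert out.min() >= 0.0 and out.max() <= 1.0


def _disk_slice(shape, center_rc, radius_px, value=0.9):
    img = np.zeros(shape)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    img[(rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px**2] = value
    return img


class TestDetect2D:
    def test_blank_slice_gives_no_detections(self):
        assert detect_nuclei_2d(np.zeros((64, 64)), SegmentationParams(), CAL) == []

    def test_single_disk_detected_at_center(self):
        img = _disk_slice((64, 64), (30, 34), radius_px=4)  # ~12.6 um^2
        dets = detect_nuclei_2d(img, SegmentationParams(), CAL)
        assert len(dets) == 1
        cx, cy = dets[0].centroid_xy_um
        assert abs(cx / CAL.pixel_size_um - 34) <= 1
        assert abs(cy / CAL.pixel_size_um - 30) <= 1

    def test_two_distant_disks_detected_separately(self):
        img = _disk_slice((96, 96), (24, 24), 4) + _disk_slice((96, 96), (70, 70), 4)
        dets = detect_nuclei_2d(img, SegmentationParams(), CAL)
        assert len(dets) == 2

    def test_touching_disks_split_by_watershed(self):
        img = _disk_slice((64, 96), (32, 40), 5) + _disk_slice((64, 96), (32, 52), 5)
        img = np.clip(img, 0, 0.9)
        dets = detect_nuclei_2d(img, SegmentationParams(), CAL)
        assert len(dets) == 2

    @pytest.mark.parametrize("n_px,expected", [
        (20, 0),   # 20 px * 0.25 um^2 = 5 um^2: boundary, excluded
        (21, 1),   # 5.25 um^2: inside the open interval
        (119, 1),  # 29.75 um^2
        (120, 0),  # 30 um^2: boundary, excluded
        (19, 0),   # below
        (140, 0),  # above
    ])
    def test_area_filter_open_interval(self, n_px, expected):
        """The per-slice area window (5, 30) um^2 excludes its bounds."""
        img = np.zeros((64, 64))
        # a compact square-ish region of exactly n_px pixels
        side = int(np.floor(np.sqrt(n_px)))
        img[20:20 + side, 20:20 + side] = 0.9
        rem = n_px - side * side
        img[20 + side, 20:20 + rem] = 0.9
        assert int((img > 0).sum()) == n_px
        dets = detect_nuclei_2d(img, SegmentationParams(), CAL)
        assert len(dets) == expected

    def test_raising_threshold_never_adds_detections(self):
        rng = np.random.default_rng(3)
        img = np.clip(
            _disk_slice((96, 96), (30, 30), 4, 0.8)
            + _disk_slice((96, 96), (60, 66), 4, 0.5)
            + rng.uniform(0, 0.15, (96, 96)),
            0, 1,
        )
        counts = []
        for thr in (0.1, 0.2, 0.35, 0.6, 0.9):
            p = SegmentationParams(detect_threshold=thr)
            counts.append(len(detect_nuclei_2d(img, p, CAL)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            detect_nuclei_2d(np.zeros((8, 8)), SegmentationParams(), None)


def _column(xy_um, slices, area_px=24):
    """A column of identical detections at one xy position."""
    dets = []
    for s in slices:
        rr, cc = np.meshgrid(np.arange(6), np.arange(4), indexing="ij")
        pixels = np.column_stack([rr.ravel(), cc.ravel()])
        dets.append(Detection2D(
            slice_index=s, pixels=pixels, area_um2=area_px * 0.25,
            centroid_xy_um=xy_um, mean_dna=100.0,
        ))
    return dets


class TestLinkZ:
    def test_six_slice_column_survives_duration_filter(self):
        by_slice = [[d] for d in _column((5.0, 5.0), range(6))]
        tracks = link_z(by_slice, SegmentationParams())
        assert len(tracks) == 1
        assert tracks[0].duration == 6

    def test_five_slice_column_is_discarded(self):
        by_slice = [[d] for d in _column((5.0, 5.0), range(5))]
        assert link_z(by_slice, SegmentationParams()) == []

    def test_parallel_distant_columns_do_not_cross_link(self):
        p = SegmentationParams()
        far = 3 * p.max_link_dist_um
        a = _column((5.0, 5.0), range(7))
        b = _column((5.0 + far, 5.0), range(7))
        by_slice = [[x, y] for x, y in zip(a, b)]
        tracks = link_z(by_slice, p)
        assert len(tracks) == 2
        for t in tracks:
            xs = {d.centroid_xy_um[0] for d in t.detections}
            assert len(xs) == 1  # each track stays on one column

    def test_no_detection_in_two_tracks(self):
        rng = np.random.default_rng(4)
        by_slice = []
        for s in range(8):
            dets = []
            for i in range(rng.integers(0, 5)):
                xy = tuple(rng.uniform(0, 30, 2))
                dets.append(Detection2D(s, np.array([[0, 0]]), 6.0, xy, 50.0))
            by_slice.append(dets)
        tracks = link_z(by_slice, SegmentationParams(min_track_len=1))
        seen = set()
        for t in tracks:
            for d in t.detections:
                assert id(d) not in seen
                seen.add(id(d))
        assert len(seen) == sum(len(d) for d in by_slice)


class TestTracksToLabels:
    def test_empty_tracks_give_zero_volume(self):
        vol = tracks_to_labels([], (4, 8, 8), CAL)
        assert vol.data.sum() == 0

    def test_voxel_count_is_additive_over_slices(self):
        from embryoquant import Nucleus3D
        dets = _column((1.0, 1.0), range(6), area_px=24)
        track = Nucleus3D(track_id=1, detections=dets)
        vol = tracks_to_labels([track], (6, 16, 16), CAL)
        assert (vol.data == 1).sum() == 6 * 24

    def test_labels_contiguous_after_relabeling(self, small_segmented):
        _, _, labels, tracks = small_segmented
        present = labels.labels
        assert np.array_equal(present, np.arange(1, len(present) + 1))


class TestSegmentStack:
    def test_noise_only_stack_yields_no_nuclei(self):
        spec = SyntheticEmbryoSpec(n_epi=0, n_pre=0, n_te=0,
                                   slice_shape=(128, 128), seed=12)
        stack, _ = render_stack(spec)
        labels, tracks = segment_stack(stack)
        assert tracks == []
        assert labels.data.max() == 0

    def test_recovers_planted_nucleus_count(self, small_segmented, small_spec):
        _, truth, _, tracks = small_segmented
        n_true = len(truth)
        assert abs(len(tracks) - n_true) <= 0.1 * n_true

    def test_deterministic_across_runs(self, small_embryo):
        stack, _ = small_embryo
        l1, _ = segment_stack(stack)
        l2, _ = segment_stack(stack)
        assert np.array_equal(l1.data, l2.data)
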