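"""Triage pipeline: masks, cup detection, content classes, motility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage
from skimage.draw import disk

from shadowimg.core import ImageStack, PixelGeometry
from shadowimg.microglia import (
    MotilityMetrics,
    PhagocyticCup,
    TipTrajectory,
    TriageParams,
    classify_cup_contents,
    classify_path,
    detect_lesion_roi,
    detect_phagocytic_cups,
    enrichment_stats,
    preprocess_coshi,
    threshold_tissue_state,
    track_metrics,
)

GEOM = PixelGeometry(dx=0.2)


def egfp_stack(frames):
    return ImageStack(np.asarray(frames, float)[:, None, None], geometry=GEOM)


class TestPreprocess:
    def test_salt_pixel_removed_by_median(self):
        frame = np.full((32, 32), 2.0)
        frame[10, 10] = 100.0
        frame[0, 0] = 0.0  # keeps the frame non-degenerate after filtering
        out = preprocess_coshi(ImageStack(frame, geometry=GEOM))
        # the hot pixel no longer stands out against its neighbourhood
        assert abs(out.plane()[10, 10] - np.median(out.plane())) < 0.1

    def test_median_matches_neighbourhood_sort_oracle(self, rng):
        from skimage.morphology import disk as disk_footprint

        frame = rng.uniform(0, 1, (16, 16))
        params = TriageParams(median_radius_px=2)
        foot = disk_footprint(2)
        filtered = ndimage.median_filter(frame, footprint=foot, mode="reflect")
        # brute-force oracle with explicit reflected padding and sorting
        pad = np.pad(frame, 2, mode="symmetric")  # scipy's 'reflect' convention
        oy, ox = np.nonzero(foot)
        for i in (0, 5, 15):
            for j in (0, 7, 15):
                vals = sorted(pad[i + oy, j + ox])
                assert filtered[i, j] == pytest.approx(vals[len(vals) // 2])

    def test_output_normalized_and_inverted(self, rng):
        frames = rng.uniform(0, 500, (2, 1, 1, 24, 24))
        out = preprocess_coshi(ImageStack(frames, geometry=GEOM))
        assert out.normalized
        assert out.data.min() >= 0 and out.data.max() <= 1


class TestThresholdTissueState:
    def _inverted(self, frame):
        s = ImageStack(np.asarray(frame, float)[None, None, None], geometry=GEOM)
        s.normalized = True
        return s

    def test_hand_enumerated_toy_frame(self):
        frame = np.full((4, 4), 0.5)
        frame[0, 0] = 0.0
        frame[0, 1] = 0.01
        frame[1, 0] = 0.8
        intact, lysed = threshold_tissue_state(self._inverted(frame))
        assert lysed.sum() == 2 and lysed[0, 0, 0] and lysed[0, 0, 1]
        assert intact.sum() == 1 and intact[0, 1, 0]

    def test_midgray_frame_gives_empty_masks(self):
        intact, lysed = threshold_tissue_state(self._inverted(np.full((4, 4), 0.5)))
        assert not intact.any() and not lysed.any()

    def test_strict_inequalities_at_degenerate_thresholds(self):
        params = TriageParams(intact_threshold=1.0, lysed_threshold=0.0)
        frame = np.zeros((4, 4))
        frame[0, 0] = 1.0
        intact, lysed = threshold_tissue_state(self._inverted(frame), params)
        assert not intact.any() and not lysed.any()

    @given(frames=hnp.arrays(float, (2, 8, 8), elements=st.floats(0, 1)))
    @settings(max_examples=30, deadline=None)
    def test_masks_always_disjoint(self, frames):
        s = ImageStack(frames[:, None, None], geometry=GEOM)
        s.normalized = True
        intact, lysed = threshold_tissue_state(s)
        assert not (intact & lysed).any()


class TestDetectLesionRoi:
    def test_no_change_no_roi(self):
        intact = np.zeros((4, 16, 16), bool)
        intact[:, 2:5, 2:5] = True  # static structure, present at baseline
        lysed = np.zeros_like(intact)
        roi = detect_lesion_roi(intact, lysed, baseline_frames=1,
                                close_radius_um=0.6, dx_um=0.2)
        assert not roi.any()

    def test_appearing_lysed_disk_enters_roi(self):
        intact = np.zeros((4, 32, 32), bool)
        lysed = np.zeros_like(intact)
        rr, cc = disk((16, 16), 6)
        lysed[2:, rr, cc] = True
        roi = detect_lesion_roi(intact, lysed, baseline_frames=1,
                                close_radius_um=0.6, dx_um=0.2)
        assert not roi[:2].any()
        assert roi[2][rr, cc].all() and roi[3][rr, cc].all()

    def test_covers_phantom_lesion_truth(self):
        from shadowimg.phantoms import LesionConfig, PhantomConfig, make_lesion_series

        cfg = PhantomConfig(seed=13, lesion=LesionConfig(n_cups=20, exact_counts=True))
        stack, truth = make_lesion_series(cfg)
        shadow = ImageStack(stack.data[:, 1:2], geometry=stack.geometry)
        params = TriageParams()
        intact, lysed = threshold_tissue_state(preprocess_coshi(shadow, params), params)
        roi = detect_lesion_roi(intact, lysed, baseline_frames=2,
                                close_radius_um=1.0, dx_um=stack.geometry.dx)
        final_truth = truth.lesion_masks[-1]
        coverage = (roi[-1] & final_truth).sum() / final_truth.sum()
        assert coverage >= 0.95


class TestDetectCups:
    def _annulus_frames(self, r_in=15, r_out=20, n_frames=1, shape=(64, 64)):
        frame = np.zeros(shape)
        rr, cc = disk((32, 32), r_out)
        frame[rr, cc] = 1.0
        rr, cc = disk((32, 32), r_in)
        frame[rr, cc] = 0.0
        return np.stack([frame] * n_frames)

    def test_solid_disk_has_no_cups(self):
        frame = np.zeros((64, 64))
        rr, cc = disk((32, 32), 20)
        frame[rr, cc] = 1.0
        assert detect_phagocytic_cups(egfp_stack([frame])) == []

    def test_annulus_diameter_recovered(self):
        # 15 px interior radius at 0.2 um/px -> 6 um equivalent diameter
        cups = detect_phagocytic_cups(egfp_stack(self._annulus_frames()))
        assert len(cups) == 1
        assert cups[0].median_diameter_um == pytest.approx(6.0, rel=0.03)
        assert cups[0].mean_circularity > 0.9

    def test_open_ring_rejected_annulus_kept(self):
        frames = self._annulus_frames()
        c_shape = np.zeros((64, 64))
        th = np.linspace(0.4, 2 * np.pi - 0.4, 300)
        for rad in range(12, 17):
            c_shape[(10 + rad * np.sin(th)).astype(int) % 64,
                    (40 + rad * np.cos(th)).astype(int) % 64] = 1.0
        combined = np.clip(frames[0] * 0 + c_shape, 0, 1)
        two = np.zeros((128, 64))
        two[:64] = frames[0]
        two[64:] = combined
        cups = detect_phagocytic_cups(egfp_stack([two]))
        assert len(cups) == 1  # only the closed annulus encloses a hole

    def test_translation_equivariance(self):
        frames = self._annulus_frames(shape=(96, 96))
        cups_a = detect_phagocytic_cups(egfp_stack(frames))
        shifted = np.roll(frames, (7, 11), axis=(1, 2))
        cups_b = detect_phagocytic_cups(egfp_stack(shifted))
        (ya, xa) = cups_a[0].centroids_um[0]
        (yb, xb) = cups_b[0].centroids_um[0]
        assert yb - ya == pytest.approx(7 * 0.2, abs=1e-9)
        assert xb - xa == pytest.approx(11 * 0.2, abs=1e-9)

    @given(data=st.data())
    @settings(max_examples=20, deadline=None)
    def test_fill_holes_matches_border_flood_fill_oracle(self, data):
        binary = data.draw(hnp.arrays(bool, (32, 32)))
        filled = ndimage.binary_fill_holes(binary)
        holes = filled & ~binary
        # oracle: enclosed background = background not reachable from border
        bg = ~binary
        labels, _ = ndimage.label(bg)
        border = np.unique(np.concatenate([
            labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
        reachable = np.isin(labels, border[border > 0])
        assert np.array_equal(holes, bg & ~reachable)


class TestClassifyContents:
    def _cup_over(self, lysed_frac, intact_frac, shape=(1, 32, 32)):
        npix = 100
        rr, cc = np.divmod(np.arange(npix), 10)
        cup = PhagocyticCup(cup_id=0, frames=[0], footprints={0: (rr + 5, cc + 5)},
                            eq_diameters_um={0: 6.0}, circularities={0: 1.0})
        lysed = np.zeros(shape, bool)
        intact = np.zeros(shape, bool)
        k = int(lysed_frac * npix)
        j = int(intact_frac * npix)
        lysed[0][(rr + 5)[:k], (cc + 5)[:k]] = True
        intact[0][(rr + 5)[k:k + j], (cc + 5)[k:k + j]] = True
        return [cup], intact, lysed

    def test_fully_lysed_interior(self):
        cups, intact, lysed = self._cup_over(1.0, 0.0)
        cups, s = classify_cup_contents(cups, intact, lysed)
        assert cups[0].content_class == "lysed"
        assert s.percent_lysed == 100.0

    def test_40_40_20_is_empty_by_median_rule(self):
        # literal median rule (no rim erosion): neither state exceeds half
        cups, intact, lysed = self._cup_over(0.4, 0.4)
        cups, _ = classify_cup_contents(cups, intact, lysed, rim_erosion_px=0)
        assert cups[0].content_class == "empty"

    def test_both_across_different_frames(self):
        rr, cc = np.divmod(np.arange(100), 10)
        cup = PhagocyticCup(cup_id=0, frames=[0, 1],
                            footprints={0: (rr, cc), 1: (rr, cc)},
                            eq_diameters_um={0: 6.0, 1: 6.0},
                            circularities={0: 1.0, 1: 1.0})
        lysed = np.zeros((2, 16, 16), bool)
        intact = np.zeros((2, 16, 16), bool)
        lysed[0, :10, :10] = True
        intact[1, :10, :10] = True
        [cup], s = classify_cup_contents([cup], intact, lysed)
        assert cup.content_class == "both"
        assert s.percent_both == 100.0

    def test_percentages_sum_to_100(self):
        from shadowimg.phantoms import LesionConfig, PhantomConfig, make_lesion_series

        cfg = PhantomConfig(seed=14, lesion=LesionConfig(n_cups=30))
        stack, _ = make_lesion_series(cfg)
        params = TriageParams()
        shadow = ImageStack(stack.data[:, 1:2], geometry=stack.geometry)
        egfp = ImageStack(stack.data[:, 0:1], geometry=stack.geometry)
        intact, lysed = threshold_tissue_state(preprocess_coshi(shadow, params), params)
        cups = detect_phagocytic_cups(egfp, params)
        _, s = classify_cup_contents(cups, intact, lysed)
        total = s.percent_lysed + s.percent_intact + s.percent_both + s.percent_empty
        assert total == pytest.approx(100.0, abs=0.1)


class TestEnrichment:
    def test_half_half_roi(self):
        lysed = np.zeros((1, 16, 16), bool)
        intact = np.zeros((1, 16, 16), bool)
        roi = np.zeros((1, 16, 16), bool)
        roi[0, :8] = True
        lysed[0, :4] = True
        intact[0, 4:8] = True
        s = enrichment_stats(intact, lysed, roi, [])
        assert s.in_roi_lysed == pytest.approx(50.0)
        assert s.in_roi_intact == pytest.approx(50.0)
        assert s.in_pc_lysed is None  # no cups anywhere

    def test_cups_enriched_over_roi(self):
        rr, cc = np.divmod(np.arange(100), 10)
        cup = PhagocyticCup(cup_id=0, frames=[0], footprints={0: (rr, cc)},
                            eq_diameters_um={0: 6.0}, circularities={0: 1.0})
        lysed = np.zeros((1, 32, 32), bool)
        intact = np.zeros((1, 32, 32), bool)
        lysed[0, :10, :10] = True   # cup interior is fully lysed
        roi = np.zeros((1, 32, 32), bool)
        roi[0] = True               # ROI is the whole field: ~10% lysed
        s = enrichment_stats(intact, lysed, roi, [cup])
        assert s.in_pc_lysed == pytest.approx(100.0)
        assert s.in_roi_lysed == pytest.approx(100 * 100 / 1024, rel=1e-6)
        assert s.in_pc_lysed > s.in_roi_lysed


class TestTrackMetrics:
    def _straight(self, n=16, step=0.1, dt=20.0):
        x = np.arange(n) * step
        return TipTrajectory(frames=np.arange(n), t_s=np.arange(n) * dt,
                             y_um=np.zeros(n), x_um=x,
                             lesion_point_um=(0.0, x[-1]))

    def test_straight_path_arithmetic(self):
        traj = self._straight()
        m = track_metrics(traj, arrival_radius_um=0.05)
        assert m.mean_velocity_um_s == pytest.approx(0.1 / 20.0)
        assert m.arrival_frame == 15
        assert m.cumulative_distance_um == pytest.approx(0.1 * 15)

    def test_velocity_window_uses_frames_3_to_7(self):
        # speeds vary per step; only transitions 3->4 ... 6->7 (1-based) count
        x = np.concatenate([[0, 1, 2], 2 + np.cumsum([10, 10, 10, 10]), [62, 63]])
        n = len(x)
        traj = TipTrajectory(frames=np.arange(n), t_s=np.arange(n) * 1.0,
                             y_um=np.zeros(n), x_um=x.astype(float),
                             lesion_point_um=(0.0, 1e6))
        m = track_metrics(traj)
        assert m.mean_velocity_um_s == pytest.approx(10.0)

    def test_stationary_tip_no_arrival(self):
        traj = TipTrajectory(frames=np.arange(10), t_s=np.arange(10) * 20.0,
                             y_um=np.zeros(10), x_um=np.zeros(10),
                             lesion_point_um=(50.0, 50.0))
        m = track_metrics(traj)
        assert m.arrival_frame is None
        assert m.mean_velocity_um_s == pytest.approx(0.0)
        assert m.cumulative_distance_um == pytest.approx(0.0)

    def test_short_trajectory_velocity_undefined(self):
        traj = self._straight(n=6)
        assert track_metrics(traj).mean_velocity_um_s is None


class TestClassifyPath:
    def _traj(self, start=(2.0, 2.0), lesion=(2.0, 18.0)):
        return TipTrajectory(frames=np.arange(8), t_s=np.arange(8) * 20.0,
                             y_um=np.full(8, start[0]), x_um=np.full(8, start[1]),
                             lesion_point_um=lesion)

    def test_empty_mask_is_neuropil(self):
        baseline = np.zeros((100, 100))
        assert classify_path(self._traj(), baseline, 0.2) == "neuropil"

    def test_disk_on_segment_is_cell_bodies(self):
        baseline = np.zeros((100, 100))
        rr, cc = disk((10, 50), 20)  # 8 um diameter at dx 0.2
        baseline[rr, cc] = 1.0
        assert classify_path(self._traj(), baseline, 0.2) == "cell_bodies"

    def test_disk_off_segment_is_neuropil(self):
        baseline = np.zeros((100, 100))
        rr, cc = disk((60, 50), 20)  # 10 um below the segment
        baseline[rr, cc] = 1.0
        traj = self._traj()
        assert classify_path(traj, baseline, 0.2) == "neuropil"
        # dense-sampling oracle agrees: no sampled point hits the mask
        ys = np.full(200, 2.0)
        xs = np.linspace(2.0, 18.0, 200)
        assert not baseline[(ys / 0.2).astype(int), (xs / 0.2).astype(int)].any()
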