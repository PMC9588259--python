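"""NCC tracker: correlation map, peak localization, sequence tracking."""

import numpy as np
import pytest

from dcrmotion import (
    AcquisitionGeometry,
    GroundTruthTrajectory,
    MotionPattern,
    TrackerConfig,
    locate_peak,
    ncc_map,
    project_and_sample,
    render_video,
    reseed,
    track_sequence,
)
from dcrmotion.tracking import STATUS_LOST, STATUS_LOW_CONFIDENCE, STATUS_TRACKED


def brute_force_ncc(template, region):
    """Direct double-loop Pearson correlation at every offset."""
    th, tw = template.shape
    rh, rw = region.shape
    out = np.zeros((rh - th + 1, rw - tw + 1))
    t = template - template.mean()
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            patch = region[i:i + th, j:j + tw]
            p = patch - patch.mean()
            denom = np.sqrt((t * t).sum() * (p * p).sum())
            out[i, j] = 0.0 if denom == 0 else (t * p).sum() / denom
    return out


class TestNccMap:
    @pytest.mark.parametrize("tsize,rsize", [(9, 21), (15, 31), (25, 31), (31, 61)])
    def test_matches_brute_force_pearson(self, rng, tsize, rsize):
        template = rng.normal(size=(tsize, tsize))
        region = rng.normal(size=(rsize, rsize))
        np.testing.assert_allclose(
            ncc_map(template, region), brute_force_ncc(template, region), atol=1e-9
        )

    def test_exact_copy_scores_one_at_its_offset(self, rng):
        region = rng.normal(size=(30, 30))
        template = region[5:14, 8:17].copy()
        m = ncc_map(template, region)
        assert m.max() == pytest.approx(1.0, abs=1e-12)
        assert np.unravel_index(np.argmax(m), m.shape) == (5, 8)

    def test_negated_template_scores_minus_one(self, rng):
        region = rng.normal(size=(30, 30))
        patch = region[5:14, 8:17]
        template = 2 * patch.mean() - patch  # flipped about its mean
        m = ncc_map(template, region)
        assert m[5, 8] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ncc_map(np.ones((5, 5)), np.random.default_rng(0).normal(size=(9, 9)))

    def test_region_must_exceed_template(self, rng):
        with pytest.raises(ValueError, match="larger"):
            ncc_map(rng.normal(size=(9, 9)), rng.normal(size=(9, 12)))

    def test_invariant_to_affine_intensity_changes(self, rng):
        """Gain/offset on either window leave every coefficient unchanged."""
        template = rng.normal(size=(9, 9))
        region = rng.normal(size=(21, 21))
        base = ncc_map(template, region)
        for gain, offset in [(2.5, 10.0), (0.3, -7.0)]:
            np.testing.assert_allclose(
                ncc_map(gain * template + offset, region), base, atol=1e-9)
            np.testing.assert_allclose(
                ncc_map(template, gain * region + offset), base, atol=1e-9)

    @pytest.mark.parametrize("shift", [(0, 0), (3, 1), (1, 4), (5, 5)])
    def test_translation_equivariance_on_periodic_pattern(self, rng, shift):
        base = rng.normal(size=(40, 40))
        template = base[2:13, 2:13].copy()
        region = base[:25, :25]
        shifted = np.roll(np.roll(base, shift[0], axis=0), shift[1], axis=1)[:25, :25]
        p0 = np.unravel_index(np.argmax(ncc_map(template, region)), (15, 15))
        p1 = np.unravel_index(np.argmax(ncc_map(template, shifted)), (15, 15))
        assert p1[0] - p0[0] == shift[0]
        assert p1[1] - p0[1] == shift[1]


class TestLocatePeak:
    def test_integer_argmax_without_subpixel(self):
        m = np.zeros((7, 9))
        m[3, 5] = 1.0
        assert locate_peak(m, subpixel=False) == (5.0, 3.0, 1.0)

    def test_symmetric_parabola_needs_no_correction(self):
        m = np.array([[0.0, 0.0, 0.0], [0.5, 1.0, 0.5], [0.0, 0.0, 0.0]]).T
        dx, dy, peak = locate_peak(m, subpixel=True)
        assert (dx, dy, peak) == (1.0, 1.0, 1.0)

    def test_asymmetric_parabola_vertex_correction(self):
        """Samples (0.6, 1.0, 0.8) put the vertex 1/6 px toward the larger side."""
        line = np.array([0.6, 1.0, 0.8])
        m = np.zeros((3, 3))
        m[1, :] = line
        dx, dy, _ = locate_peak(m, subpixel=True)
        # closed-form vertex, cross-checked against dense evaluation of the
        # parabola fitted through the three samples
        xs = np.linspace(-1, 1, 200001)
        a, b, c = np.polyfit([-1, 0, 1], line, 2)
        dense_vertex = xs[np.argmax(a * xs * xs + b * xs + c)]
        assert dx - 1.0 == pytest.approx(1 / 6, abs=1e-9)
        assert dx - 1.0 == pytest.approx(dense_vertex, abs=1e-4)

    def test_flat_map_returns_tiebreak_origin(self):
        dx, dy, peak = locate_peak(np.full((5, 5), 0.25), subpixel=True)
        assert (dx, dy, peak) == (0.0, 0.0, 0.25)

    def test_ties_break_toward_smallest_row_col(self):
        m = np.zeros((5, 5))
        m[1, 3] = m[2, 1] = 0.9
        dx, dy, _ = locate_peak(m, subpixel=False)
        assert (dy, dx) == (1.0, 3.0)

    def test_subpixel_disk_localization_bias(self, short_geom):
        """Mean |error| over fractional shifts 0.1-0.9 px stays <= 0.25 px."""
        c = (short_geom.matrix_px - 1) / 2.0
        fracs = np.arange(0.1, 0.95, 0.1)
        n = len(fracs) + 1
        x = np.concatenate([[c], c + fracs])
        traj = GroundTruthTrajectory(
            times_s=np.arange(n) / 15.0, x_mm=np.zeros(n), y_mm=np.zeros(n),
            x_px=x, y_px=np.full(n, c), magnification=1.2,
        )
        stack = render_video(traj, short_geom, noise_sd=0.0, seed=0)
        cfg = TrackerConfig(template_update="never")
        out = track_sequence(stack, (c, c), 0, cfg)
        errors = np.abs(out.x_px[1:] - x[1:])
        assert errors.mean() <= 0.25


class TestTrackSequence:
    def test_static_noiseless_scene_stays_put(self, short_geom):
        n = short_geom.n_frames
        c = short_geom.matrix_px / 2.0  # pixel-centred target
        traj = GroundTruthTrajectory(
            times_s=np.arange(n) / 15.0, x_mm=np.zeros(n), y_mm=np.zeros(n),
            x_px=np.full(n, c), y_px=np.full(n, c), magnification=1.2,
        )
        stack = render_video(traj, short_geom, noise_sd=0.0, seed=0, texture_amp=0.0)
        out = track_sequence(stack, (c, c))
        np.testing.assert_allclose(out.x_px, c, atol=1e-9)
        np.testing.assert_allclose(out.y_px, c, atol=1e-9)
        np.testing.assert_allclose(out.ncc_score, 1.0, atol=1e-9)

    def test_integer_steps_recovered_exactly(self, short_geom):
        """Noiseless 2 px/frame vertical steps are recovered without error."""
        n = 30
        c = (short_geom.matrix_px - 1) / 2.0
        y = c - 30.0 + 2.0 * np.arange(n)
        traj = GroundTruthTrajectory(
            times_s=np.arange(n) / 15.0, x_mm=np.zeros(n), y_mm=np.zeros(n),
            x_px=np.full(n, c), y_px=y, magnification=1.2,
        )
        stack = render_video(traj, short_geom, noise_sd=0.0, seed=0, texture_amp=0.0)
        cfg = TrackerConfig(subpixel=False, template_update="never")
        out = track_sequence(stack, (c, y[0]), 0, cfg)
        np.testing.assert_array_equal(out.y_px, y)
        np.testing.assert_array_equal(out.x_px, np.full(n, c))

    def test_noisy_sinusoid_tracked_within_half_pixel(self, rendered_vertical):
        """Platform pattern at 2% contrast noise: every frame within 0.5 px."""
        stack, truth = rendered_vertical
        out = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))
        assert set(out.status) == {STATUS_TRACKED}
        err = np.hypot(out.x_px - truth.x_px, out.y_px - truth.y_px)
        assert err.max() < 0.5

    def test_invalid_seed_frame_rejected(self, rendered_vertical):
        stack, truth = rendered_vertical
        with pytest.raises(ValueError, match="seed_frame"):
            track_sequence(stack, (truth.x_px[0], truth.y_px[0]), seed_frame=500)

    def test_seed_near_border_rejected(self, rendered_vertical):
        stack, _ = rendered_vertical
        with pytest.raises(ValueError, match="border"):
            track_sequence(stack, (3.0, 3.0))


def _occluded_stack(short_geom, vertical_pattern, occluded):
    truth = project_and_sample(vertical_pattern, short_geom)
    stack = render_video(truth, short_geom, noise_sd=0.0, seed=0)
    frames = stack.frames.copy()
    for k in occluded:
        frames[k] = 30000  # flat frame: target invisible
    stack.frames = frames
    return stack, truth


class TestFailureAndReseed:
    def test_occlusion_flags_low_confidence_then_lost(self, short_geom, vertical_pattern):
        occluded = range(20, 40)
        stack, truth = _occluded_stack(short_geom, vertical_pattern, occluded)
        out = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))
        assert list(out.status[20:25]) == [STATUS_LOW_CONFIDENCE] * 5
        assert set(out.status[25:]) == {STATUS_LOST}
        assert np.all(np.isfinite(out.x_px[~out.lost_mask]))

    def test_reseed_past_occlusion_recovers_ground_truth(self, short_geom, vertical_pattern):
        occluded = range(20, 40)
        stack, truth = _occluded_stack(short_geom, vertical_pattern, occluded)
        out = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))
        fixed = reseed(out, stack, 42, (truth.x_px[42], truth.y_px[42]))
        assert fixed.status[42] == "reseeded"
        err = np.hypot(fixed.x_px[42:] - truth.x_px[42:], fixed.y_px[42:] - truth.y_px[42:])
        assert err.max() < 0.5
        # earlier frames untouched
        np.testing.assert_array_equal(fixed.status[:42], out.status[:42])

    def test_reseed_at_seed_frame_reproduces_clean_track(self, rendered_vertical):
        stack, truth = rendered_vertical
        out = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))
        again = reseed(out, stack, 0, (truth.x_px[0], truth.y_px[0]))
        np.testing.assert_allclose(again.x_px, out.x_px, atol=1e-9)
        np.testing.assert_allclose(again.y_px, out.y_px, atol=1e-9)
        assert again.status[0] == "reseeded"
        assert list(again.status[1:]) == list(out.status[1:])

    def test_reseed_at_final_frame_changes_nothing_downstream(self, rendered_vertical):
        stack, truth = rendered_vertical
        out = track_sequence(stack, (truth.x_px[0], truth.y_px[0]))
        last = len(out) - 1
        fixed = reseed(out, stack, last, (128.0, 128.0))
        np.testing.assert_array_equal(fixed.x_px[:last], out.x_px[:last])
        assert fixed.x_px[last] == 128.0
        assert fixed.status[last] == "reseeded"

    def test_reseed_near_border_rejected(self, rendered_vertical):
        stack, _ = rendered_vertical
        out = track_sequence(stack, (127.5, 127.5))
        with pytest.raises(ValueError, match="border"):
            reseed(out, stack, 10, (2.0, 2.0))
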