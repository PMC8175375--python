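"""Time-intensity curve extraction and bolus-kinetics metrics."""

import numpy as np
import pytest

from ceusquant import (
    CineLoop,
    Roi,
    TimeIntensityCurve,
    apply_threshold,
    auc,
    detect_arrival,
    extract_tic,
    motion_score,
    normalized_auc,
    peak_enhancement,
    segment_phases,
    summarize_tic,
)
from ceusquant.roi_geometry import rasterize
from ceusquant.synth_cine import CompartmentSpec, bolus_curve
from conftest import random_roi


def make_tic(intensities, fps=10.0, origin=0.0, label="", patient=""):
    y = np.asarray(intensities, dtype=float)
    return TimeIntensityCurve(
        times_s=origin + np.arange(len(y)) / fps,
        intensities=y,
        roi_label=label,
        patient_id=patient,
    )


class TestExtractTic:
    def test_constant_cine(self, full_frame_roi):
        cine = CineLoop(np.full((5, 16, 16), 100, dtype=np.uint8), frame_rate_hz=10)
        tic = extract_tic(cine, full_frame_roi)
        np.testing.assert_allclose(tic.intensities, 100 / 255)

    def test_symmetric_checkerboard_mean(self):
        frame = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        cine = CineLoop(frame[None], frame_rate_hz=10)
        roi = Roi("other:full", "rectangle", bounds=(0, 0, 2, 2))
        tic = extract_tic(cine, roi)
        assert tic.intensities[0] == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_pixel_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        frames = rng.integers(0, 256, size=(20, 16, 16), dtype=np.uint8)
        cine = CineLoop(frames, frame_rate_hz=10)
        roi = random_roi(rng, (16, 16))
        tic = extract_tic(cine, roi)
        mask = rasterize(roi, (16, 16)).mask
        for k in range(20):
            total = n = 0
            for r in range(16):
                for c in range(16):
                    if mask[r, c]:
                        total += int(frames[k, r, c])
                        n += 1
            assert tic.intensities[k] == pytest.approx(total / n / 255.0, abs=1e-12)

    def test_empty_mask_names_roi(self, small_cine):
        roi = Roi("artery", "circle", center=(100, 100), radius=2)
        with pytest.raises(ValueError, match="artery"):
            extract_tic(small_cine, roi)


class TestPeakEnhancement:
    def test_simple_peak(self):
        pe, t = peak_enhancement(make_tic([0.1, 0.5, 0.3]))
        assert (pe, t) == (0.5, 0.1)

    def test_constant_ties_to_earliest(self):
        pe, t = peak_enhancement(make_tic([0.4] * 8, origin=2.0))
        assert (pe, t) == (0.4, 2.0)

    def test_gamma_variate_peak_location(self):
        spec = CompartmentSpec(
            label="artery",
            geometry=Roi("artery", "circle", center=(5, 5), radius=2),
            baseline=0.05, amplitude=0.6, onset_s=10.0, time_to_peak_s=7.0,
            shape_alpha=3.0, tail_level=0.0,
        )
        times = np.arange(0, 45, 0.1)
        tic = TimeIntensityCurve(times, bolus_curve(spec, times))
        pe, t = peak_enhancement(tic)
        assert pe == pytest.approx(0.65, abs=1e-6)  # baseline + amplitude at tau=1
        assert abs(t - 17.0) <= 0.1  # within one frame period of onset + ttp


class TestAuc:
    def test_constant_rectangle(self):
        tic = make_tic([0.4] * 11, fps=1.0)  # duration 10 s
        assert auc(tic) == pytest.approx(0.4 * 10)

    def test_triangle_closed_form(self):
        up = np.linspace(0, 0.8, 21)
        tri = np.concatenate([up, up[-2::-1]])
        tic = make_tic(tri, fps=4.0)  # 41 samples, duration 10 s
        # trapezoid on a piecewise-linear curve is exact
        assert auc(tic) == pytest.approx(0.8 * 10 / 2)

    def test_linearity(self, rng):
        y = rng.uniform(0, 0.5, size=30)
        assert auc(make_tic(2 * y)) == pytest.approx(2 * auc(make_tic(y)))

    def test_split_additivity(self, rng):
        y = rng.uniform(0, 1, size=40)
        t = np.sort(rng.uniform(0, 20, size=40))
        t += np.arange(40) * 1e-9  # ensure strict increase
        tic = TimeIntensityCurve(t, y)
        for cut in (1, 13, 38):
            left = TimeIntensityCurve(t[: cut + 1], y[: cut + 1])
            right = TimeIntensityCurve(t[cut:], y[cut:])
            assert auc(left) + auc(right) == pytest.approx(auc(tic))

    def test_baseline_subtraction(self):
        tic = make_tic([0.2, 0.6, 0.2], fps=1.0)
        assert auc(tic, baseline_subtract=True, baseline=0.2) == pytest.approx(0.4)

    def test_too_short(self):
        with pytest.raises(ValueError, match=">= 2"):
            auc(make_tic([0.5]))


class TestNormalizedAuc:
    def test_self_ratio_is_one(self):
        artery = make_tic([0.1, 0.5, 0.4, 0.2])
        assert normalized_auc(artery, artery) == 1.0

    def test_scaled_tissue(self):
        artery = make_tic([0.2, 0.8, 0.6, 0.3])
        tissue = make_tic(0.5 * artery.intensities)
        assert normalized_auc(tissue, artery) == pytest.approx(0.5)

    def test_joint_rescale_invariant(self, rng):
        a = rng.uniform(0.1, 0.9, 25)
        b = rng.uniform(0.1, 0.9, 25)
        r1 = normalized_auc(make_tic(b), make_tic(a))
        r2 = normalized_auc(make_tic(0.3 * b), make_tic(0.3 * a))
        assert r1 == pytest.approx(r2)

    def test_zero_artery_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalized_auc(make_tic([0.1, 0.2]), make_tic([0.0, 0.0]))

    def test_mismatched_time_axes_rejected(self):
        with pytest.raises(ValueError, match="time axis"):
            normalized_auc(make_tic([0.1, 0.2, 0.3]), make_tic([0.1, 0.2, 0.3], fps=5))


class TestDetectArrival:
    def test_flat_with_tiny_noise_absent(self, rng):
        y = 0.2 + rng.normal(0, 0.002, size=60)
        arrival, baseline = detect_arrival(make_tic(np.clip(y, 0, 1)))
        assert arrival is None
        assert baseline == pytest.approx(0.2, abs=0.01)

    def test_noiseless_step(self):
        y = np.zeros(50)
        y[20:] = 0.5
        arrival, baseline = detect_arrival(make_tic(y))
        assert arrival == pytest.approx(2.0)  # frame 20 at 10 Hz
        assert baseline == 0.0

    def test_gamma_onset_recovered_within_3_frames(self):
        """SNR-20 bolus onsets are localized to within 3 frame periods."""
        spec = CompartmentSpec(
            label="artery",
            geometry=Roi("artery", "circle", center=(5, 5), radius=2),
            baseline=0.1, amplitude=0.6, onset_s=5.0, time_to_peak_s=2.0,
            shape_alpha=1.0, tail_level=0.0,
        )
        times = np.arange(0, 20, 0.1)
        clean = bolus_curve(spec, times)
        noise_sd = spec.amplitude / 20
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.clip(clean + rng.normal(0, noise_sd, clean.shape), 0, 1)
            # 5 s of pre-contrast recording -> a 50-frame baseline window
            arrival, _ = detect_arrival(TimeIntensityCurve(times, y),
                                        baseline_frames=50)
            if arrival is not None and -1e-9 <= arrival - spec.onset_s <= 0.3 + 1e-6:
                hits += 1
        assert hits == 100

    def test_window_validation(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_arrival(make_tic(np.zeros(8)), baseline_frames=10)


class TestSegmentPhases:
    def test_step_plateau_degenerate(self):
        y = np.zeros(30)
        y[10:] = 1.0
        tic = make_tic(y)
        arrival, baseline = detect_arrival(tic)
        seg = segment_phases(tic, arrival, baseline)
        assert seg.baseline_end == 10
        assert seg.washin_end == 10  # arrival frame is the peak frame
        assert seg.early_washout_end == seg.last_frame == 29  # late wash-out empty
        assert "late_wash_out" not in seg.labels()

    def test_triangle_half_max_crossing(self):
        up = np.linspace(0, 1, 21)
        y = np.concatenate([np.zeros(20), up, up[-2::-1]])
        tic = make_tic(y)
        seg = segment_phases(tic, arrival_time_s=2.1, baseline=0.0)
        assert seg.washin_end == 40  # apex
        # descent hits 0.5 at frame 50; early wash-out ends just before
        assert seg.early_washout_end in (49, 50)
        labels = seg.labels()
        assert labels.count("peak") == 1
        assert len(labels) == len(y)

    def test_boundaries_partition_and_order(self):
        y = np.concatenate([np.zeros(15), np.linspace(0, 0.9, 20),
                            np.linspace(0.9, 0.05, 30)])
        tic = make_tic(y)
        arrival, baseline = detect_arrival(tic)
        seg = segment_phases(tic, arrival, baseline)
        assert 0 <= seg.baseline_end <= seg.washin_end <= seg.early_washout_end <= seg.last_frame
        assert set(seg.labels()) == {"baseline", "wash_in", "peak",
                                     "early_wash_out", "late_wash_out"}

    def test_requires_arrival(self):
        with pytest.raises(ValueError, match="arrival"):
            segment_phases(make_tic([0.1, 0.2, 0.3]), None, 0.1)


class TestApplyThreshold:
    def test_upper_zero_all_white(self):
        frame = np.arange(16, dtype=np.uint8).reshape(4, 4)
        assert np.all(apply_threshold(frame, 0, 0) == 255)

    def test_boundary_only_existing_255(self):
        frame = np.arange(255, dtype=np.uint8).reshape(15, 17)
        out = apply_threshold(frame, 0, 255)
        assert not np.any(out == 255)
        # and a frame containing 255 keeps it
        assert apply_threshold(np.array([[255]], dtype=np.uint8), 0, 255) == 255

    def test_idempotent(self, rng):
        frame = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        once = apply_threshold(frame, 40, 200)
        np.testing.assert_array_equal(apply_threshold(once, 40, 200), once)

    def test_lower_maps_to_black_middle_unchanged(self):
        frame = np.array([[10, 100, 250]], dtype=np.uint8)
        out = apply_threshold(frame, 20, 200)
        assert list(out[0]) == [0, 100, 255]

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            apply_threshold(np.zeros((2, 2), dtype=np.uint8), 200, 100)


class TestMotionScore:
    def test_static_cine_zero(self):
        cine = CineLoop(np.full((6, 8, 8), 50, dtype=np.uint8), frame_rate_hz=10)
        np.testing.assert_array_equal(motion_score(cine), np.zeros(5))

    def test_shifted_frame_dominates(self, rng):
        frames = np.tile(rng.integers(0, 256, size=(16, 16), dtype=np.uint8), (8, 1, 1))
        frames[4] = np.roll(frames[4], 5, axis=1)
        scores = motion_score(CineLoop(frames, frame_rate_hz=10))
        assert scores[3] > 0 and scores[4] > 0
        assert min(scores[3], scores[4]) > max(np.delete(scores, [3, 4]))

    def test_reversal_symmetric(self, small_cine):
        fwd = motion_score(small_cine)
        rev = motion_score(CineLoop(small_cine.frames[::-1].copy(), frame_rate_hz=10))
        np.testing.assert_allclose(fwd, rev[::-1])

    def test_single_frame_rejected(self):
        cine = CineLoop(np.zeros((1, 4, 4), dtype=np.uint8), frame_rate_hz=10)
        with pytest.raises(ValueError, match="2 frames"):
            motion_score(cine)


class TestSummarizeTic:
    def test_full_summary_fields(self):
        y = np.concatenate([np.zeros(15), np.linspace(0, 0.8, 20),
                            np.linspace(0.8, 0.1, 25)])
        tic = make_tic(y, label="tumor", patient="P07")
        artery = make_tic(np.concatenate([np.zeros(15), np.linspace(0, 0.9, 20),
                                          np.linspace(0.9, 0.1, 25)]), label="artery")
        s = summarize_tic(tic, artery_tic=artery)
        assert s.roi_label == "tumor" and s.patient_id == "P07"
        assert s.peak_enhancement == pytest.approx(0.8)
        assert s.arrival_time_s is not None
        assert s.phases is not None
        assert 0 < s.normalized_auc < 1

    def test_degrades_without_baseline(self):
        """Clips started after the bolus still yield PE and AUC."""
        y = np.linspace(0.8, 0.1, 40)  # pure wash-out, no arrival
        s = summarize_tic(make_tic(y))
        assert s.arrival_time_s is None and s.phases is None
        assert s.peak_enhancement == pytest.approx(0.8)
        assert s.auc > 0
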