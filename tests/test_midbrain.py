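"""IC event detection, bilateral pairing, tonotopic scans, retinal waves."""

import numpy as np
import pandas as pd
import pytest

from prehear.midbrain import (
    ICEvent,
    detect_band_peaks,
    detect_ic_events,
    detect_retinal_waves,
    exclude_global_events,
    match_bilateral,
    spatial_event_histogram,
    tonotopic_linescan,
)
from prehear.movie import MovieStack
from prehear.rois import ROI, ROISet
from prehear.synth import lobe_rois

from conftest import make_dff


def two_lobe_dff(events, T=600, H=64, W=128, fr=10.0):
    """dF/F movie with spatially uniform per-lobe transients."""
    data = np.zeros((T, H, W))
    t = np.arange(T) / fr
    for time, lobe, amp, width in events:
        tri = np.clip(1 - np.abs(t - time) / (width / 2), 0, None)
        sl = np.s_[:, :, : W // 2] if lobe == "left" else np.s_[:, :, W // 2 :]
        data[sl] += (amp * tri)[:, None, None]
    return make_dff(data, frame_rate=fr)


class TestDetectICEvents:
    def test_fixed_threshold_separates_amplitudes(self):
        d = two_lobe_dff([(10.0, "left", 0.10, 4.0), (30.0, "left", 0.01, 4.0)])
        events = detect_ic_events(d, lobe_rois((64, 128)))
        assert len(events) == 1
        assert events[0].lobe == "left"
        assert events[0].amplitude == pytest.approx(10.0, rel=0.02)

    def test_triangular_half_width(self):
        # symmetric triangle of base 4 s -> FWHM 2 s
        d = two_lobe_dff([(30.0, "right", 0.10, 4.0)])
        (ev,) = detect_ic_events(d, lobe_rois((64, 128)))
        assert ev.half_width == pytest.approx(2.0, abs=0.15)

    def test_missing_lobe_roi(self):
        d = two_lobe_dff([(10.0, "left", 0.1, 4.0)])
        only_left = ROISet([ROI("left", "rect", {"x": 0, "y": 0, "w": 64, "h": 64}, "left")])
        with pytest.raises(ValueError):
            detect_ic_events(d, only_left)


class TestMatchBilateral:
    @staticmethod
    def ev(time, lobe, amp):
        return ICEvent(time=time, lobe=lobe, amplitude=amp, half_width=1.0)

    def test_ratio_and_dominance(self):
        pairs, un = match_bilateral([self.ev(5.0, "left", 10.0), self.ev(5.0, "right", 6.0)])
        assert len(pairs) == 1 and not un
        assert pairs[0].ratio == pytest.approx(0.6)
        assert pairs[0].dominant_lobe == "left"

    def test_equal_amplitudes_ratio_one(self):
        pairs, _ = match_bilateral([self.ev(5.0, "left", 8.0), self.ev(5.2, "right", 8.0)])
        assert pairs[0].ratio == 1.0

    def test_lone_event_unmatched(self):
        pairs, un = match_bilateral([self.ev(5.0, "left", 8.0), self.ev(9.0, "right", 8.0)])
        assert not pairs and len(un) == 2

    def test_each_event_used_once_greedy(self):
        events = [
            self.ev(5.0, "left", 10.0),
            self.ev(5.1, "right", 9.0),
            self.ev(5.4, "right", 4.0),
        ]
        pairs, un = match_bilateral(events)
        assert len(pairs) == 1
        assert pairs[0].weak_amp == 9.0
        assert un[0].amplitude == 4.0

    def test_symmetric_under_lobe_relabel(self):
        events = [self.ev(3.0, "left", 4.0), self.ev(3.1, "right", 7.0)]
        sw = [self.ev(3.0, "right", 4.0), self.ev(3.1, "left", 7.0)]
        p1, _ = match_bilateral(events)
        p2, _ = match_bilateral(sw)
        assert p1[0].ratio == p2[0].ratio
        assert p1[0].dominant_lobe != p2[0].dominant_lobe


class TestTonotopicScan:
    def test_uniform_frame_constant_profile(self):
        d = make_dff(np.full((20, 160, 160), 0.07))
        scan = tonotopic_linescan(d, (80.0, 80.0), 55.0)
        assert scan.values.shape == (125, 20)
        assert np.allclose(scan.values, 7.0, atol=1e-6)

    def test_gaussian_band_peak_position(self):
        # band at 500 um along a +55 degree axis from anchor (80, 80), 8 um/px
        H = W = 160
        rows, cols = np.mgrid[0:H, 0:W]
        th = np.deg2rad(55.0)
        s = (cols - 80) * np.cos(th) + (rows - 80) * np.sin(th)
        pos_um = (s + 62.0) * 8.0
        band = 0.10 * np.exp(-((pos_um - 500.0) ** 2) / (2 * 50.0**2))
        data = np.zeros((10, H, W))
        data[5] = band
        scan = tonotopic_linescan(make_dff(data, um_per_px=8.0), (80.0, 80.0), 55.0)
        peak_idx = scan.values[:, 5].argmax()
        assert abs(scan.positions_um[peak_idx] - 500.0) <= 8.0  # one sample

    def test_out_of_bounds_rectangle(self):
        d = make_dff(np.zeros((5, 64, 64)))
        with pytest.raises(ValueError):
            tonotopic_linescan(d, (10.0, 10.0), 55.0)


class TestBandPeaksAndHistogram:
    def test_uniform_scan_no_peaks(self):
        from prehear.midbrain import TonotopicScan

        scan = TonotopicScan(np.ones((125, 50)), np.arange(125) * 8.0, 10.0, (0, 0), 55.0)
        assert len(detect_band_peaks(scan)) == 0

    def test_two_bands_two_peaks(self):
        from prehear.midbrain import TonotopicScan

        vals = np.zeros((125, 60))
        pos = np.arange(125) * 8.0
        vals[:, 20] = 5.0 * np.exp(-((pos - 200.0) ** 2) / (2 * 40.0**2))
        vals[:, 45] = 6.0 * np.exp(-((pos - 600.0) ** 2) / (2 * 40.0**2))
        scan = TonotopicScan(vals, pos, 10.0, (0, 0), 55.0)
        peaks = detect_band_peaks(scan, 3.0)
        assert len(peaks) == 2
        assert sorted(np.round(peaks["position_um"], -1)) == [200.0, 600.0]

    def test_lateral_medial_split(self):
        peaks = pd.DataFrame({"position_um": [100.0] * 10, "time_s": range(10)})
        hist = spatial_event_histogram(peaks, split_um=500.0, duration_min=5.0)
        assert hist["lateral_count"] == 10 and hist["medial_count"] == 0
        assert hist["lateral_per_min"] == 2.0
        assert hist["counts"].sum() == 10

    def test_exclusion_zone(self):
        peaks = pd.DataFrame({"position_um": [100.0, 690.0, 700.0, 710.0, 900.0]})
        hist = spatial_event_histogram(
            peaks, split_um=500.0, duration_min=1.0,
            exclusion_center_um=700.0, exclusion_half_width_um=50.0,
        )
        assert hist["n_excluded"] == 3
        assert hist["counts"].sum() == 2

    def test_time_permutation_invariance(self, rng):
        pos = rng.uniform(0, 1000, 40)
        p1 = pd.DataFrame({"position_um": pos, "time_s": np.arange(40)})
        p2 = pd.DataFrame({"position_um": pos, "time_s": rng.permutation(40)})
        h1 = spatial_event_histogram(p1, 500.0, 5.0)
        h2 = spatial_event_histogram(p2, 500.0, 5.0)
        assert np.array_equal(h1["counts"], h2["counts"])


class TestExcludeGlobal:
    def test_whole_field_flash_excluded_band_retained(self):
        T, H, W = 100, 64, 128
        data = np.zeros((T, H, W))
        data[20] = 0.10  # global flash on both lobes
        data[60, :, 10:22] = 0.10  # confined band, ~19% of the left lobe
        d = make_dff(data)
        rois = lobe_rois((H, W))
        events = [
            ICEvent(time=2.0, lobe="left", amplitude=10.0, half_width=1.0),
            ICEvent(time=6.0, lobe="left", amplitude=10.0, half_width=1.0),
        ]
        kept = exclude_global_events(events, d, rois)
        assert [e.time for e in kept] == [6.0]

    def test_boundary_coverage_retained(self):
        # coverage exactly at the threshold is retained (strict >)
        T, H, W = 10, 10, 20
        data = np.zeros((T, H, W))
        data[5, :8, :10] = 0.10  # exactly 80% of the 10x10 left lobe
        d = make_dff(data, frame_rate=1.0)
        events = [ICEvent(time=5.0, lobe="left", amplitude=10.0, half_width=1.0)]
        kept = exclude_global_events(events, d, lobe_rois((H, W)), coverage_frac=0.8)
        assert len(kept) == 1


def sc_movie_from_active_blocks(block_spans, T=300, fr=10.0, H=160, W=210, nblocks=0):
    """Movie where given 5x5 downsampled blocks go high for given frame spans.

    block_spans: list of (frame_lo, frame_hi, [(bi, bj), ...]).
    """
    rng = np.random.default_rng(0)
    data = np.full((T, H, W), 1000.0) + rng.normal(0, 1.0, (T, H, W))
    for lo, hi, blocks in block_spans:
        for bi, bj in blocks:
            data[lo:hi, bi * 5 : bi * 5 + 5, bj * 5 : bj * 5 + 5] += 600.0
    return MovieStack(data, fr, 8.0)


SC_ROI = ROISet([ROI("left", "rect", {"x": 0, "y": 0, "w": 210, "h": 160}, "left")])


class TestRetinalWaves:
    def test_six_pixels_two_seconds_is_one_wave(self):
        blocks = [(100, 120, [(i, j) for i in (4, 5) for j in (6, 7, 8)])]
        mv = sc_movie_from_active_blocks(blocks)
        waves, summary = detect_retinal_waves(mv, SC_ROI)
        assert len(waves) == 1
        assert waves[0].duration == pytest.approx(2.0, abs=0.1)

    def test_exactly_five_pixels_rejected(self):
        blocks = [(100, 130, [(4, j) for j in range(6, 11)])]  # exactly 5
        mv = sc_movie_from_active_blocks(blocks)
        waves, _ = detect_retinal_waves(mv, SC_ROI)
        assert waves == []

    def test_subsecond_period_rejected(self):
        blocks = [(100, 108, [(i, j) for i in (4, 5) for j in range(6, 10)])]  # 0.8 s
        mv = sc_movie_from_active_blocks(blocks)
        waves, _ = detect_retinal_waves(mv, SC_ROI)
        assert waves == []

    def test_durations_bounded_by_movie(self):
        blocks = [
            (50, 80, [(i, j) for i in (2, 3) for j in (2, 3, 4)]),
            (150, 200, [(i, j) for i in (10, 11) for j in (20, 21, 22)]),
        ]
        # long quiet tail keeps each pixel's active duty cycle realistic
        mv = sc_movie_from_active_blocks(blocks, T=900)
        waves, summary = detect_retinal_waves(mv, SC_ROI)
        assert all(w.duration >= 1.0 for w in waves)
        assert sum(w.duration for w in waves) <= mv.duration
        assert summary["left"]["n_waves"] == len(waves) == 2

    def test_small_roi_rejected(self):
        mv = MovieStack(np.full((50, 100, 100), 10.0), 10.0, 8.0)
        roi = ROISet([ROI("left", "rect", {"x": 0, "y": 0, "w": 100, "h": 100}, "left")])
        with pytest.raises(ValueError):
            detect_retinal_waves(mv, roi)
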