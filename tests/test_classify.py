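"""Candidate profiling, upright-window detection and bout labelling."""

import numpy as np
import pytest

from sedpose import (
    AlgoConfig,
    AnnotationTrack,
    CandidateProfile,
    LengthError,
    Segment,
    SimulationScript,
    TriaxialRecording,
    WindowFeatureSeries,
    classify_recording,
    detect_upright_windows,
    extract_bouts,
    label_bouts,
    profile_candidate,
    simulate_recording,
)
from sedpose.agreement import frame_confusion, overall_accuracy
from tests.conftest import make_still_recording


def make_wfs(tilt_vt, tilt_ml=None, tilt_ap=None, std_sum=None, window_rate=10.0):
    """Crafted feature series where filtered == raw (for rule-level tests)."""
    vt = np.asarray(tilt_vt, dtype=float)
    n = vt.size
    ml = np.full(n, 90.0) if tilt_ml is None else np.asarray(tilt_ml, dtype=float)
    ap = np.full(n, 90.0) if tilt_ap is None else np.asarray(tilt_ap, dtype=float)
    ss = np.zeros(n) if std_sum is None else np.asarray(std_sum, dtype=float)
    return WindowFeatureSeries(
        window_start_frame=np.arange(n) * 10,
        std_ax=ss / 3, std_ay=ss / 3, std_az=ss / 3,
        std_sum=ss, std_sum_filtered=ss,
        tilt_vt=vt, tilt_ml=ml, tilt_ap=ap,
        tilt_vt_filtered=vt, tilt_ml_filtered=ml, tilt_ap_filtered=ap,
        window_rate=window_rate,
    )


class TestProfileCandidate:
    @pytest.mark.parametrize(
        "vt, ml, ap, expected",
        [
            (160.2, 95.0, 95.0, True),
            (145.0, 95.0, 95.0, False),   # VT profile fails
            (149.2, 90.0, 90.0, True),    # ceiling(149.2) = 150 passes
            (160.0, 89.0, 95.0, False),   # ML ceiling 89 < 90
            (160.0, 90.0, 88.9, False),   # AP ceiling 89 < 90
        ],
    )
    def test_ceiling_of_mean_against_thresholds(self, vt, ml, ap, expected, config):
        wfs = make_wfs(np.full(50, vt), np.full(50, ml), np.full(50, ap))
        assert profile_candidate(wfs, config).upright_likely is expected


class TestDetectUprightWindows:
    def test_fixed_branch_tilt_thresholds(self, config):
        profile = CandidateProfile(False, 120.0, 90.0, 60.0, 0.0)
        wfs = make_wfs(
            tilt_vt=[145.0, 139.9, 145.0],
            tilt_ap=[80.0, 80.0, 74.9],
        )
        flags = detect_upright_windows(wfs, profile, config)
        assert flags.tolist() == [True, False, False]

    def test_still_lying_never_upright(self, config):
        wfs = make_wfs(np.full(30, 90.0), tilt_ap=np.full(30, 20.0))
        for likely in (True, False):
            profile = CandidateProfile(likely, 90.0, 90.0, 20.0, 0.0)
            assert not detect_upright_windows(wfs, profile, config).any()

    def test_sd_branch_strict_vs_gated(self):
        """High-movement sitting windows: upright under strict, not under gated."""
        vt = np.r_[np.full(20, 180.0), np.full(5, 140.3), np.full(20, 180.0)]
        ap = np.r_[np.full(20, 90.0), np.full(5, 50.0), np.full(20, 90.0)]
        ss = np.r_[np.full(20, 0.2), np.full(5, 0.5), np.full(20, 0.2)]
        wfs = make_wfs(vt, tilt_ap=ap, std_sum=ss)
        profile = CandidateProfile(True, 175.0, 90.0, 89.5, float(ss.mean()))
        strict = detect_upright_windows(wfs, profile, AlgoConfig(mode="strict"))
        gated = detect_upright_windows(wfs, profile, AlgoConfig(mode="gated"))
        assert strict[20:25].all()
        assert not gated[20:25].any()
        np.testing.assert_array_equal(strict[:20], gated[:20])


class TestExtractBouts:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            (
                [1, 1, 1, 0, 0, 1, 1],
                [(0, 3, True), (3, 5, False), (5, 7, True)],
            ),
            ([0, 0, 0, 0], [(0, 4, False)]),
            ([1, 1, 1], [(0, 3, True)]),
        ],
    )
    def test_run_length_segments(self, flags, expected):
        assert extract_bouts(np.array(flags, dtype=bool)) == expected

    def test_empty_rejected(self):
        with pytest.raises(LengthError):
            extract_bouts(np.array([], dtype=bool))


class TestLabelBouts:
    def test_candidate_bout_fixed_thresholds(self, config):
        """Candidate bouts relabel by mean AP: <40 lying, <80 sitting."""
        ap = np.r_[np.full(10, 35.0), np.full(10, 90.0), np.full(10, 70.0)]
        wfs = make_wfs(np.full(30, 150.0), tilt_ap=ap)
        segments = [(0, 10, True), (10, 20, True), (20, 30, True)]
        seq = label_bouts(segments, wfs, config)
        assert [b.label for b in seq] == ["lying", "upright", "sitting"]

    def test_adaptive_lying_rule(self, config):
        """Non-upright AP 30 vs preceding upright 85: 30 < 85/2.5 -> lying."""
        ap = np.r_[np.full(10, 85.0), np.full(10, 30.0)]
        wfs = make_wfs(np.full(20, 160.0), tilt_ap=ap)
        seq = label_bouts([(0, 10, True), (10, 20, False)], wfs, config)
        assert [b.label for b in seq] == ["upright", "lying"]

    def test_adaptive_sitting_rule(self, config):
        """Non-upright AP 70 vs preceding upright 85: 34 <= 70 < 85 -> sitting."""
        ap = np.r_[np.full(10, 85.0), np.full(10, 70.0)]
        wfs = make_wfs(np.full(20, 160.0), tilt_ap=ap)
        seq = label_bouts([(0, 10, True), (10, 20, False)], wfs, config)
        assert [b.label for b in seq] == ["upright", "sitting"]

    def test_adaptive_upright_rule(self, config):
        ap = np.r_[np.full(10, 85.0), np.full(10, 88.0)]
        wfs = make_wfs(np.full(20, 160.0), tilt_ap=ap)
        seq = label_bouts([(0, 10, True), (10, 20, False)], wfs, config)
        assert len(seq) == 1 and seq.bouts[0].label == "upright"

    def test_leading_segment_uses_fixed_rule(self, config):
        ap = np.r_[np.full(10, 70.0), np.full(10, 90.0)]
        wfs = make_wfs(np.full(20, 150.0), tilt_ap=ap)
        seq = label_bouts([(0, 10, False), (10, 20, True)], wfs, config)
        assert [b.label for b in seq] == ["sitting", "upright"]

    def test_demoted_candidate_does_not_update_reference(self, config):
        """A candidate relabelled sitting must not become the 'preceding
        upright bout' for the adaptive rule."""
        ap = np.r_[np.full(10, 88.0), np.full(10, 70.0), np.full(10, 30.0)]
        wfs = make_wfs(np.full(30, 160.0), tilt_ap=ap)
        segments = [(0, 10, True), (10, 20, True), (20, 30, False)]
        seq = label_bouts(segments, wfs, config)
        # 30 < 88/2.5 = 35.2 -> lying (not compared against the demoted 70)
        assert [b.label for b in seq] == ["upright", "sitting", "lying"]


class TestClassifyRecording:
    def test_still_sitting_recording_single_bout(self, config):
        """A ~70 deg AP still orientation with no upright bout anywhere is one
        sitting bout via the fixed fallback rule."""
        v = np.array([-0.94, 0.05, 0.33])
        v = v / np.linalg.norm(v)
        rec = make_still_recording(v, duration_s=60.0)
        seq = classify_recording(rec, config)
        assert len(seq) == 1
        assert seq.bouts[0].label == "sitting"
        assert seq.n_windows == 600

    def test_empty_recording_rejected(self, config):
        with pytest.raises(LengthError):
            classify_recording(
                TriaxialRecording([0.0], [1.0], [0.0], [0.0]), config
            )

    def test_bouts_tile_recording(self, config):
        script = SimulationScript(
            segments=[
                Segment("sitting", 40),
                Segment("walking", 20),
                Segment("lying", 40),
                Segment("walking", 20),
            ]
        )
        rec, _ = simulate_recording(script, seed=5)
        seq = classify_recording(rec, config)
        assert seq.bouts[0].start_frame == 0
        for a, b in zip(seq.bouts, seq.bouts[1:]):
            assert a.end_frame == b.start_frame
            assert a.label != b.label
        assert seq.n_windows * 10 <= len(rec)

    def test_deterministic(self, config):
        script = SimulationScript(
            segments=[Segment("sitting", 30), Segment("walking", 30)]
        )
        rec, _ = simulate_recording(script, seed=11)
        a = classify_recording(rec, config).as_tuples()
        b = classify_recording(rec, config).as_tuples()
        assert a == b

    def test_label_distribution_invariant_to_unit_scaling(self, config):
        script = SimulationScript(
            segments=[
                Segment("sitting", 30),
                Segment("walking", 20),
                Segment("standing", 30),
            ],
            timestamp_jitter_sd=0.0,
        )
        rec, _ = simulate_recording(script, seed=2)
        scaled = TriaxialRecording(
            rec.timestamps, rec.ax * 9.81, rec.ay * 9.81, rec.az * 9.81
        )
        assert (
            classify_recording(rec, config).as_tuples()
            == classify_recording(scaled, config).as_tuples()
        )

    def test_raising_lying_threshold_only_converts_sitting_to_lying(self):
        """Monotone threshold response on a grid of AP orientations."""
        import math

        for ap_deg in (25.0, 38.0, 45.0, 55.0, 70.0):
            v = np.array(
                [-math.cos(math.radians(ap_deg) / 2), 0.0, math.cos(math.radians(ap_deg))]
            )
            v[0] = -math.sqrt(max(1 - v[2] ** 2, 0.0))
            rec = make_still_recording(v, duration_s=30.0)
            lo = classify_recording(rec, AlgoConfig(ap_lying_fixed_deg=40.0))
            hi = classify_recording(rec, AlgoConfig(ap_lying_fixed_deg=60.0))
            for b_lo, b_hi in zip(lo, hi):
                if b_lo.label == "lying":
                    assert b_hi.label == "lying"
                if b_hi.label == "sitting":
                    assert b_lo.label == "sitting"

    def test_min_bout_duration_absorbs_short_bouts(self):
        script = SimulationScript(
            segments=[
                Segment("walking", 30),
                Segment("sitting", 2),
                Segment("walking", 30),
            ],
            timestamp_jitter_sd=0.0,
        )
        rec, _ = simulate_recording(script, seed=9)
        cfg = AlgoConfig(min_bout_s=5.0)
        seq = classify_recording(rec, cfg)
        assert all(b.n_windows >= 50 for b in seq) or len(seq) == 1
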