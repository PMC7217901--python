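"""Fixation detection and anticipatory-fixation matching."""

import math

import pytest

from letterflow.gaze import (
    AnticipatoryWindow,
    Fixation,
    build_windows,
    detect_fixations,
    find_anticipatory,
    min_fixation_frames,
    summarize_anticipatory,
)
from letterflow.session import BoardEvent, GazeFrame, PointEvent, Response
from letterflow.transcript import align_words


def frames(spec):
    """spec: list of (code, n_frames) -> contiguous GazeFrame stream."""
    out, t = [], 0
    for code, n in spec:
        for _ in range(n):
            out.append(GazeFrame(t, code))
            t += 1
    return out


class TestDetectFixations:
    def test_three_frames_at_30fps_is_a_fixation(self):
        fx = detect_fixations(frames([("K", 3)]), 30.0)
        assert len(fx) == 1
        assert fx[0].duration_ms == 100.0  # 100 ms >= 99 ms criterion

    def test_two_frames_is_below_criterion(self):
        assert detect_fixations(frames([("K", 2)]), 30.0) == []

    def test_single_interrupting_frame_splits_fixation(self):
        fx = detect_fixations(
            frames([("A", 10), ("BETWEEN_ITEMS", 1), ("A", 5)]), 30.0
        )
        assert [f.item for f in fx] == ["A", "A"]
        assert len(fx) == 2

    def test_not_visible_terminates_run(self):
        fx = detect_fixations(frames([("A", 2), ("NOT_VISIBLE", 1), ("A", 2)]), 30.0)
        assert fx == []

    def test_between_items_can_be_a_fixation_target(self):
        fx = detect_fixations(frames([("BETWEEN_ITEMS", 5)]), 30.0)
        assert len(fx) == 1 and fx[0].item == "BETWEEN_ITEMS"

    def test_merge_tolerance_bridges_single_frame_gap(self):
        stream = frames([("A", 10), ("BETWEEN_ITEMS", 1), ("A", 5)])
        fx = detect_fixations(stream, 30.0, merge_tolerance_frames=1)
        assert len(fx) == 1 and fx[0].duration_ms > 500

    def test_min_duration_threshold_in_frames(self):
        assert min_fixation_frames(99.0, 30.0) == 3
        assert min_fixation_frames(99.0, 29.97) == 3
        assert min_fixation_frames(200.0, 30.0) == 6

    @pytest.mark.parametrize("threshold", [33, 99, 200, 500])
    def test_raising_threshold_never_adds_fixations(self, threshold):
        stream = frames(
            [("A", 4), ("BETWEEN_ITEMS", 2), ("B", 7), ("K", 2), ("C", 15)]
        )
        low = detect_fixations(stream, 30.0, min_duration_ms=33)
        high = detect_fixations(stream, 30.0, min_duration_ms=threshold)
        assert len(high) <= len(low)

    def test_fixations_never_overlap(self):
        stream = frames([("A", 5), ("B", 4), ("A", 3), ("NOT_VISIBLE", 2), ("C", 6)])
        fx = detect_fixations(stream, 30.0)
        for f1, f2 in zip(fx, fx[1:]):
            assert f1.end_frame < f2.start_frame


def response_with_gaze(points, transcript, gaze, placed=0):
    end = max(points[-1].end_frame, gaze[-1].frame_index) + 5
    return Response(
        "Q1", "semi_open", 0, int(end), list(transcript),
        point_events=points,
        board_events=[BoardEvent("PLACED", placed)],
        gaze_frames=gaze,
    )


class TestWindows:
    def test_first_letter_window_opens_at_board_placement(self):
        pts = [PointEvent("S", 50, 55), PointEvent("U", 90, 95)]
        resp = response_with_gaze(pts, ["SU"], frames([("BETWEEN_ITEMS", 100)]), placed=10)
        recs = align_words(pts, ["SU"])
        windows = build_windows(resp, recs)
        assert windows[0].window_start_frame == 10.0
        assert windows[0].window_end_frame == 50.0
        assert windows[1].window_start_frame == 55.0  # end of point to S

    def test_windows_only_for_correct_letters(self):
        pts = [PointEvent("S", 50, 55), PointEvent("X", 90, 95), PointEvent("U", 120, 125)]
        resp = response_with_gaze(pts, ["SU"], frames([("BETWEEN_ITEMS", 130)]))
        recs = align_words(pts, ["SU"])
        windows = build_windows(resp, recs)
        assert [w.target_item for w in windows] == ["S", "U"]

    def test_window_reopens_after_reset(self):
        pts = [PointEvent("A", 20, 25), PointEvent("B", 120, 125)]
        resp = response_with_gaze(pts, ["A", "B"], frames([("BETWEEN_ITEMS", 130)]))
        resp.board_events.extend(
            [BoardEvent("RESET", 60), BoardEvent("PLACED", 80)]
        )
        recs = align_words(pts, ["A", "B"], resp.board_events)
        windows = build_windows(resp, recs)
        assert windows[1].window_start_frame == 80.0


class TestFindAnticipatory:
    def test_published_worked_example_lead_and_latency(self):
        # end of previous point at frame 0; fixation onset 374 ms later;
        # contact 510 ms after onset (fps chosen so the timings are integral)
        fps = 500.0
        w = AnticipatoryWindow("I", 1, 0, 374 * fps / 1000 + 510 * fps / 1000)
        fx = [Fixation("I", 374 * fps / 1000, 374 * fps / 1000 + 300, 600.0)]
        recs = find_anticipatory([w], fx, fps)
        assert recs[0].fixated
        assert recs[0].latency_ms == pytest.approx(374.0)
        assert recs[0].lead_ms == pytest.approx(510.0)

    def test_no_target_fixation(self):
        w = AnticipatoryWindow("S", 0, 0, 100)
        fx = [Fixation("R", 10, 20, 366.7)]
        recs = find_anticipatory([w], fx, 30.0)
        assert not recs[0].fixated
        assert recs[0].lead_ms is None and recs[0].rank is None

    def test_rank_counts_distinct_items(self):
        # fixation order r, v, r, s for target s -> rank 3 (type counting)
        w = AnticipatoryWindow("S", 0, 0, 200)
        fx = [
            Fixation("R", 10, 15, 200),
            Fixation("V", 30, 35, 200),
            Fixation("R", 50, 55, 200),
            Fixation("S", 80, 90, 366),
        ]
        recs = find_anticipatory([w], fx, 30.0)
        assert recs[0].rank == 3
        assert recs[0].n_fixations_in_window == 4
        assert recs[0].window_letters == ("R", "V", "R", "S")
        token = find_anticipatory([w], fx, 30.0, rank_counting="token")
        assert token[0].rank == 4

    def test_straddling_fixation_admitted_with_nonpositive_latency(self):
        # fixation begins during the previous point and persists past its end
        w = AnticipatoryWindow("U", 1, 100, 200)
        fx = [Fixation("U", 80, 150, 2000)]
        recs = find_anticipatory([w], fx, 30.0)
        assert recs[0].fixated
        assert recs[0].latency_ms < 0

    def test_fixation_ending_at_window_open_not_admitted(self):
        w = AnticipatoryWindow("U", 1, 100, 200)
        fx = [Fixation("U", 80, 100, 700)]
        recs = find_anticipatory([w], fx, 30.0)
        assert not recs[0].fixated

    def test_lead_plus_latency_equals_window_span(self):
        # when contact coincides with point onset, latency + lead = IPI
        fps = 30.0
        w = AnticipatoryWindow("I", 1, 0, 27)
        fx = [Fixation("I", 11, 27, 500)]
        rec = find_anticipatory([w], fx, fps)[0]
        assert rec.latency_ms + rec.lead_ms == pytest.approx(27 / fps * 1000)


class TestSummaries:
    def test_all_fixated_with_fixed_lead(self):
        recs = find_anticipatory(
            [AnticipatoryWindow("A", i, i * 100, i * 100 + 15) for i in range(4)],
            [Fixation("A", i * 100, i * 100 + 20, 500) for i in range(4)],
            30.0,
        )
        s = summarize_anticipatory(recs)
        assert s["pct_fixated"] == 100.0
        assert s["median_lead_ms"] == pytest.approx(500.0)

    def test_none_fixated(self):
        recs = find_anticipatory(
            [AnticipatoryWindow("A", 0, 0, 50)], [], 30.0
        )
        s = summarize_anticipatory(recs)
        assert s["pct_fixated"] == 0.0
        assert math.isnan(s["median_lead_ms"])
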