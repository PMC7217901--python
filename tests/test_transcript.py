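"""Word/letter accuracy rules and coder reliability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from letterflow.session import BoardEvent, GazeFrame, PointEvent
from letterflow.transcript import (
    align_words,
    cohens_kappa,
    letter_records,
    pct_gaze_on_board,
    score_letter_accuracy,
    score_word_accuracy,
)
from letterflow.synth import SynthParams, generate_session
from letterflow.report import analyze_session

from conftest import make_response


def points_for(letters, start=20, ipi=30, dur=6):
    pts, t = [], start
    for sym in letters:
        pts.append(PointEvent(sym, t, t + dur - 1))
        t += dur - 1 + ipi
    return pts


class TestWordAccuracyRules:
    def test_exact_spelling_is_correct(self):
        recs = align_words(points_for("SUNFLOWER"), ["SUNFLOWER"])
        assert len(recs) == 1
        assert recs[0].correct and recs[0].reason == "exact"

    def test_extra_leading_letter_is_correct(self):
        # an abandoned start ("c" then "explored") does not count as a misspelling
        recs = align_words(points_for("CEXPLORED"), ["EXPLORED"])
        assert recs[0].correct
        assert recs[0].reason == "extra_leading_or_trailing"
        assert len(recs[0].leading_extras) == 1

    def test_extra_trailing_letter_is_correct(self):
        recs = align_words(points_for("SUNFLOWERT"), ["SUNFLOWER"])
        assert recs[0].correct
        assert recs[0].reason == "extra_leading_or_trailing"

    def test_missing_final_letter_is_incorrect(self):
        recs = align_words(points_for("SUNFLOWE"), ["SUNFLOWER"])
        assert not recs[0].correct
        assert recs[0].reason == "missing_boundary_letter"

    def test_internal_substitution_is_incorrect(self):
        recs = align_words(points_for("SUMFLOWER"), ["SUNFLOWER"])
        assert not recs[0].correct

    def test_too_many_internal_letters_is_incorrect(self):
        recs = align_words(points_for("SUMNFLOWER"), ["SUNFLOWER"])
        assert not recs[0].correct
        assert recs[0].reason == "wrong_internal_count"

    def test_reset_interrupted_word_is_incorrect(self):
        pts = points_for("SUN")
        reset = BoardEvent("RESET", pts[-1].end_frame + 5)
        recs = align_words(pts, ["SUNFLOWER"], [BoardEvent("PLACED", 0), reset])
        assert not recs[0].correct
        assert recs[0].reason == "interrupted_by_reset"

    def test_empty_point_stream_marks_all_words_incorrect(self):
        recs = align_words([], ["THAT", "IS"])
        assert all(r.reason == "missing_boundary_letter" for r in recs)
        assert score_word_accuracy(recs) == 0.0

    def test_multi_word_alignment(self):
        recs = align_words(points_for("THATISHARD"), ["THAT", "IS", "HARD"])
        assert [r.target_word for r in recs] == ["THAT", "IS", "HARD"]
        assert all(r.correct for r in recs)
        assert score_word_accuracy(recs) == 100.0


class TestLetterAccuracy:
    def test_exact_word_scores_100(self):
        pts = points_for("SUNFLOWER")
        recs = align_words(pts, ["SUNFLOWER"])
        assert score_letter_accuracy(recs, pts) == 100.0

    def test_intruded_letter_scores_9_of_10(self):
        pts = points_for("SUMNFLOWER")
        recs = align_words(pts, ["SUNFLOWER"])
        assert score_letter_accuracy(recs, pts) == 90.0

    def test_every_letter_point_scored_once(self):
        pts = points_for("CEXPLORED")
        recs = align_words(pts, ["EXPLORED"])
        lrecs = letter_records(recs, pts)
        assert sorted(r.point_index for r in lrecs) == list(range(9))

    def test_non_letter_points_excluded(self):
        pts = points_for("SUNFLOWER") + [PointEvent("DONE", 500, 505)]
        recs = align_words(pts, ["SUNFLOWER"])
        assert len(letter_records(recs, pts)) == 9

    def test_empty_after_filtering_raises(self):
        pts = [PointEvent("DONE", 0, 5)]
        recs = align_words(pts, ["SUNFLOWER"])
        with pytest.raises(ValueError):
            score_letter_accuracy(recs, pts)


class TestSyntheticAccuracyRecovery:
    def test_zero_misspelling_rate_gives_perfect_accuracy(self):
        params = SynthParams(
            regime="agency", seed=21, misspelling_rate=0.0, reset_rate=0.0,
            n_responses=10,
        )
        session, _ = generate_session(params)
        a = analyze_session(session)
        assert a.summary["word_accuracy"] == 100.0
        assert a.summary["letter_accuracy"] == 100.0

    def test_misspelling_rate_recovered_within_binomial_error(self):
        # ~500 words at implant rate 0.15: observed error rate within 3 SE
        rate, n_target = 0.15, 500
        params = SynthParams(
            regime="agency", seed=22, misspelling_rate=rate, reset_rate=0.0,
            n_responses=190, done_prob=0.0,
        )
        session, truth = generate_session(params)
        a = analyze_session(session)
        n = a.summary["words_total"]
        assert n >= n_target
        observed_err = (100.0 - a.summary["word_accuracy"]) / 100.0
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed_err - rate) < 3 * se

    def test_accuracy_invariant_to_question_id_relabeling(self):
        r1 = make_response(list("SUNFLOWER"), ["SUNFLOWER"], qid="Q1")
        r2 = make_response(list("SUNFLOWER"), ["SUNFLOWER"], qid="ZZZ")
        rec1 = align_words(r1.point_events, r1.target_transcript, r1.board_events)
        rec2 = align_words(r2.point_events, r2.target_transcript, r2.board_events)
        assert score_word_accuracy(rec1) == score_word_accuracy(rec2)


class TestGazeOnBoard:
    def test_all_item_frames(self):
        frames = [GazeFrame(i, "K") for i in range(100)]
        out = pct_gaze_on_board(frames, [(0, 99)])
        assert out["on_board"] == 100.0 and out["on_assistant"] == 0.0

    def test_90_10_split(self):
        frames = [GazeFrame(i, "K") for i in range(90)]
        frames += [GazeFrame(90 + i, "ASSISTANT") for i in range(10)]
        out = pct_gaze_on_board(frames, [(0, 99)])
        assert out["on_board"] == 90.0 and out["on_assistant"] == 10.0

    def test_not_visible_excluded_from_denominator(self):
        frames = [GazeFrame(i, "K") for i in range(80)]
        frames += [GazeFrame(80 + i, "NOT_VISIBLE") for i in range(20)]
        out = pct_gaze_on_board(frames, [(0, 99)])
        assert out["on_board"] == 100.0
        assert out["pct_not_visible"] == 20.0

    def test_no_visible_frames_flagged(self):
        frames = [GazeFrame(i, "NOT_VISIBLE") for i in range(10)]
        out = pct_gaze_on_board(frames, [(0, 9)])
        assert math.isnan(out["on_board"]) and out["n_visible_frames"] == 0


class TestCohensKappa:
    def test_identical_streams_with_two_codes(self):
        a = ["A", "B"] * 50
        res = cohens_kappa(a, list(a))
        assert res.percent_agreement == 100.0
        assert res.kappa == pytest.approx(1.0)

    def test_complete_disagreement_balanced_marginals(self):
        a = ["A", "B"] * 50
        b = ["B", "A"] * 50
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(-1.0)

    def test_degenerate_constant_streams(self):
        res = cohens_kappa(["A"] * 10, ["A"] * 10)
        assert res.degenerate and res.percent_agreement == 100.0
        assert math.isnan(res.kappa)

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(99)
        n = 10_000
        a = rng.integers(0, 4, n).tolist()
        b = rng.integers(0, 4, n).tolist()
        res = cohens_kappa(a, b)
        # under independence kappa ~ 0 with SE ~ 1/sqrt(n(1-p_e))
        se = 1 / math.sqrt(n * 0.75)
        assert abs(res.kappa) < 3 * se

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        a = rng.integers(0, 3, 500).tolist()
        b = [x if rng.random() < 0.7 else int(rng.integers(0, 3)) for x in a]
        res = cohens_kappa(a, b)
        assert res.kappa == pytest.approx(cohen_kappa_score(a, b), abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")),
            min_size=2, max_size=60,
        )
    )
    def test_symmetry_and_label_permutation(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        r1, r2 = cohens_kappa(a, b), cohens_kappa(b, a)
        assert r1.percent_agreement == r2.percent_agreement
        if not r1.degenerate:
            assert r1.kappa == pytest.approx(r2.kappa)
        perm = {"A": "C", "B": "A", "C": "B"}
        r3 = cohens_kappa([perm[x] for x in a], [perm[x] for x in b])
        if not r1.degenerate:
            assert r1.kappa == pytest.approx(r3.kappa)
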