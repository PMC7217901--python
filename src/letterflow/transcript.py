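"""Word and letter accuracy, gaze-on-board time, and coder reliability.

Accuracy rules
--------------
A word is *correct* when it was spelled with the exact letters required in
the correct order, or when it carries extra leading/trailing letters but is
otherwise exact (an extra letter at the edge can be the abandoned start of
a different word rather than a misspelling).  A word is *incorrect* when
the letter sequence between its first and last letters is wrong (too few,
too many, or substituted letters), when its first or last letter is
missing, or when it was interrupted by the assistant resetting the board.

Letter accuracy counts each pointed letter as correct or not *in the
context of the word ultimately spelled*: letters of an aligned word that
match the target (by longest-common-subsequence alignment) are correct;
intruded, extra, and substituted letters are not.  Points to DONE, DELETE
and punctuation are excluded from letter-accuracy denominators.

Word segmentation is anchored on the coder-supplied target transcript
(there is no spacebar on the board, so words are not separable from the
point stream alone); alignment is greedy left-to-right, anchored on each
target word's first and last letters, with ambiguous extra letters
attached leftward.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field

from .layout import LETTERS
from .session import BoardEvent, PointEvent, Response, is_letter

#: letters of slack allowed when searching for a word's boundary anchors
ANCHOR_SLACK = 3

REASONS = (
    "exact",
    "extra_leading_or_trailing",
    "wrong_internal_count",
    "missing_boundary_letter",
    "interrupted_by_reset",
)
CORRECT_REASONS = ("exact", "extra_leading_or_trailing")


@dataclass
class WordRecord:
    target_word: str
    word_index: int
    pointed_letters: list[str]          # core segment assigned to this word
    point_indices: list[int]            # indices into response.point_events
    letter_correct: list[bool]          # per core letter, in-context
    leading_extras: list[int] = field(default_factory=list)
    trailing_extras: list[int] = field(default_factory=list)
    accuracy: str = "incorrect"
    reason: str = "missing_boundary_letter"

    def __post_init__(self):
        self.accuracy = "correct" if self.reason in CORRECT_REASONS else "incorrect"

    @property
    def correct(self) -> bool:
        return self.accuracy == "correct"


@dataclass(frozen=True)
class LetterAccuracyRecord:
    point_index: int
    symbol: str
    is_correct_in_context: bool
    word_index: int


@dataclass(frozen=True)
class ReliabilityResult:
    percent_agreement: float
    kappa: float
    degenerate: bool = False


def _normalize_word(word: str) -> str:
    return "".join(ch for ch in word.upper() if ch in LETTERS)


def _letter_correct_flags(core: list[str], target: str) -> list[bool]:
    """Per-letter in-context correctness via LCS alignment to the target."""
    flags = [False] * len(core)
    sm = difflib.SequenceMatcher(None, "".join(core), target, autojunk=False)
    for block in sm.get_matching_blocks():
        for k in range(block.size):
            flags[block.a + k] = True
    return flags


def align_words(
    point_events: list[PointEvent],
    target_transcript: list[str],
    board_events: list[BoardEvent] = (),
) -> list[WordRecord]:
    """Assign letter points to target words and apply the accuracy rules.

    Every letter point is assigned to exactly one word (as a core letter or
    a leading/trailing extra); DONE, DELETE and punctuation points are left
    unassigned.  With an empty point stream, every word is incorrect with
    reason ``missing_boundary_letter``.
    """
    if not target_transcript:
        raise ValueError("target transcript is empty")
    letter_pts = [(i, pe) for i, pe in enumerate(point_events) if is_letter(pe.item)]
    resets = sorted(float(b.frame_index) for b in board_events if b.kind == "RESET")

    def reset_between(k1: int, k2: int) -> bool:
        """True if a board reset falls between letter points k1 and k2."""
        lo = float(letter_pts[k1][1].end_frame)
        hi = float(letter_pts[k2][1].start_frame)
        return any(lo < r < hi for r in resets)

    def reset_limit(start: int) -> int:
        """Largest index reachable from *start* without crossing a reset."""
        k = start
        while k + 1 < len(letter_pts) and not reset_between(k, k + 1):
            k += 1
        return k

    def reset_follows_segment(first: int, last: int) -> bool:
        """A board reset fell after the segment began and before the next
        letter point (or, for a trailing segment, anywhere after it)."""
        lo = float(letter_pts[first][1].start_frame)
        hi = (
            float(letter_pts[last + 1][1].start_frame)
            if last + 1 < len(letter_pts)
            else math.inf
        )
        return any(lo < r < hi for r in resets)

    records: list[WordRecord] = []
    cursor = 0
    n = len(letter_pts)

    for widx, raw_word in enumerate(target_transcript):
        word = _normalize_word(raw_word)
        if not word:
            continue
        if cursor >= n:
            records.append(
                WordRecord(raw_word, widx, [], [], [], reason="missing_boundary_letter")
            )
            continue

        # anchor on the first letter, allowing a few leading extras
        first, last = word[0], word[-1]
        hi = min(cursor + len(word) + ANCHOR_SLACK, n)
        start = next(
            (j for j in range(cursor, hi) if letter_pts[j][1].item == first), None
        )
        truncated_by_reset = False

        if start is None:
            # first letter never pointed: best-effort segment, incorrect
            limit = reset_limit(cursor)
            end = min(cursor + len(word) - 1, limit, n - 1)
            seg = list(range(cursor, end + 1))
            leading: list[int] = []
            reason = (
                "interrupted_by_reset"
                if end < cursor + len(word) - 1 and reset_follows_segment(cursor, end)
                else "missing_boundary_letter"
            )
        else:
            leading = list(range(cursor, start))
            limit = reset_limit(start)
            expected_end = start + len(word) - 1
            candidates = [
                j
                for j in range(start, min(expected_end + ANCHOR_SLACK, limit, n - 1) + 1)
                if letter_pts[j][1].item == last and (j > start or len(word) == 1)
            ]
            if candidates:
                end = min(candidates, key=lambda j: (abs(j - expected_end), j))
                seg = list(range(start, end + 1))
                core = [letter_pts[j][1].item for j in seg]
                if list(core) == list(word):
                    reason = "exact"
                elif any(
                    lo < r < float(letter_pts[end][1].end_frame)
                    for r in resets
                    for lo in [float(letter_pts[start][1].start_frame)]
                ):
                    reason = "interrupted_by_reset"
                else:
                    reason = "wrong_internal_count"
            else:
                end = min(expected_end, limit, n - 1)
                seg = list(range(start, end + 1))
                reason = (
                    "interrupted_by_reset"
                    if end < expected_end and reset_follows_segment(start, end)
                    else "missing_boundary_letter"
                )

        core_letters = [letter_pts[j][1].item for j in seg]
        flags = _letter_correct_flags(core_letters, word)
        if reason == "exact" and leading:
            reason = "extra_leading_or_trailing"
        records.append(
            WordRecord(
                raw_word,
                widx,
                core_letters,
                [letter_pts[j][0] for j in seg],
                flags,
                leading_extras=[letter_pts[j][0] for j in leading],
                reason=reason,
            )
        )
        cursor = (seg[-1] + 1) if seg else cursor

    # end-of-response leftovers attach leftward as trailing extras
    if records and cursor < n:
        rec = records[-1]
        rec.trailing_extras = [letter_pts[j][0] for j in range(cursor, n)]
        if rec.reason == "exact":
            rec.reason = "extra_leading_or_trailing"
        rec.accuracy = "correct" if rec.reason in CORRECT_REASONS else "incorrect"
    return records


def letter_records(records: list[WordRecord], point_events: list[PointEvent]) -> list[LetterAccuracyRecord]:
    """Flatten word records into per-point letter accuracy records."""
    out = []
    for rec in records:
        for idx in rec.leading_extras:
            out.append(LetterAccuracyRecord(idx, point_events[idx].item, False, rec.word_index))
        for idx, sym, ok in zip(rec.point_indices, rec.pointed_letters, rec.letter_correct):
            out.append(LetterAccuracyRecord(idx, sym, ok, rec.word_index))
        for idx in rec.trailing_extras:
            out.append(LetterAccuracyRecord(idx, point_events[idx].item, False, rec.word_index))
    out.sort(key=lambda r: r.point_index)
    return out


def score_word_accuracy(records: list[WordRecord]) -> float:
    """Percentage of words spelled correctly."""
    if not records:
        raise ValueError("no word records")
    return 100.0 * sum(r.correct for r in records) / len(records)


def score_letter_accuracy(
    records: list[WordRecord], point_events: list[PointEvent]
) -> float:
    """Percentage of pointed letters correct in the context of the words spelled."""
    lrecs = letter_records(records, point_events)
    if not lrecs:
        raise ValueError("no scored letter points")
    return 100.0 * sum(r.is_correct_in_context for r in lrecs) / len(lrecs)


def spelling_interval(response: Response) -> tuple[float, float]:
    """Frame interval during which the response was being spelled.

    Opens at the first board placement (or the first point if no placement
    was coded) and closes at the last point's end.
    """
    placed = [b.frame_index for b in response.board_events if b.kind == "PLACED"]
    if response.point_events:
        start = min(placed) if placed else response.point_events[0].start_frame
        end = response.point_events[-1].end_frame
    else:
        start, end = response.start_frame, response.end_frame
    return float(start), float(end)


def pct_gaze_on_board(gaze_frames, spelling_intervals) -> dict:
    """Gaze-location percentages over visible frames while spelling.

    ``on_board`` covers item and between-item codes; ``on_assistant`` and
    ``other`` complete the visible-frame breakdown (the three sum to 100).
    ``pct_not_visible`` is reported separately over all in-interval frames.
    """
    from .layout import ASSISTANT, NOT_VISIBLE, OTHER

    in_interval = [
        g
        for g in gaze_frames
        if any(lo <= g.frame_index <= hi for lo, hi in spelling_intervals)
    ]
    visible = [g for g in in_interval if g.location != NOT_VISIBLE]
    if not visible:
        return {
            "on_board": math.nan, "on_assistant": math.nan, "other": math.nan,
            "pct_not_visible": 100.0 if in_interval else math.nan,
            "n_visible_frames": 0,
        }
    n = len(visible)
    on_assistant = sum(1 for g in visible if g.location == ASSISTANT)
    other = sum(1 for g in visible if g.location == OTHER)
    return {
        "on_board": 100.0 * (n - on_assistant - other) / n,
        "on_assistant": 100.0 * on_assistant / n,
        "other": 100.0 * other / n,
        "pct_not_visible": 100.0 * (len(in_interval) - n) / len(in_interval),
        "n_visible_frames": n,
    }


def cohens_kappa(stream_a, stream_b) -> ReliabilityResult:
    """Percent agreement and Cohen's kappa between two coders' streams.

    kappa = (p_o - p_e) / (1 - p_e) with chance agreement p_e from the
    product of the coders' marginal code frequencies.  When both coders use
    a single identical code throughout, kappa is undefined (returned as NaN
    with ``degenerate=True``) while agreement is 100%.
    """
    a, b = list(stream_a), list(stream_b)
    if len(a) != len(b) or not a:
        raise ValueError("streams must be equal-length and non-empty")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    cats = sorted(set(a) | set(b), key=str)
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if p_e == 1.0:
        return ReliabilityResult(100.0 * p_o, math.nan, degenerate=True)
    kappa = (p_o - p_e) / (1 - p_e)
    return ReliabilityResult(100.0 * p_o, kappa)
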