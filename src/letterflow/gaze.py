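"""Fixation detection and anticipatory-fixation analysis.

A *fixation* is a maximal run of consecutive frames on the same item code
lasting at least 99 ms (3 frames at 30 fps).  Any differing frame — a
different item, a between-items frame, or a blink/not-visible frame —
terminates the run; no gap merging is done by default (a configurable
merge tolerance, default 0 frames, is exposed).

An *anticipatory window* for a correct letter point opens when the point
to the previous item ends (or when the board was placed, for the first
letter) and closes at finger contact with the target.  A fixation of the
target that began before or during the previous point and persisted past
its end is admitted (its latency is then <= 0).  *Lead* is fixation onset
to contact; *latency* is window open to fixation onset; *search rank* is
the ordinal position of the target among the distinct letters fixated in
its window (type counting; token counting available via flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

from .layout import BETWEEN_ITEMS
from .session import Response, frames_to_ms, is_letter
from .transcript import WordRecord, letter_records


@dataclass(frozen=True)
class Fixation:
    item: str                  # item symbol or BETWEEN_ITEMS
    start_frame: float
    end_frame: float
    duration_ms: float


@dataclass(frozen=True)
class AnticipatoryWindow:
    target_item: str
    target_point_index: int
    window_start_frame: float   # previous point's end, or board placement
    window_end_frame: float     # contact with the target

    def __post_init__(self):
        if self.window_start_frame > self.window_end_frame:
            raise ValueError("window start after window end")


@dataclass(frozen=True)
class AnticipatoryFixationRecord:
    target_item: str
    target_point_index: int
    fixated: bool
    lead_ms: float | None = None       # fixation onset -> contact
    latency_ms: float | None = None    # window open -> fixation onset (<= 0 allowed)
    rank: int | None = None
    n_fixations_in_window: int = 0
    window_letters: tuple[str, ...] = ()   # letter fixation tokens, onset order
    response_id: str | None = None


def min_fixation_frames(min_duration_ms: float, fps: float) -> int:
    """Smallest frame count satisfying the duration criterion."""
    return max(1, math.ceil(min_duration_ms * fps / 1000 - 1e-9))


def detect_fixations(
    gaze_frames,
    fps: float,
    min_duration_ms: float = 99.0,
    merge_tolerance_frames: int = 0,
) -> list[Fixation]:
    """Maximal same-code runs meeting the duration criterion.

    Only item codes and BETWEEN_ITEMS yield fixations; assistant / other /
    not-visible frames only serve to terminate runs.  A gap in frame
    indices also terminates a run.
    """
    runs: list[tuple[str, int, int]] = []  # (code, start, end) inclusive
    for g in gaze_frames:
        if runs and runs[-1][0] == g.location and g.frame_index == runs[-1][2] + 1:
            code, s, _ = runs[-1]
            runs[-1] = (code, s, g.frame_index)
        else:
            runs.append((g.location, g.frame_index, g.frame_index))

    if merge_tolerance_frames > 0:
        merged: list[tuple[str, int, int]] = []
        for code, s, e in runs:
            if (
                len(merged) >= 2
                and merged[-2][0] == code
                and s - merged[-2][2] - 1 <= merge_tolerance_frames
            ):
                # bridge a short interposed run (blink / between-items flick)
                _, s0, _ = merged[-2]
                merged.pop()
                merged.pop()
                merged.append((code, s0, e))
            elif merged and merged[-1][0] == code and s - merged[-1][2] - 1 <= merge_tolerance_frames:
                merged[-1] = (code, merged[-1][1], e)
            else:
                merged.append((code, s, e))
        runs = merged

    min_frames = min_fixation_frames(min_duration_ms, fps)
    out = []
    for code, s, e in runs:
        if not (is_letter(code) or code == BETWEEN_ITEMS or _is_item(code)):
            continue
        n = e - s + 1
        if n >= min_frames:
            out.append(Fixation(code, s, e, frames_to_ms(n, fps)))
    return out


def _is_item(code: str) -> bool:
    from .layout import NON_ITEM_LOCATIONS

    return code not in NON_ITEM_LOCATIONS


def build_windows(
    response: Response,
    word_records: list[WordRecord] | None = None,
    correct_only: bool = True,
) -> list[AnticipatoryWindow]:
    """One anticipatory window per (correct) letter point.

    The window anchor is the later of the previous point's end and the
    latest board placement/reset before contact.  A missing placement
    before the first point falls back to the response start.
    """
    correct_idx: set[int] | None = None
    if correct_only:
        if word_records is None:
            raise ValueError("word_records required when correct_only=True")
        correct_idx = {
            r.point_index
            for r in letter_records(word_records, response.point_events)
            if r.is_correct_in_context
        }

    board_marks = sorted(
        float(b.frame_index)
        for b in response.board_events
        if b.kind in ("PLACED", "RESET")
    )
    windows = []
    prev_end: float | None = None
    for idx, pe in enumerate(response.point_events):
        contact = float(pe.start_frame)
        marks = [m for m in board_marks if m <= contact]
        anchors = [m for m in (prev_end, max(marks) if marks else None) if m is not None]
        anchor = max(anchors) if anchors else float(response.start_frame)
        if is_letter(pe.item) and (correct_idx is None or idx in correct_idx):
            windows.append(AnticipatoryWindow(pe.item, idx, anchor, contact))
        prev_end = float(pe.end_frame)
    return windows


def find_anticipatory(
    windows: list[AnticipatoryWindow],
    fixations: list[Fixation],
    fps: float,
    rank_counting: str = "type",
    response_id: str | None = None,
) -> list[AnticipatoryFixationRecord]:
    """Match fixations to anticipatory windows.

    A fixation belongs to a window when it overlaps the open interval
    (window start, contact): it began before contact and was still ongoing
    after the window opened (straddling fixations admitted).  The target
    is *fixated* when at least one of its fixations belongs to the window;
    lead and latency come from the first such fixation.
    """
    if rank_counting not in ("type", "token"):
        raise ValueError("rank_counting must be 'type' or 'token'")
    out = []
    for w in windows:
        in_window = [
            f
            for f in fixations
            if float(f.start_frame) < w.window_end_frame
            and float(f.end_frame) > w.window_start_frame
        ]
        in_window.sort(key=lambda f: float(f.start_frame))
        letter_fixes = [f for f in in_window if is_letter(f.item)]
        target_fix = next((f for f in letter_fixes if f.item == w.target_item), None)
        if target_fix is None:
            out.append(
                AnticipatoryFixationRecord(
                    w.target_item,
                    w.target_point_index,
                    fixated=False,
                    n_fixations_in_window=len(letter_fixes),
                    window_letters=tuple(f.item for f in letter_fixes),
                    response_id=response_id,
                )
            )
            continue
        onset = target_fix.start_frame
        if rank_counting == "type":
            seen: list[str] = []
            for f in letter_fixes:
                if f.item not in seen:
                    seen.append(f.item)
            rank = seen.index(w.target_item) + 1
        else:
            rank = next(
                i for i, f in enumerate(letter_fixes, start=1) if f.item == w.target_item
            )
        out.append(
            AnticipatoryFixationRecord(
                w.target_item,
                w.target_point_index,
                fixated=True,
                lead_ms=frames_to_ms(w.window_end_frame - onset, fps),
                latency_ms=frames_to_ms(onset - w.window_start_frame, fps),
                rank=rank,
                n_fixations_in_window=len(letter_fixes),
                window_letters=tuple(f.item for f in letter_fixes),
                response_id=response_id,
            )
        )
    return out


def summarize_anticipatory(records: list[AnticipatoryFixationRecord]) -> dict:
    """Percentages over correct letter points; medians over fixated ones."""
    if not records:
        raise ValueError("no anticipatory records")
    n = len(records)
    fixed = [r for r in records if r.fixated]
    out = {
        "pct_fixated": 100.0 * len(fixed) / n,
        "n_points": n,
        "n_fixated": len(fixed),
    }
    if fixed:
        out["median_lead_ms"] = median(r.lead_ms for r in fixed)
        out["median_latency_ms"] = median(r.latency_ms for r in fixed)
        out["pct_rank_le_2"] = 100.0 * sum(r.rank <= 2 for r in fixed) / len(fixed)
    else:
        out["median_lead_ms"] = math.nan
        out["median_latency_ms"] = math.nan
        out["pct_rank_le_2"] = math.nan
    return out
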