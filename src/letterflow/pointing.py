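"""Inter-point intervals, word-boundary classification, longest correct runs.

The inter-point interval (IPI) is the time between the end of a point to
one item and when the finger made contact with the next item — i.e. from
``end_frame`` of point *n-1* to ``start_frame`` of point *n*.  Pairs
spanning a board reset are excluded (a reset is a structural break, and
reset-interrupted words are coded incorrect anyway).  Point duration
(contact-interval length) is retained on the record but is not part of
the IPI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import mean, median

from .session import Response, frames_to_ms, is_letter
from .transcript import WordRecord, align_words, letter_records


@dataclass(frozen=True)
class IPIRecord:
    prev_item: str
    next_item: str
    ipi_ms: float
    prev_point_index: int
    next_point_index: int
    boundary: str | None = None        # "within_word" | "between_word"
    both_correct: bool = False
    same_word: bool = False
    distance_cm: float | None = None
    bigram_log_freq: float | None = None
    participant_id: str | None = None
    response_id: str | None = None

    def __post_init__(self):
        if self.ipi_ms <= 0:
            raise ValueError(f"IPI must be positive, got {self.ipi_ms}")


@dataclass(frozen=True)
class CorrectRun:
    letters: tuple[str, ...]
    length: int
    response_id: str | None = None
    start_point_index: int = 0


def compute_ipis(response: Response, fps: float) -> list[IPIRecord]:
    """One record per consecutive pair of point events, resets excluded."""
    pts = response.point_events
    if len(pts) < 2:
        raise ValueError("need at least two point events for an IPI")
    resets = [
        float(b.frame_index) for b in response.board_events if b.kind == "RESET"
    ]
    out = []
    for k in range(1, len(pts)):
        prev, nxt = pts[k - 1], pts[k]
        if nxt.start_frame <= prev.end_frame:
            raise ValueError(
                f"overlapping point events at index {k} (frames {prev.end_frame} / {nxt.start_frame})"
            )
        if any(float(prev.end_frame) < r < float(nxt.start_frame) for r in resets):
            continue
        out.append(
            IPIRecord(
                prev_item=prev.item,
                next_item=nxt.item,
                ipi_ms=frames_to_ms(nxt.start_frame - prev.end_frame, fps),
                prev_point_index=k - 1,
                next_point_index=k,
                response_id=response.question_id,
            )
        )
    return out


def classify_boundary(
    ipis: list[IPIRecord],
    word_records: list[WordRecord],
    response: Response,
) -> list[IPIRecord]:
    """Label letter-pair IPIs as within-word vs between-word.

    ``between_word`` means the next item begins a new aligned word of a
    multi-word response; single-word responses contribute only
    ``within_word`` records.  Pairs involving non-letter items keep
    ``boundary=None``.  ``both_correct`` requires both letters correct in
    context; ``same_word`` marks pairs inside one aligned word.
    """
    lrecs = {
        r.point_index: r for r in letter_records(word_records, response.point_events)
    }
    word_of = {}
    first_core_of_word = {}
    for rec in word_records:
        for idx in rec.leading_extras + rec.point_indices + rec.trailing_extras:
            word_of[idx] = rec.word_index
        if rec.point_indices:
            first_core_of_word[rec.word_index] = rec.point_indices[0]
    multi_word = len(word_records) > 1

    out = []
    for r in ipis:
        if not (is_letter(r.prev_item) and is_letter(r.next_item)):
            out.append(r)
            continue
        prev_l, next_l = lrecs.get(r.prev_point_index), lrecs.get(r.next_point_index)
        both_correct = bool(
            prev_l and next_l and prev_l.is_correct_in_context and next_l.is_correct_in_context
        )
        wp, wn = word_of.get(r.prev_point_index), word_of.get(r.next_point_index)
        same_word = wp is not None and wp == wn
        between = (
            multi_word
            and wn is not None
            and wn != wp
            and first_core_of_word.get(wn) == r.next_point_index
        )
        out.append(
            replace(
                r,
                boundary="between_word" if between else "within_word",
                both_correct=both_correct,
                same_word=same_word,
            )
        )
    return out


def longest_correct_run(
    response: Response, word_records: list[WordRecord]
) -> CorrectRun:
    """Longest uninterrupted run of consecutive correct letter points.

    A run is broken by an incorrect letter or any non-letter point; ties
    are broken by earliest start.
    """
    lrecs = {
        r.point_index: r for r in letter_records(word_records, response.point_events)
    }
    best: CorrectRun = CorrectRun((), 0, response.question_id)
    current: list[tuple[int, str]] = []
    for idx, pe in enumerate(response.point_events):
        rec = lrecs.get(idx)
        if rec is not None and rec.is_correct_in_context:
            current.append((idx, pe.item))
        else:
            current = []
        if len(current) > best.length:
            best = CorrectRun(
                tuple(s for _, s in current),
                len(current),
                response.question_id,
                current[0][0],
            )
    return best


def summarize_ipis(records: list[IPIRecord], word_records=None, run=None) -> dict:
    """Median/mean/n per stratum.

    Strata: ``within_correct_words`` (letter pairs inside one correctly
    spelled word, both letters correct), ``longest_run`` (pairs inside the
    supplied longest correct run), ``within_word`` / ``between_word``
    (consecutive correct-letter pairs by boundary type).  Empty strata are
    omitted.
    """
    strata: dict[str, list[float]] = {}

    def add(name, values):
        if values:
            strata[name] = values

    correct_words = set()
    if word_records:
        correct_words = {r.word_index for r in word_records if r.correct}
    word_of = {}
    if word_records:
        for rec in word_records:
            for idx in rec.point_indices:
                word_of[idx] = rec.word_index

    add(
        "within_correct_words",
        [
            r.ipi_ms
            for r in records
            if r.same_word
            and r.both_correct
            and word_of.get(r.next_point_index) in correct_words
        ],
    )
    if run is not None and run.length >= 2:
        run_indices = set(range(run.start_point_index, run.start_point_index + run.length))
        add(
            "longest_run",
            [
                r.ipi_ms
                for r in records
                if r.prev_point_index in run_indices and r.next_point_index in run_indices
            ],
        )
    add(
        "within_word",
        [r.ipi_ms for r in records if r.boundary == "within_word" and r.both_correct],
    )
    add(
        "between_word",
        [r.ipi_ms for r in records if r.boundary == "between_word" and r.both_correct],
    )

    return {
        name: {"median_ms": median(v), "mean_ms": mean(v), "n": len(v)}
        for name, v in strata.items()
    }


def response_ipi_records(response: Response, fps: float) -> tuple[list[IPIRecord], list[WordRecord]]:
    """Convenience: align words then compute classified IPIs for a response."""
    word_recs = align_words(
        response.point_events, response.target_transcript, response.board_events
    )
    ipis = classify_boundary(compute_ipis(response, fps), word_recs, response)
    return ipis, word_recs
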