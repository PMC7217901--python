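"""Data model and tidy-CSV I/O for frame-coded letterboard sessions.

A session is a ~30 fps frame-by-frame coding of one participant's
recording.  Two parallel streams exist: a *point* stream (intervals during
which the finger was in contact with a board item, marked by the board
bowing) and a *gaze* stream (per-frame location of the gaze cursor: an
item, between items, on the assistant, elsewhere, or not visible).  Board
events mark when the assistant placed, reset, or removed the board.
Responses partition the session into answers to individual questions and
carry the coder-supplied target transcript.

Frames are 0-based.  Contact intervals are inclusive of both endpoints,
matching frame-accurate human coding.  Frame fields are integers in the
CSV dialect but may be exact rationals or floats when events are built
programmatically with sub-frame timing.

CSV dialect (UTF-8, comma-separated, header row), one directory per
session:

* ``session.json`` — ``{"participant_id": ..., "fps": 30.0}``
* ``gaze.csv`` — ``frame,location`` (one row per coded frame)
* ``points.csv`` — ``item,start_frame,end_frame`` (one row per contact)
* ``board.csv`` — ``kind,frame`` (PLACED / RESET / REMOVED)
* ``responses.csv`` — ``question_id,question_type,start_frame,end_frame,``
  ``target_transcript`` (words pipe-separated)
* ``layout.json`` — optional; the default board is used when absent.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real

from .layout import (
    NON_ITEM_LOCATIONS,
    LetterboardLayout,
    LETTERS,
    default_layout,
)

QUESTION_TYPES = ("spelling", "comprehension", "semi_open", "open_ended")
BOARD_EVENT_KINDS = ("PLACED", "RESET", "REMOVED")


class SchemaError(ValueError):
    """Malformed session data; carries file, row and field context."""

    def __init__(self, message, file=None, row=None, fieldname=None):
        ctx = []
        if file is not None:
            ctx.append(f"file={file}")
        if row is not None:
            ctx.append(f"row={row}")
        if fieldname is not None:
            ctx.append(f"field={fieldname}")
        suffix = f" ({', '.join(ctx)})" if ctx else ""
        super().__init__(message + suffix)
        self.file, self.row, self.fieldname = file, row, fieldname


def frames_to_ms(n_frames, fps) -> float:
    """Convert a frame count to milliseconds: ``n / fps * 1000``.

    Exact rational arithmetic is used when both arguments are exactly
    representable (ints or Fractions), so e.g. 3 frames at 30 fps is
    exactly 100.0 ms.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    def _exact(x):
        if isinstance(x, (int, Fraction)):
            return Fraction(x)
        if isinstance(x, float) and x.is_integer():
            return Fraction(int(x))
        return None

    nf, fr = _exact(n_frames), _exact(fps)
    if nf is not None and fr is not None:
        return float(nf * 1000 / fr)
    return float(n_frames) / float(fps) * 1000.0


@dataclass(frozen=True)
class GazeFrame:
    frame_index: int
    location: str  # item symbol or one of the NON_ITEM_LOCATIONS codes


@dataclass(frozen=True)
class PointEvent:
    """Inclusive contact interval of the finger with a board item."""

    item: str
    start_frame: Real
    end_frame: Real

    def __post_init__(self):
        if self.start_frame > self.end_frame:
            raise ValueError(
                f"PointEvent on {self.item!r}: start {self.start_frame} > end {self.end_frame}"
            )

    def duration_frames(self):
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class BoardEvent:
    kind: str
    frame_index: Real

    def __post_init__(self):
        if self.kind not in BOARD_EVENT_KINDS:
            raise ValueError(f"unknown board event kind {self.kind!r}")


@dataclass
class Response:
    question_id: str
    question_type: str
    start_frame: int
    end_frame: int
    target_transcript: list[str]
    point_events: list[PointEvent] = field(default_factory=list)
    board_events: list[BoardEvent] = field(default_factory=list)
    gaze_frames: list[GazeFrame] = field(default_factory=list)

    def __post_init__(self):
        if self.question_type not in QUESTION_TYPES:
            raise ValueError(f"unknown question type {self.question_type!r}")


@dataclass
class Session:
    participant_id: str
    layout: LetterboardLayout
    fps: float = 30.0
    responses: list[Response] = field(default_factory=list)

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def ms(self, n_frames) -> float:
        return frames_to_ms(n_frames, self.fps)

    def validate(self) -> None:
        """Check stream invariants across all responses."""
        valid_locations = set(self.layout.symbols) | set(NON_ITEM_LOCATIONS)
        for resp in self.responses:
            prev_frame = None
            for gf in resp.gaze_frames:
                if gf.location not in valid_locations:
                    raise SchemaError(
                        f"unknown gaze location {gf.location!r}", fieldname="location"
                    )
                if prev_frame is not None and gf.frame_index <= prev_frame:
                    raise SchemaError(
                        f"gaze frame index {gf.frame_index} not strictly increasing"
                    )
                prev_frame = gf.frame_index
            prev_end = None
            for pe in resp.point_events:
                if pe.item not in self.layout:
                    raise SchemaError(f"point item {pe.item!r} not on board")
                if prev_end is not None and pe.start_frame <= prev_end:
                    raise SchemaError(
                        f"point events overlap at frame {pe.start_frame}"
                    )
                prev_end = pe.end_frame


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

def _read_rows(path, required):
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise SchemaError(f"missing column {col!r}", file=os.path.basename(path))
        for i, row in enumerate(reader, start=2):  # header is line 1
            yield i, row


def _int_field(row, key, path, rowno):
    try:
        return int(row[key])
    except (TypeError, ValueError):
        raise SchemaError(
            f"expected integer, got {row.get(key)!r}",
            file=os.path.basename(path), row=rowno, fieldname=key,
        ) from None


def read_session(session_dir, layout_path=None) -> Session:
    """Read a session directory in the tidy CSV dialect.

    Malformed rows raise :class:`SchemaError` naming file, row and field;
    nothing is silently dropped.
    """
    meta_path = os.path.join(session_dir, "session.json")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    if layout_path is None:
        candidate = os.path.join(session_dir, "layout.json")
        layout = (
            LetterboardLayout.read_json(candidate)
            if os.path.exists(candidate)
            else default_layout()
        )
    else:
        layout = LetterboardLayout.read_json(layout_path)

    valid_locations = set(layout.symbols) | set(NON_ITEM_LOCATIONS)

    gaze_path = os.path.join(session_dir, "gaze.csv")
    gaze = []
    prev = None
    for rowno, row in _read_rows(gaze_path, ("frame", "location")):
        frame = _int_field(row, "frame", gaze_path, rowno)
        loc = row["location"]
        if loc not in valid_locations:
            raise SchemaError(
                f"unknown location code {loc!r}",
                file="gaze.csv", row=rowno, fieldname="location",
            )
        if prev is not None and frame <= prev:
            raise SchemaError(
                f"frame index {frame} not strictly increasing",
                file="gaze.csv", row=rowno, fieldname="frame",
            )
        prev = frame
        gaze.append(GazeFrame(frame, loc))

    points_path = os.path.join(session_dir, "points.csv")
    points = []
    for rowno, row in _read_rows(points_path, ("item", "start_frame", "end_frame")):
        item = row["item"]
        if item not in layout:
            raise SchemaError(
                f"unknown item {item!r}",
                file="points.csv", row=rowno, fieldname="item",
            )
        start = _int_field(row, "start_frame", points_path, rowno)
        end = _int_field(row, "end_frame", points_path, rowno)
        if start > end:
            raise SchemaError(
                "start_frame > end_frame",
                file="points.csv", row=rowno, fieldname="start_frame",
            )
        if points and start <= points[-1].end_frame:
            raise SchemaError(
                "point events overlap",
                file="points.csv", row=rowno, fieldname="start_frame",
            )
        points.append(PointEvent(item, start, end))

    board_path = os.path.join(session_dir, "board.csv")
    board = []
    for rowno, row in _read_rows(board_path, ("kind", "frame")):
        kind = row["kind"]
        if kind not in BOARD_EVENT_KINDS:
            raise SchemaError(
                f"unknown board event kind {kind!r}",
                file="board.csv", row=rowno, fieldname="kind",
            )
        board.append(BoardEvent(kind, _int_field(row, "frame", board_path, rowno)))

    responses_path = os.path.join(session_dir, "responses.csv")
    responses = []
    req = ("question_id", "question_type", "start_frame", "end_frame", "target_transcript")
    for rowno, row in _read_rows(responses_path, req):
        qtype = row["question_type"]
        if qtype not in QUESTION_TYPES:
            raise SchemaError(
                f"unknown question type {qtype!r}",
                file="responses.csv", row=rowno, fieldname="question_type",
            )
        start = _int_field(row, "start_frame", responses_path, rowno)
        end = _int_field(row, "end_frame", responses_path, rowno)
        words = [w for w in row["target_transcript"].split("|") if w]
        responses.append(
            Response(
                question_id=row["question_id"],
                question_type=qtype,
                start_frame=start,
                end_frame=end,
                target_transcript=words,
            )
        )

    # assign stream slices to responses by frame containment
    for resp in responses:
        resp.gaze_frames = [g for g in gaze if resp.start_frame <= g.frame_index <= resp.end_frame]
        resp.point_events = [
            p for p in points if resp.start_frame <= p.start_frame and p.end_frame <= resp.end_frame
        ]
        resp.board_events = [
            b for b in board if resp.start_frame <= b.frame_index <= resp.end_frame
        ]

    session = Session(
        participant_id=str(meta["participant_id"]),
        layout=layout,
        fps=float(meta.get("fps", 30.0)),
        responses=responses,
    )
    session.validate()
    return session


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------

def write_session(session: Session, session_dir, write_layout: bool = True) -> None:
    """Write *session* to *session_dir* in the tidy CSV dialect.

    Round-trips: ``write_session(read_session(d))`` reproduces canonical
    input files byte-identically.
    """
    os.makedirs(session_dir, exist_ok=True)
    with open(os.path.join(session_dir, "session.json"), "w", encoding="utf-8") as fh:
        json.dump({"participant_id": session.participant_id, "fps": session.fps}, fh)
        fh.write("\n")
    if write_layout:
        session.layout.write_json(os.path.join(session_dir, "layout.json"))

    def _writer(name, header):
        fh = open(os.path.join(session_dir, name), "w", encoding="utf-8", newline="")
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        return fh, w

    fh, w = _writer("gaze.csv", ["frame", "location"])
    with fh:
        for resp in session.responses:
            for g in resp.gaze_frames:
                w.writerow([g.frame_index, g.location])

    fh, w = _writer("points.csv", ["item", "start_frame", "end_frame"])
    with fh:
        for resp in session.responses:
            for p in resp.point_events:
                w.writerow([p.item, p.start_frame, p.end_frame])

    fh, w = _writer("board.csv", ["kind", "frame"])
    with fh:
        for resp in session.responses:
            for b in resp.board_events:
                w.writerow([b.kind, b.frame_index])

    fh, w = _writer(
        "responses.csv",
        ["question_id", "question_type", "start_frame", "end_frame", "target_transcript"],
    )
    with fh:
        for resp in session.responses:
            w.writerow(
                [
                    resp.question_id,
                    resp.question_type,
                    resp.start_frame,
                    resp.end_frame,
                    "|".join(resp.target_transcript),
                ]
            )


def is_letter(symbol: str) -> bool:
    return symbol in LETTERS
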