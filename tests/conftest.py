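import pytest

from letterflow.layout import default_layout
from letterflow.session import BoardEvent, GazeFrame, PointEvent, Response, Session


@pytest.fixture(scope="session")
def layout():
    return default_layout()


def make_response(
    letters,
    transcript,
    qid="Q1",
    start=0,
    ipi_frames=30,
    dur_frames=6,
    placed_at=0,
    board_extra=(),
):
    """Response whose points spell *letters* with uniform IPIs, plus gaze filler."""
    points = []
    t = placed_at + 20
    for sym in letters:
        points.append(PointEvent(sym, t, t + dur_frames - 1))
        t += dur_frames - 1 + ipi_frames
    end = points[-1].end_frame + 10
    board = [BoardEvent("PLACED", placed_at)] + list(board_extra)
    gaze = [GazeFrame(i, "BETWEEN_ITEMS") for i in range(placed_at, end + 1)]
    return Response(
        question_id=qid,
        question_type="semi_open",
        start_frame=placed_at,
        end_frame=end,
        target_transcript=list(transcript),
        point_events=points,
        board_events=board,
        gaze_frames=gaze,
    )


@pytest.fixture
def sunflower_response():
    return make_response(list("SUNFLOWER"), ["SUNFLOWER"])


@pytest.fixture
def small_session(layout, sunflower_response):
    return Session(
        participant_id="P1",
        layout=layout,
        fps=30.0,
        responses=[sunflower_response],
    )
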