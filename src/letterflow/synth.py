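"""Synthetic frame-coded sessions with known ground truth.

Two generative regimes emulate the competing accounts of assisted
letterboard spelling:

* **agency** — the participant selects letters themselves: per letter, a
  latency-to-fixation and a fixation lead are drawn from lognormals with
  the study-scale medians (544 ms and 476 ms), a word-boundary planning
  cost is added on the log scale at the first letter of each new word in a
  multi-word response, and a bigram-frequency facilitation
  (``slope * z(log bigram frequency)``) is added within words.  The target
  letter is fixated before contact with high probability, usually first or
  second among the letters fixated.
* **cueing** — the assistant signals each letter: a per-letter cue
  decode time proportional to log2(26) bits is added, a geometric number
  of distractor fixations precedes (or, with probability
  ``1 - p_target_fixation``, replaces) any target fixation, and no
  word-boundary or bigram structure is injected.

Sessions are emitted in the exact stream dialect the analysis consumes
(30 fps gaze/point/board streams, responses of 1-15 words over the
32-item board, occasional misspellings implanted as grid-neighbour
substitutions and mid-word board resets), so every pipeline stage can be
tested against generator ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._words import zipf_weights
from .bigrams import BigramTable, default_bigram_table
from .layout import BETWEEN_ITEMS, DONE, NOT_VISIBLE, LetterboardLayout, default_layout
from .session import BoardEvent, GazeFrame, PointEvent, Response, Session

REGIMES = ("agency", "cueing")
_QUESTION_CYCLE = ("spelling", "comprehension", "semi_open", "open_ended")
_DECODE_BITS = math.log2(26)


@dataclass
class SynthParams:
    """Generative regime and its latency/effect/noise parameters.

    Defaults are the study-scale conditions: 24 responses per session,
    word lengths averaging ~4.8 letters, latency/lead medians at the
    observed 544/476 ms, log boundary cost 0.75 and bigram slope -0.18.
    ``p_target_fixation`` and ``distractor_fixations_geometric_p`` default
    per regime (agency: 0.71 target-fixation rate, mean 1 scanning
    fixation; cueing: 0.3 and mean 3 distractors).
    """

    regime: str
    seed: int
    fps: float = 30.0
    n_responses: int = 24
    words_per_response_mean: float = 2.7
    max_words_per_response: int = 15
    median_latency_to_fixation_ms: float = 544.0
    median_fixation_lead_ms: float = 476.0
    log_boundary_cost: float = 0.75
    bigram_slope: float = -0.18
    misspelling_rate: float = 0.12
    reset_rate: float = 0.04
    lognormal_sigma: float = 0.45
    point_duration_ms: float = 200.0
    distractor_duration_frames: tuple[int, int] = (3, 6)
    not_visible_rate: float = 0.05
    done_prob: float = 0.5
    p_target_fixation: float | None = None
    distractor_fixations_geometric_p: float | None = None
    cue_decode_ms_per_bit: float = 300.0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("misspelling_rate", "reset_rate", "not_visible_rate", "done_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "median_latency_to_fixation_ms",
            "median_fixation_lead_ms",
            "point_duration_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be non-negative")
        if self.p_target_fixation is None:
            self.p_target_fixation = 0.71 if self.regime == "agency" else 0.3
        if self.distractor_fixations_geometric_p is None:
            self.distractor_fixations_geometric_p = 0.5 if self.regime == "agency" else 0.25
        if not 0 <= self.p_target_fixation <= 1:
            raise ValueError("p_target_fixation must be in [0, 1]")
        if not 0 < self.distractor_fixations_geometric_p <= 1:
            raise ValueError("distractor_fixations_geometric_p must be in (0, 1]")


@dataclass(frozen=True)
class LetterTruth:
    response_id: str
    word_index: int
    position: int
    intended: str
    pointed: str
    boundary: bool
    z_log_freq: float | None
    log_effect: float
    latency_ms: float
    lead_ms: float
    ipi_component_ms: float
    fixated: bool
    n_distractors: int


@dataclass
class GroundTruth:
    params: SynthParams
    participant_id: str
    log_boundary_cost: float
    bigram_slope: float
    z_mean: float
    z_sd: float
    latency_multiplier: float = 1.0
    lead_multiplier: float = 1.0
    letters: list[LetterTruth] = field(default_factory=list)
    misspelled_words: int = 0
    reset_words: int = 0
    total_words: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"]["distractor_duration_frames"] = list(
            d["params"]["distractor_duration_frames"]
        )
        return d


# ----------------------------------------------------------------------
# planning pass
# ----------------------------------------------------------------------

def _vocabulary():
    """(words, weights): 2-13 letter words, Zipf-flattened and length-
    weighted so the mean sampled word length matches the study's 4.8."""
    pairs = [(w.upper(), z) for w, z in zipf_weights() if 2 <= len(w) <= 13 and w.isalpha()]
    words = [w for w, _ in pairs]
    weights = np.array([(z ** 0.2) * len(w) for w, z in pairs])
    return words, weights / weights.sum()


def _plan_session(params: SynthParams, rng, layout: LetterboardLayout):
    """Choose words, implant misspellings and resets; no timing yet."""
    words, weights = _vocabulary()
    plans = []
    for _ in range(params.n_responses):
        n_words = int(min(1 + rng.poisson(params.words_per_response_mean - 1),
                          params.max_words_per_response))
        word_plans = []
        for _ in range(n_words):
            target = words[rng.choice(len(words), p=weights)]
            pointed = list(target)
            misspelled = False
            if rng.random() < params.misspelling_rate:
                # keep boundary letters intact: substitute internally, or for
                # 2-letter words insert a stray neighbour hit after letter 1
                if len(target) > 2:
                    pos = int(rng.integers(1, len(target) - 1))
                    neighbours = layout.grid_neighbours(target[pos])
                    pointed[pos] = neighbours[rng.integers(0, len(neighbours))]
                else:
                    neighbours = [
                        c for c in layout.grid_neighbours(target[0]) if c != target[1]
                    ]
                    pointed.insert(1, neighbours[rng.integers(0, len(neighbours))])
                misspelled = True
            reset_after = None
            if rng.random() < params.reset_rate and len(pointed) >= 2:
                reset_after = int(rng.integers(1, len(pointed)))
                pointed = pointed[:reset_after]
            word_plans.append(
                {
                    "target": target,
                    "pointed": pointed,
                    "misspelled": misspelled,
                    "reset_after": reset_after,
                }
            )
        plans.append(word_plans)
    return plans


def _pair_log_freqs(plans, table: BigramTable):
    # standardization set mirrors the analysis set: pairs within cleanly
    # pointed words (misspellings and reset-truncated words are excluded
    # downstream as not-both-correct)
    vals = []
    for word_plans in plans:
        for wp in word_plans:
            if wp["misspelled"] or wp["reset_after"] is not None:
                continue
            seq = wp["pointed"]
            vals.extend(table.log_freq(a, b) for a, b in zip(seq, seq[1:]))
    return vals


# ----------------------------------------------------------------------
# timing pass
# ----------------------------------------------------------------------

def _lognormal_ms(rng, median_ms: float, sigma: float) -> float:
    return float(median_ms * math.exp(rng.normal(0.0, sigma)))


def _realize(
    plans,
    params: SynthParams,
    rng,
    layout: LetterboardLayout,
    table: BigramTable,
    z_mean: float,
    z_sd: float,
    participant_id: str,
    latency_mult: float = 1.0,
    lead_mult: float = 1.0,
    boundary_cost: float | None = None,
    bigram_slope: float | None = None,
) -> tuple[Session, GroundTruth]:
    fps = params.fps
    agency = params.regime == "agency"
    cost = params.log_boundary_cost if boundary_cost is None else boundary_cost
    slope = params.bigram_slope if bigram_slope is None else bigram_slope
    decode_ms = (
        0.0 if agency else params.cue_decode_ms_per_bit * _DECODE_BITS
    )
    to_frames = lambda ms: max(1, int(round(ms * fps / 1000.0)))

    truth = GroundTruth(
        params=params,
        participant_id=participant_id,
        log_boundary_cost=cost if agency else 0.0,
        bigram_slope=slope if agency else 0.0,
        z_mean=z_mean,
        z_sd=z_sd,
        latency_multiplier=latency_mult,
        lead_multiplier=lead_mult,
    )

    responses = []
    t = 30  # session-global frame cursor
    letters = [s for s in layout.symbols if len(s) == 1 and s.isalpha()]

    for r_idx, word_plans in enumerate(plans):
        qid = f"Q{r_idx + 1:02d}"
        t0 = t
        board = [BoardEvent("PLACED", t0)]
        points: list[PointEvent] = []
        fixation_spans: list[tuple[str, int, int]] = []  # painted over filler
        anchor = t0
        n_words = len(word_plans)

        for w_idx, wp in enumerate(word_plans):
            prev_letter = None
            for pos, letter in enumerate(wp["pointed"]):
                is_boundary = w_idx > 0 and pos == 0 and n_words > 1
                z = None
                effect = 0.0
                if pos > 0:
                    z = (table.log_freq(prev_letter, letter) - z_mean) / z_sd
                if agency:
                    if is_boundary:
                        effect += cost
                    if z is not None:
                        effect += slope * z
                scale = math.exp(effect)
                latency = (
                    _lognormal_ms(rng, params.median_latency_to_fixation_ms * latency_mult,
                                  params.lognormal_sigma) * scale + decode_ms
                )
                lead = _lognormal_ms(
                    rng, params.median_fixation_lead_ms * lead_mult, params.lognormal_sigma
                ) * scale
                onset = anchor + to_frames(latency)
                start = onset + to_frames(lead)
                dur = max(2, to_frames(_lognormal_ms(rng, params.point_duration_ms, 0.3)))
                end = start + dur - 1

                fixated = bool(rng.random() < params.p_target_fixation)
                if fixated:
                    fixation_spans.append((letter, onset, end))

                n_distractors = int(rng.geometric(params.distractor_fixations_geometric_p)) - 1
                placed_distractors = 0
                cursor = anchor + 2
                limit = (onset if fixated else start) - 2
                lo, hi = params.distractor_duration_frames
                for _ in range(n_distractors):
                    d_dur = int(rng.integers(lo, hi + 1))
                    if cursor + d_dur - 1 > limit:
                        break
                    if agency:
                        cands = layout.grid_neighbours(letter)
                    else:
                        cands = [s for s in letters if s != letter]
                    d_item = cands[rng.integers(0, len(cands))]
                    if d_item != letter:
                        fixation_spans.append((d_item, cursor, cursor + d_dur - 1))
                        placed_distractors += 1
                    cursor += d_dur + 1

                points.append(PointEvent(letter, start, end))
                truth.letters.append(
                    LetterTruth(
                        qid, w_idx, pos, wp["target"][pos] if pos < len(wp["target"]) else letter,
                        letter, is_boundary, z, effect if agency else 0.0,
                        latency, lead, latency + lead, fixated, placed_distractors,
                    )
                )
                anchor = end
                prev_letter = letter

            truth.total_words += 1
            if wp["misspelled"]:
                truth.misspelled_words += 1
            if wp["reset_after"] is not None:
                truth.reset_words += 1
                reset_f = anchor + int(rng.integers(10, 20))
                placed_f = reset_f + int(rng.integers(8, 15))
                board.append(BoardEvent("RESET", reset_f))
                board.append(BoardEvent("PLACED", placed_f))
                anchor = placed_f

        if rng.random() < params.done_prob:
            start = anchor + int(rng.integers(20, 35))
            points.append(PointEvent(DONE, start, start + 5))
            anchor = start + 5

        t_end = anchor + 15

        # gaze stream: between-items filler with blink noise, fixations on top
        loc = np.full(t_end - t0 + 1, BETWEEN_ITEMS, dtype=object)
        blink = rng.random(loc.shape[0]) < params.not_visible_rate
        loc[blink] = NOT_VISIBLE
        for item, s, e in fixation_spans:
            s2, e2 = max(s, t0), min(e, t_end)
            if s2 <= e2:
                loc[s2 - t0 : e2 - t0 + 1] = item
        gaze = [GazeFrame(t0 + i, loc[i]) for i in range(loc.shape[0])]

        responses.append(
            Response(
                question_id=qid,
                question_type=_QUESTION_CYCLE[r_idx % 4],
                start_frame=t0,
                end_frame=t_end,
                target_transcript=[wp["target"] for wp in word_plans],
                point_events=points,
                board_events=board,
                gaze_frames=gaze,
            )
        )
        t = t_end + 90  # inter-question gap

    session = Session(
        participant_id=participant_id, layout=layout, fps=fps, responses=responses
    )
    session.validate()
    return session, truth


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------

def generate_session(
    params: SynthParams,
    participant_id: str = "P1",
    layout: LetterboardLayout | None = None,
    bigram_table: BigramTable | None = None,
) -> tuple[Session, GroundTruth]:
    """Generate one session; deterministic given ``params.seed``."""
    layout = layout or default_layout()
    table = bigram_table or default_bigram_table()
    rng = np.random.default_rng(params.seed)
    plans = _plan_session(params, rng, layout)
    vals = _pair_log_freqs(plans, table)
    if len(vals) >= 2 and float(np.std(vals)) > 0:
        z_mean, z_sd = float(np.mean(vals)), float(np.std(vals))
    else:
        z_mean, z_sd = 0.0, 1.0
    return _realize(plans, params, rng, layout, table, z_mean, z_sd, participant_id)


def generate_cohort(
    n_participants: int,
    params: SynthParams | list[SynthParams],
    master_seed: int | None = None,
    between_participant_sd: float = 0.15,
    boundary_cost_sd: float = 0.05,
    bigram_slope_sd: float = 0.02,
    layout: LetterboardLayout | None = None,
    bigram_table: BigramTable | None = None,
) -> tuple[list[Session], list[GroundTruth]]:
    """Generate independent participants with per-participant random effects.

    Latency/lead medians get lognormal participant multipliers
    (sd ``between_participant_sd`` on the log scale); boundary cost and
    bigram slope get Gaussian participant deviations.  Bigram z-scoring is
    pooled over the cohort so generation and annotation share one scale.
    Per-participant RNG substreams are spawned from ``master_seed``, so a
    participant's data do not depend on processing order.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if isinstance(params, SynthParams):
        params_list = [params] * n_participants
    else:
        params_list = list(params)
        if len(params_list) != n_participants:
            raise ValueError("params_per_participant length mismatch")
    if master_seed is None:
        master_seed = params_list[0].seed

    layout = layout or default_layout()
    table = bigram_table or default_bigram_table()
    seeds = np.random.SeedSequence(master_seed).spawn(n_participants + 1)
    effects_rng = np.random.default_rng(seeds[0])

    rngs = [np.random.default_rng(s) for s in seeds[1:]]
    all_plans = [_plan_session(p, rng, layout) for p, rng in zip(params_list, rngs)]
    vals = [v for plans in all_plans for v in _pair_log_freqs(plans, table)]
    z_mean, z_sd = float(np.mean(vals)), float(np.std(vals))
    if z_sd == 0:
        z_sd = 1.0

    sessions, truths = [], []
    for i, (p, plans, rng) in enumerate(zip(params_list, all_plans, rngs)):
        lat_mult = math.exp(effects_rng.normal(0.0, between_participant_sd))
        lead_mult = math.exp(effects_rng.normal(0.0, between_participant_sd))
        cost_i = p.log_boundary_cost + effects_rng.normal(0.0, boundary_cost_sd)
        slope_i = p.bigram_slope + effects_rng.normal(0.0, bigram_slope_sd)
        sess, truth = _realize(
            plans, p, rng, layout, table, z_mean, z_sd, f"P{i + 1}",
            lat_mult, lead_mult, cost_i, slope_i,
        )
        sessions.append(sess)
        truths.append(truth)
    return sessions, truths


def write_ground_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1, default=str)
        fh.write("\n")
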