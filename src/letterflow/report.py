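"""End-to-end orchestration: session -> records -> summaries -> models -> figures.

``analyze_session`` derives every per-letter observation stream from one
coded session; ``run_pipeline`` applies it to a cohort, runs the
per-participant resampling null, fits the four timing models (boundary and
bigram effects on inter-point intervals and on fixation latencies), and
writes a machine-readable report: ``summary.json``, per-record CSVs,
``models.json`` and (optionally) figures.  The run is deterministic given
the config seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gaze as gz
from . import inference, nullsim, pointing, transcript
from .session import Session, is_letter

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Every analysis choice, overridable in one place."""

    min_fixation_ms: float = 99.0
    merge_tolerance_frames: int = 0
    rank_counting: str = "type"
    n_reps: int = 1000
    seed: int = 42
    transform: str = "log"
    correct_windows_only: bool = True
    make_figures: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class SessionAnalysis:
    participant_id: str
    words: pd.DataFrame
    letters: pd.DataFrame
    ipis: pd.DataFrame
    fixations: pd.DataFrame
    anticipatory: pd.DataFrame
    anticipatory_records: list = field(repr=False, default_factory=list)
    summary: dict = field(default_factory=dict)


def analyze_session(session: Session, config: PipelineConfig | None = None) -> SessionAnalysis:
    """Derive word, letter, IPI, fixation and anticipatory records."""
    config = config or PipelineConfig()
    words_rows, letters_rows, ipi_rows, fix_rows, ant_rows = [], [], [], [], []
    ant_records_all = []
    runs = []
    gaze_pcts = []
    audit = {"letter_points_in": 0, "letter_points_scored": 0}

    for resp in session.responses:
        if not resp.point_events or not resp.target_transcript:
            continue
        word_recs = transcript.align_words(
            resp.point_events, resp.target_transcript, resp.board_events
        )
        lrecs = transcript.letter_records(word_recs, resp.point_events)
        audit["letter_points_in"] += sum(
            1 for p in resp.point_events if is_letter(p.item)
        )
        audit["letter_points_scored"] += len(lrecs)
        for w in word_recs:
            words_rows.append(
                {
                    "participant_id": session.participant_id,
                    "response_id": resp.question_id,
                    "word_index": w.word_index,
                    "target_word": w.target_word,
                    "pointed": "".join(w.pointed_letters),
                    "accuracy": w.accuracy,
                    "reason": w.reason,
                }
            )
        for l in lrecs:
            letters_rows.append(
                {
                    "participant_id": session.participant_id,
                    "response_id": resp.question_id,
                    "point_index": l.point_index,
                    "symbol": l.symbol,
                    "correct": l.is_correct_in_context,
                    "word_index": l.word_index,
                }
            )

        if len(resp.point_events) >= 2:
            ipis = pointing.classify_boundary(
                pointing.compute_ipis(resp, session.fps), word_recs, resp
            )
            run = pointing.longest_correct_run(resp, word_recs)
            runs.append(run)
            run_idx = set(range(run.start_point_index, run.start_point_index + run.length))
            word_of = {}
            correct_words = {w.word_index for w in word_recs if w.correct}
            for w in word_recs:
                for idx in w.point_indices:
                    word_of[idx] = w.word_index
            for r in ipis:
                ipi_rows.append(
                    {
                        "participant_id": session.participant_id,
                        "response_id": resp.question_id,
                        "prev_item": r.prev_item,
                        "next_item": r.next_item,
                        "ipi_ms": r.ipi_ms,
                        "boundary": r.boundary,
                        "both_correct": r.both_correct,
                        "same_word": r.same_word,
                        "in_correct_word": (
                            r.same_word
                            and r.both_correct
                            and word_of.get(r.next_point_index) in correct_words
                        ),
                        "in_longest_run": (
                            r.prev_point_index in run_idx and r.next_point_index in run_idx
                        ),
                        "next_point_index": r.next_point_index,
                    }
                )

        fixes = gz.detect_fixations(
            resp.gaze_frames,
            session.fps,
            config.min_fixation_ms,
            config.merge_tolerance_frames,
        )
        for f in fixes:
            fix_rows.append(
                {
                    "participant_id": session.participant_id,
                    "response_id": resp.question_id,
                    "item": f.item,
                    "start_frame": f.start_frame,
                    "end_frame": f.end_frame,
                    "duration_ms": f.duration_ms,
                }
            )
        windows = gz.build_windows(resp, word_recs, config.correct_windows_only)
        ants = gz.find_anticipatory(
            windows, fixes, session.fps, config.rank_counting, resp.question_id
        )
        ant_records_all.extend(ants)
        for a in ants:
            ant_rows.append(
                {
                    "participant_id": session.participant_id,
                    "response_id": resp.question_id,
                    "target_item": a.target_item,
                    "target_point_index": a.target_point_index,
                    "fixated": a.fixated,
                    "lead_ms": a.lead_ms,
                    "latency_ms": a.latency_ms,
                    "rank": a.rank,
                    "n_fixations_in_window": a.n_fixations_in_window,
                }
            )
        gaze_pcts.append(
            transcript.pct_gaze_on_board(
                resp.gaze_frames, [transcript.spelling_interval(resp)]
            )
        )

    words = pd.DataFrame(words_rows)
    letters = pd.DataFrame(letters_rows)
    ipis_df = pd.DataFrame(ipi_rows)
    ant_df = pd.DataFrame(ant_rows)

    summary = {
        "participant_id": session.participant_id,
        "words_total": len(words),
        "word_accuracy": (
            100.0 * (words["accuracy"] == "correct").mean() if len(words) else math.nan
        ),
        "letters_total": len(letters),
        "letter_accuracy": (
            100.0 * letters["correct"].mean() if len(letters) else math.nan
        ),
        "pct_gaze_on_board": (
            float(np.nanmean([g["on_board"] for g in gaze_pcts])) if gaze_pcts else math.nan
        ),
        "longest_run": max((r.length for r in runs), default=0),
        "audit": audit,
    }
    if len(ipis_df):
        wcw = ipis_df[ipis_df["in_correct_word"]]
        summary["median_ipi_ms"] = float(wcw["ipi_ms"].median()) if len(wcw) else math.nan
    else:
        summary["median_ipi_ms"] = math.nan
    if len(ant_df):
        ant_summary = gz.summarize_anticipatory(ant_records_all)
        summary.update(
            {
                "pct_fixated": ant_summary["pct_fixated"],
                "median_lead_ms": ant_summary["median_lead_ms"],
                "median_latency_ms": ant_summary["median_latency_ms"],
                "pct_rank_le_2": ant_summary["pct_rank_le_2"],
            }
        )
    return SessionAnalysis(
        session.participant_id, words, letters, ipis_df, pd.DataFrame(fix_rows),
        ant_df, ant_records_all, summary,
    )


def latency_model_frame(analysis: SessionAnalysis) -> pd.DataFrame:
    """Fixation-latency analogue of the IPI model frame.

    Joins each fixated anticipatory record (positive latency kept by the
    log transform downstream) onto its letter-pair IPI record so boundary
    and bigram predictors carry over.
    """
    if not len(analysis.ipis) or not len(analysis.anticipatory):
        return pd.DataFrame()
    ant = analysis.anticipatory[analysis.anticipatory["fixated"]]
    merged = analysis.ipis.merge(
        ant[["response_id", "target_point_index", "latency_ms", "lead_ms"]],
        left_on=["response_id", "next_point_index"],
        right_on=["response_id", "target_point_index"],
        how="inner",
    )
    return merged


def fit_models(analyses: list[SessionAnalysis], config: PipelineConfig) -> dict:
    """The four mixed-effects models on the pooled cohort records."""
    ipi_all = pd.concat([a.ipis for a in analyses], ignore_index=True)
    ipi_cc = ipi_all[ipi_all["both_correct"] & ipi_all["boundary"].notna()].copy()
    lat_all = pd.concat(
        [latency_model_frame(a) for a in analyses], ignore_index=True
    )
    lat_cc = lat_all[lat_all["both_correct"]].copy() if len(lat_all) else lat_all

    out = {}
    bound_ipi = inference.fit_boundary_model(ipi_cc, "ipi_ms", config.transform)
    out["boundary_ipi"] = bound_ipi

    within = inference.annotate_predictors(
        ipi_cc[ipi_cc["boundary"] == "within_word"].copy()
    )
    freq, dist = inference.fit_bigram_model(within, "ipi_ms", config.transform)
    out["bigram_ipi"] = freq
    out["bigram_ipi_distance"] = dist
    sd_y = float(np.log(within["ipi_ms"]).std(ddof=0))
    out["bigram_ipi_standardized"] = inference.standardized_beta(freq, sd_y)

    if len(lat_cc) and (lat_cc["latency_ms"] > 0).sum() > 50:
        lat_pos = lat_cc[lat_cc["latency_ms"] > 0]
        if {"within_word", "between_word"} <= set(lat_pos["boundary"]):
            out["boundary_latency"] = inference.fit_boundary_model(
                lat_pos, "latency_ms", config.transform
            )
        lat_within = inference.annotate_predictors(
            lat_pos[lat_pos["boundary"] == "within_word"].copy()
        )
        freq_l, dist_l = inference.fit_bigram_model(
            lat_within, "latency_ms", config.transform
        )
        out["bigram_latency"] = freq_l
        out["bigram_latency_distance"] = dist_l
    return out


def run_pipeline(
    sessions: list[Session], out_dir, config: PipelineConfig | None = None
) -> dict:
    """Full cohort analysis; returns and writes the summary report."""
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    analyses = [analyze_session(s, config) for s in sessions]

    seeds = np.random.SeedSequence(config.seed).spawn(len(analyses))
    null_results = []
    for a, ss in zip(analyses, seeds):
        if a.anticipatory_records:
            res = nullsim.run_null_for_records(
                a.anticipatory_records,
                n_reps=config.n_reps,
                seed=ss.generate_state(1)[0] % (2**31),
                participant_id=a.participant_id,
            )
            null_results.append(res)
            a.summary["null_exceedance"] = res.exceedance
            a.summary["null_expected_pct"] = res.expected_pct

    for name in ("words", "letters", "ipis", "fixations", "anticipatory"):
        df = pd.concat([getattr(a, name) for a in analyses], ignore_index=True)
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
    if null_results:
        pd.DataFrame(
            [
                {
                    "participant_id": r.participant_id,
                    "observed_pct_fixated": r.observed_pct_fixated,
                    "expected_null_pct": r.expected_pct,
                    "null_mean": float(np.mean(r.null_pcts)),
                    "null_max": float(np.max(r.null_pcts)),
                    "exceedance": r.exceedance,
                }
                for r in null_results
            ]
        ).to_csv(os.path.join(out_dir, "null.csv"), index=False)

    models = {}
    try:
        models = fit_models(analyses, config)
    except ValueError:
        pass  # too little data for mixed models (e.g. single tiny session)
    models_json = {k: dataclasses.asdict(v) for k, v in models.items()}
    with open(os.path.join(out_dir, "models.json"), "w", encoding="utf-8") as fh:
        json.dump(models_json, fh, indent=1, default=float)

    report = {
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "participants": [a.summary for a in analyses],
        "models": models_json,
    }
    with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, default=float, sort_keys=True)

    if config.make_figures:
        fig_dir = os.path.join(out_dir, "figures")
        os.makedirs(fig_dir, exist_ok=True)
        make_figures(analyses, null_results, sessions, fig_dir)
    return report


# ----------------------------------------------------------------------
# figures
# ----------------------------------------------------------------------

def make_figures(analyses, null_results, sessions, fig_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ipi_all = pd.concat([a.ipis for a in analyses], ignore_index=True)
    if len(ipi_all):
        fig, ax = plt.subplots(figsize=(5, 4))
        strata = [
            ("within word", ipi_all.loc[ipi_all["boundary"] == "within_word", "ipi_ms"]),
            ("between words", ipi_all.loc[ipi_all["boundary"] == "between_word", "ipi_ms"]),
        ]
        data = [v.dropna() for _, v in strata if len(v.dropna())]
        labels = [k for k, v in strata if len(v.dropna())]
        if data:
            parts = ax.violinplot(data, showextrema=False)
            for i, v in enumerate(data, start=1):
                ax.hlines(v.median(), i - 0.2, i + 0.2, color="gold", lw=2)
                ax.hlines(v.mean(), i - 0.2, i + 0.2, color="red", lw=2)
            ax.set_xticks(range(1, len(data) + 1), labels)
            ax.set_ylabel("inter-point interval (ms)")
        fig.tight_layout()
        fig.savefig(os.path.join(fig_dir, "ipi_boundary.png"), dpi=100)
        plt.close(fig)

    if null_results:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot(
            [r.null_pcts for r in null_results],
            tick_labels=[r.participant_id for r in null_results],
        )
        for i, r in enumerate(null_results, start=1):
            ax.hlines(r.observed_pct_fixated, i - 0.3, i + 0.3, color="red", lw=2)
        ax.set_ylabel("% correct letters fixated")
        ax.set_xlabel("participant (red line = observed, box = resampling null)")
        fig.tight_layout()
        fig.savefig(os.path.join(fig_dir, "null_vs_observed.png"), dpi=100)
        plt.close(fig)

    # response timeline for the first multi-word response of the first session
    for sess in sessions[:1]:
        resp = next(
            (r for r in sess.responses if len(r.target_transcript) >= 2 and r.point_events),
            None,
        )
        if resp is None:
            continue
        fig, ax = plt.subplots(figsize=(8, 3))
        for i, pe in enumerate(resp.point_events):
            ax.axvspan(
                sess.ms(pe.start_frame - resp.start_frame) / 1000,
                sess.ms(pe.end_frame - resp.start_frame) / 1000,
                ymin=0.1, ymax=0.45, color="red", alpha=0.4,
            )
            ax.text(
                sess.ms(pe.start_frame - resp.start_frame) / 1000,
                0.02, pe.item, fontsize=7,
            )
        fixes = gz.detect_fixations(resp.gaze_frames, sess.fps)
        for f in fixes:
            if is_letter(f.item):
                ax.axvspan(
                    sess.ms(f.start_frame - resp.start_frame) / 1000,
                    sess.ms(f.end_frame - resp.start_frame) / 1000,
                    ymin=0.55, ymax=0.9, color="gold", alpha=0.5,
                )
        ax.set_xlabel("time (s)")
        ax.set_yticks([0.27, 0.72], ["points", "fixations"])
        ax.set_title(f"{sess.participant_id} {resp.question_id}: "
                     + " ".join(resp.target_transcript))
        fig.tight_layout()
        fig.savefig(os.path.join(fig_dir, "timeline.png"), dpi=100)
        plt.close(fig)
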