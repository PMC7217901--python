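"""Predictor annotation and mixed-effects timing models."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from letterflow.bigrams import (
    bigram_table_from_words,
    default_bigram_table,
    read_bigram_csv,
    write_bigram_csv,
)
from letterflow.inference import (
    annotate_predictors,
    fit_bigram_model,
    fit_boundary_model,
    standardized_beta,
)
from letterflow.layout import LETTERS, default_layout


class TestBigramTable:
    def test_all_676_pairs_present(self):
        tbl = default_bigram_table()
        assert len(tbl.per_million) == 26 * 26
        assert all(v >= 0 for v in tbl.per_million.values())

    def test_nt_more_frequent_than_tn(self):
        tbl = default_bigram_table()
        assert tbl.freq("N", "T") > tbl.freq("T", "N")

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="no bigrams"):
            bigram_table_from_words([])
        from letterflow.bigrams import BigramTable

        pm = {("A", "B"): 1.0}
        with pytest.raises(ValueError, match="incomplete"):
            BigramTable(pm)

    def test_csv_round_trip(self, tmp_path):
        tbl = default_bigram_table()
        path = tmp_path / "bigrams.csv"
        write_bigram_csv(tbl, path)
        tbl2 = read_bigram_csv(path)
        for pair in [("N", "T"), ("T", "N"), ("E", "E"), ("Q", "Z")]:
            assert tbl2.per_million[pair] == pytest.approx(
                tbl.per_million[pair], rel=1e-5
            )


class TestAnnotate:
    def _frame(self):
        rng = np.random.default_rng(0)
        pairs = [(a, b) for a in LETTERS[:8] for b in LETTERS[:8]]
        idx = rng.integers(0, len(pairs), 200)
        return pd.DataFrame(
            {
                "prev_item": [pairs[i][0] for i in idx],
                "next_item": [pairs[i][1] for i in idx],
            }
        )

    def test_symmetric_distance_asymmetric_frequency(self):
        df = pd.DataFrame({"prev_item": ["N", "T"], "next_item": ["T", "N"]})
        out = annotate_predictors(df)
        assert out["distance_cm"].iloc[0] == out["distance_cm"].iloc[1]
        assert out["bigram_log_freq"].iloc[0] > out["bigram_log_freq"].iloc[1]

    def test_z_scores_standardized_over_analysis_set(self):
        out = annotate_predictors(self._frame())
        assert out["z_log_freq"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["z_log_freq"].std(ddof=0) == pytest.approx(1.0)

    def test_self_pair_distance_zero(self):
        df = pd.DataFrame({"prev_item": ["E"], "next_item": ["E"], "x": [1]})
        df2 = pd.DataFrame({"prev_item": ["E", "A"], "next_item": ["E", "B"]})
        out = annotate_predictors(df2)
        assert out["distance_cm"].iloc[0] == 0.0


def _simulate_frame(
    n_participants=8,
    n_per=250,
    boundary_cost=0.6,
    freq_slope=-0.2,
    dist_slope=0.0,
    sigma=0.4,
    seed=0,
):
    """Log-linear latencies with known fixed effects, for recovery checks."""
    rng = np.random.default_rng(seed)
    layout = default_layout()
    tbl = default_bigram_table()
    letters = list(LETTERS)
    rows = []
    for p in range(n_participants):
        intercept = np.log(950) + rng.normal(0, 0.1)
        for _ in range(n_per):
            a, b = rng.choice(letters, 2)
            boundary = rng.random() < 0.15
            lf = tbl.log_freq(a, b)
            d = layout.distance(a, b)
            rows.append((f"P{p}", a, b, boundary, lf, d, intercept))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "prev_item", "next_item", "is_b", "lf", "d", "icpt"],
    )
    z = (df["lf"] - df["lf"].mean()) / df["lf"].std(ddof=0)
    zd = (df["d"] - df["d"].mean()) / df["d"].std(ddof=0)
    log_y = (
        df["icpt"]
        + boundary_cost * df["is_b"]
        + freq_slope * z * (~df["is_b"])
        + dist_slope * zd
        + rng.normal(0, sigma, len(df))
    )
    df["ipi_ms"] = np.exp(log_y)
    df["boundary"] = np.where(df["is_b"], "between_word", "within_word")
    return df


class TestBoundaryModel:
    def test_recovers_known_cost(self):
        df = _simulate_frame(boundary_cost=0.6, freq_slope=0.0, seed=1)
        res = fit_boundary_model(df, "ipi_ms")
        assert res.covers(0.6)
        assert res.t == pytest.approx(res.estimate / res.se)
        assert res.ci95[0] <= res.estimate <= res.ci95[1]

    def test_zero_cost_ci_covers_zero(self):
        df = _simulate_frame(boundary_cost=0.0, freq_slope=0.0, seed=2)
        res = fit_boundary_model(df, "ipi_ms")
        assert res.covers(0.0)

    def test_order_invariance(self):
        df = _simulate_frame(seed=3)
        res1 = fit_boundary_model(df, "ipi_ms")
        res2 = fit_boundary_model(df.sample(frac=1, random_state=0), "ipi_ms")
        assert res1.estimate == pytest.approx(res2.estimate, abs=1e-8)

    def test_single_stratum_rejected(self):
        df = _simulate_frame(seed=4)
        with pytest.raises(ValueError):
            fit_boundary_model(df[df["boundary"] == "within_word"], "ipi_ms")


class TestBigramModel:
    def test_recovers_known_slope(self):
        df = _simulate_frame(freq_slope=-0.2, seed=5)
        within = annotate_predictors(df[df["boundary"] == "within_word"].copy())
        freq, dist = fit_bigram_model(within, "ipi_ms")
        assert freq.covers(-0.2)

    def test_zero_slope_with_distance_confound(self):
        # distance effect present, frequency effect absent: the frequency CI
        # covers 0 while the distance term is clearly positive
        df = _simulate_frame(freq_slope=0.0, dist_slope=0.3, seed=6)
        within = annotate_predictors(df[df["boundary"] == "within_word"].copy())
        freq, dist = fit_bigram_model(within, "ipi_ms")
        assert freq.covers(0.0)
        assert dist.ci95[0] > 0

    def test_standardized_beta_rescaling(self):
        df = _simulate_frame(freq_slope=-0.2, seed=7)
        within = annotate_predictors(df[df["boundary"] == "within_word"].copy())
        freq, _ = fit_bigram_model(within, "ipi_ms")
        sd_y = float(np.log(within["ipi_ms"]).std(ddof=0))
        beta = standardized_beta(freq, sd_y)
        assert beta.estimate == pytest.approx(freq.estimate / sd_y)
        assert beta.standardized


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstLme4:
    def test_boundary_estimate_matches_lme4(self, tmp_path):
        df = _simulate_frame(n_participants=6, n_per=80, boundary_cost=0.5, seed=8)
        df["y"] = np.log(df["ipi_ms"])
        df["is_boundary"] = (df["boundary"] == "between_word").astype(int)
        csv = tmp_path / "d.csv"
        df[["participant_id", "y", "is_boundary"]].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(lme4))
                d <- read.csv("{csv}")
                m <- lmer(y ~ is_boundary + (1 + is_boundary | participant_id), data = d)
                cat(fixef(m)["is_boundary"], sqrt(vcov(m)["is_boundary","is_boundary"]))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, timeout=300,
        )
        assert out.returncode == 0, out.stderr
        est_r, se_r = map(float, out.stdout.split())
        res = fit_boundary_model(df, "ipi_ms")
        assert res.estimate == pytest.approx(est_r, abs=0.02)
        assert res.se == pytest.approx(se_r, rel=0.35)
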