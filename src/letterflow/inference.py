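"""Mixed-effects timing models: word-boundary and bigram-frequency effects.

Two effects characteristic of fluent spelling are modelled, each on two
dependent variables (inter-point interval and fixation latency):

* **Word boundary** — latencies are elevated at the first letter of a new
  word in a multi-word response, reflecting production planning.  Model:
  ``log(dv) ~ boundary`` with by-participant random intercepts and
  boundary slopes.
* **Bigram frequency** — within words, the second letter of a frequent
  English pair is reached faster than that of a rare pair, controlling
  for the physical distance between the two items on the board.  Model:
  ``log(dv) ~ z(log bigram frequency) + z(distance)`` with by-participant
  random intercepts and frequency slopes.

Latencies are log-transformed (they are right-skewed and the effects are
multiplicative); the transform is configurable.  Estimation delegates to
statsmodels' linear mixed model (REML).  Degrees of freedom for the t
statistic use a participant-level approximation (n_participants - 1),
appropriate when inference targets participant-level slopes; the maximal
random-effects structure is simplified to random intercepts when the fit
is singular or fails to converge, and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .bigrams import BigramTable, default_bigram_table
from .layout import LetterboardLayout


@dataclass(frozen=True)
class ModelResult:
    term: str
    estimate: float
    se: float
    df: float
    t: float
    p: float
    ci95: tuple[float, float]
    n_obs: int
    n_participants: int
    random_structure: str = "intercept+slope"
    converged: bool = True
    standardized: bool = False

    def covers(self, value: float) -> bool:
        lo, hi = self.ci95
        return lo <= value <= hi


def annotate_predictors(
    df: pd.DataFrame,
    bigram_table: BigramTable | None = None,
    layout: LetterboardLayout | None = None,
) -> pd.DataFrame:
    """Add ``distance_cm``, ``bigram_log_freq`` and ``z_log_freq`` columns.

    Expects columns ``prev_item`` and ``next_item``; z-scoring is over the
    rows of *df* (the analysis set).  Raises if a pair is missing from the
    table (tables are complete by construction).
    """
    if bigram_table is None:
        bigram_table = default_bigram_table()
    if layout is None:
        from .layout import default_layout

        layout = default_layout()
    out = df.copy()
    out["distance_cm"] = [
        layout.distance(a, b) for a, b in zip(out["prev_item"], out["next_item"])
    ]
    out["bigram_log_freq"] = [
        bigram_table.log_freq(a, b) for a, b in zip(out["prev_item"], out["next_item"])
    ]
    sd = out["bigram_log_freq"].std(ddof=0)
    if sd == 0:
        raise ValueError("bigram log frequency is constant over the analysis set")
    out["z_log_freq"] = (out["bigram_log_freq"] - out["bigram_log_freq"].mean()) / sd
    return out


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _fit_mixed(df, formula, re_formula, groups):
    """MixedLM fit with singular/convergence fallback to random intercepts."""
    import statsmodels.formula.api as smf

    def attempt(rf):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df[groups], re_formula=rf)
            res = model.fit(reml=True, method="lbfgs", maxiter=400)
        return res

    try:
        res = attempt(re_formula)
        singular = (
            not res.converged
            or not np.all(np.isfinite(res.bse.values))
            or np.any(np.diag(res.cov_re) < 1e-10)
        )
        if not singular:
            return res, re_formula, True
    except Exception:
        pass
    res = attempt("1")
    return res, "1", bool(res.converged)


def _term_result(res, term, df_resid_groups, n_obs, structure, converged, standardized):
    est = float(res.params[term])
    se = float(res.bse[term])
    dof = max(1.0, float(df_resid_groups))
    t = est / se
    p = 2 * stats.t.sf(abs(t), dof)
    half = stats.t.ppf(0.975, dof) * se
    return ModelResult(
        term=term,
        estimate=est,
        se=se,
        df=dof,
        t=t,
        p=p,
        ci95=(est - half, est + half),
        n_obs=n_obs,
        n_participants=int(df_resid_groups + 1),
        random_structure=structure,
        converged=converged,
        standardized=standardized,
    )


def fit_boundary_model(
    df: pd.DataFrame, dv: str = "ipi_ms", transform: str = "log"
) -> ModelResult:
    """Word-boundary effect on log latency.

    *df* needs columns ``participant_id``, ``boundary`` (within_word /
    between_word) and *dv* in ms.  Returns the boundary term: the log-ms
    cost of initiating a new word.
    """
    data = df[[dv, "boundary", "participant_id"]].dropna().copy()
    data = data[data[dv] > 0]
    strata = set(data["boundary"])
    if not {"within_word", "between_word"} <= strata:
        raise ValueError("both boundary strata must be non-empty")
    n_part = data["participant_id"].nunique()
    if n_part < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    data["y"] = np.log(data[dv]) if transform == "log" else data[dv]
    data["is_boundary"] = (data["boundary"] == "between_word").astype(float)
    res, structure, converged = _fit_mixed(
        data, "y ~ is_boundary", "~is_boundary", "participant_id"
    )
    return _term_result(
        res, "is_boundary", n_part - 1, len(data), structure, converged, False
    )


def fit_bigram_model(
    df: pd.DataFrame,
    dv: str = "ipi_ms",
    transform: str = "log",
    standardize: bool = False,
) -> tuple[ModelResult, ModelResult]:
    """Bigram-frequency effect on log latency, controlling distance.

    *df* holds within-word records with ``z_log_freq`` and ``distance_cm``
    already annotated.  Returns ``(frequency_term, distance_term)``.  With
    ``standardize=True`` the DV is z-scored so the frequency estimate is a
    standardized beta; otherwise it is the raw log-scale slope per SD of
    log bigram frequency.
    """
    cols = [dv, "z_log_freq", "distance_cm", "participant_id"]
    data = df[cols].dropna().copy()
    data = data[data[dv] > 0]
    n_part = data["participant_id"].nunique()
    if n_part < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    y = np.log(data[dv]) if transform == "log" else data[dv]
    data["y"] = _zscore(y) if standardize else y
    data["z_dist"] = _zscore(data["distance_cm"])
    res, structure, converged = _fit_mixed(
        data, "y ~ z_log_freq + z_dist", "~z_log_freq", "participant_id"
    )
    freq = _term_result(
        res, "z_log_freq", n_part - 1, len(data), structure, converged, standardize
    )
    dist = _term_result(
        res, "z_dist", n_part - 1, len(data), structure, converged, standardize
    )
    return freq, dist


def standardized_beta(result: ModelResult, sd_y: float) -> ModelResult:
    """Rescale a raw log-scale slope to a standardized beta given sd(log dv)."""
    if sd_y <= 0:
        raise ValueError("sd_y must be positive")
    scale = 1.0 / sd_y
    lo, hi = result.ci95
    return replace(
        result,
        estimate=result.estimate * scale,
        se=result.se * scale,
        ci95=(lo * scale, hi * scale),
        standardized=True,
    )
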