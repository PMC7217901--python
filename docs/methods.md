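# Methods

This note documents the analysis conventions, model specifications, and
the design of the synthetic session generator, including the choices that
were genuinely open and the limitations that follow from them.

## Coding conventions and units

Frames are 0-based; a point event is the inclusive interval of frames
during which the finger is in contact with an item (human coders mark
contact by the board bowing, so both endpoints are observed frames).
Time conversion is `ms = frames / fps × 1000`, computed in exact rational
arithmetic where inputs are exact; the session fps defaults to 30 and is
configurable (e.g. 29.97 for NTSC material). Frame fields are integers in
the CSV dialect; programmatic events may carry exact fractional frames so
that sub-frame timings (e.g. a published 884 ms interval, which is 26.52
frames at 30 fps) survive round-off.

The board is 21.6 × 27.9 cm with 32 items (26 letters, four punctuation
marks, DELETE and DONE icons). The true item arrangement of the study
board is not published; the package ships a default alphabetical
five-column grid in which N and T are diagonally adjacent, matching the
one geometric fact the published description fixes. Distances on this
layout therefore differ from the study's by an unknown affine factor, and
any user with the real geometry should supply their own `layout.json`.

## Accuracy rules

A word is **correct** iff the letters pointed between its first and last
letters are exactly the required ones in order; extra leading or trailing
letters are tolerated (they may be the abandoned start of a different
word). A word is **incorrect** when internal letters are wrong in number
*or identity*, when a boundary letter is missing, or when the assistant
reset the board mid-word. The reason code `wrong_internal_count` covers
any internal-sequence mismatch, including substitutions: the published
rule ("exact letters required in the correct order") provides no separate
substitution category, and a substituted word is incorrect either way.

Alignment of the point stream to the coder-supplied target transcript is
greedy left-to-right, anchored on each word's first and last letters with
three letters of slack; ambiguous extra letters attach leftward. This is
deterministic. Letter-level correctness within an aligned word uses a
longest-common-subsequence match; extra and substituted letters count as
incorrect letters. Points to DONE, DELETE and punctuation are excluded
from letter denominators. How to count a pointed letter "correct in
context" when its whole word is wrong is not fully specified by the
verbal rule; per-point LCS alignment is this package's interpretation,
and the conservation audit in the pipeline report verifies that every
letter point is scored exactly once.

## Fixations and anticipatory windows

A fixation is a maximal run of identical item codes lasting at least
99 ms — at 30 fps, `ceil(99 × 30 / 1000) = 3` frames, computed rather
than hard-coded. Any differing frame (including between-items frames and
not-visible blinks) terminates a run; a merge tolerance (default 0
frames) can bridge single-frame interruptions if desired.

The anticipatory window for a correct letter point opens at the end of
the previous point — or at the latest board placement/reset before
contact, whichever is later; the first letter's window opens at board
placement — and closes at finger contact. A fixation of the target that
began before the window opened but persisted past the previous point's
end is admitted (latency ≤ 0); how far back such a straddling fixation
may begin is unbounded here. Search rank counts *distinct* letters in
first-fixation order (type counting; token counting via flag), and
between-items fixations do not enter the rank denominator. Windows for
letters following a DELETE point reopen at the DELETE point's end,
because DELETE is itself a pointed item.

## Resampling null

For each participant, every letter fixated inside anticipatory windows
(correct or not, repeats preserved) forms a token list. Each simulation
redraws each window's `k_i` fixations with replacement from this list;
windows with `k_i = 0` are never fixated. `k_i` counts fixation tokens,
not distinct letters, matching "up to the total number of letters
actually fixated". The simulated %-fixated has the closed form

    E[%] = 100/n · Σ_i 1[k_i > 0] · (1 − (1 − c_i/m)^{k_i})

(`c_i` = target's token count, `m` = list size), which the Monte-Carlo
engine is tested against — the central correctness property of the
module. Exceedance is reported as `(1 + #{null ≥ obs}) / (1 + n_reps)`
so it is never exactly zero. RNG substreams are spawned per participant
from a master seed, so results do not depend on processing order.

## Timing models

The four models fit `log(dv)` — dv is the IPI or the fixation latency in
ms, both right-skewed with multiplicative effects, hence the log; the
transform is configurable — by REML linear mixed models:

* boundary: `log(dv) ~ is_boundary`, random intercept + boundary slope
  by participant;
* bigram: `log(dv) ~ z(log bigram frequency) + z(distance)`, within-word
  pairs between correct letters only, random intercept + frequency slope
  by participant.

When the maximal random structure is singular or fails to converge the
fit falls back to random intercepts and is flagged in the result. The t
statistic uses `df = n_participants − 1`, a participant-level
approximation in the spirit of Satterthwaite-style corrections (which the
underlying estimation engine does not provide); with nine participants
this gives df = 8, and confidence intervals use the t quantile at that
df. An lme4 cross-check in the test suite confirms estimates and
standard errors on simulated data.

The bigram model's primary estimate is the raw log-scale slope per SD of
log bigram frequency — the scale on which the generator injects its
effect, so parameter recovery is well-posed. A standardized β
(slope ÷ sd(log dv)) is also reported for comparability with
standardized effect sizes.

Standardization of the frequency predictor is over the analysis set, so
the z-scale depends (slightly) on which records survive filtering.

## Bigram frequency table

Published bigram norms are not redistributable, so the shipped table is
computed at import from a compact built-in list of ~450 common English
words with Zipf-law weights (weight ∝ 1/rank). This approximates
relative bigram frequencies well enough to preserve the orthographic
asymmetries that matter here (e.g. NT ≫ TN), and `read_bigram_csv`
loads any user-supplied `first,second,per_million` table instead. The
synthetic generator reuses the same table, which guarantees
generation/annotation consistency regardless of the table's fidelity to
corpus norms — but absolute frequencies should not be interpreted.

## Synthetic generator

The generator emits sessions in the exact stream dialect the analysis
reads, under two regimes.

**Agency** (defaults are study-scale conditions): 24 responses; 1–15
words per response (1 + Poisson(1.7), giving ~2.7 words/response);
vocabulary sampled from the built-in word list with Zipf-flattened,
length-weighted probabilities (`zipf^0.2 × length`) calibrated to a mean
word length of ~4.8 letters. Per letter, latency-to-fixation and
fixation lead are lognormal with medians 544 ms and 476 ms
(σ = 0.45 log units); at the first letter of a new word both components
are scaled by `exp(0.75)`, and within words by
`exp(−0.18 × z(log bigram frequency))`, so the injected effects are
exact on the log-IPI and log-latency scales. The target is fixated with
probability 0.71 (the observed study mean), preceded by a geometric
number (mean 1) of scanning fixations of grid-neighbour letters — chosen
once to place the first-or-second-rank share in the observed 60–75%
band. Misspellings are implanted at rate 0.12/word and board resets at
0.04/word, which puts word accuracy near the observed ~83%.
Misspellings substitute an internal letter with a grid neighbour
(2-letter words instead receive a stray neighbour insertion), keeping
boundary letters intact so one implanted error cannot cascade through
the transcript alignment. The z-standardization of bigram frequency used
during generation is computed over pairs within cleanly pointed words —
the same population the analysis standardizes over — so injected and
recovered slopes share a scale.

**Cueing**: no boundary or bigram structure; each letter incurs a decode
cost `300 ms/bit × log2(26) ≈ 1.4 s`; the target is fixated with
probability 0.3, after a geometric number (mean 3) of uniformly random
distractor fixations. This produces the anti-signature the pipeline
should detect: ~2.5 s IPIs, ~30% anticipatory fixations, majority search
rank > 2, and a bigram CI covering zero.

Cohorts draw per-participant multipliers on the latency/lead medians
(lognormal, σ = 0.15) and Gaussian deviations on the boundary cost
(σ = 0.05) and bigram slope (σ = 0.02); bigram z-scoring is pooled over
the cohort. All randomness flows from a single seed through spawned
substreams; the same seed reproduces sessions byte-identically.

What the generator does *not* emulate: raw gaze coordinates or
calibration error (generation is at the coded-stream level), coder
disagreement, DELETE-mediated corrections, gaze excursions to the
assistant, latencies ≤ 0 (straddling fixations arise only incidentally,
e.g. at repeated letters), and any dependence of fixation probability on
board position. Passing recovery tests therefore shows that the pipeline
correctly measures what the coded streams contain — not that real coded
video is free of coding artefacts.

## Problem sizes and numerics

The test suite and examples use 9-participant cohorts of 24 responses
(~2 400 within-word and ~350 between-word letter pairs per cohort),
matching the scale of the motivating study; single-session checks use
~150–200 responses where ~500 words are needed for binomial rate checks.
Medians inherit a half-frame (±16.7 ms) quantization from frame
rounding, which recovery tests allow for. Monte-Carlo checks use 3-SE
tolerances against closed forms or known rates. Ties in longest-run
selection break to the earliest run; empty summary strata are omitted
rather than reported as NaN; degenerate reliability streams (a single
shared code) return 100% agreement with κ flagged undefined rather than
dividing by zero.
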