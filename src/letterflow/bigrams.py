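"""Letter-bigram frequency table for English.

Fluent spellers are faster on letter pairs that co-occur frequently within
English words ("nt") than on rare pairs ("tn"), after controlling for the
physical distance between keys or board items.  This module provides the
frequency predictor for that effect: per-million occurrence rates for all
26 x 26 ordered letter pairs.

The shipped table is computed from the package's built-in Zipf-weighted
word list (see :mod:`letterflow._words`); :func:`read_bigram_csv` loads a
user-supplied table (columns ``first,second,per_million``) instead, e.g.
published corpus norms.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .layout import LETTERS


@dataclass(frozen=True)
class BigramTable:
    """Per-million frequencies of all 676 ordered letter pairs.

    ``log_freq`` is the natural log of the (add-one smoothed) per-million
    rate; standardization to z-scores is done over the analysis set by the
    inference step, not here.
    """

    per_million: dict[tuple[str, str], float]

    def __post_init__(self):
        missing = [
            (a, b) for a in LETTERS for b in LETTERS if (a, b) not in self.per_million
        ]
        if missing:
            raise ValueError(f"bigram table incomplete: {len(missing)} pairs missing")
        if any(v < 0 for v in self.per_million.values()):
            raise ValueError("bigram frequencies must be non-negative")

    def freq(self, first: str, second: str) -> float:
        key = (first.upper(), second.upper())
        try:
            return self.per_million[key]
        except KeyError:
            raise KeyError(f"pair {key!r} not a letter bigram") from None

    def log_freq(self, first: str, second: str) -> float:
        # add-one smoothing keeps unattested pairs finite
        return math.log(self.freq(first, second) + 1.0)

    def log_freq_matrix(self) -> np.ndarray:
        """26x26 array of log frequencies, rows = first letter."""
        out = np.empty((26, 26))
        for i, a in enumerate(LETTERS):
            for j, b in enumerate(LETTERS):
                out[i, j] = self.log_freq(a, b)
        return out


def bigram_table_from_words(word_weights) -> BigramTable:
    """Build a table from (word, weight) pairs.

    Each word contributes ``weight`` to every adjacent letter pair it
    contains; counts are normalised to per-million bigram tokens.
    """
    counts = {(a, b): 0.0 for a in LETTERS for b in LETTERS}
    total = 0.0
    for word, weight in word_weights:
        w = "".join(ch for ch in word.upper() if ch in LETTERS)
        for a, b in zip(w, w[1:]):
            counts[(a, b)] += weight
            total += weight
    if total == 0:
        raise ValueError("word list contains no bigrams")
    return BigramTable({k: v / total * 1e6 for k, v in counts.items()})


@lru_cache(maxsize=1)
def default_bigram_table() -> BigramTable:
    """The shipped table, derived from the built-in word list."""
    from ._words import zipf_weights

    return bigram_table_from_words(zipf_weights())


def read_bigram_csv(path) -> BigramTable:
    """Load a user-supplied table: columns ``first,second,per_million``."""
    pm = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            pm[(row["first"].upper(), row["second"].upper())] = float(row["per_million"])
    return BigramTable(pm)


def write_bigram_csv(table: BigramTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["first", "second", "per_million"])
        for a in LETTERS:
            for b in LETTERS:
                w.writerow([a, b, f"{table.per_million[(a, b)]:.6g}"])
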