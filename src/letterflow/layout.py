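"""Letterboard geometry.

The board is a 21.6 x 27.9 cm laminated sheet carrying 32 items: the 26
upper-case letters, four punctuation marks (comma, exclamation mark,
question mark, full stop) and two icons (DELETE, DONE).  Items live on a
grid and each has a physical centre in centimetres; inter-item distance is
the Euclidean distance between centres.

The true board used in the study is not published, so the package ships a
default alphabetical 5-column grid in which N and T are diagonally adjacent
(consistent with the published description of the board).  Distances on
this default layout are an approximation of the study's geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

LETTERS = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
PUNCTUATION = (",", "!", "?", ".")
DELETE = "DELETE"
DONE = "DONE"
ICONS = (DELETE, DONE)

#: non-item gaze location codes
BETWEEN_ITEMS = "BETWEEN_ITEMS"
ASSISTANT = "ASSISTANT"
OTHER = "OTHER"
NOT_VISIBLE = "NOT_VISIBLE"
NON_ITEM_LOCATIONS = (BETWEEN_ITEMS, ASSISTANT, OTHER, NOT_VISIBLE)


class LayoutError(ValueError):
    """Raised when a layout violates board invariants."""


@dataclass(frozen=True)
class BoardItem:
    symbol: str
    row: int
    col: int
    x_cm: float
    y_cm: float


@dataclass(frozen=True)
class LetterboardLayout:
    """32-item board with grid positions and physical centres."""

    items: tuple[BoardItem, ...]
    width_cm: float = 21.6
    height_cm: float = 27.9
    _by_symbol: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        by_symbol = {it.symbol: it for it in self.items}
        object.__setattr__(self, "_by_symbol", by_symbol)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        symbols = [it.symbol for it in self.items]
        if len(symbols) != len(set(symbols)):
            raise LayoutError("duplicate symbols on board")
        letters = [s for s in symbols if s in LETTERS]
        if sorted(letters) != sorted(LETTERS):
            raise LayoutError("board must carry exactly the 26 letters")
        grid = [(it.row, it.col) for it in self.items]
        if len(grid) != len(set(grid)):
            raise LayoutError("grid positions must be unique")
        for it in self.items:
            if not (0 <= it.x_cm <= self.width_cm and 0 <= it.y_cm <= self.height_cm):
                raise LayoutError(
                    f"item {it.symbol!r} centre ({it.x_cm}, {it.y_cm}) outside board"
                )

    # -- queries ------------------------------------------------------
    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(it.symbol for it in self.items)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def item(self, symbol: str) -> BoardItem:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} is not on the board") from None

    def distance(self, a: str, b: str) -> float:
        """Euclidean distance in cm between the centres of items *a* and *b*."""
        ia, ib = self.item(a), self.item(b)
        return math.hypot(ia.x_cm - ib.x_cm, ia.y_cm - ib.y_cm)

    def grid_neighbours(self, symbol: str) -> list[str]:
        """Letters in the 8-neighbourhood of *symbol* on the grid."""
        it = self.item(symbol)
        out = []
        for other in self.items:
            if other.symbol == symbol or other.symbol not in LETTERS:
                continue
            if abs(other.row - it.row) <= 1 and abs(other.col - it.col) <= 1:
                out.append(other.symbol)
        return out

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "board_size_cm": [self.width_cm, self.height_cm],
            "items": [
                {
                    "symbol": it.symbol,
                    "row": it.row,
                    "col": it.col,
                    "x_cm": it.x_cm,
                    "y_cm": it.y_cm,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LetterboardLayout":
        w, h = d.get("board_size_cm", (21.6, 27.9))
        items = tuple(
            BoardItem(e["symbol"], int(e["row"]), int(e["col"]), float(e["x_cm"]), float(e["y_cm"]))
            for e in d["items"]
        )
        return cls(items=items, width_cm=float(w), height_cm=float(h))

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def read_json(cls, path) -> "LetterboardLayout":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_layout() -> LetterboardLayout:
    """Alphabetical 5-column grid on a 21.6 x 27.9 cm board.

    Rows: ABCDE / FGHIJ / KLMNO / PQRST / UVWXY / Z,!?. / DELETE DONE.
    On this grid N (row 2, col 3) and T (row 3, col 4) are diagonally
    adjacent.
    """
    rows = [
        list("ABCDE"),
        list("FGHIJ"),
        list("KLMNO"),
        list("PQRST"),
        list("UVWXY"),
        ["Z", ",", "!", "?", "."],
        [DELETE, DONE],
    ]
    width, height = 21.6, 27.9
    n_rows, n_cols = len(rows), 5
    dx, dy = width / n_cols, height / n_rows
    items = []
    for r, row in enumerate(rows):
        for c, sym in enumerate(row):
            items.append(
                BoardItem(sym, r, c, round((c + 0.5) * dx, 4), round((r + 0.5) * dy, 4))
            )
    return LetterboardLayout(items=tuple(items))


def letter_distance(a: str, b: str, layout: LetterboardLayout) -> float:
    """Physical distance in cm between two board items (symmetric)."""
    return layout.distance(a, b)
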