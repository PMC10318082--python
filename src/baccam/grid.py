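"""Binary plate images: the 8x12 bit grid and its text codec.

A standard 96-well plate (rows A-H, columns 1-12) holds one bit per well.
Text payloads of up to 12 characters are stored one character per column:
the 8-bit code point of character *j* fills column *j*, most-significant
bit in row A (``MSB_ROW_A`` is the single constant both directions share).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_ROWS = 8
N_COLS = 12
N_WELLS = N_ROWS * N_COLS

ROW_LETTERS = "ABCDEFGH"

#: Bit order within a column: row A carries the most-significant bit.
MSB_ROW_A = True


@dataclass(frozen=True, order=True)
class WellAddress:
    """A plate position, convertible between "A1" style ids and a
    row-major linear index (A1=0, A12=11, B1=12, ..., H12=95)."""

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < N_ROWS and 0 <= self.col < N_COLS):
            raise ValueError(f"well out of range: row={self.row} col={self.col}")

    @property
    def index(self) -> int:
        return N_COLS * self.row + self.col

    @property
    def well_id(self) -> str:
        return f"{ROW_LETTERS[self.row]}{self.col + 1}"

    @classmethod
    def from_index(cls, index: int) -> "WellAddress":
        if not 0 <= index < N_WELLS:
            raise ValueError(f"linear index out of range: {index}")
        return cls(index // N_COLS, index % N_COLS)

    @classmethod
    def from_well_id(cls, well_id: str) -> "WellAddress":
        s = well_id.strip().upper()
        if len(s) < 2 or s[0] not in ROW_LETTERS or not s[1:].isdigit():
            raise ValueError(f"malformed well id: {well_id!r}")
        col = int(s[1:])
        if not 1 <= col <= N_COLS:
            raise ValueError(f"column out of range in well id: {well_id!r}")
        return cls(ROW_LETTERS.index(s[0]), col - 1)


def all_wells() -> list[WellAddress]:
    """All 96 wells in row-major order (A1 ... H12)."""
    return [WellAddress.from_index(i) for i in range(N_WELLS)]


class BitGrid:
    """An 8x12 binary image, one bit per well.

    Wraps a uint8 array of shape (8, 12) with entries in {0, 1}.
    """

    __slots__ = ("values",)

    def __init__(self, values) -> None:
        arr = np.asarray(values)
        if arr.shape != (N_ROWS, N_COLS):
            raise ValueError(f"grid must be {N_ROWS}x{N_COLS}, got {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("grid entries must be 0 or 1")
        self.values = arr.astype(np.uint8)

    # -- construction -------------------------------------------------
    @classmethod
    def zeros(cls) -> "BitGrid":
        return cls(np.zeros((N_ROWS, N_COLS), dtype=np.uint8))

    @classmethod
    def ones(cls) -> "BitGrid":
        return cls(np.ones((N_ROWS, N_COLS), dtype=np.uint8))

    @classmethod
    def from_flat(cls, bits) -> "BitGrid":
        arr = np.asarray(bits)
        if arr.size != N_WELLS:
            raise ValueError(f"need {N_WELLS} bits, got {arr.size}")
        return cls(arr.reshape(N_ROWS, N_COLS))

    @classmethod
    def random(cls, rng: np.random.Generator, density: float = 0.5) -> "BitGrid":
        return cls((rng.random((N_ROWS, N_COLS)) < density).astype(np.uint8))

    # -- accessors ----------------------------------------------------
    def flat(self) -> np.ndarray:
        """Row-major 96-vector (index order matches WellAddress.index)."""
        return self.values.reshape(-1)

    def __getitem__(self, well: WellAddress) -> int:
        return int(self.values[well.row, well.col])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BitGrid) and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self):  # mutable payload; identity hashing is a trap
        raise TypeError("BitGrid is unhashable")

    def complement(self) -> "BitGrid":
        return BitGrid(1 - self.values)

    def popcount(self) -> int:
        return int(self.values.sum())

    # -- text serialization (8 lines of 12 chars from {0,1}) ----------
    def to_text_lines(self) -> str:
        return "\n".join("".join(str(b) for b in row) for row in self.values) + "\n"

    @classmethod
    def from_text_lines(cls, text: str) -> "BitGrid":
        rows = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
        if len(rows) != N_ROWS or any(len(r) != N_COLS for r in rows):
            raise ValueError("grid text must be 8 lines of 12 characters")
        if any(set(r) - {"0", "1"} for r in rows):
            raise ValueError("grid text characters must be 0 or 1")
        return cls(np.array([[int(c) for c in r] for r in rows], dtype=np.uint8))

    # -- PGM (P1 plain bitmap) interoperability -----------------------
    def to_pgm(self) -> str:
        body = "\n".join(" ".join(str(b) for b in row) for row in self.values)
        return f"P1\n{N_COLS} {N_ROWS}\n{body}\n"

    @classmethod
    def from_pgm(cls, text: str) -> "BitGrid":
        tokens: list[str] = []
        for line in text.splitlines():
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
        if not tokens or tokens[0] != "P1":
            raise ValueError("not a plain PBM/P1 bitmap")
        if len(tokens) < 3:
            raise ValueError("truncated P1 header")
        w, h = int(tokens[1]), int(tokens[2])
        if (w, h) != (N_COLS, N_ROWS):
            raise ValueError(f"P1 bitmap must be {N_COLS}x{N_ROWS}, got {w}x{h}")
        bits = [int(t) for t in tokens[3:]]
        if len(bits) != N_WELLS:
            raise ValueError("wrong number of P1 pixels")
        return cls.from_flat(bits)

    def __repr__(self) -> str:
        return f"BitGrid(popcount={self.popcount()})"


def text_to_grid(text: str) -> BitGrid:
    """Encode a payload of up to 12 characters (code points 0-255), one
    8-bit character per column, MSB in row A. Unused columns are zero."""
    if len(text) > N_COLS:
        raise ValueError(
            f"payload capacity is {N_COLS} characters, got {len(text)}"
        )
    bad = [c for c in text if ord(c) > 255]
    if bad:
        raise ValueError(f"characters outside 8-bit range: {bad!r}")
    values = np.zeros((N_ROWS, N_COLS), dtype=np.uint8)
    for j, ch in enumerate(text):
        code = ord(ch)
        for row in range(N_ROWS):
            shift = (N_ROWS - 1 - row) if MSB_ROW_A else row
            values[row, j] = (code >> shift) & 1
    return BitGrid(values)


def grid_to_text(grid: BitGrid, strip_nul: bool = True) -> str:
    """Decode a grid back to its 12-character payload (inverse of
    :func:`text_to_grid`). Trailing NUL characters are stripped by default
    so short payloads round-trip readably."""
    chars = []
    for j in range(N_COLS):
        code = 0
        for row in range(N_ROWS):
            shift = (N_ROWS - 1 - row) if MSB_ROW_A else row
            code |= int(grid.values[row, j]) << shift
        chars.append(chr(code))
    text = "".join(chars)
    return text.rstrip("\x00") if strip_nul else text


def accuracy(predicted: BitGrid, truth: BitGrid) -> float:
    """Fraction of the 96 wells called correctly (1 - normalized Hamming
    distance)."""
    return float((predicted.values == truth.values).mean())


def error_mask(predicted: BitGrid, truth: BitGrid) -> np.ndarray:
    """Boolean 8x12 mask of miscalled wells."""
    return predicted.values != truth.values
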