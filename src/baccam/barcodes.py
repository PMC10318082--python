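"""Barcode layers: per-well "well-codes" and per-image dual index pairs.

Two layers of DNA barcodes tie each sequencing read back to a pixel:

* a *well-code* — a short unique oligo identifying one of the 96 wells
  (the pixel address within a plate), and
* a dual *index pair* (i7/i5) identifying which image a read belongs to
  when several plates are pooled into one library.

Well-code sets are generated greedily from a seeded random candidate
stream, accepting a candidate only if it keeps the pairwise Hamming
distance of the set at or above ``d_min``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import N_WELLS, WellAddress, all_wells

BASES = "ACGT"

#: Sentinel returned when a barcode cannot be assigned unambiguously.
UNASSIGNED = None


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class WellCodeSet:
    """A bijection between DNA well-codes and the 96 well addresses."""

    codes: tuple[str, ...]  # codes[i] belongs to WellAddress.from_index(i)
    d_min: int = 1

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("well-codes must be distinct")
        lengths = {len(c) for c in self.codes}
        if len(lengths) > 1:
            raise ValueError("well-codes must have uniform length")
        object.__setattr__(self, "_lookup", {c: i for i, c in enumerate(self.codes)})

    @property
    def length(self) -> int:
        return len(self.codes[0])

    def __len__(self) -> int:
        return len(self.codes)

    def code_for(self, well: WellAddress) -> str:
        return self.codes[well.index]

    def well_for(self, code: str) -> WellAddress | None:
        i = self._lookup.get(code)
        return None if i is None else WellAddress.from_index(i)

    def to_tsv(self) -> str:
        rows = [
            {"sequence": self.codes[w.index], "well": w.well_id}
            for w in all_wells()[: len(self.codes)]
        ]
        return pd.DataFrame(rows).to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str, d_min: int = 1) -> "WellCodeSet":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        missing = {"sequence", "well"} - set(df.columns)
        if missing:
            raise ValueError(f"well-code TSV missing columns: {sorted(missing)}")
        codes = [""] * len(df)
        for _, row in df.iterrows():
            codes[WellAddress.from_well_id(row["well"]).index] = row["sequence"]
        if "" in codes:
            raise ValueError("well-code TSV does not cover a contiguous well range")
        return cls(tuple(codes), d_min=d_min)

    def to_fasta(self) -> str:
        out = []
        for i, code in enumerate(self.codes):
            out.append(f">{WellAddress.from_index(i).well_id}\n{code}\n")
        return "".join(out)


def generate_well_codes(
    n: int = N_WELLS,
    length: int = 10,
    d_min: int = 3,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200_000,
) -> WellCodeSet:
    """Greedy closure generation of ``n`` barcodes of the given length with
    pairwise Hamming distance >= ``d_min``. Deterministic given ``seed``.

    Raises ``ValueError`` when the candidate stream is exhausted before the
    set is filled (infeasible combination of n/length/d_min).
    """
    if n < 1 or length < 1 or d_min < 1:
        raise ValueError("n, length and d_min must be positive")
    if d_min > length:
        raise ValueError("d_min cannot exceed code length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accepted: list[str] = []
    tries = 0
    while len(accepted) < n:
        if tries >= max_tries:
            raise ValueError(
                f"barcode space exhausted: found {len(accepted)}/{n} codes of "
                f"length {length} at d_min={d_min} after {tries} candidates"
            )
        cand = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        tries += 1
        if all(hamming(cand, c) >= d_min for c in accepted):
            accepted.append(cand)
    return WellCodeSet(tuple(accepted), d_min=d_min)


_DEFAULT_CODES: WellCodeSet | None = None


def default_well_codes() -> WellCodeSet:
    """The package's default 96-well code set (length 10, d_min 3, fixed
    seed) shared by the simulator and decoder unless a TSV is supplied."""
    global _DEFAULT_CODES
    if _DEFAULT_CODES is None:
        _DEFAULT_CODES = generate_well_codes(N_WELLS, length=10, d_min=3, seed=42)
    return _DEFAULT_CODES


def match_barcode(
    observed: str,
    codes: WellCodeSet,
    max_mismatch: int = 1,
) -> WellAddress | None:
    """Assign an observed sequence to the unique well-code within
    ``max_mismatch`` substitutions; ties at the minimal distance are
    discarded (returns ``UNASSIGNED``) rather than broken arbitrarily."""
    if len(observed) != codes.length:
        raise ValueError(
            f"observed length {len(observed)} != code length {codes.length}"
        )
    exact = codes.well_for(observed)
    if exact is not None:
        return exact
    if max_mismatch == 0:
        return UNASSIGNED
    best_d = max_mismatch + 1
    best_i = -1
    tied = False
    for i, code in enumerate(codes.codes):
        d = hamming(observed, code)
        if d < best_d:
            best_d, best_i, tied = d, i, False
        elif d == best_d:
            tied = True
    if best_i < 0 or tied or best_d > max_mismatch:
        return UNASSIGNED
    return WellAddress.from_index(best_i)


@dataclass(frozen=True)
class IndexEntry:
    i7: str
    i5: str
    label: str


@dataclass(frozen=True)
class IndexTable:
    """Dual-index (i7/i5) pairs identifying images within a pooled library."""

    entries: tuple[IndexEntry, ...]

    def __post_init__(self) -> None:
        pairs = [(e.i7, e.i5) for e in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("index (i7, i5) pairs must be unique")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("image labels must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, i: int) -> IndexEntry:
        return self.entries[i]

    def by_label(self, label: str) -> IndexEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(f"no index entry labelled {label!r}")

    def to_tsv(self) -> str:
        rows = [{"i7": e.i7, "i5": e.i5, "image": e.label} for e in self.entries]
        return pd.DataFrame(rows).to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str) -> "IndexTable":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
        missing = {"i7", "i5", "image"} - set(df.columns)
        if missing:
            raise ValueError(f"index TSV missing columns: {sorted(missing)}")
        return cls(
            tuple(IndexEntry(r["i7"], r["i5"], r["image"]) for _, r in df.iterrows())
        )

    @classmethod
    def default(cls, n: int = 24) -> "IndexTable":
        """Placeholder combinatorial table of ``n`` dual-index pairs.

        Eight i7 and eight i5 sequences (8 bp, pairwise Hamming >= 3,
        generated from a fixed seed) paired combinatorially, labelled
        img01, img02, ... These stand in for commercial index kits whose
        sequences are proprietary.
        """
        if n > 64:
            raise ValueError("default table supports at most 64 pairs")
        i7s = generate_well_codes(8, length=8, d_min=3, seed=101).codes
        i5s = generate_well_codes(8, length=8, d_min=3, seed=202).codes
        entries = []
        for k in range(n):
            entries.append(
                IndexEntry(i7s[k % 8], i5s[k // 8], f"img{k + 1:02d}")
            )
        return cls(tuple(entries))


def match_index_pair(
    i7_obs: str,
    i5_obs: str,
    table: IndexTable,
    max_mismatch: int = 1,
) -> IndexEntry | None:
    """Dual-index match: both i7 and i5 must sit within ``max_mismatch`` of
    the same entry; ties on total distance are discarded."""
    best: IndexEntry | None = None
    best_d = 2 * max_mismatch + 1
    tied = False
    for e in table.entries:
        if len(i7_obs) != len(e.i7) or len(i5_obs) != len(e.i5):
            continue
        d7 = hamming(i7_obs, e.i7)
        if d7 > max_mismatch:
            continue
        d5 = hamming(i5_obs, e.i5)
        if d5 > max_mismatch:
            continue
        d = d7 + d5
        if d < best_d:
            best, best_d, tied = e, d, False
        elif d == best_d:
            tied = True
    return None if tied else best
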