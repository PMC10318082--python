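"""Read parsing: demultiplex by index, route by well-code, classify each
read as excised or intact, and build per-well/per-channel ratio tables.

The bit-state statistic is the bounded excision fraction
``n_excised / (n_excised + n_intact)`` in [0, 1] (monotone-equivalent to
the raw excised:intact quotient, but defined at zero intact counts).
Wells with zero informative coverage are reported MISSING (NaN), never 0.

Reads are structured amplicons, so classification uses fixed-offset
signature windows with a small mismatch budget rather than alignment:
the window directly after the first LoxP site holds the start of the
intervening (terminator) region in intact reads and the start of the
right flank in excised reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .barcodes import (
    IndexEntry,
    IndexTable,
    WellCodeSet,
    hamming,
    match_barcode,
    match_index_pair,
)
from .grid import N_WELLS, WellAddress, all_wells
from .simulate import (
    DEFAULT_STRUCTURE,
    LibraryStructure,
    ReadRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

CHANNELS = ("blue", "red")

#: Width of the fixed-offset signature windows.
SIGNATURE_K = 16
#: Default per-window mismatch budget.
MISMATCH_BUDGET = 2


class ReadState(Enum):
    EXCISED = "excised"
    INTACT = "intact"
    AMBIGUOUS = "ambiguous"


def _window_matches(window: str, signature: str, budget: int) -> bool:
    if len(window) != len(signature):
        return False
    if window == signature:
        return True
    return hamming(window, signature) <= budget


def detect_channel(
    sequence: str,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    budget: int = MISMATCH_BUDGET,
) -> str | None:
    """Color channel of a read: the red recording construct carries the
    spacer barcode after the well-code; blue does not (the left flank
    starts there instead). Returns None when neither signature matches."""
    off = structure.spacer_offset
    w = len(structure.spacer)
    window = sequence[off : off + w]
    is_red = _window_matches(window, structure.spacer, budget)
    is_blue = _window_matches(window, structure.left[:w], budget)
    if is_red == is_blue:  # both (impossible by design) or neither
        return None
    return "red" if is_red else "blue"


def classify_read(
    read: ReadRecord | str,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    color: str | None = None,
    budget: int = MISMATCH_BUDGET,
) -> ReadState:
    """EXCISED / INTACT / AMBIGUOUS call for one read.

    INTACT when the intervening-region signature sits after the first LoxP
    site; EXCISED when the right flank (the excision junction) does.
    AMBIGUOUS when neither or both match within the mismatch budget.
    """
    seq = read.sequence if isinstance(read, ReadRecord) else read
    if color is None:
        color = detect_channel(seq, structure, budget)
        if color is None:
            return ReadState.AMBIGUOUS
    off = structure.signature_offset(color)
    window = seq[off : off + SIGNATURE_K]
    intact = _window_matches(window, structure.intervening[:SIGNATURE_K], budget)
    excised = _window_matches(window, structure.right[:SIGNATURE_K], budget)
    if intact == excised:
        return ReadState.AMBIGUOUS
    return ReadState.INTACT if intact else ReadState.EXCISED


def classify_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    budget: int = MISMATCH_BUDGET,
) -> ReadState:
    """Paired-end classification: the locus is read from R2. The template
    3' end is loxp+right+i5 in both states; what precedes that LoxP
    distinguishes them (intervening tail = intact, left-flank tail =
    excised)."""
    tail = reverse_complement(r2.sequence)
    anchor = structure.i5_length + len(structure.right) + len(structure.loxp)
    window = tail[-(anchor + SIGNATURE_K) : -anchor]
    intact = _window_matches(window, structure.intervening[-SIGNATURE_K:], budget)
    excised = _window_matches(window, structure.left[-SIGNATURE_K:], budget)
    if intact == excised:
        return ReadState.AMBIGUOUS
    return ReadState.INTACT if intact else ReadState.EXCISED


@dataclass
class DemuxResult:
    """Per-image read sets plus everything that could not be assigned."""

    assigned: dict[str, list[ReadRecord]]
    unassigned: list[ReadRecord]
    reasons: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.assigned.values()) + len(self.unassigned)


def demultiplex(
    reads: list[ReadRecord],
    index_table: IndexTable,
    max_mismatch: int = 1,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
) -> DemuxResult:
    """Assign each read to at most one image by dual-index match (both i7
    and i5 within ``max_mismatch``; ties discarded)."""
    n7, n5 = structure.i7_length, structure.i5_length
    exact = {(e.i7, e.i5): e.label for e in index_table.entries}
    assigned: dict[str, list[ReadRecord]] = {e.label: [] for e in index_table.entries}
    unassigned: list[ReadRecord] = []
    reasons: Counter = Counter()
    for r in reads:
        seq = r.sequence
        if len(seq) < n7 + n5:
            unassigned.append(r)
            reasons["too_short"] += 1
            continue
        key = (seq[:n7], seq[-n5:])
        label = exact.get(key)
        if label is None:
            entry = match_index_pair(key[0], key[1], index_table, max_mismatch)
            label = entry.label if entry is not None else None
        if label is None:
            unassigned.append(r)
            reasons["no_index_match"] += 1
        else:
            assigned[label].append(r)
    if unassigned:
        logger.warning(
            "demultiplex: %d/%d reads unassigned (%s)",
            len(unassigned),
            len(reads),
            dict(reasons),
        )
    return DemuxResult(assigned=assigned, unassigned=unassigned, reasons=reasons)


@dataclass
class WellCounts:
    """Per-well excised/intact/ambiguous read counts for one channel."""

    channel: str
    n_excised: np.ndarray = field(
        default_factory=lambda: np.zeros(N_WELLS, dtype=np.int64)
    )
    n_intact: np.ndarray = field(
        default_factory=lambda: np.zeros(N_WELLS, dtype=np.int64)
    )
    n_ambiguous: np.ndarray = field(
        default_factory=lambda: np.zeros(N_WELLS, dtype=np.int64)
    )

    @property
    def assigned_total(self) -> int:
        return int(self.n_excised.sum() + self.n_intact.sum() + self.n_ambiguous.sum())


@dataclass
class RatioTable:
    """Per-well bounded excision fraction for one color channel.

    values[i] = n_excised / (n_excised + n_intact) for the well with
    linear index i; NaN marks MISSING wells (zero informative coverage).
    """

    channel: str
    values: np.ndarray  # float, NaN = MISSING
    coverage: np.ndarray  # int, n_excised + n_intact
    counts: WellCounts | None = None

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @classmethod
    def from_counts(cls, counts: WellCounts) -> "RatioTable":
        coverage = counts.n_excised + counts.n_intact
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(
                coverage > 0, counts.n_excised / np.maximum(coverage, 1), np.nan
            )
        return cls(
            channel=counts.channel,
            values=values.astype(float),
            coverage=coverage,
            counts=counts,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in all_wells():
            i = w.index
            rows.append(
                {
                    "well": w.well_id,
                    "channel": self.channel,
                    "n_excised": int(self.counts.n_excised[i]) if self.counts else None,
                    "n_intact": int(self.counts.n_intact[i]) if self.counts else None,
                    "n_ambiguous": (
                        int(self.counts.n_ambiguous[i]) if self.counts else None
                    ),
                    "value": self.values[i],
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def count_and_ratio(
    reads: list[ReadRecord],
    codes: WellCodeSet,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    max_mismatch: int = 1,
    budget: int = MISMATCH_BUDGET,
) -> dict[str, RatioTable]:
    """Route one image's reads to wells and build per-channel ratio tables.

    Each read is assigned by well-code (exact lookup, then nearest within
    ``max_mismatch``; ties dropped), split into blue/red by the spacer
    signature, and classified excised/intact/ambiguous. Reads that fail
    well-code or channel assignment are counted and logged, never
    double-counted.
    """
    counts = {ch: WellCounts(channel=ch) for ch in CHANNELS}
    dropped: Counter = Counter()
    off = structure.code_offset
    clen = structure.code_length
    code_exact = {c: i for i, c in enumerate(codes.codes)}
    for r in reads:
        seq = r.sequence
        code_obs = seq[off : off + clen]
        if len(code_obs) < clen:
            dropped["too_short"] += 1
            continue
        widx = code_exact.get(code_obs)
        if widx is None:
            well = match_barcode(code_obs, codes, max_mismatch)
            if well is None:
                dropped["no_well_code"] += 1
                continue
            widx = well.index
        channel = detect_channel(seq, structure, budget)
        if channel is None:
            dropped["no_channel"] += 1
            continue
        state = classify_read(seq, structure, color=channel, budget=budget)
        wc = counts[channel]
        if state is ReadState.EXCISED:
            wc.n_excised[widx] += 1
        elif state is ReadState.INTACT:
            wc.n_intact[widx] += 1
        else:
            wc.n_ambiguous[widx] += 1
    if dropped:
        logger.warning(
            "count_and_ratio: dropped %d reads (%s)",
            sum(dropped.values()),
            dict(dropped),
        )
    return {ch: RatioTable.from_counts(counts[ch]) for ch in CHANNELS}
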