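"""Synthetic recording-channel simulator.

Emulates the full physical channel between a projected light pattern and a
pooled sequencing library:

* each well holds a population of recorder cells whose excision plasmid is
  cut between two directly repeated 34-bp LoxP sites when the cell saw
  light — the *latent excision fraction* f_w of a well is drawn from a
  Beta distribution whose parameters differ by the well's true bit state
  (light-exposed wells excise most of their plasmid, dark wells almost
  none);
* per-well read depth varies (negative-binomial by default);
* each read is an amplicon following :class:`LibraryStructure`, with i.i.d.
  substitution errors;
* plates are pooled, serially diluted (Bernoulli thinning) and selectively
  re-amplified by index (random access).

The red-light recording construct carries an extra spacer barcode between
the well-code and the LoxP locus; blue reads do not, which is how the two
color channels are separated at readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import BASES, IndexEntry, WellCodeSet, hamming
from .grid import BitGrid, WellAddress, all_wells

# Canonical 34-bp LoxP recombinase recognition site.
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

# Fixed amplicon scaffold constants. Arbitrary but mutually Hamming-distant
# (verified by tests) so fixed-offset signature windows cannot collide.
UPSTREAM_PAD = "ACGGTCTTAGCACGTACTCA"
COLOR_SPACER = "CCATGGATCGTT"  # present on the red recording construct only
LEFT_FLANK = "TGGCAGTCAACTGGACGTAC"
INTERVENING = "GCTTCAGCCAAGCTAGGCAACTTTCGGATCAGGCTTCAAC"  # terminator region
RIGHT_FLANK = "ATCCGAGTTGTCAGAAGGCG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LibraryStructure:
    """Segment layout of the sequenced amplicon.

    Intact template (blue):
        i7 | pad | well-code | left | LoxP | intervening | LoxP | right | i5
    Excised template retains exactly one LoxP site (Cre excision between
    direct repeats): i7 | pad | well-code | left | LoxP | right | i5.
    Red templates insert the color spacer between well-code and left flank.
    """

    pad: str = UPSTREAM_PAD
    spacer: str = COLOR_SPACER
    left: str = LEFT_FLANK
    loxp: str = LOXP
    intervening: str = INTERVENING
    right: str = RIGHT_FLANK
    code_length: int = 10
    i7_length: int = 8
    i5_length: int = 8

    # -- offsets ------------------------------------------------------
    @property
    def code_offset(self) -> int:
        return self.i7_length + len(self.pad)

    @property
    def spacer_offset(self) -> int:
        return self.code_offset + self.code_length

    def locus_offset(self, color: str) -> int:
        extra = len(self.spacer) if color == "red" else 0
        return self.spacer_offset + extra

    def signature_offset(self, color: str) -> int:
        """Offset of the window directly after the first LoxP site: holds
        the intervening region in intact reads, the right flank in excised
        reads."""
        return self.locus_offset(color) + len(self.left) + len(self.loxp)

    # -- templates ----------------------------------------------------
    def locus(self, excised: bool) -> str:
        if excised:
            return self.left + self.loxp + self.right
        return self.left + self.loxp + self.intervening + self.loxp + self.right

    def template(
        self, i7: str, well_code: str, i5: str, color: str, excised: bool
    ) -> str:
        if color not in ("blue", "red"):
            raise ValueError(f"color must be 'blue' or 'red', got {color!r}")
        spacer = self.spacer if color == "red" else ""
        return i7 + self.pad + well_code + spacer + self.locus(excised) + i5

    def read_length(self, color: str, excised: bool) -> int:
        return (
            self.i7_length
            + len(self.pad)
            + self.code_length
            + (len(self.spacer) if color == "red" else 0)
            + len(self.locus(excised))
            + self.i5_length
        )


DEFAULT_STRUCTURE = LibraryStructure()


_QUAL_CACHE: dict[int, str] = {}


def _placeholder_quality(n: int) -> str:
    q = _QUAL_CACHE.get(n)
    if q is None:
        q = _QUAL_CACHE[n] = "?" * n
    return q


@dataclass(slots=True)
class ReadRecord:
    """A sequencing read; quality is a constant placeholder (Q30)."""

    name: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            # shared placeholder string keeps multi-million-read pools small
            self.quality = _placeholder_quality(len(self.sequence))


FractionModel = float | tuple[float, float]


@dataclass(frozen=True)
class ChannelParams:
    """Noise model of the recording channel.

    f_on / f_off: latent excision-fraction model for light-exposed ('1')
    and dark ('0') wells. A (a, b) tuple is a Beta(a, b) distribution; a
    bare float is a point mass (degenerate, noiseless channel). The
    channel is separable only when E[f_on] > E[f_off].

    depth_mean / depth_dispersion: per-well read count. Dispersion r > 0
    gives a negative binomial with mean depth_mean and size r; ``inf``
    gives Poisson; ``None`` a fixed depth.

    sub_error_rate: i.i.d. per-base substitution probability.
    """

    f_on: FractionModel = (9.0, 1.0)
    f_off: FractionModel = (1.0, 9.0)
    depth_mean: float = 500.0
    depth_dispersion: float | None = 5.0
    sub_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in (("f_on", self.f_on), ("f_off", self.f_off)):
            if isinstance(f, tuple):
                if len(f) != 2 or f[0] <= 0 or f[1] <= 0:
                    raise ValueError(f"{name}: Beta parameters must be positive")
            elif not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}: point mass must lie in [0, 1]")
        if self.mean_fraction(self.f_on) <= self.mean_fraction(self.f_off):
            raise ValueError("channel not separable: need E[f_on] > E[f_off]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0.0 <= self.sub_error_rate < 1.0:
            raise ValueError("sub_error_rate must be in [0, 1)")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive (or None)")

    @staticmethod
    def mean_fraction(f: FractionModel) -> float:
        if isinstance(f, tuple):
            return f[0] / (f[0] + f[1])
        return float(f)


def _draw_fraction(f: FractionModel, rng: np.random.Generator) -> float:
    if isinstance(f, tuple):
        return float(rng.beta(f[0], f[1]))
    return float(f)


def _draw_depth(params: ChannelParams, rng: np.random.Generator) -> int:
    m, r = params.depth_mean, params.depth_dispersion
    if r is None:
        return int(round(m))
    if np.isinf(r):
        return int(rng.poisson(m))
    p = r / (r + m)
    return int(rng.negative_binomial(r, p))


def _apply_substitutions(
    seq: str, n_subs: int, rng: np.random.Generator
) -> str:
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class PlateSimulation:
    """Reads plus the ground-truth sidecar of one simulated plate."""

    reads: list[ReadRecord]
    latent: pd.DataFrame  # columns: well, bit, latent_fraction, depth
    label: str
    color: str

    def latent_tsv(self) -> str:
        return self.latent.to_csv(sep="\t", index=False)


def simulate_plate(
    truth: BitGrid,
    params: ChannelParams,
    codes: WellCodeSet,
    index: IndexEntry,
    color: str = "blue",
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    seed: int | None = None,
) -> PlateSimulation:
    """Simulate sequencing reads for one plate exposed to ``truth``.

    For each well: draw the latent excision fraction from f_on or f_off
    according to the true bit, draw a read depth, emit that many reads
    (each excised with probability f_w) with substitution errors.
    """
    if len(codes) != 96:
        raise ValueError("simulate_plate needs a full 96-well code set")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    reads: list[ReadRecord] = []
    sidecar = []
    serial = 0
    e = params.sub_error_rate
    for well in all_wells():
        bit = truth[well]
        f_w = _draw_fraction(params.f_on if bit else params.f_off, rng)
        depth = _draw_depth(params, rng)
        code = codes.code_for(well)
        templates = {
            True: structure.template(index.i7, code, index.i5, color, excised=True),
            False: structure.template(index.i7, code, index.i5, color, excised=False),
        }
        if depth > 0:
            excised_flags = rng.random(depth) < f_w
            if e > 0:
                sub_counts = {
                    exc: rng.binomial(len(templates[exc]), e, size=depth)
                    for exc in (True, False)
                }
            for i in range(depth):
                exc = bool(excised_flags[i])
                seq = templates[exc]
                if e > 0 and sub_counts[exc][i] > 0:
                    seq = _apply_substitutions(seq, int(sub_counts[exc][i]), rng)
                reads.append(ReadRecord(f"{index.label}_{serial}", seq))
                serial += 1
        sidecar.append(
            {
                "well": well.well_id,
                "bit": bit,
                "latent_fraction": f_w,
                "depth": depth,
            }
        )
    return PlateSimulation(
        reads=reads,
        latent=pd.DataFrame(sidecar),
        label=index.label,
        color=color,
    )


def make_paired(
    record: ReadRecord,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    r1_length: int = 60,
    r2_length: int = 80,
) -> tuple[ReadRecord, ReadRecord]:
    """Split a full-template read into a dual-index paired-end pair:
    R1 from the 5' end (index + well-code + spacer), R2 the reverse
    complement of the 3' end (LoxP locus + i5)."""
    seq = record.sequence
    r1 = seq[:r1_length]
    r2 = reverse_complement(seq[-r2_length:])
    return (
        ReadRecord(record.name + "/1", r1),
        ReadRecord(record.name + "/2", r2),
    )


def pool_images(
    read_sets: list[list[ReadRecord]], seed: int = 0
) -> list[ReadRecord]:
    """Pool several plates' reads into one shuffled library."""
    if not read_sets:
        raise ValueError("need at least one read set to pool")
    pooled: list[ReadRecord] = []
    for rs in read_sets:
        pooled.extend(rs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pooled))
    return [pooled[i] for i in order]


def dilute(
    pool: list[ReadRecord], factor: float, seed: int = 0
) -> list[ReadRecord]:
    """Tenfold-style serial dilution: each read survives independently with
    probability 1/factor."""
    if factor < 1:
        raise ValueError("dilution factor must be >= 1")
    if factor == 1:
        return list(pool)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pool)) < 1.0 / factor
    return [r for r, k in zip(pool, keep) if k]


def random_access(
    pool: list[ReadRecord],
    target_index: IndexEntry,
    amplification: float = 1.0,
    off_target_rate: float = 0.0,
    seed: int = 0,
    structure: LibraryStructure = DEFAULT_STRUCTURE,
    max_mismatch: int = 1,
) -> list[ReadRecord]:
    """Selective re-amplification of one image from a pooled library.

    Reads whose in-line i7/i5 both sit within ``max_mismatch`` of the
    target index are resampled with replacement to ``amplification`` times
    their count; other reads persist with probability ``off_target_rate``
    (carry-over). Emulates index-specific PCR before re-sequencing.
    """
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    if not 0.0 <= off_target_rate <= 1.0:
        raise ValueError("off_target_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n7, n5 = structure.i7_length, structure.i5_length
    on_target: list[ReadRecord] = []
    carried: list[ReadRecord] = []
    for r in pool:
        seq = r.sequence
        if len(seq) < n7 + n5:
            continue
        i7_obs, i5_obs = seq[:n7], seq[-n5:]
        hit = (
            i7_obs == target_index.i7 and i5_obs == target_index.i5
        ) or (
            hamming(i7_obs, target_index.i7) <= max_mismatch
            and hamming(i5_obs, target_index.i5) <= max_mismatch
        )
        if hit:
            on_target.append(r)
        elif off_target_rate > 0 and rng.random() < off_target_rate:
            carried.append(r)
    if not on_target:
        warnings.warn(
            f"random_access: no reads match index {target_index.label!r}; "
            "returning carry-over only",
            stacklevel=2,
        )
        amplified: list[ReadRecord] = []
    else:
        n_out = int(round(amplification * len(on_target)))
        picks = rng.integers(0, len(on_target), size=n_out)
        amplified = [on_target[i] for i in picks]
    out = amplified + carried
    order = rng.permutation(len(out))
    return [out[i] for i in order]
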