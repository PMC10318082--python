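"""File formats and run configuration.

FASTQ (optionally gzipped, autodetected by extension) via Biopython;
grid text / PGM; TSV tables via pandas; JSON decode reports. A master
seed fans out to per-stage seeds by stable hashing of stage names, so
each pipeline stage is independently reproducible.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .grid import BitGrid
from .simulate import ReadRecord


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse a FASTQ file into ReadRecords (gzip ok)."""
    records = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            records.append(ReadRecord(rec.id, str(rec.seq), qual))
    return records


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = [
                ord(c) - 33 for c in r.quality
            ]
            SeqIO.write(rec, fh, "fastq")


def read_grid(path: str | Path) -> BitGrid:
    text = Path(path).read_text()
    if text.lstrip().startswith("P1"):
        return BitGrid.from_pgm(text)
    return BitGrid.from_text_lines(text)


def write_grid(grid: BitGrid, path: str | Path, pgm: bool = False) -> None:
    Path(path).write_text(grid.to_pgm() if pgm else grid.to_text_lines())


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed by stable hashing of
    the stage name (CRC32), keeping the result below 2**31."""
    return (zlib.crc32(stage.encode("utf-8")) ^ (master_seed & 0x7FFFFFFF)) % (
        2**31
    )


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    seed: int = 0
    color: str = "blue"
    # channel
    f_on: list[float] | float = field(default_factory=lambda: [9.0, 1.0])
    f_off: list[float] | float = field(default_factory=lambda: [1.0, 9.0])
    depth_mean: float = 500.0
    depth_dispersion: float | None = 5.0
    sub_error_rate: float = 0.001
    # barcodes
    code_length: int = 10
    d_min: int = 3
    # readout
    max_mismatch: int = 1
    mismatch_budget: int = 2
    # deconvolution
    method: str = "gmm"
    k: int = 3
    eps: float = 0.2
    min_samples: int = 5
    xi: float = 0.05
    n_neighbors: int | None = None
    contamination: float = 0.05
    cutoff: float = 0.5
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fraction(self, which: str):
        f = self.f_on if which == "on" else self.f_off
        return tuple(f) if isinstance(f, (list, tuple)) else float(f)
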