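"""Named benchmark patterns.

The study's benchmark set comprises four picture patterns (NUS, SYNCTI,
BACCAM, SMILEY) and one text payload ("Heloo wo{|d!"). The original
pixel art is not reproduced here; each name is rendered to a plate via
the text codec, which preserves what matters for the decoding benchmarks
(distinct, mixed-density 96-bit patterns). The text payload is the
original one.
"""

from __future__ import annotations

from .grid import BitGrid, text_to_grid

HELLO_PAYLOAD = "Heloo wo{|d!"

PATTERN_NAMES = ("NUS", "SYNCTI", "BACCAM", "SMILEY", HELLO_PAYLOAD)


def named_pattern(name: str) -> BitGrid:
    """BitGrid for one of the five benchmark patterns (rendered via the
    text codec)."""
    if name not in PATTERN_NAMES:
        raise KeyError(f"unknown pattern {name!r}; choose from {PATTERN_NAMES}")
    return text_to_grid(name)


def benchmark_patterns() -> dict[str, BitGrid]:
    return {name: named_pattern(name) for name in PATTERN_NAMES}
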