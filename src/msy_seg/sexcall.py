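"""Read-level sex inference from Y-marker (Sry coding) sequence.

A sample is called female only when zero reads carry any Y-marker probe;
any Sry evidence at all classifies the sample as male-class, so that
male-contaminated female libraries are treated as males downstream —
their reads can carry MSY-derived alleles with the same probability as
Sry sequence itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._seq import check_dna, revcomp

FEMALE = "female"
MALE_CLASS = "male_class"


@dataclass(frozen=True)
class SexCall:
    sample: str
    y_marker_reads: int
    inferred_class: str
    declared_sex: str | None = None

    def __post_init__(self) -> None:
        if self.y_marker_reads < 0:
            raise ValueError("y_marker_reads must be >= 0")
        expected = FEMALE if self.y_marker_reads == 0 else MALE_CLASS
        if self.inferred_class != expected:
            raise ValueError(
                f"inferred_class {self.inferred_class!r} inconsistent with "
                f"{self.y_marker_reads} marker reads"
            )


def infer_sex(
    reads: Iterable[str],
    probes: Sequence[str],
    sample: str = "sample",
    declared_sex: str | None = None,
) -> SexCall:
    """Count reads containing any probe (either strand, exact match).

    The male-class threshold is a single marker read: any Sry evidence
    is taken as male-class, with no minimum count.
    """
    probes = [check_dna(p, "probe") for p in probes]
    if not probes:
        raise ValueError("probe set must be non-empty")
    needles = set(probes) | {revcomp(p) for p in probes}
    hits = 0
    for read in reads:
        read = read.upper()
        if any(n in read for n in needles):
            hits += 1
    cls = FEMALE if hits == 0 else MALE_CLASS
    return SexCall(sample=sample, y_marker_reads=hits, inferred_class=cls, declared_sex=declared_sex)
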