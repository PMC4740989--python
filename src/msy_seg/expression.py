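"""Copy-specific transcript quantification via marker probes.

Reads carrying a copy-identifying probe (exact match, either strand) are
counted once per read, normalized to reads per million (RPM) of the
dataset, and compared between a Y-borne copy and its X/autosomal
homolog as a Y-fraction.  The distinguishability analysis determines
which gene copies can be identified at all with reads of a given
length: a copy with no read-length window carrying a variant
combination unique to it is reported "nd" (not determined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import check_dna, revcomp
from .mapping import MarkerProbe

DETERMINABLE = "determinable"
ND = "nd"


@dataclass
class ExpressionRecord:
    dataset_id: str
    tissue: str | None
    sex: str | None
    total_reads: int
    hits: dict[str, int]

    def rpm_table(self) -> dict[str, float]:
        return {k: rpm(v, self.total_reads) for k, v in self.hits.items()}


def count_marker_hits(reads: Sequence[str], probe: MarkerProbe | str) -> int:
    """Number of reads containing the probe or its reverse complement.

    A read containing the probe more than once still counts once: the
    unit is positive reads, not matches.  The exact-substring criterion
    guarantees every counted read carries all identifying SNVs.
    """
    seq = probe.sequence if isinstance(probe, MarkerProbe) else probe
    seq = check_dna(seq, "probe")
    reads = [r.upper() for r in reads]
    if reads and len(seq) > max(len(r) for r in reads):
        raise ValueError(
            f"probe ({len(seq)} nt) is longer than every read; it cannot be contained"
        )
    rc = revcomp(seq)
    return sum(1 for r in reads if seq in r or rc in r)


def rpm(hits: int, total_reads: int) -> float:
    """Reads per million: hits / total_reads * 1e6."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if hits < 0:
        raise ValueError("hits must be >= 0")
    return hits / total_reads * 1e6


def y_fraction(y_hits: int, homolog_hits: int) -> float | None:
    """Y-copy share of transcripts: y / (y + homolog); None when both zero.

    0.5 means a 50/50 transcript ratio between the MSY copy and its
    X/autosomal homolog; 0 means homolog-only expression.
    """
    if y_hits < 0 or homolog_hits < 0:
        raise ValueError("hit counts must be >= 0")
    total = y_hits + homolog_hits
    if total == 0:
        return None
    return y_hits / total


def copy_profile(
    datasets: Mapping[str, Sequence[str]],
    probes: Mapping[str, MarkerProbe | str],
    focal_copy: str = "Sry2",
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-dataset per-copy RPM with focal / non-focal classification.

    ``datasets`` maps dataset id to its read set; ``totals`` overrides
    the library size (defaults to the number of reads supplied).  A
    dataset is classified non-focal-expressing iff any probe other than
    the focal copy's has RPM > 0.
    """
    if focal_copy not in probes:
        raise ValueError(f"focal copy {focal_copy!r} absent from probe panel")
    rows = []
    for ds_id, reads in datasets.items():
        total = totals[ds_id] if totals is not None else len(reads)
        row: dict[str, object] = {"dataset": ds_id}
        hit_counts = {copy: count_marker_hits(reads, p) for copy, p in probes.items()}
        for copy, h in hit_counts.items():
            row[copy] = rpm(h, total) if total > 0 else 0.0
        focal_hits = hit_counts[focal_copy]
        nonfocal_hits = sum(h for c, h in hit_counts.items() if c != focal_copy)
        row["focal_only"] = focal_hits > 0 and nonfocal_hits == 0
        row["non_focal_expressing"] = nonfocal_hits > 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


def distinguishability(
    panel: Mapping[str, Mapping[int, str]],
    read_length: int,
    all_positions: Iterable[int] | None = None,
) -> dict[str, str]:
    """Which copies are identifiable with reads of ``read_length``.

    ``panel`` maps copy name to {position: allele} on a shared
    coordinate frame (positions absent from a copy's map carry the
    reference allele).  A copy is "nd" iff no window of at most
    ``read_length`` bases contains a variant combination unique to that
    copy, i.e. for every window some other copy shows the identical
    allele pattern over the variant positions it covers.
    """
    if not panel:
        raise ValueError("copy panel must be non-empty")
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    positions = set(all_positions or [])
    for variants in panel.values():
        positions.update(variants)
    ordered = sorted(positions)

    def profile(copy: str, window: Sequence[int]) -> tuple:
        return tuple(panel[copy].get(p, "ref") for p in window)

    status: dict[str, str] = {}
    for copy in panel:
        others = [c for c in panel if c != copy]
        determinable = False
        for i in range(len(ordered)):
            for j in range(i, len(ordered)):
                window = ordered[i : j + 1]
                if window[-1] - window[0] + 1 > read_length:
                    break
                mine = profile(copy, window)
                if all(profile(other, window) != mine for other in others):
                    determinable = True
                    break
            if determinable:
                break
        status[copy] = DETERMINABLE if (determinable or not others) else ND
    return status
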