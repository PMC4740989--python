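"""Localizing duplicated genes on MSY contigs and classifying them.

Male-specific SNVs are chained into clusters (two or more within 20
bases), turned into marker probes that carry the alternate alleles, and
searched exactly (both strands) against MSY contig sequence.  The
mechanism of duplication is then read off the locus: a retroposed copy
is the spliced mRNA reinserted without introns, a transposed copy keeps
the source gene's introns, a partial transposition carries only a
proper subset of exons, and an MSY-native gene that spawned the
autosomal homolog is flagged from the annotation.  Pseudogene status
joins ORF integrity with marker expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._seq import check_dna, find_all, revcomp, translate

DEFAULT_MAX_GAP = 20
MIN_PROBE_LENGTH = 24
DEFAULT_RPM_THRESHOLD = 0.01

RETROPOSED = "retroposed"
TRANSPOSED = "transposed"
PARTIAL_TRANSPOSED = "partial_transposed"
MSY_DUPLICATION = "msy_duplication"
UNPLACED = "unplaced"

FUNCTIONAL = "functional"
PSEUDOGENE = "pseudogene"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class MarkerProbe:
    """A short sequence carrying one or more copy-identifying SNVs.

    SNVs are placed in the middle or on the ends of the sequence so any
    exact match of the probe necessarily covers every identifying SNV.
    """

    probe_id: str
    sequence: str
    snv_offsets: tuple[int, ...]
    placement: str = "middle"
    source_gene: str | None = None

    def __post_init__(self) -> None:
        check_dna(self.sequence, f"probe {self.probe_id}")
        if len(self.sequence) < MIN_PROBE_LENGTH:
            raise ValueError(
                f"probe {self.probe_id} is {len(self.sequence)} nt; "
                f"probes must be >= {MIN_PROBE_LENGTH} nt"
            )
        for off in self.snv_offsets:
            if not 0 <= off < len(self.sequence):
                raise ValueError(f"SNV offset {off} outside probe {self.probe_id}")


@dataclass
class DuplicationCall:
    gene: str
    msy_contig: str | None
    msy_position: int | None
    mechanism: str
    pseudogene: str = INDETERMINATE
    hits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.mechanism == UNPLACED) != (self.msy_contig is None):
            raise ValueError("mechanism 'unplaced' iff msy_contig is None")


def cluster_snvs(
    positions: Sequence[tuple[str, int]], max_gap: int = DEFAULT_MAX_GAP
) -> list[list[tuple[str, int]]]:
    """Chain same-chromosome SNVs with inter-site gap <= max_gap.

    Chaining is transitive single-linkage (a 3-SNV run at 18-base
    spacings is one cluster); singleton chains are discarded, keeping
    only clusters of two or more SNVs.
    """
    ordered = sorted(set(positions))
    clusters: list[list[tuple[str, int]]] = []
    current: list[tuple[str, int]] = []
    for site in ordered:
        if current and site[0] == current[-1][0] and site[1] - current[-1][1] <= max_gap:
            current.append(site)
        else:
            if len(current) >= 2:
                clusters.append(current)
            current = [site]
    if len(current) >= 2:
        clusters.append(current)
    return clusters


def build_probe(
    context: str,
    context_start: int,
    cluster_positions: Sequence[int],
    alt_alleles: Sequence[str],
    flank: int = 12,
    placement: str = "middle",
    probe_id: str = "probe",
    source_gene: str | None = None,
) -> MarkerProbe:
    """Build a marker probe around a cluster, substituting alternate alleles.

    ``context`` is reference sequence beginning at 1-based coordinate
    ``context_start`` on the same chromosome as ``cluster_positions``.
    placement="middle" centers the cluster with ``flank`` bases on each
    side; placement="ends" puts the outermost (first) SNV at the probe
    boundary and extends 2*flank beyond the last SNV.
    """
    if placement not in ("middle", "ends"):
        raise ValueError(f"placement must be 'middle' or 'ends', got {placement!r}")
    if len(cluster_positions) != len(alt_alleles):
        raise ValueError("one alternate allele per cluster position required")
    positions = list(cluster_positions)
    first, last = min(positions), max(positions)
    if placement == "middle":
        start, end = first - flank, last + flank
    else:
        start, end = first, last + 2 * flank
    if start < context_start or end > context_start + len(context) - 1:
        raise ValueError(
            f"context [{context_start}, {context_start + len(context) - 1}] too short "
            f"for probe span [{start}, {end}]"
        )
    seq = list(context[start - context_start : end - context_start + 1].upper())
    offsets = []
    for pos, alt in zip(positions, alt_alleles):
        off = pos - start
        seq[off] = check_dna(alt, "alt allele")
        offsets.append(off)
    return MarkerProbe(
        probe_id=probe_id,
        sequence="".join(seq),
        snv_offsets=tuple(offsets),
        placement=placement,
        source_gene=source_gene,
    )


def locate_on_msy(
    probe: MarkerProbe | str, contigs: Mapping[str, str]
) -> list[tuple[str, int, str]]:
    """Exact hits of probe (and reverse complement) on MSY contigs.

    Returns (contig, 1-based position, strand) tuples; an empty list
    means the probe is absent and the gene is reported unplaced.
    """
    seq = probe.sequence if isinstance(probe, MarkerProbe) else probe
    seq = check_dna(seq, "probe")
    if not contigs:
        raise ValueError("MSY contig set must be non-empty")
    rc = revcomp(seq)
    hits: list[tuple[str, int, str]] = []
    for name in contigs:
        contig = contigs[name].upper()
        for start in find_all(contig, seq):
            hits.append((name, start + 1, "+"))
        if rc != seq:
            for start in find_all(contig, rc):
                hits.append((name, start + 1, "-"))
    return hits


def locate_template(
    template: str, contigs: Mapping[str, str], max_mismatches: int = 0
) -> tuple[str, int, int, str, int] | None:
    """Best approximate occurrence of a template on the contigs.

    Returns (contig, 0-based start, 0-based inclusive end, strand, edit
    distance) of the lowest-distance infix alignment within
    ``max_mismatches`` edits (both strands), or None.  With
    ``max_mismatches=0`` this reduces to exact substring search.
    """
    template = check_dna(template, "template")
    best: tuple[str, int, int, str, int] | None = None
    if max_mismatches == 0:
        for name in contigs:
            contig = contigs[name].upper()
            for seq, strand in ((template, "+"), (revcomp(template), "-")):
                starts = find_all(contig, seq)
                if starts:
                    return (name, starts[0], starts[0] + len(seq) - 1, strand, 0)
        return None
    import edlib

    for name in contigs:
        contig = contigs[name].upper()
        for seq, strand in ((template, "+"), (revcomp(template), "-")):
            res = edlib.align(seq, contig, mode="HW", task="locations", k=max_mismatches)
            if res["editDistance"] == -1:
                continue
            start, end = res["locations"][0]
            cand = (name, start, end, strand, res["editDistance"])
            if best is None or cand[4] < best[4]:
                best = cand
    return best


def _found(template: str, contigs: Mapping[str, str], max_mismatches: int = 0) -> bool:
    return locate_template(template, contigs, max_mismatches) is not None


def classify_mechanism(
    exon_seqs: Sequence[str],
    intron_seqs: Sequence[str],
    contigs: Mapping[str, str],
    source_on_msy: bool = False,
    placed: bool = True,
    max_mismatches: int = 0,
) -> str:
    """Classify the duplication mechanism from the MSY locus content.

    ``exon_seqs``/``intron_seqs`` are the source gene's sequences with
    the male-specific alternate alleles applied (the Y-borne copy carries
    them).  Intronless source genes cannot discriminate retro- from
    transposition; the tie is broken to retroposed with a warning.
    """
    if not placed:
        raise ValueError("cannot classify an unplaced locus; call unplaced upstream")
    if source_on_msy:
        return MSY_DUPLICATION
    exon_seqs = [check_dna(e, "exon") for e in exon_seqs]
    intron_seqs = [check_dna(i, "intron") for i in intron_seqs]
    k = max_mismatches
    spliced = "".join(exon_seqs)
    if not intron_seqs:
        if _found(spliced, contigs, k):
            warnings.warn(
                "intronless source gene: retro- vs transposition indistinguishable; "
                "defaulting to retroposed",
                stacklevel=2,
            )
            return RETROPOSED
    else:
        genomic_parts = [exon_seqs[0]]
        for intron, exon in zip(intron_seqs, exon_seqs[1:]):
            genomic_parts.extend([intron, exon])
        genomic = "".join(genomic_parts)
        if _found(genomic, contigs, k):
            return TRANSPOSED
        if _found(spliced, contigs, k):
            return RETROPOSED
    n_present = sum(_found(e, contigs, k) for e in exon_seqs)
    if 0 < n_present < len(exon_seqs):
        return PARTIAL_TRANSPOSED
    if n_present == len(exon_seqs):
        # all exons individually present but neither template contiguous
        return PARTIAL_TRANSPOSED
    raise ValueError("no exon of the source gene found at the MSY locus")


def assess_pseudogene(
    orf_seq: str,
    expression_rpm: float,
    rpm_threshold: float = DEFAULT_RPM_THRESHOLD,
) -> str:
    """Joint pseudogene call from ORF integrity and marker expression.

    A premature stop in the translated MSY ORF combined with expression
    below ``rpm_threshold`` (reads per million) calls a pseudogene; an
    intact ORF with expression at or above it calls a functional copy;
    conflicting evidence is indeterminate.  ORFs whose length is not a
    multiple of three are handled by scanning the three frames and
    keeping the one with the fewest internal stops.
    """
    if expression_rpm < 0:
        raise ValueError("expression RPM must be >= 0")
    orf_seq = check_dna(orf_seq, "ORF")
    if len(orf_seq) % 3 == 0:
        frames = [0]  # in-frame coding sequence: read as given
    else:
        frames = [0, 1, 2]  # ambiguous frame: keep the cleanest one
    internal_stops = []
    for frame in frames:
        protein = translate(orf_seq[frame:])
        internal_stops.append(protein[:-1].count("*") if protein else 0)
    premature_stop = min(internal_stops) > 0
    expressed = expression_rpm >= rpm_threshold
    if premature_stop and not expressed:
        return PSEUDOGENE
    if not premature_stop and expressed:
        return FUNCTIONAL
    return INDETERMINATE
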