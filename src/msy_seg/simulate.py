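"""Synthetic genome panels, read sets, and phenotype tables.

The generator emulates the statistical structure the downstream stages
assume, with full ground truth, so every stage runs and is testable
without external data:

* a panel of male, female, and male-contaminated-female whole-genome
  samples with per-site read counts at fixed coverage;
* duplication marker sites whose alternate reads in males are drawn
  Binomial(coverage, p) with p = c/(c+2) for an autosomal source and
  c/(c+1) for an X-linked source of a gene with ``c`` MSY-borne copies,
  and zero alternate reads in females;
* strain-private background SNVs at a per-Mb rate, elevated on the MSY
  by a configurable multiplier (ground truth for the density fold);
* MSY contigs ("BAC"-like, one per duplicated gene) carrying the
  inserted copy — spliced for retroposed genes, intron-bearing for
  transposed genes, a proper exon subset for partial transpositions —
  with the marker alternate alleles embedded;
* DNA read sets per sample for Sry-based sex inference (contaminated
  females carry a trace fraction of marker reads);
* RNA-like read sets whose copy-specific marker content follows
  configurable expression weights;
* long-format phenotype tables with configurable strain and sex effects.

Randomness flows from one top-level seed through deterministic
per-stage substreams keyed by stage name, so stages rerun independently
reproduce byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .errors import ConfigurationError
from .segregation import VariantTable, expected_duplication_af

BASES = np.array(list("ACGT"))

# all 61 non-stop codons, for building ORFs that stay open in frame 0
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

MECHANISMS = ("retroposed", "transposed", "partial_transposed", "msy_duplication")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic substream for a named stage of the simulation."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class DuplicatedGeneSpec:
    """Ground-truth description of one gene duplicated onto the MSY."""

    gene: str
    origin_chromosome: str
    origin_kind: str = "autosome"  # autosome | chrX
    y_copy_number: int = 1
    mechanism: str = "retroposed"
    n_marker_snvs: int = 10
    strains_lacking: frozenset = frozenset()
    expressed: bool = False
    premature_stop: bool = False
    expression_weight: float = 0.0
    n_exons: int = 3

    def __post_init__(self) -> None:
        if self.origin_kind not in ("autosome", "chrX"):
            raise ConfigurationError(f"origin_kind: invalid value {self.origin_kind!r}")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"mechanism: invalid value {self.mechanism!r}")
        if self.y_copy_number < 0:
            raise ConfigurationError("y_copy_number: must be >= 0")
        if self.n_marker_snvs < 0:
            raise ConfigurationError("n_marker_snvs: must be >= 0")
        if self.n_exons < 2 and self.mechanism in ("transposed", "partial_transposed"):
            raise ConfigurationError("n_exons: intron-bearing mechanisms need >= 2 exons")
        if self.expressed and self.expression_weight <= 0:
            raise ConfigurationError("expression_weight: expressed genes need weight > 0")

    @property
    def expected_af(self) -> float:
        return expected_duplication_af(self.origin_kind, self.y_copy_number)

    @property
    def expected_status(self) -> str:
        if self.premature_stop and not self.expressed:
            return "pseudogene"
        if not self.premature_stop and self.expressed:
            return "functional"
        return "indeterminate"


@dataclass(frozen=True)
class SryCopySpec:
    """One Sry paralog on the shared coordinate frame."""

    name: str
    variant_offsets: tuple = ()  # ((offset, alt_base), ...)
    expression_weight: float = 0.0


@dataclass(frozen=True)
class PhenotypeEffect:
    """Generative model for one phenotype/treatment across strains."""

    phenotype: str
    treatment: str
    baseline: float
    strain_effects: Mapping[str, float]
    sex_effects: Mapping[str, float] | float = 0.0
    noise_sd: float = 1.0
    n_per_group: int = 10

    def sex_effect(self, strain: str) -> float:
        if isinstance(self.sex_effects, Mapping):
            return float(self.sex_effects.get(strain, 0.0))
        return float(self.sex_effects)


def default_duplicated_genes() -> list[DuplicatedGeneSpec]:
    """A ten-gene panel mirroring the published mechanism mix.

    Seven retroposed genes, one multi-copy transposed gene, one partial
    transposition, and one MSY-native duplication; one gene lacking in
    strain FHL; one pseudogene with a premature stop and no expression;
    two expressed functional copies.
    """
    return [
        DuplicatedGeneSpec("Ect2", "chr2", n_marker_snvs=25),
        DuplicatedGeneSpec(
            "Ube2q2", "chr8", n_marker_snvs=16, expressed=True, expression_weight=0.25
        ),
        DuplicatedGeneSpec("Havcr2", "chr10", n_marker_snvs=33),
        DuplicatedGeneSpec("Limd2", "chr10", n_marker_snvs=40, premature_stop=True),
        DuplicatedGeneSpec("RGD1560580", "chr12", mechanism="msy_duplication", n_marker_snvs=4),
        DuplicatedGeneSpec(
            "Xpr1", "chr13", mechanism="transposed", y_copy_number=4, n_marker_snvs=24
        ),
        DuplicatedGeneSpec("Prrc2c", "chr13", n_marker_snvs=2),
        DuplicatedGeneSpec("Vom2r67", "chr14", n_marker_snvs=5),
        DuplicatedGeneSpec("Lsm1", "chr16", mechanism="partial_transposed", n_marker_snvs=5),
        DuplicatedGeneSpec(
            "Med14",
            "chrX",
            origin_kind="chrX",
            n_marker_snvs=33,
            strains_lacking=frozenset({"FHL"}),
            expressed=True,
            expression_weight=0.20,
        ),
    ]


def default_sry_panel() -> list[SryCopySpec]:
    """Four Sry paralogs; Sry3 shares all its variants with Sry3BI and
    is therefore indistinguishable ("nd") at short read lengths."""
    return [
        SryCopySpec("Sry1", ((100, "T"),), 0.05),
        SryCopySpec("Sry2", ((250, "A"),), 0.60),
        SryCopySpec("Sry3", ((400, "C"),), 0.0),
        SryCopySpec("Sry3BI", ((400, "C"), (560, "G")), 0.05),
    ]


def default_phenotype_effects() -> list[PhenotypeEffect]:
    strains = {"BN": 0.0, "FHH": 0.0, "FHH-YBN": 0.0}
    return [
        PhenotypeEffect(
            "Body weight (kg)",
            "21 % O2, 0.4 % salt",
            baseline=0.30,
            strain_effects={**strains, "FHH-YBN": 0.06},
            sex_effects=0.05,
            noise_sd=0.01,
        ),
        PhenotypeEffect(
            "Plasma hematocrit (%)",
            "21 % O2, 0.4 % salt",
            baseline=45.0,
            strain_effects={**strains, "FHH-YBN": 4.0},
            sex_effects={"BN": 5.0},
            noise_sd=1.0,
        ),
        PhenotypeEffect(
            "Plasma lymph abs (E3)",
            "12 % O2, 0.4 % salt",
            baseline=6.0,
            strain_effects={**strains, "FHH-YBN": 2.0},
            sex_effects={"FHH": 2.5, "FHH-YBN": 2.5},
            noise_sd=0.5,
        ),
        PhenotypeEffect(
            "Plasma sodium (mmol/L)",
            "21 % O2, 0.4 % salt",
            baseline=140.0,
            strain_effects=strains,
            sex_effects=0.0,
            noise_sd=2.0,
        ),
    ]


_DEFAULT_MALE_STRAINS = ("ACI", "FHH", "FHL", "SBH", "SBN", "SR", "SS")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic panel; the defaults are the study
    conditions the package is tested under (a 23-genome panel with 18
    male-class samples, ~2x MSY SNV density, the ten-gene duplication
    panel)."""

    n_male_samples: int = 16
    n_female_samples: int = 5
    n_contaminated_females: int = 2
    coverage: int = 30
    chromosome_lengths: Mapping[str, float] = field(
        default_factory=lambda: {
            "chr2": 2.0,
            "chr8": 2.0,
            "chr10": 2.0,
            "chr12": 2.0,
            "chr13": 2.0,
            "chr14": 2.0,
            "chr16": 2.0,
            "chrX": 2.0,
            "chrY": 2.0,
        }
    )
    background_snv_rate: float = 400.0  # SNVs per Mb per strain
    msy_rate_multiplier: float = 2.0
    duplicated_genes: list = field(default_factory=default_duplicated_genes)
    sry_copy_panel: list = field(default_factory=default_sry_panel)
    phenotype_effects: list = field(default_factory=default_phenotype_effects)
    seed: int = 0
    msy_name: str = "chrY"
    male_names: Sequence[str] | None = None
    contamination_read_fraction: float = 0.001
    contaminated_variant_fraction: float = 0.0
    reads_per_sample: int = 200
    dna_read_length: int = 100
    male_marker_read_fraction: float = 0.05
    rna_read_length: int = 100
    rna_total_reads: int = 20000
    rna_background_weight: float = 0.30
    sry_frame_length: int = 700

    def __post_init__(self) -> None:
        for fname in ("n_male_samples", "n_female_samples", "n_contaminated_females"):
            if getattr(self, fname) < 0:
                raise ConfigurationError(f"{fname}: must be >= 0")
        if self.coverage < 1:
            raise ConfigurationError("coverage: must be >= 1")
        if self.msy_rate_multiplier <= 0:
            raise ConfigurationError("msy_rate_multiplier: must be > 0")
        if self.background_snv_rate < 0:
            raise ConfigurationError("background_snv_rate: must be >= 0")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigurationError(f"chromosome_lengths: {chrom} must be > 0 Mb")
        if self.msy_name not in self.chromosome_lengths:
            raise ConfigurationError("chromosome_lengths: missing the MSY chromosome")
        for spec in self.duplicated_genes:
            if spec.origin_chromosome not in self.chromosome_lengths:
                raise ConfigurationError(
                    f"duplicated_genes: {spec.gene} on unknown chromosome "
                    f"{spec.origin_chromosome!r}"
                )
        if not 0.0 <= self.contamination_read_fraction <= 1.0:
            raise ConfigurationError("contamination_read_fraction: must be in [0, 1]")
        if not 0.0 <= self.contaminated_variant_fraction <= 1.0:
            raise ConfigurationError("contaminated_variant_fraction: must be in [0, 1]")

    @property
    def male_samples(self) -> list[str]:
        if self.male_names is not None:
            names = list(self.male_names)
            if len(names) != self.n_male_samples:
                raise ConfigurationError("male_names: length must equal n_male_samples")
            return names
        names = list(_DEFAULT_MALE_STRAINS[: self.n_male_samples])
        names += [f"M{i:02d}" for i in range(len(names) + 1, self.n_male_samples + 1)]
        return names

    @property
    def contaminated_samples(self) -> list[str]:
        return [f"CF{i:02d}" for i in range(1, self.n_contaminated_females + 1)]

    @property
    def female_samples(self) -> list[str]:
        return [f"F{i:02d}" for i in range(1, self.n_female_samples + 1)]


@dataclass
class SyntheticGene:
    """Internal ground truth for one generated gene."""

    spec: DuplicatedGeneSpec
    gene_start: int  # 1-based on origin chromosome
    exon_seqs: list[str]  # reference alleles
    intron_seqs: list[str]
    marker_genomic_offsets: list[int]  # 0-based within genomic gene seq
    marker_spliced_offsets: list[int]  # 0-based within spliced CDS
    ref_alleles: list[str]
    alt_alleles: list[str]
    stop_spliced_offset: int | None = None  # planted premature stop (copy only)
    contig_name: str = ""
    copy_positions: list[int] = field(default_factory=list)  # 1-based on contig
    expression_insert: str = ""

    @property
    def genomic_seq(self) -> str:
        parts = [self.exon_seqs[0]]
        for intron, exon in zip(self.intron_seqs, self.exon_seqs[1:]):
            parts.extend([intron, exon])
        return "".join(parts)

    @property
    def spliced_seq(self) -> str:
        return "".join(self.exon_seqs)

    @property
    def gene_end(self) -> int:
        return self.gene_start + len(self.genomic_seq) - 1

    def marker_positions(self) -> list[int]:
        return [self.gene_start + off for off in self.marker_genomic_offsets]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_NON_STOP_CODONS), size=n_codons)
    body = "".join(_NON_STOP_CODONS[i] for i in codons)
    return "ATG" + body[3:] + "TAA"


def _split_exons(rng: np.random.Generator, cds: str, n_exons: int) -> list[str]:
    cuts = sorted(rng.choice(np.arange(60, len(cds) - 60), size=n_exons - 1, replace=False))
    # keep exon pieces comfortably apart so each holds marker clusters
    while len(cuts) >= 2 and min(np.diff(cuts)) < 120:
        cuts = sorted(rng.choice(np.arange(60, len(cds) - 60), size=n_exons - 1, replace=False))
    bounds = [0] + list(cuts) + [len(cds)]
    return [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def _codon_safe_alt(rng: np.random.Generator, cds: list[str], spliced_off: int) -> str:
    """An alternate base that keeps frame-0 of the CDS stop-free."""
    ref = cds[spliced_off]
    codon_start = spliced_off - spliced_off % 3
    for alt in rng.permutation([b for b in "ACGT" if b != ref]):
        trial = cds[codon_start : codon_start + 3]
        trial[spliced_off - codon_start] = alt
        if "".join(trial) not in _STOPS:
            return str(alt)
    raise RuntimeError("no stop-free alternate allele exists")  # pragma: no cover


def _build_gene(rng: np.random.Generator, spec: DuplicatedGeneSpec, gene_start: int) -> SyntheticGene:
    margin, pair_gap, anchor_step = 15, 8, 70

    # exons eligible for markers: partial transpositions only carry a
    # proper prefix of the exons, so markers must live there
    if spec.mechanism == "partial_transposed":
        usable_exons = list(range(spec.n_exons - 1))
    else:
        usable_exons = list(range(spec.n_exons))

    # grow the gene until the usable exons hold the marker quota
    n_codons = max(90, 40 + 12 * spec.n_marker_snvs)
    while True:
        cds = _random_cds(rng, n_codons)
        exons = _split_exons(rng, cds, spec.n_exons)
        anchors = _marker_anchors(exons, usable_exons, margin, pair_gap, anchor_step)
        if 2 * len(anchors) >= spec.n_marker_snvs:
            break
        n_codons = int(n_codons * 1.5) + 30
    introns = ["GT" + _random_seq(rng, int(rng.integers(60, 140))) + "AG" for _ in exons[1:]]

    exon_spliced_starts, exon_genomic_starts = [], []
    s_off = g_off = 0
    for i, exon in enumerate(exons):
        exon_spliced_starts.append(s_off)
        exon_genomic_starts.append(g_off)
        s_off += len(exon)
        g_off += len(exon)
        if i < len(introns):
            g_off += len(introns[i])

    cds_list = list(cds)
    spliced_offsets: list[int] = []
    alts: list[str] = []
    remaining = spec.n_marker_snvs
    for a in anchors:
        if remaining <= 0:
            break
        offs = [a, a + pair_gap] if remaining >= 2 else [a]
        for off in offs:
            alt = _codon_safe_alt(rng, cds_list, off)
            cds_list[off] = alt  # applied so later safety checks see it
            spliced_offsets.append(off)
            alts.append(alt)
            remaining -= 1

    def to_genomic(s: int) -> int:
        i = max(k for k, start in enumerate(exon_spliced_starts) if start <= s)
        return exon_genomic_starts[i] + (s - exon_spliced_starts[i])

    genomic_offsets = [to_genomic(s) for s in spliced_offsets]
    refs = [cds[s] for s in spliced_offsets]

    stop_off = None
    if spec.premature_stop:
        marker_codons = {s // 3 for s in spliced_offsets}

        def codon_in_one_exon(k: int) -> bool:
            for start, exon in zip(exon_spliced_starts, exons):
                if start <= 3 * k and 3 * k + 3 <= start + len(exon):
                    return True
            return False

        candidates = [
            k
            for k in range(5, len(cds) // 3 - 5)
            if k not in marker_codons and codon_in_one_exon(k)
        ]
        stop_off = 3 * int(rng.choice(candidates))

    return SyntheticGene(
        spec=spec,
        gene_start=gene_start,
        exon_seqs=exons,
        intron_seqs=introns,
        marker_genomic_offsets=genomic_offsets,
        marker_spliced_offsets=spliced_offsets,
        ref_alleles=refs,
        alt_alleles=alts,
        stop_spliced_offset=stop_off,
    )


def _marker_anchors(exons, usable_exons, margin, pair_gap, anchor_step):
    anchors: list[int] = []
    start = 0
    for i, exon in enumerate(exons):
        if i in usable_exons:
            a = start + margin
            hi = start + len(exon) - margin - pair_gap
            while a <= hi:
                anchors.append(a)
                a += anchor_step
        start += len(exon)
    return anchors


def _copy_sequences(gene: SyntheticGene) -> str:
    """The sequence actually inserted on the MSY: marker alternate
    alleles applied, plus the planted premature stop where configured."""
    spec = gene.spec
    substitutions: dict[int, str] = dict(
        zip(gene.marker_spliced_offsets, gene.alt_alleles)
    )
    if gene.stop_spliced_offset is not None:
        for i, base in enumerate("TAA"):
            substitutions[gene.stop_spliced_offset + i] = base

    spliced = list(gene.spliced_seq)
    for off, alt in substitutions.items():
        spliced[off] = alt
    spliced_copy = "".join(spliced)

    exon_copies: list[str] = []
    s_off = 0
    for exon in gene.exon_seqs:
        piece = list(exon)
        for off, alt in substitutions.items():
            if s_off <= off < s_off + len(exon):
                piece[off - s_off] = alt
        exon_copies.append("".join(piece))
        s_off += len(exon)

    if spec.mechanism == "retroposed":
        return spliced_copy
    if spec.mechanism in ("transposed", "msy_duplication"):
        parts = [exon_copies[0]]
        for intron, exon in zip(gene.intron_seqs, exon_copies[1:]):
            parts.extend([intron, exon])
        return "".join(parts)
    # partial transposition: proper exon prefix with its introns
    k = spec.n_exons - 1
    parts = [exon_copies[0]]
    for intron, exon in zip(gene.intron_seqs[: k - 1], exon_copies[1:k]):
        parts.extend([intron, exon])
    return "".join(parts)


@dataclass
class Panel:
    """Everything one simulation run produces, plus its ground truth."""

    config: SimulationConfig
    variants: VariantTable
    sample_sheet: pd.DataFrame
    contigs: dict[str, str]
    annotation: pd.DataFrame
    ref_segments: dict[str, str]  # gene -> reference genomic sequence
    dna_reads: dict[str, list[str]]
    rna_datasets: dict[str, list[str]]
    sex_probe: str
    sry_probes: dict[str, str]
    truth: dict

    def write(self, outdir) -> None:
        from . import io as _io

        _io.write_panel(self, outdir)


def simulate_panel(config: SimulationConfig) -> Panel:
    """Generate the full synthetic panel from one validated config.

    Deterministic in ``config.seed``: the same config yields
    byte-identical variant tables, contigs, reads, and truth records.
    """
    males = config.male_samples
    contaminated = config.contaminated_samples
    females = config.female_samples
    samples = males + contaminated + females
    male_class = males + contaminated
    cov = config.coverage

    # --- genes, contigs, annotation -------------------------------------
    cursors: dict[str, int] = {}
    genes: list[SyntheticGene] = []
    for spec in config.duplicated_genes:
        rng = stage_rng(config.seed, f"gene:{spec.gene}")
        start = cursors.get(spec.origin_chromosome, 100_000)
        gene = _build_gene(rng, spec, start)
        cursors[spec.origin_chromosome] = gene.gene_end + 50_000
        genes.append(gene)

    contigs: dict[str, str] = {}
    for gene in genes:
        rng = stage_rng(config.seed, f"contig:{gene.spec.gene}")
        copy_seq = _copy_sequences(gene)
        n_copies = max(1, gene.spec.y_copy_number)
        parts = [_random_seq(rng, 300)]
        positions = []
        offset = 300
        for i in range(n_copies):
            positions.append(offset + 1)
            parts.append(copy_seq)
            offset += len(copy_seq)
            spacer = _random_seq(rng, 120)
            parts.append(spacer)
            offset += len(spacer)
        parts.append(_random_seq(rng, 180))
        name = f"AC_{gene.spec.gene}"
        contigs[name] = "".join(parts)
        gene.contig_name = name
        gene.copy_positions = positions

    annotation = pd.DataFrame(
        [
            {
                "gene": g.spec.gene,
                "chromosome": g.spec.origin_chromosome,
                "gene_start": g.gene_start,
                "gene_end": g.gene_end,
                "exon_starts": ",".join(
                    str(g.gene_start + off)
                    for off in _exon_genomic_starts(g)
                ),
                "exon_ends": ",".join(
                    str(g.gene_start + off + len(exon) - 1)
                    for off, exon in zip(_exon_genomic_starts(g), g.exon_seqs)
                ),
                "msy_native": g.spec.mechanism == "msy_duplication",
            }
            for g in genes
        ]
    )
    ref_segments = {g.spec.gene: g.genomic_seq for g in genes}

    # --- variant table ---------------------------------------------------
    site_rows: list[dict] = []
    ref_mat: list[np.ndarray] = []
    alt_mat: list[np.ndarray] = []

    rng_counts = stage_rng(config.seed, "marker-counts")
    for gene in genes:
        spec = gene.spec
        p = spec.expected_af
        for pos, ref, alt in zip(gene.marker_positions(), gene.ref_alleles, gene.alt_alleles):
            ref_row = np.full(len(samples), cov, dtype=np.int64)
            alt_row = np.zeros(len(samples), dtype=np.int64)
            for j, s in enumerate(samples):
                if s in males and s not in spec.strains_lacking and p > 0:
                    a = int(rng_counts.binomial(cov, p))
                elif s in contaminated and config.contaminated_variant_fraction > 0 and p > 0:
                    a = int(rng_counts.binomial(cov, p * config.contaminated_variant_fraction))
                else:
                    a = 0
                alt_row[j] = a
                ref_row[j] = cov - a
            site_rows.append(
                {"chrom": spec.origin_chromosome, "pos": pos, "ref": ref, "alt": alt}
            )
            ref_mat.append(ref_row)
            alt_mat.append(alt_row)

    site_frames = [pd.DataFrame(site_rows, columns=["chrom", "pos", "ref", "alt"])]
    ref_blocks = [np.vstack(ref_mat)] if ref_mat else [np.empty((0, len(samples)), np.int64)]
    alt_blocks = [np.vstack(alt_mat)] if alt_mat else [np.empty((0, len(samples)), np.int64)]

    rng_bg = stage_rng(config.seed, "background-snvs")
    female_like = np.array([s in set(contaminated) | set(females) for s in samples])
    for strain in males:
        j = samples.index(strain)
        for chrom, length_mb in config.chromosome_lengths.items():
            rate = config.background_snv_rate * length_mb
            if chrom == config.msy_name:
                rate *= config.msy_rate_multiplier
            n = int(rng_bg.poisson(rate))
            if n == 0:
                continue
            length_bp = int(length_mb * 1e6)
            positions = np.unique(rng_bg.integers(1, length_bp + 1, size=n))
            k = len(positions)
            ref_idx = rng_bg.integers(0, 4, size=k)
            alt_idx = (ref_idx + rng_bg.integers(1, 4, size=k)) % 4
            ref_block = np.full((k, len(samples)), cov, dtype=np.int64)
            alt_block = np.zeros((k, len(samples)), dtype=np.int64)
            ref_block[:, j] = 0
            alt_block[:, j] = cov  # strain-private homozygous SNV
            if chrom == config.msy_name:
                ref_block[:, female_like] = 0  # females have no Y coverage
            site_frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": positions.astype(np.int64),
                        "ref": BASES[ref_idx],
                        "alt": BASES[alt_idx],
                    }
                )
            )
            ref_blocks.append(ref_block)
            alt_blocks.append(alt_block)

    sites = pd.concat(site_frames, ignore_index=True)
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    variants = VariantTable(
        sites.loc[order],
        pd.DataFrame(np.vstack(ref_blocks)[order], columns=samples),
        pd.DataFrame(np.vstack(alt_blocks)[order], columns=samples),
    )

    # --- Sry frame, sex-marker probe, DNA reads --------------------------
    rng_sry = stage_rng(config.seed, "sry-frame")
    frame = _random_seq(rng_sry, config.sry_frame_length)
    copy_seqs: dict[str, str] = {}
    for copy in config.sry_copy_panel:
        seq = list(frame)
        for off, alt in copy.variant_offsets:
            seq[off] = alt
        copy_seqs[copy.name] = "".join(seq)
    sry1 = copy_seqs.get("Sry1", frame)
    sex_probe = sry1[70:130]

    rng_reads = stage_rng(config.seed, "dna-reads")
    dna_reads: dict[str, list[str]] = {}
    n_reads, read_len = config.reads_per_sample, config.dna_read_length
    for s in samples:
        if s in males:
            n_marker = int(rng_reads.binomial(n_reads, config.male_marker_read_fraction))
        elif s in contaminated:
            n_marker = max(1, int(round(config.contamination_read_fraction * n_reads)))
        else:
            n_marker = 0
        reads = []
        for i in range(n_reads):
            if i < n_marker:
                pad = read_len - len(sex_probe)
                left = int(rng_reads.integers(0, pad + 1))
                read = (
                    _random_seq(rng_reads, left)
                    + sex_probe
                    + _random_seq(rng_reads, pad - left)
                )
            else:
                read = _random_seq(rng_reads, read_len)
            if rng_reads.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        perm = rng_reads.permutation(n_reads)
        dna_reads[s] = [reads[i] for i in perm]

    # --- RNA-like datasets ------------------------------------------------
    for gene in genes:
        spliced = list(gene.spliced_seq)
        for off, alt in zip(gene.marker_spliced_offsets, gene.alt_alleles):
            spliced[off] = alt
        first = sorted(gene.marker_spliced_offsets)[:2]
        lo = max(0, min(first) - 30)
        hi = min(len(spliced), max(first) + 31)
        gene.expression_insert = "".join(spliced[lo:hi])

    inserts: dict[str, str] = {}
    weights: dict[str, float] = {}
    for gene in genes:
        if gene.spec.expression_weight > 0:
            inserts[gene.spec.gene] = gene.expression_insert
            weights[gene.spec.gene] = gene.spec.expression_weight
    sry_probes: dict[str, str] = {}
    for copy in config.sry_copy_panel:
        off = copy.variant_offsets[0][0] if copy.variant_offsets else 100
        lo, hi = max(0, off - 40), min(len(frame), off + 41)
        inserts[copy.name] = copy_seqs[copy.name][lo:hi]
        sry_probes[copy.name] = copy_seqs[copy.name][max(0, off - 18) : off + 19]
        if copy.expression_weight > 0:
            weights[copy.name] = copy.expression_weight
    rna_datasets = {
        "testis_male": simulate_reads(
            inserts,
            weights,
            total_reads=config.rna_total_reads,
            read_length=config.rna_read_length,
            seed=int(stage_rng(config.seed, "rna-testis").integers(0, 2**31 - 1)),
            background_weight=config.rna_background_weight,
        ),
        "uterus_female": simulate_reads(
            inserts,
            weights,
            total_reads=max(1, config.rna_total_reads // 4),
            read_length=config.rna_read_length,
            seed=int(stage_rng(config.seed, "rna-uterus").integers(0, 2**31 - 1)),
            background_weight=1.0,
            female=True,
        ),
    }

    sample_sheet = pd.DataFrame(
        {
            "sample": samples,
            "declared_sex": ["male"] * len(males) + ["female"] * (len(contaminated) + len(females)),
            "true_class": ["male_class"] * len(male_class) + ["female"] * len(females),
        }
    )

    truth = {
        "seed": config.seed,
        "samples": dict(zip(sample_sheet["sample"], sample_sheet["true_class"])),
        "sex_marker_probe": sex_probe,
        "msy_rate_multiplier": config.msy_rate_multiplier,
        "genes": {
            g.spec.gene: {
                "mechanism": g.spec.mechanism,
                "origin_kind": g.spec.origin_kind,
                "origin_chromosome": g.spec.origin_chromosome,
                "y_copy_number": g.spec.y_copy_number,
                "expected_af": g.spec.expected_af,
                "n_marker_snvs": g.spec.n_marker_snvs,
                "strains_lacking": sorted(g.spec.strains_lacking),
                "premature_stop": g.spec.premature_stop,
                "expressed": g.spec.expressed,
                "expected_status": g.spec.expected_status,
                "msy_contig": g.contig_name,
                "copy_positions": g.copy_positions,
                "marker_positions": g.marker_positions(),
                "alt_alleles": g.alt_alleles,
            }
            for g in genes
        },
        "sry_panel": {
            c.name: {
                "variants": {int(off): alt for off, alt in c.variant_offsets},
                "expression_weight": c.expression_weight,
            }
            for c in config.sry_copy_panel
        },
    }

    return Panel(
        config=config,
        variants=variants,
        sample_sheet=sample_sheet,
        contigs=contigs,
        annotation=annotation,
        ref_segments=ref_segments,
        dna_reads=dna_reads,
        rna_datasets=rna_datasets,
        sex_probe=sex_probe,
        sry_probes=sry_probes,
        truth=truth,
    )


def _exon_genomic_starts(gene: SyntheticGene) -> list[int]:
    starts, off = [], 0
    for i, exon in enumerate(gene.exon_seqs):
        starts.append(off)
        off += len(exon)
        if i < len(gene.intron_seqs):
            off += len(gene.intron_seqs[i])
    return starts


def simulate_reads(
    inserts: Mapping[str, str],
    weights: Mapping[str, float],
    total_reads: int,
    read_length: int,
    seed: int,
    background_weight: float = 0.0,
    female: bool = False,
) -> list[str]:
    """Marker-bearing read set with copy-specific expression weights.

    Each read is drawn from one source: copy ``k`` with probability
    proportional to ``weights[k]`` (or pure background, proportional to
    ``background_weight``), so the marker-hit count of copy ``k`` is
    Binomial(total_reads, w_k / sum w).  Reads embed the copy's insert
    at a random offset and are emitted on a random strand.  With
    ``female=True`` every read is background: no Y-marker content.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if any(w < 0 for w in weights.values()) or background_weight < 0:
        raise ValueError("weights must be >= 0")
    rng = np.random.default_rng(int(seed))
    if female:
        names, probs = ["__background__"], np.array([1.0])
    else:
        names = [n for n in weights if weights[n] > 0]
        probs = np.array([weights[n] for n in names], dtype=float)
        if background_weight > 0:
            names.append("__background__")
            probs = np.append(probs, background_weight)
        if total_reads > 0 and (probs.size == 0 or probs.sum() == 0):
            raise ValueError("all-zero weights with total_reads > 0")
        probs = probs / probs.sum() if probs.size else probs
    for name in names:
        if name != "__background__" and len(inserts[name]) > read_length:
            raise ValueError(
                f"read_length {read_length} shorter than insert for {name!r}"
            )
    if total_reads == 0:
        return []
    counts = rng.multinomial(total_reads, probs)
    reads: list[str] = []
    for name, count in zip(names, counts):
        for _ in range(count):
            if name == "__background__":
                read = _random_seq(rng, read_length)
            else:
                insert = inserts[name]
                pad = read_length - len(insert)
                left = int(rng.integers(0, pad + 1))
                read = (
                    _random_seq(rng, left) + insert + _random_seq(rng, pad - left)
                )
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm]


def simulate_phenotypes(
    effects: Sequence[PhenotypeEffect], seed: int
) -> pd.DataFrame:
    """Long-format phenotype table: value ~ Normal(base + strain + sex
    effect, noise SD), ``n_per_group`` animals per strain x sex cell."""
    rng = np.random.default_rng(int(seed))
    rows = []
    for eff in effects:
        if eff.noise_sd <= 0:
            raise ValueError(f"noise SD must be > 0 for {eff.phenotype!r}")
        if eff.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2 for {eff.phenotype!r}")
        for strain, strain_eff in eff.strain_effects.items():
            for sex in ("male", "female"):
                mean = eff.baseline + strain_eff
                if sex == "male":
                    mean += eff.sex_effect(strain)
                values = rng.normal(mean, eff.noise_sd, size=eff.n_per_group)
                for v in values:
                    rows.append(
                        {
                            "phenotype": eff.phenotype,
                            "treatment": eff.treatment,
                            "strain": strain,
                            "sex": sex,
                            "value": float(v),
                        }
                    )
    return pd.DataFrame(rows)
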