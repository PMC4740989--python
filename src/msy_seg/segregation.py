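"""Male/female allele-frequency segregation filters.

This is the core of the duplication-detection method.  A gene copied
onto the male-specific region of chromosome Y (MSY) is absent from the
reference assembly used for alignment, so its reads pile onto the source
locus and create apparent heterozygous variants — but only in males.
At such a marker site a male with ``c`` Y-borne copies of an autosomal
gene is expected to show an alternate-allele read fraction of
``c / (c + 2)`` (two autosomal copies plus ``c`` Y copies), and
``c / (c + 1)`` for an X-linked source gene (one X in a male).  For a
single duplicated copy of an autosomal gene this is the 33 % expectation
against which per-gene averages are compared.

The filters operate on per-sample read counts: a candidate site must be
invariant (AF = 0) in every female sample and show an intermediate
alternate fraction (0.1–99.9 % by default) in every male-class sample.
Leave-one-out filtering then finds strains whose MSY lacks a given copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

FEMALE = "female"
MALE_CLASS = "male_class"

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class SegregationConfig:
    """Allele-frequency windows for the male/female segregation filter.

    Defaults encode the published rule: females at exactly 0 % AF, males
    anywhere between 0.1 % and 99.9 % (inclusive, read as fractions).
    Sites with read depth below ``min_depth`` in any sample are excluded
    from candidacy rather than imputed as reference-homozygous.
    """

    female_max_af: float = 0.0
    male_af_lower: float = 0.001
    male_af_upper: float = 0.999
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.female_max_af < self.male_af_lower < self.male_af_upper <= 1.0):
            raise ConfigurationError(
                "SegregationConfig requires 0 <= female_max_af < male_af_lower "
                f"< male_af_upper <= 1; got {self}"
            )
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")


class VariantTable:
    """Biallelic SNVs with per-sample (ref_count, alt_count).

    ``sites`` holds one row per variant (chrom, pos, ref, alt; 1-based
    positions) and ``ref_counts`` / ``alt_counts`` are integer frames
    aligned to it with one column per sample.
    """

    def __init__(self, sites: pd.DataFrame, ref_counts: pd.DataFrame, alt_counts: pd.DataFrame):
        sites = sites.reset_index(drop=True)
        ref_counts = ref_counts.reset_index(drop=True)
        alt_counts = alt_counts.reset_index(drop=True)
        if list(ref_counts.columns) != list(alt_counts.columns):
            raise ValueError("ref_counts and alt_counts must have identical sample columns")
        if not (len(sites) == len(ref_counts) == len(alt_counts)):
            raise ValueError("sites and count frames must have equal row counts")
        if (sites["pos"] < 1).any():
            raise ValueError("positions are 1-based; found pos < 1")
        if (ref_counts.to_numpy() < 0).any() or (alt_counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        self.sites = sites
        self.ref_counts = ref_counts.astype(np.int64)
        self.alt_counts = alt_counts.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.ref_counts.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depth(self) -> pd.DataFrame:
        return self.ref_counts + self.alt_counts

    def allele_freq(self) -> pd.DataFrame:
        """Per-sample alternate fraction; NaN where depth is zero."""
        depth = self.depth().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            af = self.alt_counts.to_numpy(dtype=float) / depth
        return pd.DataFrame(af, columns=self.samples)

    def subset(self, mask) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.sites.loc[mask], self.ref_counts.loc[mask], self.alt_counts.loc[mask]
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VariantTable)
            and self.sites.equals(other.sites)
            and self.ref_counts.equals(other.ref_counts)
            and self.alt_counts.equals(other.alt_counts)
        )


def allele_frequency(ref_count: int, alt_count: int) -> float | None:
    """Alternate fraction alt/(ref+alt); ``None`` at zero depth."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        return None
    return alt_count / depth


def _split_classes(samples: Iterable[str], sex_classes: Mapping[str, str]):
    females, males = [], []
    for sample in samples:
        if sample not in sex_classes:
            raise ValueError(f"sample {sample!r} has no sex call")
        cls = sex_classes[sample]
        if cls == FEMALE:
            females.append(sample)
        elif cls == MALE_CLASS:
            males.append(sample)
        else:
            raise ValueError(f"unknown sex class {cls!r} for sample {sample!r}")
    return females, males


def male_specific_sites(
    table: VariantTable,
    sex_classes: Mapping[str, str],
    config: SegregationConfig | None = None,
) -> pd.Series:
    """Boolean mask of sites passing the male/female segregation filter.

    A site passes when every sample has depth >= min_depth, every female
    AF <= female_max_af, and every male-class AF lies inside
    [male_af_lower, male_af_upper].
    """
    config = config or SegregationConfig()
    females, males = _split_classes(table.samples, sex_classes)
    af = table.allele_freq()
    ok = (table.depth() >= config.min_depth).all(axis=1)
    if females:
        ok &= (af[females] <= config.female_max_af).all(axis=1)
    if males:
        within = (af[males] >= config.male_af_lower) & (af[males] <= config.male_af_upper)
        ok &= within.all(axis=1)
    return ok.rename("male_specific")


def strain_specific_sites(
    table: VariantTable,
    sex_classes: Mapping[str, str],
    config: SegregationConfig | None = None,
) -> dict[str, pd.Series]:
    """Leave-one-out masks: sites absent in exactly one male strain.

    For each male-class strain ``s`` the returned mask selects sites
    where ``s`` has AF <= female_max_af while all other males pass the
    male window and all females pass the female filter.  A site absent
    in two strains therefore appears under neither.
    """
    config = config or SegregationConfig()
    females, males = _split_classes(table.samples, sex_classes)
    if len(males) < 2:
        raise ValueError("leave-one-out filtering requires >= 2 male-class samples")
    af = table.allele_freq()
    base = (table.depth() >= config.min_depth).all(axis=1)
    if females:
        base &= (af[females] <= config.female_max_af).all(axis=1)
    out: dict[str, pd.Series] = {}
    for strain in males:
        others = [m for m in males if m != strain]
        mask = base & (af[strain] <= config.female_max_af)
        within = (af[others] >= config.male_af_lower) & (af[others] <= config.male_af_upper)
        mask &= within.all(axis=1)
        out[strain] = mask.rename(strain)
    return out


def expected_duplication_af(origin_kind: str, y_copy_number: int) -> float:
    """Expected male alternate fraction for ``c`` MSY-borne copies.

    An autosomal source contributes two reference-bearing copies in a
    male, an X-linked source only one, so the alternate reads from the
    ``c`` Y copies are expected at c/(c+2) and c/(c+1) respectively
    (1/3, i.e. 33 %, for the single-copy autosomal case).
    """
    if y_copy_number < 0:
        raise ValueError("y_copy_number must be >= 0")
    if origin_kind == "autosome":
        denom = y_copy_number + 2
    elif origin_kind == "chrX":
        denom = y_copy_number + 1
    else:
        raise ValueError(f"origin_kind must be 'autosome' or 'chrX', got {origin_kind!r}")
    if y_copy_number == 0:
        return 0.0
    return y_copy_number / denom


@dataclass
class GeneAFSummary:
    """Per-gene evidence summary in the style of the discovery table."""

    gene: str
    chromosome: str
    n_snvs: int
    mean_af: float
    sem_af: float | None
    strains_lacking: frozenset[str] = frozenset()
    strain_specific_snvs: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "gene": self.gene,
            "chromosome": self.chromosome,
            "n_snvs": self.n_snvs,
            "mean_af_pct": round(100.0 * self.mean_af, 1),
            "sem_af_pct": None if self.sem_af is None else round(100.0 * self.sem_af, 1),
            "strains_lacking": ",".join(sorted(self.strains_lacking)),
            "strain_specific_snvs": ";".join(
                f"{s}({n})" for s, n in sorted(self.strain_specific_snvs.items())
            ),
        }


def assign_genes(sites: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Map each site to at most one gene by gene-span containment.

    ``annotation`` needs columns gene, chromosome, gene_start, gene_end
    (1-based inclusive).  A site inside two gene spans is an error; a
    site outside every span maps to NaN.
    """
    assigned = pd.Series(pd.NA, index=sites.index, dtype="object")
    for _, gene_row in annotation.iterrows():
        hit = (
            (sites["chrom"] == gene_row["chromosome"])
            & (sites["pos"] >= gene_row["gene_start"])
            & (sites["pos"] <= gene_row["gene_end"])
        )
        clash = hit & assigned.notna()
        if clash.any():
            site = sites.loc[clash.idxmax()]
            raise ValueError(
                f"site {site['chrom']}:{site['pos']} overlaps two genes "
                f"({assigned[clash.idxmax()]} and {gene_row['gene']})"
            )
        assigned[hit] = gene_row["gene"]
    return assigned


def gene_af_summary(
    table: VariantTable,
    sex_classes: Mapping[str, str],
    annotation: pd.DataFrame,
    config: SegregationConfig | None = None,
) -> list[GeneAFSummary]:
    """Summarize candidate sites per gene: SNV count, mean AF ± SEM,
    strains lacking the copy, and partial strain-specific absences.

    Candidate sites are the union of all-male sites and leave-one-out
    strain-specific sites, so a gene whose copy is missing in one strain
    (and hence fails the all-male filter at every site) is still
    reported, with that strain listed under ``strains_lacking``.  The
    per-site AF is averaged over male strains excluding strains lacking
    the gene; the SEM is taken across sites (NA for single-site genes).
    """
    config = config or SegregationConfig()
    _, males = _split_classes(table.samples, sex_classes)
    male_mask = male_specific_sites(table, sex_classes, config)
    loo = (
        strain_specific_sites(table, sex_classes, config)
        if len(males) >= 2
        else {}
    )
    candidate = male_mask.copy()
    for mask in loo.values():
        candidate |= mask
    genes = assign_genes(table.sites, annotation)
    af = table.allele_freq()
    summaries: list[GeneAFSummary] = []
    for _, gene_row in annotation.iterrows():
        name = gene_row["gene"]
        in_gene = genes.eq(name).fillna(False).astype(bool)
        idx = candidate[in_gene & candidate].index
        n = len(idx)
        if n == 0:
            continue
        absent_counts = {s: int(mask[idx].sum()) for s, mask in loo.items()}
        lacking = frozenset(s for s, k in absent_counts.items() if k == n)
        partial = {s: k for s, k in absent_counts.items() if 0 < k < n}
        carriers = [m for m in males if m not in lacking]
        per_site = af.loc[idx, carriers].mean(axis=1)
        mean_af = float(per_site.mean())
        sem = float(per_site.std(ddof=1) / math.sqrt(n)) if n > 1 else None
        summaries.append(
            GeneAFSummary(
                gene=name,
                chromosome=gene_row["chromosome"],
                n_snvs=n,
                mean_af=mean_af,
                sem_af=sem,
                strains_lacking=lacking,
                strain_specific_snvs=partial,
            )
        )
    return summaries
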