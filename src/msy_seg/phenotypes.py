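"""Consomic phenotype statistics.

Consomic strains carry one donor chromosome (here the male-specific
region of Y) introgressed onto another strain's background, so a
phenotype differing between consomic and parental males implicates that
chromosome.  Comparisons use the Mann-Whitney U test with a Bonferroni
adjustment over the phenotype family tested per consomic (131 and 223
in the reference panels), significance at adjusted P < 0.05.  Each
significant phenotype is then classified by whether the two parental
strains show a male-vs-female difference (both / A-only / B-only /
neither), and per-chromosome contribution is scored as the fraction of
measured phenotypes that reached significance, normalized per Mb of
chromosome or per ten genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

BOTH = "both"
A_ONLY = "A_only"
B_ONLY = "B_only"
NEITHER = "neither"
CLASSES = (BOTH, A_ONLY, B_ONLY, NEITHER)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test: returns (U of group_a, p).

    The p-value is exact (full enumeration) when the smaller group has
    at most 8 observations and there are no ties; otherwise the normal
    approximation with mid-ranks and tie-corrected variance is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m), m >= number of tests.

    ``m`` defaults to the number of p-values but may be larger when the
    tested family exceeds the p-values at hand (e.g. the full phenotype
    panel of a consomic comparison).
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError(f"family size m={m} smaller than number of p values ({len(p_values)})")
    adjusted = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p value {p} outside [0, 1]")
        adjusted.append(min(1.0, p * m))
    return adjusted


@dataclass(frozen=True)
class PhenotypeComparison:
    phenotype: str
    treatment: str
    consomic: str
    consomic_vs_parental_p_adj: float
    parent_a_mf_significant: bool
    parent_b_mf_significant: bool

    @property
    def sex_diff_class(self) -> str:
        if self.parent_a_mf_significant and self.parent_b_mf_significant:
            return BOTH
        if self.parent_a_mf_significant:
            return A_ONLY
        if self.parent_b_mf_significant:
            return B_ONLY
        return NEITHER


def classify_sex_difference(
    table: pd.DataFrame, flag_a: str, flag_b: str
) -> tuple[dict[str, int], pd.Series]:
    """Classify rows by which parental strain shows a sex difference.

    ``flag_a`` / ``flag_b`` name boolean columns (parental male-vs-female
    significance).  Returns per-class counts (summing to the number of
    rows) and the per-row class labels.  Missing flags are an error.
    """
    for col in (flag_a, flag_b):
        if col not in table.columns:
            raise ValueError(f"missing flag column {col!r}")
        if table[col].isna().any():
            idx = table[table[col].isna()].index[0]
            raise ValueError(f"missing {col!r} flag in row {idx}")
    a = table[flag_a].astype(bool)
    b = table[flag_b].astype(bool)
    labels = pd.Series(NEITHER, index=table.index, dtype="object")
    labels[a & b] = BOTH
    labels[a & ~b] = A_ONLY
    labels[~a & b] = B_ONLY
    counts = {cls: int((labels == cls).sum()) for cls in CLASSES}
    return counts, labels


def load_table3() -> pd.DataFrame:
    """The packaged consomic sex-difference table (verbatim transcription).

    Columns: phenotype, treatment, consomic, bn_significant,
    fhh_significant, ss_significant.  Flags are "Yes"/"No"; "-" marks a
    parental strain not part of that consomic cross.  Duplicated rows
    are kept as distinct rows exactly as printed, since the published
    per-class counts are row-level.
    """
    with resources.files("msy_seg.data").joinpath("table3.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _flags(series: pd.Series) -> pd.Series:
    return series.map({"Yes": True, "No": False}).astype("object")


def table3_class_counts(table: pd.DataFrame | None = None) -> dict[str, dict[str, int]]:
    """Sex-difference class counts per consomic from the packaged table.

    For each consomic the background-parent flag (FHH or SS) is class A
    and the MSY donor BN is class B, so "A_only" reads e.g. FHH-only and
    "B_only" BN-only.
    """
    table = load_table3() if table is None else table
    out: dict[str, dict[str, int]] = {}
    for consomic, parent_col in (
        ("FHH-YBN/Mcwi", "fhh_significant"),
        ("SS-YBN/Mcwi", "ss_significant"),
    ):
        sub = table[table["consomic"] == consomic].copy()
        sub["parent"] = _flags(sub[parent_col])
        sub["bn"] = _flags(sub["bn_significant"])
        counts, _ = classify_sex_difference(sub, "parent", "bn")
        out[consomic] = counts
    return out


def compare_consomic(
    phenotypes: pd.DataFrame,
    consomic: str,
    parental: str,
    family_size: int | None = None,
    alpha: float = ALPHA,
    sex: str = "male",
) -> pd.DataFrame:
    """Consomic-vs-parental Mann-Whitney over every phenotype/treatment.

    ``phenotypes`` is long-format (phenotype, treatment, strain, sex,
    value).  Returns one row per phenotype x treatment with U, raw and
    Bonferroni-adjusted p (family ``family_size``, defaulting to the
    number of comparisons), and a significance flag at ``alpha``.
    """
    sub = phenotypes[phenotypes["sex"] == sex]
    keys, raw_p, stats_u = [], [], []
    for (phen, treat), grp in sub.groupby(["phenotype", "treatment"], sort=True):
        a = grp.loc[grp["strain"] == consomic, "value"].to_numpy()
        b = grp.loc[grp["strain"] == parental, "value"].to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        u, p = mann_whitney(a, b)
        keys.append((phen, treat))
        stats_u.append(u)
        raw_p.append(p)
    adj = bonferroni(raw_p, m=max(family_size or 0, len(raw_p)))
    return pd.DataFrame(
        {
            "phenotype": [k[0] for k in keys],
            "treatment": [k[1] for k in keys],
            "consomic": consomic,
            "parental": parental,
            "U": stats_u,
            "p_raw": raw_p,
            "p_adj": adj,
            "significant": [p < alpha for p in adj],
        }
    )


def sex_difference_flags(
    phenotypes: pd.DataFrame,
    strain: str,
    family_size: int | None = None,
    alpha: float = ALPHA,
) -> dict[tuple[str, str], bool]:
    """Male-vs-female significance per phenotype/treatment for one strain."""
    sub = phenotypes[phenotypes["strain"] == strain]
    keys, raw_p = [], []
    for (phen, treat), grp in sub.groupby(["phenotype", "treatment"], sort=True):
        males = grp.loc[grp["sex"] == "male", "value"].to_numpy()
        females = grp.loc[grp["sex"] == "female", "value"].to_numpy()
        if males.size == 0 or females.size == 0:
            continue
        _, p = mann_whitney(males, females)
        keys.append((phen, treat))
        raw_p.append(p)
    adj = bonferroni(raw_p, m=max(family_size or 0, len(raw_p)))
    return {k: p < alpha for k, p in zip(keys, adj)}


@dataclass
class ContributionRecord:
    metrics: pd.DataFrame
    fold_vs_mean_per_mb: float
    fold_vs_max_per_mb: float
    fold_vs_mean_per_10_genes: float
    fold_vs_max_per_10_genes: float
    skipped: list[str] = field(default_factory=list)


def contribution_fold(
    significance: pd.DataFrame,
    msy_name: str = "chrY",
) -> ContributionRecord:
    """Per-chromosome phenotype contribution and the MSY fold.

    ``significance`` needs columns chromosome, n_significant,
    n_measured, size_mb, n_genes.  The per-Mb metric is
    (n_significant / n_measured) / size_mb; the per-10-genes analogue
    divides by n_genes/10 instead.  The MSY fold is reported against
    both the mean and the maximum of the other chromosomes ("than any
    other chromosome").  Chromosomes with n_measured = 0 are skipped
    with a warning.
    """
    df = significance.copy()
    skipped = [str(c) for c in df.loc[df["n_measured"] == 0, "chromosome"]]
    if skipped:
        warnings.warn(f"skipping chromosomes with no measured phenotypes: {skipped}")
        df = df[df["n_measured"] > 0]
    if (df["size_mb"] <= 0).any():
        raise ValueError("all chromosome sizes must be > 0")
    if (df["n_genes"] <= 0).any():
        raise ValueError("gene counts must be > 0 for the per-10-genes metric")
    frac = df["n_significant"] / df["n_measured"]
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("n_significant must lie in [0, n_measured]")
    df = df.assign(
        fraction_significant=frac,
        per_mb=frac / df["size_mb"],
        per_10_genes=frac / (df["n_genes"] / 10.0),
    )
    msy = df[df["chromosome"] == msy_name]
    if msy.empty:
        raise ValueError(f"{msy_name!r} missing from the significance table")
    others = df[df["chromosome"] != msy_name]
    if others.empty or not (others["per_mb"] > 0).any():
        raise ValueError("no non-MSY chromosome with positive contribution to compare against")

    def fold(metric: str, against) -> float:
        return float(msy[metric].iloc[0] / against(others[metric]))

    return ContributionRecord(
        metrics=df.reset_index(drop=True),
        fold_vs_mean_per_mb=fold("per_mb", pd.Series.mean),
        fold_vs_max_per_mb=fold("per_mb", pd.Series.max),
        fold_vs_mean_per_10_genes=fold("per_10_genes", pd.Series.mean),
        fold_vs_max_per_10_genes=fold("per_10_genes", pd.Series.max),
        skipped=skipped,
    )
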