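"""Per-chromosome SNV density and the MSY fold-elevation.

SNV counts are normalized to chromosome size in Mb; the MSY elevation
is the per-strain ratio of MSY density to the mean density of all other
chromosomes, summarized as mean ± SEM across strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd


def density_table(
    counts: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    lengths_mb: Mapping[str, float],
) -> pd.DataFrame:
    """Long-format table of SNVs/Mb per (strain, chromosome).

    ``counts`` maps strain -> chromosome -> SNV count (or an equivalent
    strain x chromosome frame).  Every called chromosome must have a
    length; densities are count / length_mb.
    """
    if isinstance(counts, pd.DataFrame):
        counts = {s: counts.loc[s].to_dict() for s in counts.index}
    rows = []
    for strain, per_chrom in counts.items():
        for chrom, count in per_chrom.items():
            if chrom not in lengths_mb:
                raise ValueError(f"no length provided for chromosome {chrom!r}")
            length = float(lengths_mb[chrom])
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            if count < 0:
                raise ValueError("SNV counts must be >= 0")
            rows.append(
                {
                    "strain": strain,
                    "chromosome": chrom,
                    "snv_count": int(count),
                    "length_mb": length,
                    "density": count / length,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class MsyFold:
    mean: float
    sem: float | None
    per_strain: dict[str, float]


def msy_fold(
    table: pd.DataFrame,
    msy_name: str = "chrY",
    aggregate: str = "per_chromosome_mean",
) -> MsyFold:
    """MSY density elevation over the other chromosomes, across strains.

    Per strain, fold = density(MSY) / aggregate density of non-MSY
    chromosomes, where the aggregate is the unweighted mean of
    per-chromosome densities (default, matching the per-chromosome
    box-plot framing) or the length-weighted genome-wide density
    (aggregate="genome_wide").  SEM is across strains (NA for one).
    """
    if aggregate not in ("per_chromosome_mean", "genome_wide"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    folds: dict[str, float] = {}
    for strain, sub in table.groupby("strain"):
        msy_rows = sub[sub["chromosome"] == msy_name]
        if msy_rows.empty:
            raise ValueError(f"strain {strain!r} has no {msy_name} row")
        others = sub[sub["chromosome"] != msy_name]
        if aggregate == "per_chromosome_mean":
            denom = others["density"].mean()
        else:
            denom = others["snv_count"].sum() / others["length_mb"].sum()
        if not denom > 0:
            raise ValueError(f"strain {strain!r} has zero non-{msy_name} density")
        folds[str(strain)] = float(msy_rows["density"].iloc[0] / denom)
    values = pd.Series(folds, dtype=float)
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else None
    return MsyFold(mean=float(values.mean()), sem=sem, per_strain=folds)
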