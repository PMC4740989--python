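"""Readers and writers for the formats the pipeline touches.

VCF handling is a deliberate subset of v4.2: biallelic SNVs with a
per-sample AD (allelic depth) field, which is all the segregation
filters need.  Reading goes through pysam; the writer emits the subset
as text.  FASTA/FASTQ go through Biopython; tabular data are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .segregation import VariantTable

VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
]


def write_vcf(table: VariantTable, path) -> None:
    """Write the minimal VCF subset: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + AD."""
    path = Path(path)
    samples = table.samples
    with path.open("w") as fh:
        for line in VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom in dict.fromkeys(table.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        ref_m = table.ref_counts.to_numpy()
        alt_m = table.alt_counts.to_numpy()
        for i, row in enumerate(table.sites.itertuples(index=False)):
            ads = "\t".join(f"{ref_m[i, j]},{alt_m[i, j]}" for j in range(len(samples)))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tAD\t{ads}\n")


def read_vcf_minimal(path) -> VariantTable:
    """Read a VCF 4.x with per-sample AD into a VariantTable.

    Multi-allelic records are split into one biallelic record per
    alternate allele (AD ref count shared, alt count per allele);
    1-based positions are preserved.  A record without AD for some
    sample is an error naming the sample and site.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: not a parseable VCF: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    rows, ref_rows, alt_rows = [], [], []
    for rec_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
        alts = rec.alts or ()
        ads = []
        for s in samples:
            ad = rec.samples[s].get("AD")
            if ad is None or any(v is None for v in ad):
                raise FormatError(
                    f"{path}: missing AD for sample {s!r} at record {rec_no} "
                    f"({rec.chrom}:{rec.pos})"
                )
            if len(ad) != 1 + len(alts):
                raise FormatError(
                    f"{path}: AD has {len(ad)} values for {1 + len(alts)} alleles "
                    f"at {rec.chrom}:{rec.pos} (sample {s!r})"
                )
            ads.append(ad)
        for alt_i, alt in enumerate(alts, start=1):
            rows.append({"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt})
            ref_rows.append([ad[0] for ad in ads])
            alt_rows.append([ad[alt_i] for ad in ads])
    vcf.close()
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    shape = (len(rows), len(samples))
    return VariantTable(
        sites,
        pd.DataFrame(np.array(ref_rows, dtype=np.int64).reshape(shape), columns=samples),
        pd.DataFrame(np.array(alt_rows, dtype=np.int64).reshape(shape), columns=samples),
    )


def write_variant_tsv(table: VariantTable, path) -> None:
    """TSV twin of the VCF subset: one "ref,alt" count cell per sample."""
    df = table.sites.copy()
    for s in table.samples:
        df[s] = [
            f"{r},{a}" for r, a in zip(table.ref_counts[s], table.alt_counts[s])
        ]
    df.to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: variant TSV needs columns {sorted(required)}")
    samples = [c for c in df.columns if c not in required]
    refs, alts = {}, {}
    for s in samples:
        try:
            parts = df[s].astype(str).str.split(",", expand=True).astype(np.int64)
        except ValueError as exc:
            raise FormatError(f"{path}: bad count cell in column {s!r}: {exc}") from exc
        refs[s], alts[s] = parts[0], parts[1]
    return VariantTable(
        df[["chrom", "pos", "ref", "alt"]], pd.DataFrame(refs), pd.DataFrame(alts)
    )


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (qualities are ignored:
    matching is identity-based) or a plain one-sequence-per-line list."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        fmt = "fastq"
    elif suffix in (".fa", ".fasta", ".fna"):
        fmt = "fasta"
    else:
        with path.open() as fh:
            return [line.strip().upper() for line in fh if line.strip()]
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    required = {"gene", "chromosome", "gene_start", "gene_end", "exon_starts", "exon_ends"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation missing columns {sorted(missing)}")
    if "msy_native" not in df.columns:
        df["msy_native"] = False
    df["msy_native"] = df["msy_native"].astype(bool)
    return df


def read_lengths(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"chromosome", "length_mb"}.issubset(df.columns):
        raise FormatError(f"{path}: lengths TSV needs chromosome and length_mb columns")
    return dict(zip(df["chromosome"].astype(str), df["length_mb"].astype(float)))


def write_panel(panel, outdir) -> None:
    """Write every artifact of a simulated panel under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(panel.variants, outdir / "panel.vcf")
    write_variant_tsv(panel.variants, outdir / "panel.tsv")
    panel.sample_sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_fasta(panel.contigs, outdir / "msy_contigs.fa")
    write_fasta(panel.ref_segments, outdir / "gene_reference.fa")
    panel.annotation.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "chromosome": list(panel.config.chromosome_lengths),
            "length_mb": list(panel.config.chromosome_lengths.values()),
        }
    ).to_csv(outdir / "chromosome_lengths.tsv", sep="\t", index=False)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for sample, reads in panel.dna_reads.items():
        write_fasta(
            {f"{sample}_read{i}": r for i, r in enumerate(reads, 1)},
            reads_dir / f"{sample}.fa",
        )
    for ds, reads in panel.rna_datasets.items():
        write_fasta(
            {f"{ds}_read{i}": r for i, r in enumerate(reads, 1)},
            reads_dir / f"{ds}.fa",
        )
    write_fasta({"sex_marker": panel.sex_probe}, outdir / "sex_probe.fa")
    write_fasta(panel.sry_probes, outdir / "sry_probes.fa")
    with (outdir / "truth.json").open("w") as fh:
        json.dump(panel.truth, fh, indent=1, sort_keys=True)
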