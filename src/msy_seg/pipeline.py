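"""End-to-end orchestration: simulate -> sex-call -> segregate ->
map-duplications -> quantify -> density -> phenotypes.

``run_all`` executes the stages in dependency order from a single
configuration, writes every intermediate artifact, and returns a
summary comparable against the generator's truth record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .density import density_table, msy_fold
from .errors import ConfigurationError
from .expression import copy_profile, count_marker_hits, distinguishability, rpm
from .mapping import (
    INDETERMINATE,
    PARTIAL_TRANSPOSED,
    UNPLACED,
    assess_pseudogene,
    build_probe,
    classify_mechanism,
    cluster_snvs,
    locate_on_msy,
    locate_template,
)
from .phenotypes import (
    classify_sex_difference,
    compare_consomic,
    sex_difference_flags,
    table3_class_counts,
)
from .segregation import (
    SegregationConfig,
    assign_genes,
    gene_af_summary,
    male_specific_sites,
    strain_specific_sites,
)
from .sexcall import infer_sex
from .simulate import (
    DuplicatedGeneSpec,
    Panel,
    PhenotypeEffect,
    SimulationConfig,
    SryCopySpec,
    simulate_panel,
    simulate_phenotypes,
    stage_rng,
)

log = logging.getLogger("msy_seg")


@dataclass
class PipelineConfig:
    """One configuration for the whole pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    segregation: SegregationConfig = field(default_factory=SegregationConfig)
    max_gap: int = 20
    flank: int = 12
    placement: str = "middle"
    rpm_threshold: float = 0.01
    template_max_mismatches: int = 3
    alpha: float = 0.05
    bonferroni_family: int | None = None
    consomic: str = "FHH-YBN"
    parental: str = "FHH"
    sex_diff_parents: tuple[str, str] = ("FHH", "BN")
    expression_dataset: str = "testis_male"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha: must be in (0, 1)")
        if self.max_gap < 1:
            raise ConfigurationError("max_gap: must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = dict(data.pop("simulation", {}))
        if "duplicated_genes" in sim:
            sim["duplicated_genes"] = [
                DuplicatedGeneSpec(
                    **{
                        **g,
                        "strains_lacking": frozenset(g.get("strains_lacking", [])),
                    }
                )
                for g in sim["duplicated_genes"]
            ]
        if "sry_copy_panel" in sim:
            sim["sry_copy_panel"] = [
                SryCopySpec(
                    name=c["name"],
                    variant_offsets=tuple(
                        (int(o), a) for o, a in c.get("variant_offsets", [])
                    ),
                    expression_weight=float(c.get("expression_weight", 0.0)),
                )
                for c in sim["sry_copy_panel"]
            ]
        if "phenotype_effects" in sim:
            sim["phenotype_effects"] = [PhenotypeEffect(**p) for p in sim["phenotype_effects"]]
        seg = SegregationConfig(**data.pop("segregation", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config fields: {sorted(unknown)}")
        if "sex_diff_parents" in data:
            data["sex_diff_parents"] = tuple(data["sex_diff_parents"])
        return cls(simulation=SimulationConfig(**sim), segregation=seg, **data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def demo_config(seed: int | None = None) -> PipelineConfig:
    """The packaged demo panel configuration (fixed seed unless given)."""
    with resources.files("msy_seg.data").joinpath("demo.yaml").open("r") as fh:
        cfg = PipelineConfig.from_dict(yaml.safe_load(fh))
    if seed is not None:
        cfg = replace(cfg, simulation=replace(cfg.simulation, seed=int(seed)))
    return cfg


def map_duplications(
    variants,
    classes,
    annotation,
    ref_segments,
    contigs,
    cfg: PipelineConfig,
    rna_reads=(),
) -> dict[str, dict]:
    """Segregation + clustering + MSY placement + classification per gene.

    Returns one record per gene with candidate SNVs: counts, AF summary,
    strain absences, MSY placement, mechanism, marker RPM in
    ``rna_reads`` (if given), and pseudogene status.
    """
    male_mask = male_specific_sites(variants, classes, cfg.segregation)
    loo = strain_specific_sites(variants, classes, cfg.segregation)
    candidate = male_mask.copy()
    for mask in loo.values():
        candidate |= mask
    summaries = {
        s.gene: s for s in gene_af_summary(variants, classes, annotation, cfg.segregation)
    }
    gene_of_site = assign_genes(variants.sites, annotation)
    rna_reads = list(rna_reads)
    rna_total = len(rna_reads)
    gene_report: dict[str, dict] = {"_n_male_specific_sites": int(male_mask.sum())}
    for row in annotation.itertuples(index=False):
        gene = row.gene
        mask = gene_of_site.eq(gene).fillna(False).astype(bool) & candidate
        sites = variants.sites[mask.to_numpy()].sort_values("pos")
        if sites.empty:
            continue
        clusters = cluster_snvs(list(zip(sites["chrom"], sites["pos"])), cfg.max_gap)
        alt_by_pos = dict(zip(sites["pos"], sites["alt"]))
        context = ref_segments[gene]
        probes = [
            build_probe(
                context,
                row.gene_start,
                [p for _, p in cluster],
                [alt_by_pos[p] for _, p in cluster],
                flank=cfg.flank,
                placement=cfg.placement,
                probe_id=f"{gene}_cluster{i}",
                source_gene=gene,
            )
            for i, cluster in enumerate(clusters, 1)
        ]
        hits = [h for p in probes for h in locate_on_msy(p, contigs)]
        placed = bool(hits)

        # exon/intron sequences with detected alternate alleles applied:
        # the Y-borne copy carries the male-specific variants
        exon_starts = [int(x) for x in str(row.exon_starts).split(",")]
        exon_ends = [int(x) for x in str(row.exon_ends).split(",")]
        seg = list(context)
        for pos, alt in alt_by_pos.items():
            seg[pos - row.gene_start] = alt
        exon_seqs = [
            "".join(seg[s - row.gene_start : e - row.gene_start + 1])
            for s, e in zip(exon_starts, exon_ends)
        ]
        intron_seqs = [
            "".join(seg[e - row.gene_start + 1 : s2 - row.gene_start])
            for e, s2 in zip(exon_ends[:-1], exon_starts[1:])
        ]
        if placed:
            mechanism = classify_mechanism(
                exon_seqs,
                intron_seqs,
                contigs,
                source_on_msy=bool(row.msy_native),
                max_mismatches=cfg.template_max_mismatches,
            )
        else:
            mechanism = UNPLACED

        gene_rpm = 0.0
        if probes and rna_total > 0:
            gene_rpm = rpm(count_marker_hits(rna_reads, probes[0]), rna_total)

        if not placed or mechanism == PARTIAL_TRANSPOSED:
            status = INDETERMINATE
        else:
            orf = _extract_orf(
                mechanism, exon_seqs, intron_seqs, contigs, cfg.template_max_mismatches
            )
            status = (
                assess_pseudogene(orf, gene_rpm, cfg.rpm_threshold)
                if orf
                else INDETERMINATE
            )

        summary = summaries.get(gene)
        gene_report[gene] = {
            "chromosome": row.chromosome,
            "n_snvs": summary.n_snvs if summary else int(mask.sum()),
            "mean_af_pct": round(100 * summary.mean_af, 1) if summary else None,
            "sem_af_pct": (
                round(100 * summary.sem_af, 1)
                if summary and summary.sem_af is not None
                else None
            ),
            "strains_lacking": sorted(summary.strains_lacking) if summary else [],
            "strain_specific_snvs": summary.strain_specific_snvs if summary else {},
            "n_clusters": len(clusters),
            "msy_contig": hits[0][0] if placed else None,
            "msy_position": hits[0][1] if placed else None,
            "n_hits": len(hits),
            "mechanism": mechanism,
            "rpm": gene_rpm,
            "status": status,
        }
    return gene_report


def analyze_panel(panel: Panel, cfg: PipelineConfig) -> dict:
    """Run every analysis stage on an in-memory panel; returns the summary."""
    declared = dict(zip(panel.sample_sheet["sample"], panel.sample_sheet["declared_sex"]))
    calls = {
        s: infer_sex(panel.dna_reads[s], [panel.sex_probe], sample=s, declared_sex=declared[s])
        for s in panel.sample_sheet["sample"]
    }
    classes = {s: c.inferred_class for s, c in calls.items()}

    variants = panel.variants
    gene_report = map_duplications(
        variants,
        classes,
        panel.annotation,
        panel.ref_segments,
        panel.contigs,
        cfg,
        rna_reads=panel.rna_datasets.get(cfg.expression_dataset, []),
    )
    n_male_specific = gene_report.pop("_n_male_specific_sites")

    # --- Sry copy panel ---------------------------------------------------
    sry_summary: dict = {}
    if panel.sry_probes:
        profile = copy_profile(
            panel.rna_datasets,
            panel.sry_probes,
            focal_copy=(
                "Sry2" if "Sry2" in panel.sry_probes else next(iter(panel.sry_probes))
            ),
        )
        variant_map = {
            name: {int(o): a for o, a in info["variants"].items()}
            for name, info in panel.truth["sry_panel"].items()
        }
        nd_status = distinguishability(variant_map, panel.config.rna_read_length)
        sry_summary = {
            "copy_profile": profile.reset_index().to_dict(orient="records"),
            "distinguishability": nd_status,
        }

    # --- SNV density ------------------------------------------------------
    male_declared = panel.sample_sheet.loc[
        panel.sample_sheet["declared_sex"] == "male", "sample"
    ]
    alt_pos = variants.alt_counts[list(male_declared)].to_numpy() > 0
    counts = {
        s: dict(
            variants.sites.loc[alt_pos[:, j], "chrom"]
            .value_counts()
            .reindex(panel.config.chromosome_lengths.keys(), fill_value=0)
        )
        for j, s in enumerate(male_declared)
    }
    dens = density_table(counts, panel.config.chromosome_lengths)
    fold = msy_fold(dens, msy_name=panel.config.msy_name)

    # --- phenotypes -------------------------------------------------------
    pheno_summary: dict = {}
    pheno_table = pd.DataFrame()
    if panel.config.phenotype_effects:
        pheno_seed = int(stage_rng(panel.config.seed, "phenotypes").integers(0, 2**31 - 1))
        pheno_table = simulate_phenotypes(panel.config.phenotype_effects, pheno_seed)
        comparisons = compare_consomic(
            pheno_table,
            cfg.consomic,
            cfg.parental,
            family_size=cfg.bonferroni_family,
            alpha=cfg.alpha,
        )
        parent_a, parent_b = cfg.sex_diff_parents
        flags_a = sex_difference_flags(pheno_table, parent_a, cfg.bonferroni_family, cfg.alpha)
        flags_b = sex_difference_flags(pheno_table, parent_b, cfg.bonferroni_family, cfg.alpha)
        sig = comparisons[comparisons["significant"]].copy()
        sig["parent_a_mf"] = [
            flags_a.get((p, t), False) for p, t in zip(sig["phenotype"], sig["treatment"])
        ]
        sig["parent_b_mf"] = [
            flags_b.get((p, t), False) for p, t in zip(sig["phenotype"], sig["treatment"])
        ]
        if len(sig):
            class_counts, _ = classify_sex_difference(sig, "parent_a_mf", "parent_b_mf")
        else:
            class_counts = {}
        pheno_summary = {
            "n_tested": int(len(comparisons)),
            "n_significant": int(comparisons["significant"].sum()),
            "class_counts": class_counts,
            "comparisons": comparisons.to_dict(orient="records"),
        }

    return {
        "version": __version__,
        "seed": panel.config.seed,
        "sex_calls": {
            s: {"class": c.inferred_class, "y_marker_reads": c.y_marker_reads}
            for s, c in calls.items()
        },
        "n_male_specific_sites": n_male_specific,
        "genes": gene_report,
        "sry": sry_summary,
        "density": {
            "fold_mean": fold.mean,
            "fold_sem": fold.sem,
            "per_strain": fold.per_strain,
        },
        "phenotypes": pheno_summary,
        "table3_class_counts": table3_class_counts(),
    }


def _extract_orf(mechanism, exon_seqs, intron_seqs, contigs, max_mm) -> str | None:
    """Read the coding sequence back off the MSY locus itself, so planted
    disruptions (e.g. a premature stop absent from the expected template)
    are seen by the pseudogene assessment."""
    if mechanism == "retroposed":
        template = "".join(exon_seqs)
        loc = locate_template(template, contigs, max_mm)
        if loc is None:
            return None
        name, start, end, strand, _ = loc
        seq = contigs[name].upper()[start : end + 1]
        if strand == "-":
            from ._seq import revcomp

            seq = revcomp(seq)
        return seq
    # transposed / msy_duplication: locate the genomic copy, then splice
    parts = [exon_seqs[0]]
    for intron, exon in zip(intron_seqs, exon_seqs[1:]):
        parts.extend([intron, exon])
    template = "".join(parts)
    loc = locate_template(template, contigs, max_mm)
    if loc is None:
        return None
    name, start, end, strand, _ = loc
    seq = contigs[name].upper()[start : end + 1]
    if strand == "-":
        from ._seq import revcomp

        seq = revcomp(seq)
    orf, off = [], 0
    for i, exon in enumerate(exon_seqs):
        orf.append(seq[off : off + len(exon)])
        off += len(exon)
        if i < len(intron_seqs):
            off += len(intron_seqs[i])
    return "".join(orf)


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Simulate the panel, run every stage, and write all artifacts.

    Writes the panel under ``outdir/panel``, per-stage TSV reports, and
    ``summary.json``; returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_digest = hashlib.sha256(repr(cfg).encode()).hexdigest()[:12]
    log.info(
        "msy-seg %s run-all seed=%s config=%s", __version__, cfg.simulation.seed, cfg_digest
    )
    panel = simulate_panel(cfg.simulation)
    panel.write(outdir / "panel")
    summary = analyze_panel(panel, cfg)

    pd.DataFrame(
        [
            {
                "sample": s,
                "declared_sex": panel.sample_sheet.set_index("sample").loc[s, "declared_sex"],
                "y_marker_reads": info["y_marker_reads"],
                "inferred_class": info["class"],
            }
            for s, info in summary["sex_calls"].items()
        ]
    ).to_csv(outdir / "sex_calls.tsv", sep="\t", index=False)

    report_rows = []
    for gene, info in summary["genes"].items():
        report_rows.append(
            {
                "gene": gene,
                "chromosome": info["chromosome"],
                "n_snvs": info["n_snvs"],
                "mean_af_pct": info["mean_af_pct"],
                "sem_af_pct": info["sem_af_pct"],
                "strains_lacking": ",".join(info["strains_lacking"]),
                "strain_specific_snvs": ";".join(
                    f"{s}({n})" for s, n in sorted(info["strain_specific_snvs"].items())
                ),
                "msy_contig": info["msy_contig"],
                "mechanism": info["mechanism"],
                "rpm": info["rpm"],
                "status": info["status"],
            }
        )
    pd.DataFrame(report_rows).to_csv(outdir / "dup_candidates.tsv", sep="\t", index=False)

    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return summary
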