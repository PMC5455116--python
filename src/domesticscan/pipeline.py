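"""End-to-end orchestration: from reference + GFF3 + per-accession VCFs to
report tables and track files.

Stages, in order: per-accession filtered variant sets; per-species
common/percent-common tables; species-specific variants; the all-wild
partition; wild-vs-cultivated differential alleles with region/effect
annotation; genic ratios; resistance-gene report; cultivated-panel window
statistics with wild-vs-cultivated Fst; SNP density tracks; threshold-merged
Tajima's D selection regions.  A manifest records parameters and per-stage
record counts for reproducibility.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_algebra import (
    AccessionVariantSet,
    CohortSpec,
    CommonWildPartition,
    common_within_species,
    common_wild_partition,
    percent_common_table,
    species_specific,
    wild_differential,
)
from .gene_annotation import (
    DEFAULT_RESISTANCE_KEYWORDS,
    GENIC_REGIONS,
    FLANK_DOWN,
    FLANK_UP,
    GeneIndex,
    annotate_variants,
    annotations_to_frame,
    filter_genes_by_keyword,
    genic_ratio,
)
from .popgen_windows import (
    density_track,
    regions_to_frame,
    selection_regions,
    snp_windows,
    tally_sites,
    windows_to_frame,
)
from .variant_io import (
    ConfigurationError,
    FilterPolicy,
    Genotype,
    ReferenceGenome,
    VariantRecord,
    keys_to_frame,
    normalize_variant,
    read_gene_models,
    read_vcf,
    write_bed,
    write_bedgraph,
    write_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reference: str
    gff: str
    vcf_dir: str
    cohort: str
    outdir: str = "domesticscan_out"
    min_depth: int = 5
    min_qual: float = 30.0
    use_gq: bool = False
    window_snps: int = 500
    step_snps: int = 100
    d_low: float = -3.0
    d_high: float = 2.0
    flank: int = 2000
    density_bin: int = 1_000_000
    keywords: list[str] = field(default_factory=lambda: list(DEFAULT_RESISTANCE_KEYWORDS))
    percent_common_denominator: str = "union"
    assess_start_gain: bool = True
    include_partial_windows: bool = False

    def __post_init__(self):
        if not (self.window_snps >= self.step_snps >= 1):
            raise ConfigurationError("need window_snps >= step_snps >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    cohort: CohortSpec
    sets: dict[str, AccessionVariantSet]
    percent_common: pd.DataFrame
    species_specific: dict[str, frozenset]
    partition: CommonWildPartition
    differential: frozenset
    differential_table: pd.DataFrame
    effect_summary: pd.DataFrame
    genic_ratios: pd.DataFrame
    rgene_table: pd.DataFrame
    windows: pd.DataFrame
    regions: pd.DataFrame
    manifest: dict


def load_accession_records(
    config: PipelineConfig, cohort: CohortSpec, reference: ReferenceGenome
) -> dict[str, list[VariantRecord]]:
    """Read, normalize and collect each accession's VCF records."""
    vcf_dir = Path(config.vcf_dir)
    records: dict[str, list[VariantRecord]] = {}
    for member in cohort.members:
        path = vcf_dir / f"{member.accession_id}.vcf"
        if not path.exists():
            path = vcf_dir / f"{member.accession_id}.vcf.gz"
        if not path.exists():
            raise ConfigurationError(f"no VCF found for accession {member.accession_id}")
        recs = []
        for rec in read_vcf(path, member.accession_id):
            if rec.vtype != "SNP":
                rec = normalize_variant(rec, reference)
            recs.append(rec)
        records[member.accession_id] = recs
    return records


def build_sets(
    config: PipelineConfig,
    cohort: CohortSpec,
    records: dict[str, list[VariantRecord]],
) -> dict[str, AccessionVariantSet]:
    wild_policy = FilterPolicy(
        min_depth=config.min_depth,
        min_qual=config.min_qual,
        require_fixed_nonref=True,
        use_gq=config.use_gq,
    )
    sets = {}
    for member in cohort.members:
        policy = wild_policy if member.group == "wild" else FilterPolicy.unfiltered()
        sets[member.accession_id] = AccessionVariantSet.from_records(
            records[member.accession_id], member, policy
        )
    return sets


def run_all(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    outdir = Path(config.outdir)
    stage = "load"
    try:
        reference = ReferenceGenome.from_fasta(config.reference)
        genes = read_gene_models(config.gff, reference.lengths)
        index = GeneIndex(genes, flank=config.flank)
        cohort = CohortSpec.from_tsv(config.cohort)
        cohort.validate_for_differential()
        records = load_accession_records(config, cohort, reference)
        sets = build_sets(config, cohort, records)
        manifest_counts = {
            "accessions": len(cohort.members),
            "wild_accessions": len(cohort.wild_accessions),
            "cultivated_accessions": len(cohort.cultivated_accessions),
            "genes": len(genes),
        }

        stage = "common"
        pct = percent_common_table(sets, cohort, config.percent_common_denominator)
        common_sets = {
            sp: common_within_species([sets[a] for a in cohort.species_accessions[sp]])
            for sp in cohort.wild_species
        }

        stage = "specific"
        specific = {
            sp: species_specific(sp, sets, cohort)
            for sp in cohort.wild_species
            if len(cohort.species_accessions[sp]) >= 2
        }
        manifest_counts["species_specific"] = {sp: len(v) for sp, v in specific.items()}

        stage = "partition"
        wild_sets = [sets[a] for a in cohort.wild_accessions]
        partition = common_wild_partition(wild_sets)
        manifest_counts["common_wild"] = partition.counts()

        stage = "differential"
        cultivated_sets = [sets[a] for a in cohort.cultivated_accessions]
        differential = wild_differential(partition, cultivated_sets)
        manifest_counts["differential"] = {
            "total": len(differential),
            "snps": sum(1 for k in differential if k.is_snp),
            "indels": sum(1 for k in differential if not k.is_snp),
        }

        stage = "annotate"
        annotations = annotate_variants(
            differential,
            index,
            reference,
            assess_start_gain=config.assess_start_gain,
        )
        diff_table = annotations_to_frame(annotations)
        genic_hits = diff_table[diff_table["region"].isin(GENIC_REGIONS)]
        flank_hits = diff_table[diff_table["region"].isin((FLANK_UP, FLANK_DOWN))]
        manifest_counts["differential_annotation"] = {
            "genic": int(len(genic_hits)),
            "genes_hit": int(genic_hits["gene_id"].nunique()),
            "cds": int((diff_table["region"] == "CDS").sum()),
            "flank_2kb": int(len(flank_hits)),
        }

        stage = "effects"
        high = diff_table[diff_table["impact"] == "HIGH"]
        effect_counts = Counter(high["effect"])
        effect_summary = pd.DataFrame(
            sorted(effect_counts.items()), columns=["effect", "n_variants"]
        )
        manifest_counts["high_impact"] = dict(effect_counts)

        stage = "genic_ratio"
        ratio_rows = []
        for sp, common in common_sets.items():
            for vtype in ("SNP", "INDEL"):
                r = genic_ratio(common, index, sp, vtype)
                ratio_rows.append(
                    {
                        "species": sp,
                        "vtype": vtype,
                        "n_genic": r.n_genic,
                        "n_total": r.n_total,
                        "ratio": r.ratio,
                    }
                )
        ratios = pd.DataFrame(ratio_rows)

        stage = "rgenes"
        rgenes = filter_genes_by_keyword(genes, config.keywords)
        rgene_ids = {g.gene_id for g in rgenes}
        rgene_hits = genic_hits[genic_hits["gene_id"].isin(rgene_ids)].copy()
        rgene_hits["annotation"] = rgene_hits["gene_id"].map(
            {g.gene_id: g.annotation for g in rgenes}
        )
        manifest_counts["resistance_genes"] = {
            "keyword_matches": len(rgenes),
            "with_differential_variant": int(rgene_hits["gene_id"].nunique()),
        }

        stage = "popgen"
        cult_records = {a: records[a] for a in cohort.cultivated_accessions}
        sites = tally_sites(cult_records, cohort.cultivated_accessions)
        # wild allele counts at the same sites, for the between-group Fst
        wild_records = {a: records[a] for a in cohort.wild_accessions}
        wild_sites = tally_sites(wild_records, cohort.wild_accessions, min_n=2)
        wild_lookup = {
            (r.chrom, r.pos, r.alt): (r.k, r.n) for r in wild_sites.itertuples(index=False)
        }
        n_wild_default = 2 * len(cohort.wild_accessions)
        k2, n2 = [], []
        for r in sites.itertuples(index=False):
            kw, nw = wild_lookup.get((r.chrom, r.pos, r.alt), (0, n_wild_default))
            k2.append(kw)
            n2.append(nw)
        sites = sites.assign(k2=k2, n2=n2)
        windows = snp_windows(sites, config.window_snps, config.step_snps)
        windows_df = windows_to_frame(windows)
        manifest_counts["popgen"] = {
            "sites": int(len(sites)),
            "windows": int(len(windows)),
        }

        stage = "regions"
        regions = selection_regions(
            windows,
            low=config.d_low,
            high=config.d_high,
            genes=genes,
            include_partial=config.include_partial_windows,
        )
        regions_df = regions_to_frame(regions)
        per_chrom = (
            regions_df[regions_df["direction"] == "purifying"]
            .groupby("chrom")["length_bp"]
            .sum()
            .to_dict()
            if len(regions_df)
            else {}
        )
        manifest_counts["selection_regions"] = {
            "purifying": int((regions_df["direction"] == "purifying").sum()) if len(regions_df) else 0,
            "balancing": int((regions_df["direction"] == "balancing").sum()) if len(regions_df) else 0,
            "purifying_bp_by_chrom": per_chrom,
        }

        manifest = {
            "tool": "domesticscan",
            "version": __version__,
            "parameters": asdict(config),
            "counts": manifest_counts,
        }

        result = PipelineResult(
            cohort=cohort,
            sets=sets,
            percent_common=pct,
            species_specific=specific,
            partition=partition,
            differential=differential,
            differential_table=diff_table,
            effect_summary=effect_summary,
            genic_ratios=ratios,
            rgene_table=rgene_hits,
            windows=windows_df,
            regions=regions_df,
            manifest=manifest,
        )

        if write_outputs:
            stage = "write"
            _write_outputs(config, result, reference, cohort, common_sets, sites)
        return result
    except Exception as exc:
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_outputs(config, result, reference, cohort, common_sets, sites) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()

    write_table(result.percent_common, outdir / "percent_common.tsv")
    for sp, keys in result.species_specific.items():
        safe = sp.replace(" ", "_").replace(".", "")
        write_table(keys_to_frame(keys), outdir / f"species_specific.{safe}.tsv")
    write_table(keys_to_frame(result.partition.same_allele), outdir / "common_wild_same_allele.tsv")
    part_df = pd.DataFrame([result.partition.counts()])
    write_table(part_df, outdir / "common_wild_summary.tsv")
    write_table(result.differential_table, outdir / "differential_variants.tsv")
    write_table(result.effect_summary, outdir / "high_impact_summary.tsv")
    write_table(result.genic_ratios, outdir / "genic_ratios.tsv")
    write_table(result.rgene_table, outdir / "rgene_report.tsv")
    write_table(result.windows, outdir / "window_stats.tsv")
    write_table(result.regions, outdir / "selection_regions.tsv")
    if len(result.regions):
        write_bed(
            [
                (r.chrom, r.start, r.end, r.direction)
                for r in result.regions.itertuples(index=False)
            ],
            outdir / "selection_regions.bed",
        )
    # density tracks: cultivated sites plus each species' common set
    lengths = reference.lengths
    write_bedgraph(
        density_track(sites[["chrom", "pos"]], lengths, config.density_bin),
        outdir / "density.cultivated.bedgraph",
    )
    for sp, keys in common_sets.items():
        safe = sp.replace(" ", "_").replace(".", "")
        df = keys_to_frame([k for k in keys if k.is_snp])
        write_bedgraph(
            density_track(df[["chrom", "pos"]] if len(df) else pd.DataFrame({"chrom": [], "pos": []}), lengths, config.density_bin),
            outdir / f"density.common.{safe}.bedgraph",
        )
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    logger.info("wrote pipeline outputs to %s", outdir)
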