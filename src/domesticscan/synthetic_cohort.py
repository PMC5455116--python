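"""Synthetic multi-species cohort generator with planted ground truth.

Emulates the study design the pipeline targets: a wild panel of 12 species /
29 accessions with species-level allele sharing driven by reproductive
behavior (selfing species share most variants, outcrossing species few), a
low-diversity cultivated panel of 40 accessions, and planted variant
categories with known truth for every downstream stage:

* per-species **species-specific** variants (present in every accession of
  one species, absent everywhere else), with a configured genic fraction;
* **differential** alleles carried identically by every wild accession and by
  no cultivated allele call, split across CDS effect classes, introns,
  2-kb flanks, intergenic space and indels;
* **cultivated-shared** all-wild alleles that at least one cultivated
  accession also carries (negative controls for the differential set);
* **discordant** positions where every wild accession is variant but at
  least two alleles segregate (never genic);
* **filter negative controls** failing the depth/quality/homozygosity filter;
* a **sweep segment** whose cultivated-panel sites are all singletons,
  forcing windowed Tajima's D below -3 (a hard sweep also removes standing
  background variation, so no neutral cultivated sites are drawn inside the
  segment).

Everything is drawn from one seeded :class:`numpy.random.Generator`; the same
seed reproduces byte-identical FASTA/GFF3/VCF output.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from collections.abc import Mapping
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort_algebra import CohortMember, CohortSpec
from .gene_annotation import predict_effect
from .variant_io import (
    GeneModel,
    ReferenceGenome,
    VariantKey,
    VariantRecord,
    normalize_variant,
    reverse_complement,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

RESISTANCE_NOTES = (
    "NBS-LRR disease resistance protein",
    "TMV resistance N-like protein",
    "receptor like kinase",
    "Mlo family defense protein",
    "late blight resistance protein homolog",
    "disease resistance response protein",
)
BENIGN_NOTES = (
    "cytochrome P450 family protein",
    "MADS box transcription factor",
    "ubiquitin ligase family protein",
    "heat shock protein 70",
    "auxin response factor",
    "gibberellin 2-oxidase",
    "wax synthase isoform",
    "pectinesterase inhibitor",
    "pentatricopeptide repeat protein",
    "unknown protein",
    "serine carboxypeptidase",
    "glycosyl hydrolase family protein",
)


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    n_accessions: int
    sharing: float  # within-species probability that an accession carries a pool variant
    genic_fraction: float  # genic share of planted species-specific variants


# Wild panel mirroring the study cohort: accession counts per species, with
# sharing probabilities tracking reproductive behavior (high for selfers) and
# genic fractions increasing with distance from the cultivated species.
DEFAULT_WILD_PANEL: tuple[SpeciesConfig, ...] = (
    SpeciesConfig("S. pimpinellifolium", 3, 0.75, 0.08),
    SpeciesConfig("S. cheesmaniae", 2, 0.80, 0.06),
    SpeciesConfig("S. galapagense", 1, 0.80, 0.08),
    SpeciesConfig("S. chmielewskii", 2, 0.92, 0.20),
    SpeciesConfig("S. arcanum", 2, 0.35, 0.24),
    SpeciesConfig("S. neorickii", 2, 0.85, 0.22),
    SpeciesConfig("S. huaylasense", 3, 0.40, 0.28),
    SpeciesConfig("S. peruvianum", 2, 0.55, 0.32),
    SpeciesConfig("S. corneliomuelleri", 1, 0.60, 0.34),
    SpeciesConfig("S. chilense", 2, 0.55, 0.36),
    SpeciesConfig("S. habrochaites", 7, 0.30, 0.43),
    SpeciesConfig("S. pennellii", 2, 0.20, 0.40),
)


@dataclass(frozen=True)
class SweepConfig:
    chrom: str = "ch03"
    start: int = 2_000_000
    end: int = 2_400_000
    n_sites: int = 1600
    mode: str = "singleton"  # singleton | neutral


@dataclass(frozen=True)
class EffectPlan:
    stop_gained: int = 6
    stop_lost: int = 4
    start_lost: int = 2
    splice_site: int = 4
    frameshift: int = 3
    start_gained: int = 1

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"ch01": 5_000_000, "ch02": 5_000_000, "ch03": 5_000_000}
    )
    n_genes: int = 150
    codon_range: tuple[int, int] = (60, 300)
    cds_segment_range: tuple[int, int] = (1, 5)
    resistance_fraction: float = 0.10
    wild_panel: tuple[SpeciesConfig, ...] = DEFAULT_WILD_PANEL
    n_cultivated: int = 40
    wild_background_per_species: int = 2000
    cultivated_background_sites: int = 18_000
    cultivated_freq_range: tuple[float, float] = (0.0125, 0.5)
    n_species_specific: int = 50
    n_cultivated_shared: int = 80
    n_differential_genic_other: int = 30
    n_differential_flank: int = 20
    n_differential_intergenic: int = 40
    n_differential_indel: int = 10
    n_discordant: int = 30
    n_negative_controls: int = 30
    effects: EffectPlan = field(default_factory=EffectPlan)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    depth_offset: int = 5
    depth_poisson_mean: float = 15.0
    qual_range: tuple[float, float] = (40.0, 90.0)

    def __post_init__(self):
        if self.sweep.chrom not in self.chrom_lengths:
            raise ValueError("sweep chromosome not in chrom_lengths")
        if self.sweep.end > self.chrom_lengths[self.sweep.chrom]:
            raise ValueError("sweep span exceeds its chromosome")

    @classmethod
    def small(cls, seed: int = 0) -> "SimulationConfig":
        """Scaled-down configuration for fast structural tests."""
        panel = (
            SpeciesConfig("sp_selfer", 2, 0.9, 0.2),
            SpeciesConfig("sp_outcrosser", 3, 0.4, 0.4),
            SpeciesConfig("sp_single", 1, 0.7, 0.3),
            SpeciesConfig("sp_mid", 2, 0.7, 0.3),
        )
        return cls(
            seed=seed,
            chrom_lengths={"ch01": 600_000, "ch02": 600_000},
            n_genes=40,
            wild_panel=panel,
            n_cultivated=12,
            wild_background_per_species=300,
            cultivated_background_sites=2500,
            n_species_specific=20,
            n_cultivated_shared=15,
            n_differential_genic_other=8,
            n_differential_flank=5,
            n_differential_intergenic=10,
            n_differential_indel=4,
            n_discordant=8,
            n_negative_controls=9,
            effects=EffectPlan(2, 2, 1, 2, 2, 1),
            sweep=SweepConfig("ch02", 200_000, 320_000, 700),
        )


class GroundTruthError(RuntimeError):
    """Planting a ground-truth category failed (configuration infeasible)."""


@dataclass
class TruthSet:
    """Planted ground truth, serialized alongside the emitted cohort."""

    species_specific: dict[str, list[str]] = field(default_factory=dict)
    differential: list[str] = field(default_factory=list)
    effect_classes: dict[str, list[str]] = field(default_factory=dict)
    cultivated_shared: list[str] = field(default_factory=list)
    discordant_positions: list[list] = field(default_factory=list)
    negative_controls: list[dict] = field(default_factory=list)
    sweep: dict = field(default_factory=dict)
    genic_ratio: dict[str, dict] = field(default_factory=dict)
    common_by_species: dict[str, int] = field(default_factory=dict)
    resistance_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))

    def differential_keys(self) -> set[VariantKey]:
        return {VariantKey.from_string(s) for s in self.differential}

    def species_specific_keys(self, species: str) -> set[VariantKey]:
        return {VariantKey.from_string(s) for s in self.species_specific.get(species, [])}


# ---------------------------------------------------------------------------
# Reference + gene models
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.36) -> bytearray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(rng.choice(alphabet, size=length, p=p).tobytes())


def _partition_lengths(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    if parts == 1:
        return [total]
    extra = total - minimum * parts
    if extra < 0:
        raise GroundTruthError("cannot partition CDS into requested segments")
    weights = rng.dirichlet(np.ones(parts))
    alloc = np.floor(weights * extra).astype(int)
    alloc[0] += extra - alloc.sum()
    return [minimum + int(a) for a in alloc]


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random genome (GC ~ 0.36) plus non-overlapping gene models.

    Every gene's coding sequence starts with ATG, ends with a stop codon and
    contains no internal stop; 1-5 CDS segments on mixed strands; about 10%
    of annotation notes mention resistance-related functions.
    """
    seqs = {c: _random_sequence(rng, L) for c, L in config.chrom_lengths.items()}
    total_len = sum(config.chrom_lengths.values())
    genes: list[GeneModel] = []

    # distribute gene counts across chromosomes proportionally to length
    chroms = list(config.chrom_lengths)
    counts = {c: int(round(config.n_genes * config.chrom_lengths[c] / total_len)) for c in chroms}
    drift = config.n_genes - sum(counts.values())
    counts[chroms[0]] += drift

    n_res = int(round(config.resistance_fraction * config.n_genes))
    res_flags = np.zeros(config.n_genes, dtype=bool)
    res_flags[:n_res] = True
    rng.shuffle(res_flags)

    gene_no = 0
    for chrom in chroms:
        n = counts[chrom]
        if n <= 0:
            continue
        # draw structural components first, then fit them with random gaps
        plans = []
        for _ in range(n):
            n_seg = int(rng.integers(config.cds_segment_range[0], config.cds_segment_range[1] + 1))
            n_codons = int(rng.integers(config.codon_range[0], config.codon_range[1] + 1))
            coding_len = 3 * n_codons
            seg_lens = _partition_lengths(rng, coding_len, n_seg, 9)
            introns = [int(rng.integers(60, 601)) for _ in range(n_seg - 1)]
            utr5 = int(rng.integers(100, 401))
            utr3 = int(rng.integers(100, 401))
            span = utr5 + sum(seg_lens) + sum(introns) + utr3
            plans.append((utr5, utr3, seg_lens, introns, span))
        margin = 3000
        occupied = sum(p[4] for p in plans)
        free = config.chrom_lengths[chrom] - occupied - 2 * margin
        if free <= n:
            raise GroundTruthError(f"gene placement infeasible on {chrom}")
        gaps = np.floor(rng.dirichlet(np.ones(n + 1)) * free).astype(int)
        cursor = margin
        for i, (utr5, utr3, seg_lens, introns, span) in enumerate(plans):
            cursor += int(gaps[i])
            start = cursor
            end = start + span - 1
            cursor = end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            gid = f"gene_{chrom}_{gene_no:04d}"

            # genomic CDS segment coordinates (left to right)
            seg_coords = []
            pos = start + (utr5 if strand == "+" else utr3)
            for j, seg_len in enumerate(seg_lens if strand == "+" else seg_lens[::-1]):
                seg_coords.append((pos, pos + seg_len - 1))
                pos += seg_len
                if j < len(seg_lens) - 1:
                    pos += introns[j] if strand == "+" else introns[::-1][j]

            n_internal = sum(seg_lens) // 3 - 2
            internal_idx = rng.integers(0, len(_NON_STOP_CODONS), n_internal)
            coding = (
                "ATG"
                + "".join(_NON_STOP_CODONS[j] for j in internal_idx)
                + _STOPS[int(rng.integers(0, 3))]
            )
            genomic = coding if strand == "+" else reverse_complement(coding)
            # write coding sequence into the genome across the segments
            offset = 0
            for s, e in seg_coords:
                seg_len = e - s + 1
                seqs[chrom][s - 1 : e] = genomic[offset : offset + seg_len].encode()
                offset += seg_len

            # phases in transcription order, mapped back to genomic order
            tx_order = seg_coords if strand == "+" else seg_coords[::-1]
            phases_tx = []
            cum = 0
            for s, e in tx_order:
                phases_tx.append((3 - cum % 3) % 3)
                cum += e - s + 1
            phase_by_seg = dict(zip(tx_order, phases_tx))
            cds = tuple((s, e, phase_by_seg[(s, e)]) for s, e in seg_coords)

            note = (
                str(rng.choice(RESISTANCE_NOTES))
                if res_flags[gene_no - 1]
                else str(rng.choice(BENIGN_NOTES))
            )
            annotation = f"ID={gid};Name={gid};Note={note}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    cds=cds,
                    annotation=annotation,
                    transcript_id=f"{gid}.1",
                )
            )

    reference = ReferenceGenome({c: bytes(s).decode() for c, s in seqs.items()})
    return reference, genes


def write_gff(genes: list[GeneModel], chrom_lengths: Mapping[str, int], path: str | Path) -> None:
    path = Path(path)
    lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{g.annotation}"
        )
        tid = g.transcript_id or f"{g.gene_id}.1"
        lines.append(
            f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}"
        )
        for s, e, phase in g.cds:
            lines.append(
                f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tID={tid}.cds;Parent={tid}"
            )
    path.write_text("\n".join(lines) + "\n")


def write_fasta(reference: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(reference[c]), id=c, description="") for c in reference]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

CallRow = tuple[str, str, str, int]  # (gt, dp, qual) packed as (gt, qual_str, ref?) -- see _CallData


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    reference: ReferenceGenome
    genes: list[GeneModel]
    cohort: CohortSpec
    calls: dict[str, dict[VariantKey, tuple[str, int, float]]]  # accession -> key -> (gt, dp, qual)
    truth: TruthSet


class _Planter:
    """Internal helper carrying shared state during simulation."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.reference, self.genes = generate_reference(config, rng)
        self.used: dict[str, set[int]] = {c: set() for c in config.chrom_lengths}
        self.gene_starts: dict[str, list[int]] = {}
        self.gene_rows: dict[str, list[GeneModel]] = {}
        for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
            self.gene_starts.setdefault(g.chrom, []).append(g.start)
            self.gene_rows.setdefault(g.chrom, []).append(g)
        self.chroms = list(config.chrom_lengths)
        lengths = np.array([config.chrom_lengths[c] for c in self.chroms], dtype=float)
        self.chrom_weights = lengths / lengths.sum()

    # -- position helpers ------------------------------------------------

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        starts = self.gene_starts.get(chrom, [])
        i = bisect_right(starts, pos) - 1
        if i >= 0:
            g = self.gene_rows[chrom][i]
            if g.contains(pos):
                return g
        return None

    def near_gene(self, chrom: str, pos: int, flank: int = 2000) -> bool:
        starts = self.gene_starts.get(chrom, [])
        i = bisect_right(starts, pos) - 1
        for j in (i, i + 1):
            if 0 <= j < len(starts):
                g = self.gene_rows[chrom][j]
                if g.start - flank <= pos <= g.end + flank:
                    return True
        return False

    def in_sweep(self, chrom: str, pos: int) -> bool:
        sw = self.config.sweep
        return chrom == sw.chrom and sw.start <= pos <= sw.end

    def claim(self, chrom: str, pos: int, span: int = 1) -> bool:
        cells = range(pos, pos + span)
        if pos < 2 or pos + span - 1 > self.config.chrom_lengths[chrom] - 1:
            return False
        if any(p in self.used[chrom] for p in cells):
            return False
        self.used[chrom].update(cells)
        return True

    def sample_position(self, predicate=None, chrom: str | None = None, span: int = 1, tries: int = 10_000):
        for _ in range(tries):
            c = chrom or str(self.rng.choice(self.chroms, p=self.chrom_weights))
            pos = int(self.rng.integers(2, self.config.chrom_lengths[c] - span))
            if predicate is not None and not predicate(c, pos):
                continue
            if self.claim(c, pos, span):
                return c, pos
        raise GroundTruthError("could not place a variant after many tries")

    def ref_base(self, chrom: str, pos: int) -> str:
        return self.reference[chrom][pos - 1]

    def alt_base(self, ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return str(self.rng.choice(choices))

    def conf_depth(self) -> int:
        return int(self.config.depth_offset + self.rng.poisson(self.config.depth_poisson_mean))

    def conf_qual(self) -> float:
        return float(round(self.rng.uniform(*self.config.qual_range), 1))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full cohort with planted ground truth (see module doc)."""
    rng = np.random.default_rng(config.seed)
    P = _Planter(config, rng)
    reference, genes = P.reference, P.genes

    members: list[CohortMember] = []
    idx = 0
    for sp in config.wild_panel:
        for _ in range(sp.n_accessions):
            idx += 1
            members.append(CohortMember(f"WA{idx:02d}", sp.name, "wild"))
    for i in range(config.n_cultivated):
        members.append(CohortMember(f"CU{i + 1:02d}", "S. lycopersicum", "cultivated"))
    cohort = CohortSpec(members)
    wild_ids = cohort.wild_accessions
    cult_ids = cohort.cultivated_accessions
    species_ids = {sp.name: cohort.species_accessions[sp.name] for sp in config.wild_panel}

    calls: dict[str, dict[VariantKey, tuple[str, int, float]]] = {
        m.accession_id: {} for m in members
    }
    truth = TruthSet()
    truth.resistance_genes = sorted(
        g.gene_id for g in genes if any(k.lower() in g.annotation.lower() for k in ("resistance", "nbs-lrr", "kinase", "mlo", "blight"))
    )

    def add_wild_all(key: VariantKey) -> None:
        for acc in wild_ids:
            calls[acc][key] = ("1/1", P.conf_depth(), P.conf_qual())

    # -- species-specific variants --------------------------------------
    multi_species = [sp for sp in config.wild_panel if sp.n_accessions >= 2]
    for sp in multi_species:
        n_genic = int(round(sp.genic_fraction * config.n_species_specific))
        planted: list[str] = []
        for i in range(config.n_species_specific):
            if i < n_genic:
                c, pos = P.sample_position(lambda c, p: P.gene_at(c, p) is not None)
            else:
                c, pos = P.sample_position(lambda c, p: P.gene_at(c, p) is None)
            ref = P.ref_base(c, pos)
            key = VariantKey(c, pos, ref, P.alt_base(ref))
            for acc in species_ids[sp.name]:
                calls[acc][key] = ("1/1", P.conf_depth(), P.conf_qual())
            planted.append(str(key))
        truth.species_specific[sp.name] = planted

    # -- differential alleles (all wild, no cultivated) ------------------
    differential: list[VariantKey] = []

    # effect-class variants inside CDS / splice windows / 5' UTR
    coding_pool = [g for g in genes if g.complete and g.cds_length >= 60]
    rng.shuffle(coding_pool)

    def next_gene(cond=lambda g: True) -> GeneModel:
        nonlocal coding_pool
        for g in list(coding_pool):
            if cond(g):
                coding_pool.remove(g)
                return g
        raise GroundTruthError("ran out of candidate genes for effect planting")

    def plant_effect(effect: str) -> VariantKey:
        for _ in range(200):
            if effect == "splice_site":
                gene = next_gene(lambda g: len(g.cds) >= 2)
            elif effect == "start_gained":
                gene = next_gene(lambda g: g.five_prime_genic_range() is not None
                                 and g.five_prime_genic_range()[1] - g.five_prime_genic_range()[0] >= 20)
            else:
                gene = next_gene()
            key = _try_plant_effect(P, gene, effect)
            if key is not None:
                return key
        raise GroundTruthError(f"could not plant effect {effect}")

    for effect, count in config.effects.as_dict().items():
        planted_keys: list[str] = []
        for _ in range(count):
            key = plant_effect(effect)
            add_wild_all(key)
            differential.append(key)
            planted_keys.append(str(key))
        if count:
            truth.effect_classes[effect] = planted_keys

    # intron (genic non-coding) differential SNPs, clear of splice windows
    def intron_interior(c: str, p: int) -> bool:
        g = P.gene_at(c, p)
        return g is not None and g.in_intron(p) and not g.is_splice_region(p, 4)

    for _ in range(config.n_differential_genic_other):
        c, pos = P.sample_position(intron_interior)
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        add_wild_all(key)
        differential.append(key)

    # 2-kb flank differential SNPs (near a gene but in no gene span)
    def flankish(c: str, p: int) -> bool:
        return P.gene_at(c, p) is None and P.near_gene(c, p)

    for _ in range(config.n_differential_flank):
        c, pos = P.sample_position(flankish)
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        add_wild_all(key)
        differential.append(key)

    # strictly intergenic differential SNPs
    def intergenic(c: str, p: int) -> bool:
        return not P.near_gene(c, p)

    for _ in range(config.n_differential_intergenic):
        c, pos = P.sample_position(intergenic)
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        add_wild_all(key)
        differential.append(key)

    # intergenic differential indels, emitted in canonical normalized form
    n_indels = 0
    while n_indels < config.n_differential_indel:
        c, pos = P.sample_position(intergenic, span=3)
        seq = reference[c]
        if rng.random() < 0.5:  # deletion of the base after the anchor
            key = VariantKey(c, pos, seq[pos - 1 : pos + 1], seq[pos - 1])
        else:  # insertion after the anchor
            ins = P.alt_base(seq[pos - 1])
            key = VariantKey(c, pos, seq[pos - 1], seq[pos - 1] + ins)
        rec = VariantRecord(key.chrom, key.pos, key.ref, key.alt)
        if normalize_variant(rec, reference).key != key:
            continue  # not canonical here; try another position
        add_wild_all(key)
        differential.append(key)
        n_indels += 1

    truth.differential = sorted(str(k) for k in differential)

    # -- all-wild alleles shared with cultivated -------------------------
    for _ in range(config.n_cultivated_shared):
        c, pos = P.sample_position(lambda c, p: not P.in_sweep(c, p))
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        add_wild_all(key)
        carriers = [a for a in cult_ids if rng.random() < 0.5]
        if not carriers:
            carriers = [str(rng.choice(cult_ids))]
        for acc in carriers:
            calls[acc][key] = ("0/1", P.conf_depth(), P.conf_qual())
        truth.cultivated_shared.append(str(key))

    # -- discordant all-wild positions (never genic) ----------------------
    for i in range(config.n_discordant):
        c, pos = P.sample_position(lambda c, p: P.gene_at(c, p) is None)
        ref = P.ref_base(c, pos)
        alts = [b for b in _BASES if b != ref]
        rng.shuffle(alts)
        alt_a, alt_b = alts[0], alts[1]
        split_sp = multi_species[i % len(multi_species)]
        split_acc = str(rng.choice(species_ids[split_sp.name]))
        for acc in wild_ids:
            alt = alt_b if acc == split_acc else alt_a
            calls[acc][VariantKey(c, pos, ref, alt)] = ("1/1", P.conf_depth(), P.conf_qual())
        truth.discordant_positions.append([c, pos])

    # -- filter negative controls -----------------------------------------
    modes = ("low_depth", "low_qual", "het")
    for i in range(config.n_negative_controls):
        acc = str(rng.choice(wild_ids))
        c, pos = P.sample_position()
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        mode = modes[i % 3]
        if mode == "low_depth":
            calls[acc][key] = ("1/1", int(rng.integers(1, 5)), P.conf_qual())
        elif mode == "low_qual":
            calls[acc][key] = ("1/1", P.conf_depth(), float(round(rng.uniform(5, 29.4), 1)))
        else:
            calls[acc][key] = ("0/1", P.conf_depth(), P.conf_qual())
        truth.negative_controls.append({"key": str(key), "accession": acc, "mode": mode})

    # -- wild background ---------------------------------------------------
    for sp in config.wild_panel:
        accs = species_ids[sp.name]
        for _ in range(config.wild_background_per_species):
            c, pos = P.sample_position()
            ref = P.ref_base(c, pos)
            key = VariantKey(c, pos, ref, P.alt_base(ref))
            mask = rng.random(len(accs)) < sp.sharing
            if not mask.any():
                continue
            for acc, has in zip(accs, mask):
                if has:
                    calls[acc][key] = ("1/1", P.conf_depth(), P.conf_qual())
            # a pool variant shared by a whole multi-accession species would
            # masquerade as species-specific: park the allele in one
            # cultivated accession, which excludes it by definition
            if len(accs) >= 2 and mask.all():
                blocker = str(rng.choice(cult_ids))
                calls[blocker][key] = ("0/1", P.conf_depth(), P.conf_qual())

    # -- cultivated background (outside the sweep span) --------------------
    p_lo, p_hi = config.cultivated_freq_range
    n_bg = config.cultivated_background_sites
    bg_sites = [P.sample_position(lambda c, p: not P.in_sweep(c, p)) for _ in range(n_bg)]
    freqs = rng.uniform(p_lo, p_hi, n_bg)
    allele_draws = rng.random((n_bg, config.n_cultivated, 2)) < freqs[:, None, None]
    alt_dosage = allele_draws.sum(axis=2)
    depths = config.depth_offset + rng.poisson(config.depth_poisson_mean, (n_bg, config.n_cultivated))
    quals = np.round(rng.uniform(*config.qual_range, (n_bg, config.n_cultivated)), 1)
    bg_keys = []
    for c, pos in bg_sites:
        ref = P.ref_base(c, pos)
        bg_keys.append(VariantKey(c, pos, ref, P.alt_base(ref)))
    for a, acc in enumerate(cult_ids):
        acc_calls = calls[acc]
        for s in np.nonzero(alt_dosage[:, a])[0]:
            gt = "1/1" if alt_dosage[s, a] == 2 else "0/1"
            acc_calls[bg_keys[s]] = (gt, int(depths[s, a]), float(quals[s, a]))

    # -- sweep segment: singleton-heavy cultivated frequency spectrum ------
    sw = config.sweep
    sweep_keys = []
    for _ in range(sw.n_sites):
        c, pos = P.sample_position(
            lambda c, p: P.in_sweep(c, p), chrom=sw.chrom
        )
        ref = P.ref_base(c, pos)
        key = VariantKey(c, pos, ref, P.alt_base(ref))
        sweep_keys.append(key)
        if sw.mode == "singleton":
            carrier = str(rng.choice(cult_ids))
            calls[carrier][key] = ("0/1", P.conf_depth(), P.conf_qual())
        else:  # neutral control mode
            p = float(rng.uniform(p_lo, p_hi))
            dosage = (rng.random((config.n_cultivated, 2)) < p).sum(axis=1)
            for acc, d in zip(cult_ids, dosage):
                if d:
                    calls[acc][key] = ("1/1" if d == 2 else "0/1", P.conf_depth(), P.conf_qual())
    truth.sweep = {
        "chrom": sw.chrom,
        "start": sw.start,
        "end": sw.end,
        "n_sites": sw.n_sites,
        "mode": sw.mode,
        "sites": sorted(str(k) for k in sweep_keys),
        "genes": sorted(
            g.gene_id
            for g in genes
            if g.chrom == sw.chrom and g.start <= sw.end and g.end >= sw.start
        ),
    }

    # -- ground-truth summaries -------------------------------------------
    passing: dict[str, set[VariantKey]] = {}
    for acc in wild_ids:
        passing[acc] = {
            k
            for k, (gt, dp, q) in calls[acc].items()
            if gt == "1/1" and dp >= 5 and q >= 30
        }
    for sp in config.wild_panel:
        accs = species_ids[sp.name]
        common = set(passing[accs[0]])
        for acc in accs[1:]:
            common &= passing[acc]
        truth.common_by_species[sp.name] = len(common)
        ratios = {}
        for vtype, pred in (("SNP", lambda k: k.is_snp), ("INDEL", lambda k: not k.is_snp)):
            keys = [k for k in common if pred(k)]
            n_genic = sum(1 for k in keys if P.gene_at(k.chrom, k.pos) is not None)
            ratios[vtype] = {"n_genic": n_genic, "n_total": len(keys)}
        truth.genic_ratio[sp.name] = ratios

    return SyntheticCohort(config, reference, genes, cohort, calls, truth)


def _try_plant_effect(P: _Planter, gene: GeneModel, effect: str) -> VariantKey | None:
    """Attempt to plant one SNP/indel of the requested effect class in `gene`,
    verifying the classification against :func:`predict_effect`."""
    rng = P.rng
    ref_genome = P.reference
    cds_seq = gene.cds_sequence(ref_genome)
    n_codons = len(cds_seq) // 3
    key: VariantKey | None = None

    if effect in ("stop_gained", "stop_lost", "start_lost"):
        if effect == "stop_gained":
            codon_idxs = list(rng.permutation(range(1, n_codons - 1)))
        elif effect == "stop_lost":
            codon_idxs = [n_codons - 1]
        else:
            codon_idxs = [0]
        for ci in codon_idxs:
            codon = cds_seq[ci * 3 : ci * 3 + 3]
            for within in range(3):
                for b in _BASES:
                    if b == codon[within]:
                        continue
                    new = codon[:within] + b + codon[within + 1 :]
                    if effect == "stop_gained" and not (codon not in _STOPS and new in _STOPS):
                        continue
                    if effect == "stop_lost" and not (codon in _STOPS and new not in _STOPS):
                        continue
                    if effect == "start_lost" and not (codon == "ATG" and new != "ATG"):
                        continue
                    gpos = gene.genomic_position(ci * 3 + within)
                    gref = ref_genome[gene.chrom][gpos - 1]
                    galt = b if gene.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                    key = VariantKey(gene.chrom, gpos, gref, galt)
                    if _finalize_effect_key(P, gene, key, effect):
                        return key
                    key = None
            if key is None and effect != "stop_gained":
                return None
        return None

    if effect == "splice_site":
        boundaries: list[int] = []
        for i, (s, e, _) in enumerate(gene.cds):
            if i > 0:
                boundaries.extend([s - 1, s - 2])
            if i < len(gene.cds) - 1:
                boundaries.extend([e + 1, e + 2])
        rng.shuffle(boundaries)
        for pos in boundaries:
            gref = ref_genome[gene.chrom][pos - 1]
            key = VariantKey(gene.chrom, pos, gref, P.alt_base(gref))
            if _finalize_effect_key(P, gene, key, effect):
                return key
        return None

    if effect == "frameshift":
        seq = ref_genome[gene.chrom]
        segs = [seg for seg in gene.cds if seg[1] - seg[0] >= 12]
        if not segs:
            return None
        s, e, _ = segs[int(rng.integers(len(segs)))]
        for _ in range(30):
            pos = int(rng.integers(s + 3, e - 4))
            if rng.random() < 0.5:
                key = VariantKey(gene.chrom, pos, seq[pos - 1 : pos + 1], seq[pos - 1])
            else:
                ins = P.alt_base(seq[pos - 1])
                if ins == seq[pos]:
                    continue
                key = VariantKey(gene.chrom, pos, seq[pos - 1], seq[pos - 1] + ins)
            rec = VariantRecord(key.chrom, key.pos, key.ref, key.alt)
            if normalize_variant(rec, ref_genome).key != key:
                continue
            if _finalize_effect_key(P, gene, key, effect, span=len(key.ref)):
                return key
        return None

    if effect == "start_gained":
        rng_range = gene.five_prime_genic_range()
        if rng_range is None:
            return None
        lo, hi = rng_range
        seq = ref_genome[gene.chrom]
        if gene.strand == "+":
            cds_anchor = gene.cds[0][0]
            starts = [a for a in range(lo, hi - 1) if (cds_anchor - a) % 3 == 0]
        else:
            cds_anchor = gene.cds[-1][1]
            starts = [a for a in range(lo, hi - 1) if ((a + 2) - cds_anchor) % 3 == 0]
        rng.shuffle(starts)
        for a in starts:
            tri = seq[a - 1 : a + 2]
            target = "ATG" if gene.strand == "+" else reverse_complement("ATG")
            mism = [i for i in range(3) if tri[i] != target[i]]
            if len(mism) != 1:
                continue
            i = mism[0]
            key = VariantKey(gene.chrom, a + i, tri[i], target[i])
            if _finalize_effect_key(P, gene, key, effect):
                return key
        return None

    raise ValueError(f"unknown effect class {effect!r}")


def _finalize_effect_key(
    P: _Planter, gene: GeneModel, key: VariantKey, effect: str, span: int = 1
) -> bool:
    if key.ref == key.alt:
        return False
    if any(p in P.used[key.chrom] for p in range(key.pos, key.pos + span)):
        return False
    ann = predict_effect(key, gene, P.reference, assess_start_gain=True)
    if ann.effect != effect:
        return False
    return P.claim(key.chrom, key.pos, span)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_vcf(
    accession_id: str,
    acc_calls: Mapping[VariantKey, tuple[str, int, float]],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=domesticscan-simulate",
    ]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{accession_id}")
    for key in sorted(acc_calls, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
        gt, dp, q = acc_calls[key]
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t{q:.1f}\t.\t.\tGT:DP\t{gt}:{dp}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, GFF3, cohort spec TSV, per-accession VCFs and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "gff": outdir / "genes.gff3",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.json",
        "vcf_dir": outdir / "vcf",
    }
    write_fasta(cohort.reference, paths["reference"])
    write_gff(cohort.genes, cohort.config.chrom_lengths, paths["gff"])
    cohort.cohort.to_tsv(paths["cohort"])
    cohort.truth.to_json(paths["truth"])
    paths["vcf_dir"].mkdir(exist_ok=True)
    for member in cohort.cohort.members:
        write_vcf(
            member.accession_id,
            cohort.calls[member.accession_id],
            cohort.config.chrom_lengths,
            paths["vcf_dir"] / f"{member.accession_id}.vcf",
        )
    return paths
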