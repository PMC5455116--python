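"""Placement of variants relative to gene models and coding-effect prediction.

Region assignment distinguishes genic positions (anywhere within the annotated
gene span, introns and UTRs included), 2-kb strand-aware upstream/downstream
flanks, and intergenic space.  For genic variants a simplified effect
classifier translates the affected codon before and after the change
(standard nuclear code, strand-aware) and assigns the conventional
HIGH/MODERATE/LOW/MODIFIER impact tiers:

=============  ========  =============================================
effect         impact    condition
=============  ========  =============================================
stop_gained    HIGH      non-stop codon becomes a stop
stop_lost      HIGH      annotated stop codon destroyed
start_lost     HIGH      initiator ATG destroyed
splice_site    HIGH      intronic base within 2 bp of a CDS boundary
frameshift     HIGH      CDS indel with length not divisible by 3
start_gained   HIGH*     ATG created 5' of the CDS, in frame (*optional)
missense       MODERATE  amino-acid change
inframe_indel  MODERATE  CDS indel, length divisible by 3
synonymous     LOW       same amino acid
non_coding     MODIFIER  everything else
=============  ========  =============================================
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .variant_io import GeneModel, ReferenceGenome, VariantKey

# region labels
CDS = "CDS"
INTRON = "intron"
GENIC_OTHER = "genic_other"  # UTR or non-coding genic
FLANK_UP = "flank_up_2kb"
FLANK_DOWN = "flank_down_2kb"
INTERGENIC = "intergenic"

GENIC_REGIONS = frozenset({CDS, INTRON, GENIC_OTHER})

HIGH_EFFECTS = frozenset({"stop_gained", "stop_lost", "start_lost", "splice_site", "frameshift"})

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = frozenset({"TAA", "TAG", "TGA"})


def _impact(effect: str, start_gain_high: bool = True) -> str:
    if effect in HIGH_EFFECTS:
        return "HIGH"
    if effect == "start_gained":
        return "HIGH" if start_gain_high else "MODIFIER"
    if effect in ("missense", "inframe_indel"):
        return "MODERATE"
    if effect == "synonymous":
        return "LOW"
    return "MODIFIER"


@dataclass(slots=True)
class VariantAnnotation:
    key: VariantKey
    region: str
    gene_id: str | None = None
    effect: str | None = None
    impact: str = "MODIFIER"
    all_genes: tuple[str, ...] = ()
    flagged: bool = False  # effect computed on an incomplete CDS model


class GeneIndex:
    """Interval index over gene spans plus their flanks."""

    def __init__(self, genes: Iterable[GeneModel], flank: int = 2000):
        self.flank = flank
        self.by_id: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.by_id[g.gene_id] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # interval end is exclusive
            tree.addi(max(1, g.start - flank), g.end + flank + 1, g.gene_id)

    def genes_near(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.by_id[iv.data] for iv in tree.at(pos)]
        return sorted(hits, key=lambda g: (g.span_length, g.gene_id))

    @property
    def genes(self) -> list[GeneModel]:
        return list(self.by_id.values())


def _refine_genic(gene: GeneModel, pos: int) -> str:
    if gene.in_cds(pos):
        return CDS
    if gene.in_intron(pos):
        return INTRON
    return GENIC_OTHER


def assign_region(key: VariantKey, index: GeneIndex) -> VariantAnnotation:
    """Primary region label for a variant position.

    Genic beats flank; among multiple overlapping genes the primary hit is
    deterministic: smallest span, then lexicographic gene id.  Flank direction
    is relative to the primary flanking gene's strand.
    """
    pos = key.pos
    near = index.genes_near(key.chrom, pos)
    genic = [g for g in near if g.contains(pos)]
    if genic:
        primary = genic[0]
        return VariantAnnotation(
            key,
            _refine_genic(primary, pos),
            gene_id=primary.gene_id,
            all_genes=tuple(g.gene_id for g in genic),
        )
    if near:
        primary = near[0]
        if primary.strand == "+":
            upstream = pos < primary.start
        else:
            upstream = pos > primary.end
        return VariantAnnotation(
            key,
            FLANK_UP if upstream else FLANK_DOWN,
            gene_id=primary.gene_id,
            all_genes=tuple(g.gene_id for g in near),
        )
    return VariantAnnotation(key, INTERGENIC)


def _coding_base(base: str, strand: str) -> str:
    return _COMP[base] if strand == "-" else base


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _snp_effect_in_cds(
    key: VariantKey, gene: GeneModel, cds_seq: str
) -> tuple[str, bool]:
    offset = gene.coding_offset(key.pos)
    assert offset is not None
    codon_i, within = divmod(offset, 3)
    flagged = not gene.complete
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:  # trailing partial codon of an incomplete model
        return "non_coding", True
    new_base = _coding_base(key.alt, gene.strand)
    old_base = _coding_base(key.ref, gene.strand)
    if codon[within] != old_base:
        raise ValueError(
            f"{key}: CDS sequence of {gene.gene_id} disagrees with REF allele"
        )
    new_codon = codon[:within] + new_base + codon[within + 1 :]
    if codon_i == 0 and codon == "ATG" and new_codon != "ATG":
        return "start_lost", flagged
    if codon in _STOPS and new_codon not in _STOPS:
        return "stop_lost", flagged
    if codon not in _STOPS and new_codon in _STOPS:
        return "stop_gained", flagged
    if _translate(codon) == _translate(new_codon):
        return "synonymous", flagged
    return "missense", flagged


def _start_gained(key: VariantKey, gene: GeneModel, reference: Mapping[str, str]) -> bool:
    """Does the SNP create an in-frame ATG in the genic region 5' of the CDS?"""
    rng = gene.five_prime_genic_range()
    if rng is None or not (rng[0] <= key.pos <= rng[1]):
        return False
    seq = reference[gene.chrom]
    if gene.strand == "+":
        cds_start = gene.cds[0][0]
        for atg_start in (key.pos - 2, key.pos - 1, key.pos):
            if atg_start < rng[0] or atg_start + 2 > rng[1]:
                continue
            if (cds_start - atg_start) % 3 != 0:
                continue
            tri = list(seq[atg_start - 1 : atg_start + 2])
            if "".join(tri) == "ATG":
                continue  # already a start codon without the variant
            tri[key.pos - atg_start] = key.alt
            if "".join(tri) == "ATG":
                return True
    else:
        cds_start = gene.cds[-1][1]  # first coding base in transcription order
        for atg_end in (key.pos + 2, key.pos + 1, key.pos):
            atg_start = atg_end - 2
            if atg_start < rng[0] or atg_end > rng[1]:
                continue
            if (atg_end - cds_start) % 3 != 0:
                continue
            tri = list(seq[atg_start - 1 : atg_end])
            idx = key.pos - atg_start
            from .variant_io import reverse_complement

            if reverse_complement("".join(tri)) == "ATG":
                continue
            tri[idx] = key.alt
            if reverse_complement("".join(tri)) == "ATG":
                return True
    return False


def _indel_touches_cds(key: VariantKey, gene: GeneModel) -> bool:
    if key.vtype == "DEL":
        # deleted reference bases are pos+1 .. pos+len(ref)-1 (anchor retained)
        return any(
            gene.in_cds(p) for p in range(key.pos + 1, key.pos + len(key.ref))
        )
    # insertion lands between pos and pos+1: inside CDS iff both sides coding
    return gene.in_cds(key.pos) and gene.in_cds(key.pos + 1)


def _indel_touches_splice(key: VariantKey, gene: GeneModel, window: int) -> bool:
    if key.vtype == "DEL":
        positions = range(key.pos + 1, key.pos + len(key.ref))
    else:
        positions = (key.pos, key.pos + 1)
    return any(gene.is_splice_region(p, window) for p in positions)


def predict_effect(
    key: VariantKey,
    gene: GeneModel,
    reference: ReferenceGenome | Mapping[str, str],
    *,
    splice_window: int = 2,
    assess_start_gain: bool = False,
    cds_seq: str | None = None,
) -> VariantAnnotation:
    """Classify the coding effect of a genic (or splice-window) variant.

    ``cds_seq`` may be passed to avoid re-extracting the coding sequence when
    many variants hit the same gene.  Incomplete CDS models are classified on
    the available frame and flagged.
    """
    region = _refine_genic(gene, key.pos) if gene.contains(key.pos) else INTERGENIC
    ann = VariantAnnotation(key, region, gene_id=gene.gene_id)

    if key.is_snp:
        if gene.is_splice_region(key.pos, splice_window):
            ann.effect = "splice_site"
        elif gene.in_cds(key.pos) and gene.cds:
            if cds_seq is None:
                cds_seq = gene.cds_sequence(reference)
            ann.effect, ann.flagged = _snp_effect_in_cds(key, gene, cds_seq)
        elif assess_start_gain and _start_gained(key, gene, reference):
            ann.effect = "start_gained"
        else:
            ann.effect = "non_coding"
    else:
        if _indel_touches_cds(key, gene):
            indel_len = abs(len(key.ref) - len(key.alt))
            ann.effect = "frameshift" if indel_len % 3 else "inframe_indel"
            ann.flagged = not gene.complete
        elif _indel_touches_splice(key, gene, splice_window):
            ann.effect = "splice_site"
        else:
            ann.effect = "non_coding"

    ann.impact = _impact(ann.effect, start_gain_high=True)
    return ann


def annotate_variants(
    keys: Iterable[VariantKey],
    index: GeneIndex,
    reference: ReferenceGenome | Mapping[str, str],
    *,
    splice_window: int = 2,
    assess_start_gain: bool = False,
) -> list[VariantAnnotation]:
    """Region + effect annotation for a collection of variants."""
    cds_cache: dict[str, str] = {}
    out = []
    for key in sorted(keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt)):
        ann = assign_region(key, index)
        if ann.region in GENIC_REGIONS and ann.gene_id is not None:
            gene = index.by_id[ann.gene_id]
            if gene.cds:
                if gene.gene_id not in cds_cache:
                    cds_cache[gene.gene_id] = gene.cds_sequence(reference)
                eff = predict_effect(
                    key,
                    gene,
                    reference,
                    splice_window=splice_window,
                    assess_start_gain=assess_start_gain,
                    cds_seq=cds_cache[gene.gene_id],
                )
                ann.effect, ann.impact, ann.flagged = eff.effect, eff.impact, eff.flagged
                ann.region = eff.region
            else:
                ann.effect, ann.impact = "non_coding", "MODIFIER"
        out.append(ann)
    return out


def annotations_to_frame(annotations: Sequence[VariantAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [a.key.chrom for a in annotations],
            "pos": [a.key.pos for a in annotations],
            "ref": [a.key.ref for a in annotations],
            "alt": [a.key.alt for a in annotations],
            "vtype": [a.key.vtype for a in annotations],
            "region": [a.region for a in annotations],
            "gene_id": [a.gene_id for a in annotations],
            "effect": [a.effect for a in annotations],
            "impact": [a.impact for a in annotations],
            "flagged": [a.flagged for a in annotations],
        }
    )


@dataclass(frozen=True, slots=True)
class GenicRatio:
    species: str
    vtype: str
    n_genic: int
    n_total: int

    @property
    def ratio(self) -> float | None:
        return None if self.n_total == 0 else self.n_genic / self.n_total


def genic_ratio(
    keys: Iterable[VariantKey],
    index: GeneIndex,
    species: str,
    vtype: str | None = "SNP",
) -> GenicRatio:
    """Fraction of a species' variants falling within annotated gene spans."""
    n_genic = n_total = 0
    for key in keys:
        if vtype == "SNP" and not key.is_snp:
            continue
        if vtype == "INDEL" and key.is_snp:
            continue
        n_total += 1
        if any(g.contains(key.pos) for g in index.genes_near(key.chrom, key.pos)):
            n_genic += 1
    return GenicRatio(species, vtype or "ALL", n_genic, n_total)


def filter_genes_by_keyword(
    genes: Iterable[GeneModel], keywords: Sequence[str]
) -> list[GeneModel]:
    """Genes whose annotation text matches any keyword (case-insensitive
    substring/regex).  An empty keyword list yields an empty result."""
    if not keywords:
        import logging

        logging.getLogger(__name__).warning("empty keyword list: no genes selected")
        return []
    patterns = [re.compile(k, re.IGNORECASE) for k in keywords]
    return [g for g in genes if any(p.search(g.annotation) for p in patterns)]


DEFAULT_RESISTANCE_KEYWORDS = (
    "NBS-LRR",
    "resistance",
    "receptor like kinase",
    "receptor-like kinase",
    "Mlo",
    "disease",
)
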