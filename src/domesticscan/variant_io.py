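"""Reading, normalization and filtering of variant, reference and gene-model inputs.

This module owns the on-disk formats (VCF v4.x via :mod:`pysam`, FASTA via
:mod:`pyfaidx`, GFF3 via :mod:`gffutils`) and the in-memory primitives the rest
of the pipeline is built on: :class:`VariantRecord`, :class:`VariantKey`,
:class:`GeneModel` and :class:`FilterPolicy`.

Coordinates are 1-based inclusive everywhere internally (the native VCF/GFF3
convention); only the BED/bedGraph writers convert to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class VcfParseError(ValueError):
    """A VCF body line could not be interpreted."""


class ConfigurationError(ValueError):
    """Inputs are inconsistent with the requested analysis."""


class ReferenceMismatchError(ValueError):
    """A record's REF allele disagrees with the reference sequence."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Identity of a variant: same variant iff all four fields are equal.

    Two records at the same ``(chrom, pos)`` but with different alleles are
    *positionally* shared but are different variants; both levels of identity
    matter downstream (same-allele vs variable-allele partition).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def position(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def is_snp(self) -> bool:
        return self.vtype == "SNP"

    def __str__(self) -> str:  # used in truth JSON and report tables
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "VariantKey":
        chrom, pos, alleles = text.split(":")
        ref, alt = alleles.split(">")
        return cls(chrom, int(pos), ref, alt)


@dataclass(frozen=True, slots=True)
class Call:
    """One accession's genotype call at a site."""

    genotype: Genotype
    depth: int | None = None
    qual: float | None = None
    gq: float | None = None
    ref_support: bool | None = None  # from AD when present, else unknown


@dataclass(slots=True)
class VariantRecord:
    """A normalized biallelic variant with per-accession calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, Call] = field(default_factory=dict)

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def vtype(self) -> str:
        return self.key.vtype

    def validate(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if set(self.ref) - _VALID_BASES or set(self.alt) - _VALID_BASES:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} < 1")


@dataclass(frozen=True, slots=True)
class FilterPolicy:
    """High-confidence call filter.

    The wild-panel default demands read depth >= 5, site quality >= 30 and a
    fixed (homozygous) non-reference genotype; cultivated accessions are taken
    unfiltered to maximise the alleles observed on the cultivated side.
    """

    min_depth: int = 5
    min_qual: float = 30.0
    require_fixed_nonref: bool = True
    use_gq: bool = False  # quality from per-genotype GQ instead of site QUAL

    @classmethod
    def wild_default(cls) -> "FilterPolicy":
        return cls()

    @classmethod
    def unfiltered(cls) -> "FilterPolicy":
        return cls(min_depth=0, min_qual=0.0, require_fixed_nonref=False)


def apply_filter(record: VariantRecord, accession_id: str, policy: FilterPolicy) -> bool:
    """True iff the accession's call at this record passes the policy.

    Missing depth/quality when the policy requires them counts as a failure
    (stringent-confidence stance); ``require_fixed_nonref`` demands a hom-alt
    genotype with no reference-supporting reads when AD is available.
    """
    call = record.calls.get(accession_id)
    if call is None:
        return False
    if policy.min_depth > 0:
        if call.depth is None or call.depth < policy.min_depth:
            return False
    if policy.min_qual > 0:
        qual = call.gq if policy.use_gq else call.qual
        if qual is None or qual < policy.min_qual:
            return False
    if policy.require_fixed_nonref:
        if call.genotype is not Genotype.HOM_ALT:
            return False
        if call.ref_support is True:
            return False
    return True


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


class ReferenceGenome(Mapping):
    """In-memory reference: chromosome id -> uppercase sequence string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
        return cls({name: str(fasta[name][:]) for name in fasta.keys()})

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self):
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self._seqs[chrom][start - 1 : end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _recode_genotype(gt: tuple | None, allele_index: int) -> Genotype:
    if gt is None or any(a is None for a in gt) or len(gt) == 0:
        return Genotype.MISSING
    n_alt = sum(1 for a in gt if a == allele_index)
    if n_alt == 0:
        return Genotype.HOM_REF
    if n_alt == len(gt):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_vcf(path: str | Path, accession_id: str | None = None) -> Iterator[VariantRecord]:
    """Stream records from a VCF, splitting multi-allelic rows.

    Each ALT allele of a row becomes an independent :class:`VariantRecord`
    with the genotype re-coded against that allele (a 1/1 call at a G,T row
    is hom-alt for G and hom-ref for T).  Depth comes from the per-sample DP
    field, falling back to INFO/DP; quality from the site QUAL column.

    Records are checked to arrive in (chrom, pos) sorted order.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot open VCF: {exc}") from exc

    samples = list(vcf.header.samples)
    if accession_id is None:
        if len(samples) != 1:
            raise ConfigurationError(
                f"{path}: accession_id required for multi-sample VCF ({len(samples)} samples)"
            )
        accession_id = samples[0]
    elif accession_id not in samples:
        raise ConfigurationError(f"{path}: no genotype column for accession {accession_id!r}")

    seen_chroms: list[str] = []
    last_pos = 0
    for line_no, rec in enumerate(vcf, start=1):
        try:
            chrom, pos = rec.chrom, rec.pos
            if not seen_chroms or chrom != seen_chroms[-1]:
                if chrom in seen_chroms:
                    raise VcfParseError(f"{path}: chromosome {chrom} re-appears out of order")
                seen_chroms.append(chrom)
                last_pos = 0
            if pos < last_pos:
                raise VcfParseError(f"{path}: unsorted position {chrom}:{pos}")
            last_pos = pos

            sample = rec.samples[accession_id]
            gt = sample.get("GT")
            depth = sample.get("DP")
            if depth is None:
                depth = rec.info.get("DP")
            ad = sample.get("AD")
            gq = sample.get("GQ")
            ref = (rec.ref or "").upper()
            for i, alt in enumerate(rec.alts or ()):
                alt = (alt or "").upper()
                if not alt or set(alt) - _VALID_BASES or set(ref) - _VALID_BASES:
                    continue  # symbolic / spanning-deletion / IUPAC alleles
                if alt == ref:
                    continue
                genotype = _recode_genotype(gt, i + 1)
                ref_support = None
                if ad is not None and len(ad) > 0 and ad[0] is not None:
                    ref_support = ad[0] > 0
                call = Call(
                    genotype=genotype,
                    depth=int(depth) if depth is not None else None,
                    qual=float(rec.qual) if rec.qual is not None else None,
                    gq=float(gq) if gq is not None else None,
                    ref_support=ref_support,
                )
                record = VariantRecord(chrom, pos, ref, alt, {accession_id: call})
                record.validate()
                yield record
        except VcfParseError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"{path}: malformed record #{line_no} at {rec.chrom}:{rec.pos}: {exc}") from exc


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_variant(record: VariantRecord, reference: ReferenceGenome | Mapping[str, str]) -> VariantRecord:
    """Left-align and trim an indel to its minimal VCF representation.

    SNPs are returned unchanged.  The algorithm is the canonical one: repeatedly
    drop a shared trailing base (extending to the left with reference sequence
    whenever an allele would become empty), then drop shared leading bases.
    Idempotent, and maps every representation of the same haplotypic change to
    one canonical (pos, ref, alt).
    """
    seq = reference[record.chrom]
    pos, ref, alt = record.pos, record.ref, record.alt
    if seq[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"{record.chrom}:{pos} REF {ref!r} != reference {seq[pos - 1:pos - 1 + len(ref)]!r}"
        )
    if len(ref) == 1 and len(alt) == 1:
        return record

    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                raise ReferenceMismatchError(
                    f"{record.chrom}:{record.pos} cannot left-extend past chromosome start"
                )
            pos -= 1
            base = seq[pos - 1]
            ref, alt = base + ref, base + alt
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if (pos, ref, alt) == (record.pos, record.ref, record.alt):
        return record
    out = replace(record, pos=pos, ref=ref, alt=alt)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene with its representative transcript's CDS structure.

    ``cds`` holds (start, end, phase) segments in genomic order; for minus
    strand genes the coding sequence is the reverse complement of the
    concatenated segments.  ``complete`` is False when the concatenated CDS
    length is not a multiple of three (partial models).
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: tuple[tuple[int, int, int], ...] = ()
    annotation: str = ""
    transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = 0
        for s, e, _ in self.cds:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: CDS segments overlap or unsorted")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: CDS outside gene span")
            prev_end = e

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def complete(self) -> bool:
        return bool(self.cds) and self.cds_length % 3 == 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in self.cds)

    def in_intron(self, pos: int) -> bool:
        if len(self.cds) < 2 or not (self.cds[0][0] <= pos <= self.cds[-1][1]):
            return False
        return not self.in_cds(pos)

    def cds_sequence(self, reference: ReferenceGenome | Mapping[str, str]) -> str:
        seq = reference[self.chrom]
        joined = "".join(seq[s - 1 : e] for s, e, _ in self.cds)
        return reverse_complement(joined) if self.strand == "-" else joined

    def coding_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the coding sequence."""
        if not self.in_cds(pos):
            return None
        upstream = 0
        for s, e, _ in self.cds:
            if s <= pos <= e:
                genomic_off = upstream + (pos - s)
                if self.strand == "+":
                    return genomic_off
                return self.cds_length - 1 - genomic_off
            upstream += e - s + 1
        return None

    def genomic_position(self, offset: int) -> int:
        """Inverse of :meth:`coding_offset`."""
        if not 0 <= offset < self.cds_length:
            raise IndexError(f"coding offset {offset} outside CDS of {self.gene_id}")
        genomic_off = offset if self.strand == "+" else self.cds_length - 1 - offset
        for s, e, _ in self.cds:
            seg_len = e - s + 1
            if genomic_off < seg_len:
                return s + genomic_off
            genomic_off -= seg_len
        raise AssertionError("unreachable")

    def is_splice_region(self, pos: int, window: int = 2) -> bool:
        """Intronic position within `window` bp of a CDS/intron boundary."""
        if len(self.cds) < 2:
            return False
        for i, (s, e, _) in enumerate(self.cds):
            if i > 0 and s - window <= pos <= s - 1:
                return True
            if i < len(self.cds) - 1 and e + 1 <= pos <= e + window:
                return True
        return False

    def five_prime_genic_range(self) -> tuple[int, int] | None:
        """Genic region 5' of the CDS (the annotated 5' UTR), or None."""
        if not self.cds:
            return None
        if self.strand == "+":
            lo, hi = self.start, self.cds[0][0] - 1
        else:
            lo, hi = self.cds[-1][1] + 1, self.end
        return (lo, hi) if lo <= hi else None


def read_gene_models(
    gff_path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/CDS features into :class:`GeneModel` objects.

    One model per gene; when a gene has several mRNAs the representative is
    the one minimal by (start, transcript id).  Attribute text is retained
    verbatim (joined ``key=value`` pairs) for keyword search.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    n_skipped_cds = 0
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = sorted(
            db.children(gene, featuretype="mRNA"), key=lambda f: (f.start, f.id or "")
        )
        if mrnas:
            rep = mrnas[0]
            cds_feats = sorted(db.children(rep, featuretype="CDS"), key=lambda f: f.start)
            transcript_id = rep.id or ""
        else:
            cds_feats = sorted(db.children(gene, featuretype="CDS"), key=lambda f: f.start)
            transcript_id = ""
        cds = []
        for f in cds_feats:
            if f.start < gene.start or f.end > gene.end:
                n_skipped_cds += 1
                continue
            phase = int(f.frame) if f.frame not in (None, ".") else 0
            cds.append((f.start, f.end, phase))
        if chrom_lengths is not None:
            length = chrom_lengths.get(gene.seqid)
            if length is None or gene.end > length:
                raise ValueError(
                    f"gene {gene.id} at {gene.seqid}:{gene.start}-{gene.end} exceeds chromosome bounds"
                )
        annotation = ";".join(f"{k}={','.join(v)}" for k, v in gene.attributes.items())
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                start=gene.start,
                end=gene.end,
                cds=tuple(cds),
                annotation=annotation,
                transcript_id=transcript_id,
            )
        )
    if n_skipped_cds:
        logger.warning("skipped %d CDS features outside their gene span", n_skipped_cds)
    return genes


# ---------------------------------------------------------------------------
# Writers (TSV / BED / bedGraph)
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited table with header row; NA rendered as '.'."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path: str | Path) -> None:
    """BED from 1-based inclusive intervals (chrom, start, end, name)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """bedGraph from a frame with 1-based inclusive start/end and a value column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.value:g}\n")


def keys_to_frame(keys: Iterable[VariantKey]) -> pd.DataFrame:
    """Sorted tabular view of a variant-key collection."""
    rows = sorted(keys, key=lambda k: (k.chrom, k.pos, k.ref, k.alt))
    return pd.DataFrame(
        {
            "chrom": [k.chrom for k in rows],
            "pos": [k.pos for k in rows],
            "ref": [k.ref for k in rows],
            "alt": [k.alt for k in rows],
            "vtype": [k.vtype for k in rows],
        }
    )
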