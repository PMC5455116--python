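"""Set algebra over accession variant sets.

All cohort comparisons reduce to operations on sets of :class:`VariantKey`:
within-species intersections (common variants), species-specific variants
(common in one species, absent everywhere else), the all-wild partition into
same-allele vs variable-allele positions, and the wild-vs-cultivated
differential alleles that mark domestication-associated erosion.

Identity is allele-level (chrom, pos, ref, alt); position-level views are
derived from it.  An accession "possesses" a variant when its genotype call
carries the alternate allele (het or hom-alt); wild sets are built under the
high-confidence :class:`~domesticscan.variant_io.FilterPolicy`, cultivated
sets without filtering.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variant_io import (
    ConfigurationError,
    FilterPolicy,
    VariantKey,
    VariantRecord,
    apply_filter,
)

WILD = "wild"
CULTIVATED = "cultivated"


@dataclass(frozen=True, slots=True)
class CohortMember:
    accession_id: str
    species: str
    group: str  # wild | cultivated


class CohortSpec:
    """Accession -> species -> group mapping driving all intersections."""

    def __init__(self, members: Iterable[CohortMember]):
        self.members = tuple(members)
        ids = [m.accession_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate accession ids in cohort spec")
        for m in self.members:
            if m.group not in (WILD, CULTIVATED):
                raise ConfigurationError(f"{m.accession_id}: unknown group {m.group!r}")
        self.species_accessions: dict[str, list[str]] = {}
        self.group_of: dict[str, str] = {}
        self.species_of: dict[str, str] = {}
        for m in self.members:
            self.species_accessions.setdefault(m.species, []).append(m.accession_id)
            self.group_of[m.accession_id] = m.group
            self.species_of[m.accession_id] = m.species

    @property
    def wild_accessions(self) -> list[str]:
        return [m.accession_id for m in self.members if m.group == WILD]

    @property
    def cultivated_accessions(self) -> list[str]:
        return [m.accession_id for m in self.members if m.group == CULTIVATED]

    @property
    def wild_species(self) -> list[str]:
        seen: list[str] = []
        for m in self.members:
            if m.group == WILD and m.species not in seen:
                seen.append(m.species)
        return seen

    def validate_for_differential(self) -> None:
        if not self.wild_accessions or not self.cultivated_accessions:
            raise ConfigurationError(
                "differential analysis needs at least one wild and one cultivated accession"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortSpec":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"accession_id", "species", "group"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"cohort spec must have columns {sorted(required)}")
        return cls(
            CohortMember(r.accession_id, r.species, r.group)
            for r in df.itertuples(index=False)
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "accession_id": [m.accession_id for m in self.members],
                "species": [m.species for m in self.members],
                "group": [m.group for m in self.members],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AccessionVariantSet:
    """The keyed variant set of one accession, ready for set algebra."""

    accession_id: str
    species: str
    group: str
    variants: frozenset[VariantKey]

    @property
    def snps(self) -> frozenset[VariantKey]:
        return frozenset(k for k in self.variants if k.is_snp)

    @property
    def indels(self) -> frozenset[VariantKey]:
        return frozenset(k for k in self.variants if not k.is_snp)

    @property
    def positions(self) -> frozenset[tuple[str, int]]:
        return frozenset(k.position for k in self.variants)

    def view(self, vtype: str | None) -> frozenset[VariantKey]:
        if vtype is None:
            return self.variants
        if vtype == "SNP":
            return self.snps
        return self.indels

    @classmethod
    def from_records(
        cls,
        records: Iterable[VariantRecord],
        member: CohortMember,
        policy: FilterPolicy | None = None,
    ) -> "AccessionVariantSet":
        """Build the set; a record enters iff the genotype carries the alt
        allele and (when a policy is given) passes the confidence filter."""
        if policy is None:
            policy = FilterPolicy.unfiltered()
        keys = set()
        for rec in records:
            call = rec.calls.get(member.accession_id)
            if call is None or not call.genotype.carries_alt:
                continue
            if apply_filter(rec, member.accession_id, policy):
                keys.add(rec.key)
        return cls(member.accession_id, member.species, member.group, frozenset(keys))


@dataclass(frozen=True)
class CommonWildPartition:
    """Positions variant in every wild accession, split by allele agreement."""

    same_allele: frozenset[VariantKey]
    variable_allele: frozenset[tuple[str, int]]

    @property
    def all_positions(self) -> frozenset[tuple[str, int]]:
        return frozenset(k.position for k in self.same_allele) | self.variable_allele

    def counts(self) -> dict[str, int]:
        snps = sum(1 for k in self.same_allele if k.is_snp)
        return {
            "common_positions": len(self.all_positions),
            "same_allele_positions": len({k.position for k in self.same_allele}),
            "variable_allele_positions": len(self.variable_allele),
            "same_allele_snps": snps,
            "same_allele_indels": len(self.same_allele) - snps,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def common_within_species(sets: Sequence[AccessionVariantSet]) -> frozenset[VariantKey]:
    """Variants shared (same allele) by every accession of one species.

    A single-accession species returns its own set unchanged.
    """
    if not sets:
        raise ConfigurationError("common_within_species: empty input")
    species = {s.species for s in sets}
    if len(species) != 1:
        raise ConfigurationError(f"common_within_species: mixed species {sorted(species)}")
    common = set(sets[0].variants)
    for s in sets[1:]:
        common &= s.variants
    return frozenset(common)


def percent_common(
    sets: Sequence[AccessionVariantSet],
    vtype: str | None = "SNP",
    denominator: str = "union",
) -> float | None:
    """100 x |intersection| / |denominator| for one species' accessions.

    Reported as NA (None) for single-accession species and for an empty
    denominator.  The denominator is the union of all accession sets by
    default; "mean" (mean set size) and "min" (smallest set) are available
    since the original computation left this choice unstated.
    """
    if len(sets) < 2:
        return None
    views = [s.view(vtype) for s in sets]
    inter = set(views[0])
    union: set[VariantKey] = set()
    for v in views:
        inter &= v
        union |= v
    if denominator == "union":
        denom = float(len(union))
    elif denominator == "mean":
        denom = sum(len(v) for v in views) / len(views)
    elif denominator == "min":
        denom = float(min(len(v) for v in views))
    else:
        raise ConfigurationError(f"unknown percent_common denominator {denominator!r}")
    if denom == 0:
        return None
    return 100.0 * len(inter) / denom


def species_specific(
    target_species: str,
    sets_by_accession: dict[str, AccessionVariantSet],
    cohort: CohortSpec,
    allow_single_accession: bool = False,
) -> frozenset[VariantKey]:
    """Variants common to all accessions of `target_species` and absent
    (allele-level) from every other accession, wild or cultivated."""
    if target_species not in cohort.species_accessions:
        raise ConfigurationError(f"species {target_species!r} absent from cohort")
    target_ids = cohort.species_accessions[target_species]
    if len(target_ids) < 2 and not allow_single_accession:
        raise ConfigurationError(
            f"species {target_species!r} has a single accession; "
            "pass allow_single_accession=True to override"
        )
    common = common_within_species([sets_by_accession[a] for a in target_ids])
    others: set[VariantKey] = set()
    for acc_id, s in sets_by_accession.items():
        if cohort.species_of.get(acc_id) != target_species:
            others |= s.variants
    return frozenset(common - others)


def common_wild_partition(
    wild_sets: Sequence[AccessionVariantSet],
) -> CommonWildPartition:
    """Partition the positions variant in ALL wild accessions.

    same_allele: one identical VariantKey present in every accession.
    variable_allele: every accession variant at the position, but with at
    least two distinct alleles across accessions.
    """
    if not wild_sets:
        return CommonWildPartition(frozenset(), frozenset())
    pos_sets = [s.positions for s in wild_sets]
    common_positions = set(pos_sets[0])
    for p in pos_sets[1:]:
        common_positions &= p

    key_inter = set(wild_sets[0].variants)
    for s in wild_sets[1:]:
        key_inter &= s.variants
    same_allele = frozenset(k for k in key_inter if k.position in common_positions)
    same_positions = {k.position for k in same_allele}
    variable = frozenset(common_positions - same_positions)
    return CommonWildPartition(same_allele, variable)


def wild_differential(
    partition: CommonWildPartition,
    cultivated_sets: Sequence[AccessionVariantSet],
) -> frozenset[VariantKey]:
    """Common wild alleles absent from every cultivated allele call.

    A cultivated het call contributes its alt allele and therefore vetoes a
    matching wild allele; a missing or absent call contributes no alleles and
    does not veto (absence of evidence under the unfiltered cultivated calls).
    """
    cultivated_alleles: set[VariantKey] = set()
    for s in cultivated_sets:
        cultivated_alleles |= s.variants
    return frozenset(k for k in partition.same_allele if k not in cultivated_alleles)


def percent_common_table(
    sets_by_accession: dict[str, AccessionVariantSet],
    cohort: CohortSpec,
    denominator: str = "union",
) -> pd.DataFrame:
    """Per-species percent-common summary for SNPs and InDels."""
    rows = []
    for species in cohort.wild_species:
        sets = [sets_by_accession[a] for a in cohort.species_accessions[species]]
        rows.append(
            {
                "species": species,
                "n_accessions": len(sets),
                "percent_common_snp": percent_common(sets, "SNP", denominator),
                "percent_common_indel": percent_common(sets, "INDEL", denominator),
                "n_common_snp": len(common_within_species(sets) & sets[0].snps)
                if len(sets) > 1
                else len(sets[0].snps),
            }
        )
    return pd.DataFrame(rows)
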