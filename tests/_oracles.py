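"""Independent brute-force oracles used by the test suite.

Each function here deliberately re-derives a quantity from first principles
(pair enumeration, naive set loops, whole-protein re-translation) rather than
sharing code with the package, so tests compare two independent routes.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

from domesticscan.variant_io import GeneModel, VariantKey


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------


def pi_pair_enumeration(ks: list[int], n: int) -> float:
    """Mean pairwise differences via literal haplotype-pair enumeration."""
    sites = np.zeros((n, len(ks)), dtype=np.int8)
    for j, k in enumerate(ks):
        sites[:k, j] = 1
    total = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(sites[i] != sites[j]))
            n_pairs += 1
    return total / n_pairs * 1.0 if n_pairs else 0.0


def pi_pairwise_sum(ks: list[int], n: int) -> float:
    """Window pi (sum form) from the same enumeration: mean pairwise
    differences equals the window pi when n is constant."""
    return pi_pair_enumeration(ks, n)


def theta_direct(S: int, n: int) -> float:
    a1 = 0.0
    for i in range(1, n):
        a1 += 1.0 / i
    return S / a1


def tajima_d_direct(pi: float, S: int, n: int) -> float:
    """Tajima's D with the constants written out independently."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fst_hudson_per_site(k1, n1, k2, n2) -> float | None:
    hw_sum = hb_sum = 0.0
    any_site = False
    for a, b, c, d in zip(k1, n1, k2, n2):
        if b < 2 or d < 2:
            continue
        any_site = True
        p1, p2 = a / b, c / d
        hw_sum += (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        hb_sum += p1 * (1 - p2) + p2 * (1 - p1)
    if not any_site or hb_sum == 0:
        return None
    return 1 - hw_sum / hb_sum


# ---------------------------------------------------------------------------
# Set algebra (naive loops over plain lists)
# ---------------------------------------------------------------------------


def naive_common_within(variant_lists: list[list[VariantKey]]) -> set[VariantKey]:
    out = set()
    for v in variant_lists[0]:
        if all(v in other for other in variant_lists[1:]):
            out.add(v)
    return out


def naive_species_specific(
    target_lists: list[list[VariantKey]], other_lists: list[list[VariantKey]]
) -> set[VariantKey]:
    common = naive_common_within(target_lists)
    out = set()
    for v in common:
        if not any(v in other for other in other_lists):
            out.add(v)
    return out


def naive_partition(wild_lists: list[list[VariantKey]]):
    positions_per_acc = [{(v.chrom, v.pos) for v in lst} for lst in wild_lists]
    all_pos = set.intersection(*positions_per_acc) if positions_per_acc else set()
    same, variable = set(), set()
    for pos in all_pos:
        alleles_per_acc = [
            {v for v in lst if (v.chrom, v.pos) == pos} for lst in wild_lists
        ]
        shared = set.intersection(*alleles_per_acc)
        if shared:
            same |= shared
        else:
            variable.add(pos)
    return same, variable


def naive_differential(
    same_allele: set[VariantKey], cultivated_lists: list[list[VariantKey]]
) -> set[VariantKey]:
    out = set()
    for v in same_allele:
        if not any(v in lst for lst in cultivated_lists):
            out.add(v)
    return out


# ---------------------------------------------------------------------------
# Region assignment (linear scan)
# ---------------------------------------------------------------------------


def region_by_linear_scan(key: VariantKey, genes: list[GeneModel], flank: int = 2000):
    pos = key.pos
    genic = [g for g in genes if g.chrom == key.chrom and g.start <= pos <= g.end]
    if genic:
        g = min(genic, key=lambda g: (g.span_length, g.gene_id))
        if any(s <= pos <= e for s, e, _ in g.cds):
            label = "CDS"
        elif g.cds and g.cds[0][0] <= pos <= g.cds[-1][1]:
            label = "intron"
        else:
            label = "genic_other"
        return label, g.gene_id
    near = [
        g
        for g in genes
        if g.chrom == key.chrom and g.start - flank <= pos <= g.end + flank
    ]
    if near:
        g = min(near, key=lambda g: (g.span_length, g.gene_id))
        upstream = pos < g.start if g.strand == "+" else pos > g.end
        return ("flank_up_2kb" if upstream else "flank_down_2kb"), g.gene_id
    return "intergenic", None


# ---------------------------------------------------------------------------
# Coding effects (whole-CDS re-translation diff)
# ---------------------------------------------------------------------------


def effect_by_retranslation(key: VariantKey, gene: GeneModel, reference, splice_window: int = 2):
    """Classify by mutating the chromosome, re-extracting and re-translating
    the whole CDS, and diffing the protein products."""
    chrom_seq = reference[key.chrom]

    if not key.is_snp:
        if key.vtype == "DEL":
            affected = range(key.pos + 1, key.pos + len(key.ref))
        else:
            affected = (key.pos, key.pos + 1) if gene.in_cds(key.pos) and gene.in_cds(key.pos + 1) else (key.pos,)
        if key.vtype == "DEL":
            touches = any(gene.in_cds(p) for p in affected)
        else:
            touches = gene.in_cds(key.pos) and gene.in_cds(key.pos + 1)
        if touches:
            return "frameshift" if abs(len(key.ref) - len(key.alt)) % 3 else "inframe_indel"
        if any(gene.is_splice_region(p, splice_window) for p in (range(key.pos + 1, key.pos + len(key.ref)) if key.vtype == "DEL" else (key.pos, key.pos + 1))):
            return "splice_site"
        return "non_coding"

    if gene.is_splice_region(key.pos, splice_window):
        return "splice_site"
    if not gene.in_cds(key.pos):
        return "non_coding"

    mutated = chrom_seq[: key.pos - 1] + key.alt + chrom_seq[key.pos :]
    old_cds = gene.cds_sequence(reference)
    new_cds = gene.cds_sequence({key.chrom: mutated})
    if old_cds[:3] == "ATG" and new_cds[:3] != "ATG":
        return "start_lost"
    old_p = str(Seq(old_cds).translate())
    new_p = str(Seq(new_cds).translate())
    old_stop = old_p.find("*")
    new_stop = new_p.find("*")
    if old_stop != -1 and (new_stop == -1 or new_stop > old_stop):
        return "stop_lost"
    if new_stop != -1 and (old_stop == -1 or new_stop < old_stop):
        return "stop_gained"
    return "synonymous" if old_p == new_p else "missense"
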