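"""Sliding-window population-genetics statistics and selection regions.

Per-site inputs are alternate-allele counts ``k`` out of ``n`` allele calls
(two per called diploid genotype, missing calls excluded).  Windows are
defined in SNP-index space (default 500 sites, step 100) and carry:

* ``S``   segregating sites (0 < k < n)
* ``pi``  nucleotide diversity as the sum over sites of the unbiased
          per-site pairwise-difference term ``2 k (n - k) / (n (n - 1))``
* ``theta_w``  Watterson's estimator ``S / a1`` with ``a1 = sum_{i<n} 1/i``
* ``tajima_d`` the standard normalized difference (Tajima 1989 constants)
* ``fst``  Hudson's two-group estimator, ratio of window averages
           ``1 - mean(Hw) / mean(Hb)`` (optional)

Windows passing a Tajima's D threshold are projected to base-pair intervals
via their SNP span and merged into selection regions: strongly negative D
(default < -3) marks candidate purifying/sweep regions, high D (default >= 2)
candidate balancing regions.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GeneModel, VariantRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Per-site reduction
# ---------------------------------------------------------------------------


def tally_sites(
    records_by_accession: Mapping[str, Iterable[VariantRecord]],
    accessions: Sequence[str],
    *,
    min_n: int = 4,
    absent_is_hom_ref: bool = True,
) -> pd.DataFrame:
    """Reduce per-accession variant records to per-site (k, n) counts.

    Accessions without a record at a site are counted as hom-ref when
    ``absent_is_hom_ref`` (the convention for per-accession variant-only
    VCFs); genotypes called missing are excluded from ``n``.  When several
    alternate alleles are observed at one position the most frequent one is
    kept (ties broken lexicographically) and the rest dropped with a log
    message.  Sites with fewer than ``min_n`` allele calls are dropped.

    Returns a frame with columns chrom, pos, ref, alt, k, n sorted by
    (chrom, pos), SNPs only.
    """
    accessions = list(accessions)
    n_total = len(accessions)
    alt_counts: dict[tuple, int] = {}
    missing: dict[tuple[str, int], set[str]] = {}
    for acc in accessions:
        for rec in records_by_accession.get(acc, ()):
            if not rec.key.is_snp:
                continue
            call = rec.calls.get(acc)
            if call is None:
                continue
            site = (rec.chrom, rec.pos, rec.ref, rec.alt)
            from .variant_io import Genotype

            if call.genotype is Genotype.MISSING:
                missing.setdefault((rec.chrom, rec.pos), set()).add(acc)
                alt_counts.setdefault(site, 0)
            elif call.genotype is Genotype.HET:
                alt_counts[site] = alt_counts.get(site, 0) + 1
            elif call.genotype is Genotype.HOM_ALT:
                alt_counts[site] = alt_counts.get(site, 0) + 2
            else:
                alt_counts.setdefault(site, 0)

    # resolve one alt per position
    best: dict[tuple[str, int], tuple] = {}
    n_conflicts = 0
    for site, k in alt_counts.items():
        pos_key = (site[0], site[1])
        prev = best.get(pos_key)
        if prev is None:
            best[pos_key] = site
        else:
            n_conflicts += 1
            if (k, prev[3]) > (alt_counts[prev], site[3]):
                best[pos_key] = site
    if n_conflicts:
        logger.info("dropped %d minor alleles at multi-allelic positions", n_conflicts)

    rows = []
    n_dropped = 0
    for (chrom, pos), site in best.items():
        k = alt_counts[site]
        n = 2 * (n_total - len(missing.get((chrom, pos), ())))
        if not absent_is_hom_ref:
            n = None  # not supported without explicit hom-ref records
            raise NotImplementedError("absent_is_hom_ref=False is not supported")
        if n < min_n or k == 0:
            n_dropped += 1
            continue
        rows.append((chrom, pos, site[2], site[3], k, n))
    if n_dropped:
        logger.info("dropped %d sites with k=0 or n < %d", n_dropped, min_n)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "k", "n"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


def harmonic_sq(n: int) -> float:
    """a2 = sum_{i=1}^{n-1} 1/i^2."""
    return float(sum(1.0 / (i * i) for i in range(1, n)))


def watterson_theta(S: int, n: int, span: int | None = None) -> float | None:
    """Watterson's estimator S/a1; per-site when a bp span is given."""
    if n < 2:
        return None
    theta = S / harmonic(n)
    if span:
        theta /= span
    return theta


def pi_from_counts(k: np.ndarray | Sequence[int], n: np.ndarray | Sequence[int]) -> float:
    """Window pi: sum over sites of 2 k (n-k) / (n (n-1))."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        terms = 2.0 * k * (n - k) / (n * (n - 1.0))
    return float(np.nansum(terms))


@dataclass(frozen=True, slots=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_sample_size(cls, n: int) -> "TajimaConstants":
        a1 = harmonic(n)
        a2 = harmonic_sq(n)
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
        e1 = c1 / a1
        e2 = c2 / (a1 * a1 + a2)
        return cls(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(pi: float, S: int, n: int) -> float | None:
    """Tajima's normalized D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Undefined (None) when there are no segregating sites or fewer than four
    allele calls.
    """
    if S < 1 or n < 4:
        return None
    c = TajimaConstants.for_sample_size(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi - S / c.a1) / math.sqrt(var)


def fst_hudson(
    k1: Sequence[int], n1: Sequence[int], k2: Sequence[int], n2: Sequence[int]
) -> float | None:
    """Hudson's two-group Fst as a window ratio of averages.

    Per usable site (both groups with n >= 2): within-group heterozygosity
    Hw = (2 p1 q1 + 2 p2 q2) / 2 and between-group Hb = p1 q2 + p2 q1;
    Fst = 1 - sum(Hw)/sum(Hb).  None when no usable site or Hb sums to zero.
    """
    k1 = np.asarray(k1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    usable = (n1 >= 2) & (n2 >= 2)
    if not usable.any():
        return None
    p1 = k1[usable] / n1[usable]
    p2 = k2[usable] / n2[usable]
    hw = (2.0 * p1 * (1 - p1) + 2.0 * p2 * (1 - p2)) / 2.0
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    denom = float(hb.sum())
    if denom == 0:
        return None
    return 1.0 - float(hw.sum()) / denom


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class WindowStat:
    chrom: str
    index: int
    start_site: int  # 0-based index of first SNP in the window
    first_pos: int
    last_pos: int
    n_sites: int
    S: int
    n: int  # modal allele-call count
    pi: float
    theta_w: float | None
    tajima_d: float | None
    fst: float | None = None
    partial: bool = False


def snp_windows(
    sites: pd.DataFrame,
    window_snps: int = 500,
    step_snps: int = 100,
) -> list[WindowStat]:
    """SNP-index sliding windows per chromosome with attached statistics.

    Emits a window at every step while sites remain; terminal windows with
    fewer than ``window_snps`` sites are flagged partial.  When the frame
    carries ``k2``/``n2`` columns a Hudson Fst against that second group is
    attached per window.
    """
    if window_snps < 1 or step_snps < 1 or step_snps > window_snps:
        raise ValueError("need window_snps >= step_snps >= 1")
    has_fst = {"k2", "n2"}.issubset(sites.columns)
    out: list[WindowStat] = []
    for chrom, chrom_df in sites.groupby("chrom", sort=True):
        chrom_df = chrom_df.sort_values("pos", kind="mergesort")
        pos = chrom_df["pos"].to_numpy()
        k = chrom_df["k"].to_numpy()
        n = chrom_df["n"].to_numpy()
        total = len(chrom_df)
        widx = 0
        for start in range(0, total, step_snps):
            stop = min(start + window_snps, total)
            kw, nw = k[start:stop], n[start:stop]
            seg = (kw > 0) & (kw < nw)
            S = int(seg.sum())
            counts = np.bincount(nw)
            n_mode = int(counts.argmax())
            pi = pi_from_counts(kw, nw)
            theta = watterson_theta(S, n_mode) if n_mode >= 2 else None
            d = tajimas_d(pi, S, n_mode)
            fst = None
            if has_fst:
                fst = fst_hudson(
                    kw,
                    nw,
                    chrom_df["k2"].to_numpy()[start:stop],
                    chrom_df["n2"].to_numpy()[start:stop],
                )
            out.append(
                WindowStat(
                    chrom=str(chrom),
                    index=widx,
                    start_site=start,
                    first_pos=int(pos[start]),
                    last_pos=int(pos[stop - 1]),
                    n_sites=stop - start,
                    S=S,
                    n=n_mode,
                    pi=pi,
                    theta_w=theta,
                    tajima_d=d,
                    fst=fst,
                    partial=(stop - start) < window_snps,
                )
            )
            widx += 1
            if stop >= total:
                break
    return out


def windows_to_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "window": [w.index for w in windows],
            "first_pos": [w.first_pos for w in windows],
            "last_pos": [w.last_pos for w in windows],
            "n_sites": [w.n_sites for w in windows],
            "S": [w.S for w in windows],
            "n": [w.n for w in windows],
            "pi": [w.pi for w in windows],
            "theta_w": [w.theta_w for w in windows],
            "tajima_d": [w.tajima_d for w in windows],
            "fst": [w.fst for w in windows],
            "partial": [w.partial for w in windows],
        }
    )


# ---------------------------------------------------------------------------
# Density tracks and selection regions
# ---------------------------------------------------------------------------


def density_track(
    positions: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Variant counts in fixed 1-based inclusive bins [1, bin], [bin+1, 2*bin]...

    All bins of every chromosome are emitted (zeros included) so the output
    is directly plottable as a genome track.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = (length + bin_size - 1) // bin_size
        sub = positions.loc[positions["chrom"] == chrom, "pos"]
        idx = ((sub.to_numpy() - 1) // bin_size).astype(int)
        counts = np.bincount(idx, minlength=n_bins) if len(idx) else np.zeros(n_bins, int)
        for b in range(n_bins):
            rows.append(
                {
                    "chrom": chrom,
                    "start": b * bin_size + 1,
                    "end": min((b + 1) * bin_size, length),
                    "value": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)


@dataclass(slots=True)
class SelectionRegion:
    chrom: str
    start: int
    end: int
    direction: str  # purifying | balancing
    n_windows: int
    extreme_d: float
    genes: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _merge_intervals(spans: list[tuple[int, int, float]]) -> list[tuple[int, int, int, float]]:
    """Merge overlapping or book-ended intervals; track count and extreme D."""
    spans = sorted(spans)
    merged: list[list] = []
    for s, e, d in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += 1
            merged[-1][3] = d if abs(d) > abs(merged[-1][3]) else merged[-1][3]
        else:
            merged.append([s, e, 1, d])
    return [tuple(m) for m in merged]


def selection_regions(
    windows: Sequence[WindowStat],
    *,
    low: float = -3.0,
    high: float = 2.0,
    genes: Iterable[GeneModel] = (),
    include_partial: bool = False,
) -> list[SelectionRegion]:
    """Threshold-merged Tajima's D regions with resident genes.

    Purifying: D strictly below ``low``; balancing: D at or above ``high``.
    Passing windows are projected to their [first SNP, last SNP] bp span and
    overlapping/adjacent spans merged per chromosome and direction.  Partial
    terminal windows are excluded by default (unstable variance at small S).
    """
    genes = list(genes)
    by_dir_chrom: dict[tuple[str, str], list[tuple[int, int, float]]] = {}
    for w in windows:
        if w.tajima_d is None or (w.partial and not include_partial):
            continue
        if w.tajima_d < low:
            direction = "purifying"
        elif w.tajima_d >= high:
            direction = "balancing"
        else:
            continue
        by_dir_chrom.setdefault((direction, w.chrom), []).append(
            (w.first_pos, w.last_pos, w.tajima_d)
        )
    regions: list[SelectionRegion] = []
    for (direction, chrom), spans in sorted(by_dir_chrom.items()):
        for s, e, count, d in _merge_intervals(spans):
            resident = tuple(
                sorted(
                    g.gene_id
                    for g in genes
                    if g.chrom == chrom and g.start <= e and g.end >= s
                )
            )
            regions.append(SelectionRegion(chrom, s, e, direction, count, d, resident))
    return regions


def regions_to_frame(regions: Sequence[SelectionRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "direction": [r.direction for r in regions],
            "length_bp": [r.length for r in regions],
            "n_windows": [r.n_windows for r in regions],
            "extreme_d": [r.extreme_d for r in regions],
            "n_genes": [len(r.genes) for r in regions],
            "genes": [",".join(r.genes) for r in regions],
        }
    )
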