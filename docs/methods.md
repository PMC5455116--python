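# Methods

## Variant identity and normalization

All set algebra operates on allele-level keys `(chrom, pos, ref, alt)` with
1-based inclusive coordinates. Multi-allelic VCF rows are split before
anything else; each `(position, alt)` pair is an independent variant with
the genotype re-coded against that allele. Two records are *the same
variant* only when all four fields agree; *the same position* when chrom and
pos agree. This two-level identity is what separates the same-allele from
the variable-allele component of the all-wild partition.

Indels are left-aligned and trimmed to minimal representation (the shared
leading base of the VCF convention retained) against the reference before
comparison, so that the same haplotypic change written differently in two
accessions maps to one key. The algorithm is the canonical one: repeatedly
drop shared trailing bases, extending leftward with reference sequence when
an allele empties, then drop shared leading bases; it is idempotent.

## The high-confidence filter

Wild-panel calls pass only with depth ≥ `min_depth` (default 5), site
quality ≥ `min_qual` (default 30, from the QUAL column; per-genotype GQ can
be selected with `use_gq` — the choice is configurable because either is a
defensible reading of a "quality score" cutoff) and a homozygous
non-reference genotype. When an AD field is present, any reference-
supporting read also fails the call ("100% non-reference"); without AD, the
GT 1/1 call suffices. Missing depth or quality counts as failure: the
filter's purpose is confidence, and an unknown value is not evidence.
Cultivated accessions are never filtered — the cultivated side of the
differential comparison should see every allele the crop may still carry,
so sensitivity is preferred over precision there.

An accession *possesses* a variant when its genotype carries the alternate
allele (het or hom-alt). A missing genotype in a wild accession therefore
breaks within-species commonality (strict intersection), while a missing
cultivated genotype contributes no alleles and does not veto a differential
candidate: absence of a call is not evidence of an allele.

## Cohort set algebra

* `common_within_species` — allele-level intersection over a species'
  accessions; a single-accession species returns its own set.
* `percent_common` — 100·|intersection|/|union| for species with ≥ 2
  accessions (NA otherwise). The denominator is configurable (`union`,
  `mean`, `min`) because the quantity's denominator is a genuine free
  choice; union is the default as the most conservative.
* `species_specific` — the species' common set minus every variant present
  in any other accession, wild or cultivated. Reported only for species
  with ≥ 2 accessions (a single accession cannot distinguish species-level
  from accession-level variation); an override flag exists.
* `common_wild_partition` — positions variant in *all* wild accessions,
  split into same-allele (identical key everywhere) and variable-allele
  (position shared, alleles differ).
* `wild_differential` — same-allele keys whose alt occurs in no cultivated
  genotype call. A het cultivated call contributes both its alleles, so it
  vetoes; SNPs and indels are counted separately in the reports.

## Gene annotation and coding effects

*Genic* means within the annotated gene span, introns and UTRs included;
CDS membership is a separate, finer label. Flanks are 2 kb (configurable),
strand-aware and exclusive of gene spans. Overlapping genes all appear in
the annotation, with the primary hit chosen deterministically (smallest
span, then lexicographic gene id). When a gene has several mRNAs the
representative transcript is minimal by (start, transcript id) — a
deterministic stand-in for "first in file" that coincides with it for
single-mRNA annotations.

The effect classifier translates the affected codon before and after a CDS
SNP (standard nuclear code, strand-aware): initiator ATG destroyed →
start_lost; stop codon created/destroyed → stop_gained / stop_lost;
otherwise synonymous or missense by amino-acid identity. Intronic positions
within 2 bp of a CDS boundary (the canonical donor/acceptor dinucleotides;
window configurable) are splice_site. CDS indels are frameshift when the
length difference is not a multiple of three, in-frame otherwise.
start_gained — a SNP creating an ATG in the genic region 5′ of the CDS, in
frame with the annotated start — is assessed only when
`assess_start_gain` is on (default in the differential-effect report, off
elsewhere), since upstream ATG creation is only meaningful for that
analysis. Impact tiers follow the conventional scheme: HIGH for stop/start
loss-gain, splice and frameshift; MODERATE for missense and in-frame
indels; LOW for synonymous; MODIFIER otherwise. Incomplete CDS models
(length not divisible by three) are classified on the available frame and
flagged.

The test suite checks the classifier against an independent oracle that
mutates the chromosome, re-extracts and re-translates the whole CDS and
diffs the proteins, on both strands, plus a strand-symmetry property
(mirroring the genome leaves every label unchanged).

## Window statistics

Sites are reduced to alternate-allele counts `k` out of `n` allele calls,
two per called diploid genotype; missing genotypes shrink `n` site by site
and sites with `n < 4` are dropped. Accessions without a record at a
position are hom-ref — the convention for variant-only per-accession VCFs.
A haploid mode is not needed for the default workflow but the estimators
take `(k, n)` directly, so any calling convention can be fed in.

Windows are 500 SNPs with 100-SNP steps (both configurable), per
chromosome, in SNP-index space; emission stops once a window reaches the
final site, and a terminal window shorter than the window size is flagged
partial. Per window:

* π = Σ_sites 2k(n−k)/(n(n−1)) — the unbiased pairwise-difference sum,
  using each site's exact n;
* θ_W = S/a₁ and Tajima's D with its 1989 normalization constants, using
  the window's **modal** per-site n (per-site n varies only through
  missingness; the mode is the panel size in the common case);
* Hudson's F_ST as a ratio of window averages, 1 − ΣH_w/ΣH_b with
  H_w = (2p₁q₁ + 2p₂q₂)/2 and H_b = p₁q₂ + p₂q₁, skipping sites where
  either group has n < 2. The default grouping is wild vs cultivated; the
  grouping is user-specifiable since different contrasts are meaningful.

Selection regions: windows with D strictly below −3.0 (purifying) or at or
above 2.0 (balancing) are projected to the bp span of their first and last
SNP and overlapping or book-ended spans merged per chromosome and
direction. Region lengths are therefore data-dependent, as they must be for
SNP-index windows. Partial windows are excluded by default (unstable
variance at small S). Resident genes are those whose span overlaps the
region. Density tracks count variants in fixed 1-Mb bins, 1-based inclusive
(position 1,000,000 belongs to bin 1), with zero bins emitted.

A useful closed-form anchor: an all-singleton window with S = 500 and
n = 80 gives D = −3.036, the most negative value attainable at that size —
the purifying cutoff of −3 sits just above the singleton extreme for this
window geometry.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions: a wild panel of 12 species / 29
accessions with per-species sharing probabilities tracking reproductive
behavior (selfers ~0.75–0.92, outcrossers ~0.2–0.55), 40 cultivated
accessions drawn from a shared pool, 3 × 5 Mb chromosomes, 150 genes and
~45k distinct variant positions — sized so a full five-seed analysis runs
in minutes on one CPU.

Planted categories are mutually exclusive by position and recorded in a
truth JSON: 50 species-specific variants per multi-accession species with a
per-species genic fraction (rising with distance from the cultivated
lineage, up to 0.43); 120 differential alleles split across CDS effect
classes (6 stop_gained, 4 stop_lost, 2 start_lost, 4 splice_site,
3 frameshift, 1 start_gained — each verified against the classifier at
planting time), intron, flank, intergenic and indel placements; 80
cultivated-shared all-wild alleles; 30 discordant positions (never genic,
and split within a species so they cannot masquerade as species-specific);
and 30 filter negative controls (low depth, low quality, or heterozygous).

Two design points matter for exact truth recovery. First, a background
variant that lands in every accession of a multi-accession species would be
indistinguishable from a planted species-specific variant; the generator
parks such alleles in one cultivated accession, which excludes them by
definition without touching within-species sharing. Second, the sweep
segment (400 kb, 1600 sites) gives every site exactly one heterozygous
cultivated carrier — a pure singleton spectrum — and draws no neutral
cultivated background inside the span, mirroring the biology of a hard
sweep that removes standing variation; windows inside the segment then sit
deterministically at the singleton extreme D = −3.036 < −3, and the planted
span is recovered with bp-Jaccard ≥ 0.85 (window-start quantization can
shave at most ~99 sites off each edge). Frequency-spectrum skew by
singleton assignment was chosen over coalescent simulation deliberately: it
is fully controllable and sufficient to drive D below the threshold; a
neutral mode (Binomial(n, p) carriers, p ~ Uniform) is available for
control chromosomes.

Depth is 5 + Poisson(15) and quality Uniform(40, 90) for confident calls;
negative controls sample the failing side of each criterion. Everything
derives from one seeded generator, so a seed reproduces byte-identical
FASTA/GFF3/VCF output.

What the generator does **not** emulate: linkage disequilibrium and
recombination structure, coalescent demography, alignment or genotyping
error beyond the planted negative controls, multi-allelic sites, and
read-level artifacts. Passing ground-truth recovery therefore demonstrates
the correctness of the set algebra, annotation and scan machinery on
cleanly structured input — not robustness to the messiness of real
resequencing data, for which the filter thresholds are the first defense.

## Numerical and degenerate-input conventions

Tajima's D is NA for S = 0 or n < 4; θ_W is NA for n < 2; percent-common is
NA for single-accession species or an empty denominator; F_ST is NA when no
site is usable in both groups. NA renders as `.` in TSV output. Ties in
primary-gene selection break by span length then gene id; multi-allelic
positions in the window tally keep the most frequent alternate (ties
lexicographic). All randomness in tests is seeded; hypothesis properties
run derandomized.
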