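# Methods

This note records the statistical procedures chromkit implements, the
choices made where a procedure admits more than one reasonable
definition, and what the synthetic-data generators do and do not emulate.

## Interval statistics

All interval arithmetic uses BED conventions: 0-based, half-open
coordinates, strand `+`/`-`/`.`. Base-pair statistics are defined on the
*merged* representation of a set (sorted, overlapping and zero-gap
adjacent intervals fused), so a set is treated as a subset of the genome
rather than a multiset of records.

**Jaccard.** `J(A, B) = |A ∩ B| / |A ∪ B|` in base pairs, computed as
`|A| + |B| − |A ∩ B|` on merged sets. The statistic is undefined (raised
as an error, not reported as 0) when both sets are empty; inside the
matrix helper this surfaces as a missing value with a warning.

**Venn membership.** Figure-style Venn counts are per *interval* of a
designated unit set: an interval belongs to signature S if it overlaps
every set in S by at least 1 bp and no set outside S. Counts over
signatures therefore partition the unit set. A base-pair variant
(`multiway_membership_bp`) partitions the covered genome instead.
The 1-bp minimum-overlap rule follows bedtools default semantics and is
also used for `fraction_of_regions_overlapped`.

**Shuffle null.** `shuffle` repositions every interval uniformly at
random on its own chromosome (start drawn from
`[0, chrom_len − interval_len]`), preserving the interval count and the
per-chromosome length multiset. Shuffled intervals may overlap each
other; no blacklist or exclusion regions are modelled. The null is fully
seeded: a base seed expands into per-shuffle substreams, so results are
bit-reproducible.

**Fold enrichment.** `fold = observed / mean(statistic over n shuffles)`
for one of three statistics: intersection base pairs, Jaccard, or the
fraction of peak intervals touching the target. The empirical p-value
uses the add-one rule `(1 + #{shuffle ≥ observed}) / (n + 1)`, which can
never report 0. A zero null mean is reported as an infinite-fold
sentinel with a flag rather than an exception. Note that because the
observed statistic is computed on the merged peak set, a peak set dense
enough to self-overlap is compressed relative to a sparse null; planted-
truth simulations in the test suite therefore use peak sets whose total
length is small relative to the target.

**TSS distance classes.** Peaks are assigned by the unsigned distance
from their midpoint to the nearest single-base TSS anchor on the same
chromosome, ties broken toward the smaller coordinate. Default bins are
<1 kb, 1–3 kb, 3–10 kb, 10–100 kb, >100 kb; peaks on chromosomes without
an anchor fall in the open top bin.

## Chromatin-state profiling

A segmentation is a state-labelled interval set whose segments are
disjoint within a chromosome, validated against a closed alphabet
defaulting to the 25 imputed-state labels of the Roadmap 25-state model.
`state_jaccard_profile` returns `J(peaks, segments of s)` over the whole
alphabet; states absent from the segmentation contribute 0 (with a
warning), not missing, so group sums are well defined.

**Group ratios.** The promoter:enhancer and active:other-promoter
statistics are ratios of *summed per-state Jaccards* within named state
groups. Summing keeps the statistic decomposable per state; a pooled
variant (segments of the group merged into one set before a single
Jaccard) is available behind `pooled=True` since the two definitions
differ and either is defensible. A zero denominator yields `inf`.

## Metaprofiles

Coverage is a per-chromosome step function with non-negative values;
uncovered bases are 0. Signal extraction integrates the step function
exactly (prefix-integral queries), so bin values are exact mean per-base
coverage, identical to brute-force per-base averaging. Windows are
centered on single-base anchors; for `-` strand anchors the bin order is
reversed so gene-downstream is always to the right. Windows truncated by
a chromosome edge are zero-padded and flagged.

**Summit offset.** The signed center of the maximal bin of the average
profile, negative meaning upstream in gene orientation; ties break
toward 0. With the default ±2 kb window and 50-bp bins, bin centers sit
at ±25, ±75, … bp, so an offset is resolved to half a bin.

**Background correction.** Each matrix records the mean genome-wide
coverage of its source track (total signal mass divided by genome length
when a layout is given, else by the covered extent). Correction divides
each matrix by this depth, subtracts, and clips at zero — a CPM-like
scaling chosen because sequencing-depth differences between signal and
control tracks would otherwise dominate the subtraction. A
`log2_ratio` variant is provided; scaling can be disabled when tracks
are already comparable.

## Conservation

The conservation score of a reference position is the information
content in bits used in sequence logos:

    bits = log2(20) + Σ_i p_i log2 p_i,    0 · log 0 := 0,

where `p_i` is the frequency of amino acid *i* among the non-gap, non-X
residues of the alignment column. Gaps are excluded from the frequency
vector rather than treated as a 21st symbol, because the maximal entropy
in the formula is `log2(20)`. Only columns where the reference row is
non-gap are scored, indexed by 1-based reference residue number, so the
profile length always equals the ungapped reference length. Columns with
fewer than 10 scored residues are flagged low-support but reported.

**Redundancy filtering.** Database-style inputs are thinned in three
steps before alignment-based scoring: (1) greedy longest-first
clustering at 80% global identity — a CD-HIT-style approximation where
identity is the maximal number of matched residues in a global alignment
with free gaps, divided by the shorter sequence's length; desk-scale
inputs make the O(n²) pairwise pass acceptable; (2) removal of
sequences shorter than 90% of the reference (inclusive bound); (3) one
sequence per (species, paralogue), keeping the longest, ties by
lexicographic id.

**Identity/similarity.** Percent identity counts exact matches over
non-double-gap columns; percent similarity additionally counts pairs
within a conservative substitution group, defaulting to {AGS}, {ILVM},
{FWY}, {KRH}, {DENQ}, {ST}, {C}, {P}. There is no community-standard
definition of "similarity"; the groups are configurable.

## Mutation landscape

Mutation records carry gene, sample, 1-based residue position,
normalized consequence, screen type, and tissue. The consequence
vocabulary is closed (missense, nonsense, frameshift, inframe_indel,
synonymous, unknown); the mapping from raw table strings is an external
schema so the loader is not pinned to one COSMIC release. The standard
filter keeps whole-genome-screen records with a known consequence and
reports the removed fraction; it is idempotent.

**Densities.** Missense density is missense count divided by residues
in the region; in-frame indels are excluded. Counting is per record,
not per unique patient. Merging disjoint regions gives the
residue-weighted mean density, so densities are scale-consistent.

**Motif slots.** The C4HC2C/H zinc-chelating motif positions are
labelled slots (C1–C4, H1, C5, C6, C7/H2) aggregated across the PHD
domains of each gene; counts are raw (not normalized per slot
occurrence), with the occurrence counts recoverable from the annotation.

**Enrichment test.** Under a uniform null the number of missense
mutations inside a region is `Binomial(n_total, region/protein)`; the
test is the exact two-sided binomial test. Because the exact p-value of
a discrete test is super-uniform (conservative) under the null, a
`randomized=True` variant smooths the tie mass with a uniform draw,
producing a p-value that is exactly Uniform(0,1) under the null; this is
the standard calibration diagnostic for discrete tests and is what the
calibration checks use. Inference defaults to the deterministic exact
p-value.

## Synthetic data

The generators emulate the statistical structure of the real inputs at
desk scale; defaults are chosen once to mirror the study conditions the
analyses were designed for:

- **Genome**: 2 chromosomes × 1 Mb. Real genomes are ~3 Gb; all
  statistics here are scale-free, so a smaller genome only widens
  Monte-Carlo error.
- **Segmentation**: all 25 states, geometric segment lengths with mean
  1 kb (the memoryless analogue of an HMM segmentation), Roadmap-like
  base-pair shares (mostly quiescent, promoter/enhancer states ~1%
  each). States are assigned to segments by largest base-pair deficit
  then shuffled in order, pinning realized shares within the stated 2%
  of target.
- **Peaks**: 1 000 peaks, Gaussian lengths 500 ± 150 bp (min 50), 80%
  of midpoints planted uniformly inside TssA/PromD1 segments, the rest
  uniformly elsewhere; truth recorded in a sidecar table.
- **Coverage**: Gaussian bump (amplitude 10, sd 75 bp) centered 175 bp
  upstream of each of 200 stranded anchors — the summit-upstream
  geometry reported for clustered PHD readers — plus truncated-Gaussian
  noise at 10% of amplitude, written as 10-bp bedGraph runs within
  ±2.5 kb of anchors.
- **MSA**: columns are two-level mixtures (consensus residue with
  probability solving the entropy equation for the target bits,
  remainder uniform over the other 19); the reference row is the
  consensus. This matches the scoring formula exactly but is not a
  substitution model: it has no phylogenetic correlation between rows,
  no gaps, and no indel structure.
- **Mutations**: 5 000 records, 33% marked unknown, 90% WGS, 70%
  missense among known; missense positions drawn with a 5× rate
  multiplier inside a 200-residue PHD-cluster annotation (three
  ~65-residue domains with 8 motif slots each) and an extra 3× at motif
  residues.

Every generator is deterministic given the spec seed (independent
substreams per generator), and regeneration is bit-identical.

**What passing tests do not show.** The generators share none of the
correlation structure of real data: no fragment-length or GC bias, no
read-level noise, no phylogeny in the MSA, no mutational signatures or
patient-level clustering. Recovery tests therefore validate the
*estimators* — that each statistic recovers what was planted under its
own model — not the biological conclusions one would draw from real
peak sets or mutation tables.

## Numerical choices

- Conservation bits are clamped to [0, log2 20] against float residue;
  closed-form columns reproduce log2(20), 0, and log2(20) − 1 to 1e-9.
- Summit ties break toward 0; nearest-TSS ties toward the smaller
  coordinate; cluster assignment is first-fit in longest-first order.
- Empirical p-values use the add-one rule and cannot be 0; expected-mean
  0 in fold enrichment yields an infinite-fold sentinel, not an error.
- Problem sizes in tests and the acceptance script (toy genomes of
  10³–10⁵ bp for exact oracles, 0.4–2 Mb genomes for simulation, 20
  seeds for recovery checks, 2 000 replicates for calibration) were
  chosen so each check's Monte-Carlo error is far below its assertion
  tolerance.

## Known limitations

- No BAM/bigWig parsing; coverage is consumed as bedGraph text.
- The shuffle null has no blacklist awareness and keeps each interval on
  its own chromosome; enrichment against targets that correlate with
  chromosome identity is therefore conservative.
- Greedy clustering is order-dependent (longest-first); it approximates
  but does not reproduce cd-hit's word-filtered clusters.
- The group-ratio statistic depends on the chosen aggregation (summed
  vs pooled Jaccards); both are provided and can differ materially when
  group states have very different genomic extents.
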