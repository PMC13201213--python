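# Methods

## Overview

`pirnakit` couples a small-RNA analysis pipeline with a generative
simulator. The pipeline measures piRNA signatures in oxidized small-RNA
libraries; the simulator produces raw FASTQ libraries whose generative
parameters (5′-uridine bias, ping-pong pairing, phasing, methylation,
class composition) are known exactly, so each analysis stage can be tested
for parameter recovery rather than plausibility.

## Coordinate and sequence conventions

All coordinates are 0-based, half-open (BED-native) in every module, which
keeps mask, tile and alignment arithmetic free of off-by-one conversions.
Sequences are stored as uppercase DNA; a `U` in any report is a display
alias for `T`. `N` never matches any base — including another `N` — so
simulated padding can never produce phantom alignments. TE consensus
sequences are stored on their sense (mRNA-like) strand; a read aligned to
the `-` strand of a consensus is TE-antisense.

## The toy reference

`simulate.build_toy_reference(seed, params)` builds, deterministically for
a fixed seed:

* 3 contigs × 50 kb of uniform-random sequence (configurable);
* a TE consensus library (4 elements × 2 kb, uniform base composition);
* 2 piRNA clusters (8 kb) each embedding 3 × 600 nt TE consensus
  fragments, antisense with probability 0.8;
* 4 dispersed TE insertions (500 nt, annotated as `TE_insertion`);
* rRNA, snRNA, snoRNA, miRNA, tRNA loci, one hairpin-RNA (hpRNA) locus and
  one *aubergine*-like locus, all annotated over the random background.

Two deliberate design choices:

* **Disjoint consensus segments.** Every genomic TE copy (cluster-embedded
  or dispersed) is carved from a *distinct* segment of the consensus
  library. Simulated piRNAs are therefore genome-unique mappers, which is
  what the uniqueness filter of the tile analysis selects for on a real
  genome; repeated identical copies would instead split read weight across
  loci and dilute phasing and tile statistics in ways real piRNA analyses
  avoid by discarding multi-mappers.
* **Uniform base composition.** With uniform composition, "no 5′ bias"
  coincides with a first-base U frequency of 0.25, so a null library is
  exactly null for the z-statistics; U-richness sufficient for the 1U and
  downstream-U biases is obtained by rejection sampling over positions
  rather than by skewing the sequence itself.
* Cluster-embedded fragments are recorded in a sidecar fragment table
  (`te_fragments.tsv`) rather than as `TE_insertion` annotation records:
  they are *inside* `piRNA_cluster` features, and the insertion records
  are reserved for dispersed copies.

## The simulated library

`simulate.simulate_small_rna_population` draws `n_reads` primary reads
from four classes (defaults: piRNA 0.55, hpRNA-siRNA 0.15, miRNA 0.20,
degradation 0.10 — free parameters chosen as a plausible oxidized-library
composition, not literature values). Ping-pong partners are emitted *in
addition* to the primary draws, so a library with pairing enabled contains
more reads than `n_reads`; the truth table marks partners explicitly.

Per-class generative model:

* **piRNA** (23–32 nt, from cluster TE fragments). Orientation is
  antisense to the TE consensus with probability 0.8. The 5′ end falls on
  a read-strand uridine with probability `u1_bias` (default 0.9),
  implemented by sampling from the uridine/non-uridine position pools so
  the configured probability is recovered exactly. The 3′ end is *phased*:
  with probability `phasing_downstream_u` (default 0.5) the read length is
  chosen so the next genomic base on the read strand is uridine, jointly
  resampling the 5′ position (up to 30 tries) when no length in range
  works. With probability `pingpong_fraction` an antisense piRNA emits a
  sense partner whose 5′ end lies 10 nt into the antisense read, making
  the partner's 10th base the complement of the mate's 1st (10A when the
  mate starts with U) — the partner's position is fixed by this geometry,
  so when no phased length exists for it the length falls back to uniform,
  which dilutes the measured downstream-U frequency by roughly half a
  percentage point at default settings.
* **hpRNA-siRNA**: 21 nt from the hairpin locus, either strand. These are
  the normalization denominator downstream.
* **miRNA**: 22 nt from miRNA loci on the annotated strand.
* **degradation**: 18–40 nt uniform from random genomic positions.

piRNAs and siRNAs are 2′-*O*-methylated (probability 1.0 by default);
miRNA and degradation reads are not. `apply_oxidation` retains methylated
reads and keeps unmethylated ones with probability 0.02 (periodate
oxidation survival); it never creates reads.

`render_fastq` writes 75-cycle records laid out as
`4 nt UMI + insert + 4 nt UMI + 3′ adapter`, with constant quality `I` and
`G` fill past the adapter (dark-cycle convention); a sidecar truth TSV
links read ids to class, placement, methylation and partner.

## Preprocessing

Adapter trimming is exact-match: the leftmost occurrence of the full
adapter anywhere in the read, or of an adapter prefix of ≥ 6 nt anchored
at the read's 3′ end, wins. Reads without adapter evidence are excluded
(no insert boundary can be determined). Four bases are then stripped from
each end (the randomized UMIs), and inserts of 18–40 nt inclusive are
kept; the size window is applied once, for all downstream stages
(configurable via `size_select_all`). No quality filtering is applied.
Counts are conserved exactly across the four outcomes (kept, untrimmed,
too-short, size-filtered).

## Mapping

`align.map_reads` is an exhaustive k-mismatch placement engine with
Bowtie1-style all-best-strata reporting: for each read it finds the
minimal achievable mismatch count m\* (0–3) over all offsets of both
strands of all targets and reports exactly the tied-at-m\* placements.
Implementation: an exact-occurrence fast path plus a pigeonhole seed index
(m+1 disjoint seeds of length 12/9/6/4 for max mismatches 0/1/2/3), with a
full sliding-window scan for reads too short for disjoint seeds; mismatch
verification is vectorized. Correctness is defined by an independent
brute-force scanner in the test suite, not by the index scheme.

Multi-mappers carry total weight 1, split 1/n over the n reported
placements. Infrastructural annotation (rRNA, snRNA, snoRNA, miRNA, tRNA,
plus the hpRNA locus; ≤ 1 mismatch) flags reads but does not remove them
from genome or TE mapping — exclusion happens only in the tile mask.
Genome mapping allows 1 mismatch, TE mapping 3; the two are independent
mappings, not a competition for read assignment.

## Signatures

* **Size distribution**: weighted counts per length (18–40) and TE
  orientation, normalized per million hpRNA reads (raw counts retained,
  and flagged unavailable, when the denominator is zero).
* **Frequency windows**: 11 positions, anchor at index 5 (centre), around
  the antisense 1st or sense 10th base of reads > 22 nt; positions
  upstream of the read come from the alignment target on the read strand,
  windows running past the target are dropped and counted. Columns
  normalize to 1 wherever any weight was used.
* **Ping-pong z-score**: `z = (f[anchor] − mean) / SD` with mean and
  *population* SD (divisor n) taken over the 11 per-position frequencies
  of the base. Two consequences are worth stating plainly. First, a
  single-outlier window has `|z| = √10 ≈ 3.162` regardless of the outlier
  magnitude — this closed form documents the convention and is asserted in
  the tests. Second, √10 is a hard *upper bound* for any single anchor
  under this convention (spread among the other 10 values only inflates
  the SD), so a strong biological signal saturates near 3.16 rather than
  growing without limit; distinguishing signal from null therefore uses
  the separation from |z| ≤ 2 rather than large z magnitudes. A zero-SD
  window returns z = 0 with a degeneracy flag, which arises on tiny toy
  inputs and should not be treated as evidence of absence.
* **Phasing**: frequency of uridine at the genomic base immediately 3′ of
  each >22-nt genome alignment (plus-strand: base at `end`; minus-strand:
  complement of the base at `start − 1`), weighted, split into TE-mapping /
  non-TE / all categories. Edge-abutting alignments are dropped and
  counted.
* **TE-mapping fraction**: fraction of >22-nt reads with at least one TE
  alignment; flagged undefined when no such reads exist.

## Tiles

The exclusion mask pads tRNA/snRNA/snoRNA features by ±100 nt (clipped,
merged) and adds the *aubergine* locus unpadded. Unique genome mappers of
>22-nt reads overlapping the mask by ≥ 1 nt are removed (the strictest
overlap reading); survivors are assigned to the single tile containing
their 5′ end. Tile width is not dictated by the statistic, so it is
configurable with a 1,000-nt default — conventional for cluster-scale
tiling and comfortably sub-cluster on the toy genome; read-granularity
(5′-end) assignment rather than per-base coverage keeps count conservation
exact. Cluster abundance sums normalized tile values over tiles whose
midpoint lies inside the cluster; a cluster shorter than a tile can catch
no midpoint and reports 0 with a flag. Ratios to a reference library are
per-cluster, with zero-reference clusters flagged undefined.

## TE mRNA abundance

TPM-style arithmetic on transcript-level count tables: per-transcript rate
`count/length`, scaled to one million over host and TE transcripts
together. Effective-length correction is deliberately not applied —
upstream quantification is out of scope and counts are taken as given.
Library comparisons use log2 ratios with a pseudo-abundance (default 1
per-million unit) so a TE absent from both libraries reports 0.
`simulate.simulate_te_counts` provides negative-binomial count tables for
two conditions with configurable per-TE fold changes, mean depth and
dispersion.

## What the simulator does and does not emulate

The simulator reproduces the *statistical structure* the analysis
measures: size ranges, strand biases, ping-pong 5′ geometry, phased 3′
ends, methylation-dependent oxidation survival, adapter/UMI read layout,
and class composition. It does not model sequencing errors, PCR
duplication, ligation bias, gel size-selection efficiency curves, genomic
repeat families (TE copies are deliberately unique), or the genic/
unannotated piRNA component of real libraries. Passing tests therefore
demonstrate that the analysis recovers known generative parameters through
the full read-processing chain — not that real tissue libraries will show
any particular signature strength.

## Problem sizes and numerical choices

Simulated libraries in the test suite and acceptance script use 50,000
primary reads for signature-recovery statistics (binomial SE ≈ 0.003 on
the phasing frequency), 10,000 for parameter-recovery and contrast checks,
and a few thousand elsewhere; mapper-oracle equivalence uses 200 reads ×
3 references × mismatch allowances {0, 1, 3}. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; simulator
outputs are byte-identical across runs for a fixed seed. Frequencies and
TPM values are held to 1e-9 and 1e-3 absolute tolerance respectively in
the invariants.

## Known limitations

* The toy TE library is a stand-in; no curated transposon set is shipped.
* The z-score saturates at √10 by construction (see above); comparisons
  across libraries near saturation are not meaningful.
* Adapter trimming is exact-match only; a sequencing-error model would
  require mismatch-tolerant trimming.
* The classic 5′-overlap ping-pong histogram (z over overlaps 1–20) is not
  implemented; the positional-frequency z-scores above are the supported
  statistics.
* UMI deduplication is intentionally absent (the library chemistry's UMIs
  are stripped, not collapsed).
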