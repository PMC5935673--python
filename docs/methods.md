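# Methods

## Overview

`pirnakit` quantifies where in the genome a germline knockdown removes
piRNAs, and what co-occurs at those loci: precursor splicing de-repression,
chromatin (ChIP) enrichment, ping-pong amplification, and evolutionary age
of the affected transposon insertions. The package is built around a
synthetic-data generator whose parameters *are* the study conditions: every
analysis stage is validated by recovering known effect sizes from simulated
reads, never from the generator's internal ledger.

## Read processing and mapping model

Small-RNA reads enter at 18–30 nt; only 23–29 nt reads are treated as
piRNAs. Two mapping routes feed all downstream counts:

* **Consensus route** — alignment to transposon family consensus sequences
  permitting up to 2 mismatches. Every placement in the read's
  minimum-mismatch stratum is reported, on either strand of any family;
  a read that aligns to several families counts once per family, with no
  fractional weighting. Per-family totals are therefore interpretable per
  family but not additive across families. Best-stratum reporting prevents
  a perfectly matching read from also counting at its 2-mismatch shadow
  positions.
* **Genome route** — exact (0-mismatch) alignment carrying the genome-wide
  hit count; only uniquely mapping reads (`n_hits == 1`) feed cluster,
  insertion and window counts. An alignment is assigned to a feature only
  if its full span lies inside the feature; a read can hit at most one
  insertion but also the cluster enclosing it (feature sets are counted
  independently).

`N` never matches anything, including another `N`. Both aligners are
seed-indexed (pigeonhole chunk seeding for the mismatch-tolerant route, a
12-mer prefix seed for the exact route) and are tested record-identical to
exhaustive position × strand × target scans.

## Normalization and fold changes

Counts are scaled to reads per million of either library depth or the
library's miRNA-mapping read count (full-length exact matches to the miRNA
reference set). miRNA normalization is the primary mode: miRNA abundance is
unaffected by a germline piRNA-pathway knockdown, so it recovers absolute
piRNA changes even when the piRNA pool shrinks. A library with no miRNA
matches falls back to depth normalization with a logged warning.

Fold reduction is `FR = (control + ψ)/(KD + ψ)` on normalized counts with
pseudocount ψ = 1 normalized unit (config-exposed); fold upregulation is
its reciprocal. When two knockdown replicates are supplied, FR is computed
per replicate and the mean log₂ FR is reported. Thresholds are bound to
config keys: ≥2.5-fold for cluster loss and transposon de-repression,
≥2-fold for family-level loss, ≥3-fold for insertion-level loss in the age
analysis.

## Compartment analysis

Insertion counts are consolidated per cytolocation bin (a labeled interval
tiling each chromosome; 30-kb fixed-width bins in the synthetic genome, a
real cytoband BED can be substituted). An insertion belongs to the unique
bin containing its midpoint; bins need more than 1000 uniquely mapping
control reads to be analysed. Each bin, cluster and insertion is classified
into telomeric / pericentric / arm by the compartment-map interval
containing its midpoint (half-open intervals, so boundaries belong to the
right-hand interval).

Smoothing of log₂ FR along chromosomes uses local polynomial regression:
for each point, the `ceil(span·n)` nearest neighbours are fit by weighted
least squares of degree 2 under tricube weights, with no robustness
iterations. Span defaults to 0.3. Log scale was chosen so loss and gain are
treated symmetrically; span, degree and scale are config keys since the
method's canonical parameters are conventions rather than theory.

## Ping-pong signature

For each family, per-position 5′-end depth vectors are formed from its
consensus alignments (a minus-strand read's 5′ end is its rightmost base in
forward coordinates). The overlap histogram is
`N_k = Σ_p plus(p)·minus(p + k − 1)` — the product-of-depths formulation,
identical to enumerating all read pairs. Probabilities are normalized over
k ∈ {2..20}; k = 1 is excluded from both the normalization and the
background so the focal overlap (k = 10) and its background share one
support. `z = (p₁₀ − mean(p_b))/sd(p_b)` with the population (n-divisor)
standard deviation over the 18 background values; a flag switches to the
sample SD. Histograms with no pairs, or with a degenerate (constant)
background, are flagged undefined rather than reported as 0.

## Precursor splicing (SSR, FPKM)

Splice-aware alignment at this scale is realized by exact matching against
two references per feature: the unspliced genomic precursor and the
precomputed spliced isoform. A read is *spliced* if it matches the spliced
isoform across the exon–exon junction with ≥5 nt (the anchor) on each
side; *unspliced* if it lies wholly inside the intron or crosses an
exon–intron boundary with ≥5 nt in the intron; exon-interior reads are
compatible with both isoforms and stay unassigned, so
spliced + unspliced + unassigned equals the feature's read total.
`SSR = spliced/unspliced` (flagged undefined at unspliced = 0);
`FPKM = count·10⁹/(length·total mapped reads)` with totals over the whole
library. The junction-detectability factor (the fraction of isoform
positions a read can occupy while satisfying the anchor rule) cancels in
the KD/control SSR fold change, which is why a spliced-fraction change
0.2 → 0.5 yields a fold change of exactly (0.5/0.5)/(0.2/0.8) = 4 in
expectation. Spliced-FPKM fold increases are averaged over replicates per
cluster when replicates exist. Surrogate protein-coding genes with a
condition-independent spliced fraction serve as the negative control.

## ChIP enrichment

ChIP and IgG alignments (exact, unique) are assigned to 10-kb windows by
midpoint on a half-open grid, each library normalized to reads per million,
and enrichment computed by subtraction, `E = ChIP_norm − IgG_norm`, as a
per-window track (E may be negative; a log-ratio mode would be a config
extension). Per-cytolocation mean E over member windows summarizes the
track; "mean enrichment per cytolocation" is this package's operational
definition for relating chromatin occupancy to piRNA loss, and the relation
is tested with a tie-corrected Spearman rank correlation over bins passing
both the enrichment (non-empty) and loss (>1000 control reads) filters.

## Age stratification

Eligibility follows the distinct-sequence reading of "targeted by at least
20 unique piRNAs": an insertion qualifies when its control library contains
≥20 distinct read sequences uniquely mapping within it (a config flag
switches to the plain read-count reading; the ambiguity is real and both
are supported). Per family, the fraction of eligible insertions with
FR ≥ 3 is reported with its n. Log₂ FRs are compared across age classes
with one-sided Mann–Whitney tests (alternative: fixed-class loss is
stochastically larger than common / rare), two planned comparisons reported
separately without multiple-testing correction. A dedicated consensus pass
at ≤3 mismatches counts, per family, piRNAs whose best alignment carries
2–3 mismatches — a proxy for targeting of old, diverged copies — and that
count is rank-correlated with the family fold reduction.

## Statistical utilities

Mann–Whitney U switches to exact permutation enumeration when the combined
sample size is ≤12 (two-sided p by symmetric-tail reflection around
n_a·n_b/2, which gives p = 1 for identical samples); otherwise the
tie-corrected normal approximation. Kolmogorov–Smirnov (asymptotic),
Spearman and the Shapiro–Wilk normality gate delegate to scipy; the gate
returns a routing decision (normal / non-normal at α = 0.05) and logs it.
Undefined results (e.g. correlation of a constant vector) carry NaN
p-values rather than being coerced.

## The synthetic-data generator

The generator emulates the structure the analyses depend on, at a scale
where exhaustive oracles are feasible:

* **Genome**: 3 chromosomes × 300 kb of random sequence. Compartments: the
  outer 10% of each chromosome end is telomeric; a central 20% band around
  a simulated metacentric centromere is pericentric (one 30-kb cytolocation
  bin either side of the midpoint, so compartment boundaries fall on bin
  edges and pericentric bins can clear the 1000-read filter); the rest is
  arm.
* **Transposons**: 12 families of 1.5-kb consensus; 8 insertions each,
  placed as consensus copies with age-class-dependent divergence (fixed
  0.08, common 0.04, rare 0.01 substitutions per site — chosen so 2–3-
  mismatch piRNAs arise naturally from old insertions). Two families are
  telomere-restricted; fixed-class insertions of the others are biased
  (p = 0.7) into the pericentric compartment.
* **Clusters**: 4 (one telomeric, one pericentric, two arm), each 15 kb of
  concatenated 300–800-bp consensus fragments in both orientations at 10%
  divergence, with a central 2-kb intron. The 10% fragment divergence keeps
  most cluster-derived 23–29-mers unique in the genome.
* **Small-RNA libraries**: a deterministic composition of miRNA reads
  (15%, exact copies of 20 simulated miRNAs), uniform genomic background
  (2%, 18–30 nt) and piRNAs (23–29-nt substrings of clusters and
  insertions, sampling weight ∝ locus length). The knockdown *thins* the
  piRNA pool: locus weights are multiplied by the compartment multiplier
  (and optional per-age-class multipliers) and the piRNA read total shrinks
  by the weighted mean multiplier, while miRNA and background absolute
  counts stay fixed. Expected per-locus KD counts therefore scale exactly
  by the multiplier, and miRNA-normalized fold reduction recovers its
  reciprocal (e.g. multiplier 0.2 → FR 5). A fraction φ of piRNA reads is
  emitted as sense/antisense pairs on consensus coordinates with exactly
  10-nt 5′ overlap (sense 5′ at p, antisense 5′ at p + 9), so the
  ping-pong statistic is testable on consensus mappings.
* **RNA-seq**: 100-nt stranded reads from cluster precursors (spliced with
  probability s in control, s′ in KD; defaults 0.2 → 0.5) and from five
  surrogate genes with condition-independent splicing (0.8).
* **ChIP/IgG**: 50-nt reads; IgG uniform over the genome, ChIP weighted by
  per-compartment enrichment (default 5× at telomeric and pericentric).

Every simulator is a pure function of (config, truth, seed); the same seed
reproduces byte-identical files. Every read has exactly one truth-ledger
row; recovery tests consume only the FASTQs. No sequencing-error model is
applied by default, so downstream mismatch counts are interpretable as
evolutionary divergence.

**What the simulation does not emulate** — and hence what passing tests do
not show about real data: sequencing error and quality variation, adapter
remnants and PCR duplicates, 2S rRNA contamination, nested or truncated
insertions, copy-number polymorphism between strains, somatic cell
contamination of ovary libraries, and the fragment-size and GC biases of
real ChIP. Results on real libraries depend on upstream cleaning that is
out of scope here.

## Numerical choices and degenerate inputs

* Pseudocount ψ = 1 normalized unit on both sides of every fold ratio;
  zero-count features are therefore finite and shrink toward 1.
* Loess neighbourhoods keep a strictly positive weight floor (10⁻⁹) so the
  farthest neighbour (tricube weight exactly 0) cannot zero a row of the
  design; a rank-deficient local fit raises an error suggesting a larger
  span.
* The ping-pong background SD is treated as zero (z undefined) when it is
  below 10⁻¹² of the background mean, absorbing float residue on exactly
  flat histograms.
* Window grids are half-open and assigned by midpoint; the last window of a
  chromosome may be short.
* Problem sizes in the test suite and the acceptance script (60–100 k reads
  per small-RNA library, 20-seed repetition for calibration properties,
  25 k reads per seed for rank-order recovery) were chosen so binomial
  sampling error is small against the effect sizes under test while the
  whole suite stays comfortably runnable on a laptop-class single CPU.

## Known limitations

* The aligners handle substitutions only — no indels, no quality awareness;
  they are desk-scale replacements, not Bowtie.
* Consensus multi-mapping is counted once per family; alternative
  weightings (fractional, primary-only) are not implemented.
* The per-cytolocation ChIP summary is a mean of window enrichments, one of
  several defensible definitions of "enrichment likelihood".
* FPKM uses the junction / intron read counts as isoform proxies, which
  undercounts both isoforms by their detectability factors; this cancels in
  condition ratios but the absolute FPKMs are not comparable across
  features with different geometry.
* Heterochromatin/unassembled-scaffold exclusion and real cytoband
  nomenclature are data-selection steps for real genomes, applied at
  annotation load, not algorithms of this package.
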