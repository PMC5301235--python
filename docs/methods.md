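# Methods

This note documents the models, estimators, and numerical choices
behind `kmerdiv`, and what the synthetic data used by the tests does
and does not emulate.

## Canonical k-mer counting and spectra

A k-mer (default k = 25, limit k ≤ 31) is stored as its canonical form,
the lexicographic minimum of the k-mer and its reverse complement,
packed two bits per base into a 64-bit integer. Canonical counting is
the right choice for whole-genome shotgun data because the sequenced
strand is unobserved; counting the reverse-complemented read set yields
an identical table by construction. Windows containing any non-ACGT
character are skipped rather than randomized, so an N never creates a
phantom k-mer. Counting is exact (a vectorized merge-sort of packed
codes), not sketch- or Bloom-filter-based; the design target is
desk-scale data (up to ~10⁸ counted positions in memory), not
billion-read production counting.

Upstream read error correction is deliberately **not** reimplemented.
Its role — removing k-mers created by sequencing errors — is played by
a minimum-count filter: error k-mers are overwhelmingly singletons at
any realistic depth, and the spectrum's error trough gives a principled
cutoff. This is a stated substitute, so genome-size estimates from this
package are not comparable to estimates produced inside an
error-correction pipeline, only to the truth of the simulation.

The abundance spectrum (histogram of count → number of distinct
k-mers) is smoothed with a 3-bin moving average before extremum
detection; window 3 is the smallest window that suppresses
single-bin sampling noise without displacing the peak at desk-scale
depths. The **trough** is the smoothed minimum between abundance 1 and
the first local maximum; a boundary maximum at abundance 1 is treated
as the error tail, not a peak (a peak requires a strict rise from its
left). The **single-copy peak** is the smoothed argmax above the
trough. Genome size is estimated as

    size = Σ_{a ≥ trough} a · hist[a] / peak_depth,

i.e. total counted k-mer instances above the error trough divided by
the single-copy depth. For error-free reads of length L at fold
coverage D the expected single-copy k-mer depth is D·(L−k+1)/L, so the
estimate is depth-invariant (verified at 20× vs 40× within 2%).

The **single-copy band** defaults to [round(0.55·peak),
round(1.35·peak)], calibrated so a peak depth of 37 reproduces the
fixed band [20, 50] used at ~37× k-mer depth; an explicit override
reproduces fixed published bounds exactly (inclusive on both ends).
When summarizing how many single-copy k-mers two genotypes share, a
k-mer counts as shared if it is *present at any count* in the other
genotype's table (default), because a single-copy sequence of one
genotype may legitimately be multi-copy in the other; band-membership
mode is available for symmetric analyses.

## Differential abundance (HAKmers)

HAKmers are k-mers with combined count ≥ `min_total` across the two
compared libraries (absent = 0). The published threshold, 20,000
combined counts at roughly 92× combined coverage, corresponds to a
copy-number floor of about 200; the config can rescale the threshold
proportionally to the configured combined depth so the same floor
applies to desk-scale simulations.

Each HAKmer is tested with a 1-degree-of-freedom chi-square
goodness-of-fit of (c_A, c_B) against the library-size-proportional
expectation e_A = T·L_A/(L_A+L_B), e_B = T·L_B/(L_A+L_B), T = c_A+c_B,
without continuity correction. This is the natural formalization of
"no relationship between k-mer counts and genotype" that also corrects
depth imbalance. P-values are Benjamini–Hochberg adjusted over all
tested HAKmers; a gain call additionally requires a two-fold change in
library-size-normalized counts, with a zero count floored at one raw
count before the ratio. Note that at a *true* two-fold difference the
observed fold straddles the threshold, so roughly half of exactly
two-fold k-mers are called — the fold rule is a deliberate conservative
filter, not a power guarantee at its own boundary.

Genotype-specific HAKmers have ≤ 10 counts in one genotype; by the
extraction threshold their count in the other genotype then exceeds
`min_total` − 10 (19,990 at published scale). Specific labels
supersede gain labels so the five call labels partition the records.

Annotation replaces a BLASTN workflow with a defined, deterministic
matcher: a k-mer hits a library entry if it aligns end-to-end inside
the entry (either strand) with ≤ 2 substitutions and the alignment
contains an exact run of ≥ 12 bases (the BLASTN word size). The best
hit minimizes mismatches, then maximizes the exact run, then takes
library order. Every such alignment is found via a 12-mer seed index,
and the matcher is verified against an exhaustive
all-offsets/all-strands oracle in the tests. Reference mapping reports
all exact full-length matches on both strands with 1-based starts;
since matching is canonical, a palindromic k-mer yields one hit per
position, never two. Per-bin hit counts use half-open 100-kb bins with
a configurable reporting floor (default 10 hits).

## Conserved single-copy normalization

Across a panel, raw counts confound copy number with library size and
organelle contamination. Candidate k-mers (single-copy in the two
reference genotypes) are ranked by the Pearson correlation of their
per-line counts with per-line library sizes — Pearson rather than
Spearman because the model is proportionality, not monotonicity — and
the top 5% become the conserved single-copy set. With C_i the total
count of that set in line i, the factor

    f_i = mean_j(C_j) / C_i

makes the normalized conserved total equal to the panel mean in every
line, exactly (an algebraic identity the tests assert). This
multiplicative form is chosen because equalizing the conserved
single-copy signal across lines is precisely the property the
normalization exists to deliver.

Repeat copy number is the **median** (not mean — robustness to
dropout, divergence, and multi-mapping) over a family's conserved
k-mers of count / single-copy depth, with the single-copy depth taken
from the line's own spectrum peak. For a family with an internally
duplicated sub-span the per-k-mer estimates are bimodal and the median
reports the majority mode; this is documented behavior, not an error.
The family k-mer set must be pre-filtered against other repeat classes
and organelle sequence by the caller.

## cnvQTL mapping

Normalized k-mer abundance per DH line is the trait. DH genotypes are
fully homozygous and fully informative at markers, so Haley–Knott
regression degenerates to single-marker regression and no interval
model is fitted; peaks are reported at marker resolution. The score is
the likelihood-ratio LOD under a normal model with MLE variances:

    LOD = (n/2) · log10(RSS0 / RSS1)

with RSS0 around the grand mean and RSS1 around the two
genotype-class means (pairwise deletion of missing genotypes per
marker; markers with fewer than two lines in either class are reported
missing). Perfect separation (RSS1 = 0) is reported at a ceiling of 50
as a flagged degenerate value; finite scores are never clipped, so
strong peaks still order correctly.

Genome-wide significance is the (1−α) empirical quantile (type-7 /
linear interpolation) of the permuted genome-wide maximum LOD over
1,000 trait shuffles. For calibration work the package also draws
independent standard-normal null traits, which is equivalent in law
under the null. On a 280-line panel with 10 chromosomes of 140 cM and
1 cM marker spacing this 5% threshold is ≈ 3.0–3.1 (estimator SD
≈ 0.08 at 1,000 replicates); peaks are declared above
max(threshold, 4). Peak calling is greedy on decreasing LOD with
suppression of markers within 30 cM on the same chromosome, up to 4
peaks per k-mer — repeats present at multiple genomic clusters
legitimately map to multiple chromosomes.

## Group trends

Highly variable k-mers satisfy two strict predicates: normalized count
> 1,000 in ≥ 5 lines and < 10 in ≥ 5 other lines (thresholds strict
exactly as published; desk-scale runs rescale the magnitudes through
the config). Each is tested by one-way fixed-effects ANOVA across the
ordered evolutionary groups on normalized (not log) counts, with
Bonferroni control at α/m; zero within-group variance with equal means
is reported as p = 1. Profiles of significant k-mers are scaled by
their row maximum (entries in [0, 1]) and clustered with a Gaussian
mixture whose components share one full covariance matrix (the equal
volume/shape/orientation parameterization), G ∈ 1..12 chosen by BIC,
k-means initialization with 10 restarts, covariance ridge 10⁻⁶.

Cluster direction (the published analysis grouped clusters manually)
is automated: a cluster is "decrease" when its first-group mean
exceeds its last-group mean by more than 20% of the profile scale
(profiles are max-scaled, so this is 0.2 in scaled units), "increase"
for the reverse, else "flat". The threshold is applied to the scaled
data range rather than the cluster mean's own range because a flat
cluster's internal range is pure noise and a range-relative rule would
assign it a random direction. PCA of lines over a k-mer set is
centered but not scaled, matching an analysis of normalized counts in
common units.

## Allele-specific expression

A single-nucleotide variant inside an otherwise conserved repeat
yields k-mer pairs identical except at one base; Hamming comparison is
performed over both relative orientations because the canonical forms
of the two alleles can sit on opposite strands. Pair finding requires
one member to be abundant in one genotype but near-absent in the other
(a genotype-restricted allele) and its mate abundant in the other
genotype; pairs are formed greedily by abundance, each k-mer joining at
most one pair, and output order is input-order invariant.

Per-sample allelic balance is log2((c_B + 0.5)/(c_A + 0.5)); the 0.5
pseudocount stabilizes zeros, and samples with both members at zero
are omitted. The ratio is computed within one library, so no
cross-library depth normalization enters it. Pooled maternal:paternal
ratios per stage use summed counts rather than the mean of per-pair
ratios, because the sum-based estimator is variance-minimizing for
Poisson counts; zero paternal counts give an infinity flag (the
expected outcome in maternal-only early kernels), not an error.
A triploid endosperm with 2 maternal : 1 paternal genomes and equal
per-copy transcription gives a pooled ratio of 2, which the Poisson
simulation recovers within sampling error.

## Synthetic data: what it emulates, what it does not

Genomes are a uniform random backbone shared between genotypes, plus
clustered head-to-tail tandem arrays (satellite-like 156-bp,
knob-like 180-bp, telomere-motif, and a 9-kb rDNA-like unit with
18S/ITS1/5.8S/ITS2/26S/IGS sub-spans for planting genotype-specific
IGS variants and a 26S SNV), with per-copy divergence 0.5% so family
k-mers are shared within a family yet families stay distinguishable.
Genotypes differ in SNVs (first genotype carries the reference allele)
and family copy numbers. Coordinates in truth records are 1-based
inclusive. Reads are uniform over positions and strands with i.i.d.
substitution errors and constant quality; fragments in paired mode
have a fixed insert of three read lengths.

DH populations follow Haldane's map function with no crossover
interference; any intermated-population map expansion is assumed
already expressed in the supplied cM map. Marker spacing defaults to
1 marker/cM (a modeling choice, not a measured density). Grouped
panels draw per-family copy numbers from per-group (mean, sd) normal
profiles rounded and truncated at zero, line depths uniform in a
configured range, and contaminate libraries with reads from a single
150-kb circular plasmid-like organelle sequence, holding total library
bases fixed so contamination dilutes nuclear depth exactly as in real
libraries. Allelic transcript counts are independent Poisson draws per
pair at dosage × per-copy rate.

Not modeled: indels and structural-variant read signatures, GC bias,
realistic quality strings, PCR duplicates, crossover interference,
organelle sequence diversity, and transcription noise beyond Poisson.
Passing tests therefore demonstrate correctness of the estimators
under these idealized conditions, not robustness to every artifact of
real libraries.

Test and demo problem sizes (hundreds of kilobases of genome, a
few-fold to 30× depth, tens to hundreds of panel lines) are the
package's desk-scale defaults; every published threshold that encodes
a depth (HAKmer `min_total`, the >1000/<10 variable filter) is
rescaled through the config rather than edited, so the published
values remain the documented defaults.

## Degenerate inputs and tie-breaks

- Monotone spectra raise "no peak"; an empty single-copy band
  intersection is an empty set, not an error.
- A class with zero normalized count in one genotype reports an
  infinite ratio flag; zero in both reports NaN.
- Constant traits scan to all-zero LOD with a warning and are skipped
  (and logged) in batch mapping.
- Annotation ties break by fewest mismatches, then longest exact run,
  then library order, making results independent of query order.
- All-zero profile rows are rejected by name before scaling.
- The mixture's EM keeps the best of its restarts; non-convergence
  returns the best-so-far fit with sklearn's warning.
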