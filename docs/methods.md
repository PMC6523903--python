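# Methods

## Assay model

The pipeline models a double-digest reduced-representation methylation
assay. Genomic DNA is cut by the methylation-insensitive MseI (`T^TAA`)
and one methylation-sensitive enzyme per cytosine context (AciI `C^CGC`
for CG, EcoT22I `ATGCA^T` for CHH, Fnu4HI `GC^NGC` for CHG). Cuts are
modelled as blunt single offsets on the top strand; overhangs are ignored
because only fragment boundaries and the restriction remnant left at a
fragment end matter downstream. A sensitive site is cut with probability
`prod(1 - m)` over its blocking cytosines (one per strand), independently
per sample digest; MseI always cuts. Fragments therefore tile each
chromosome exactly, which is asserted as an invariant.

Library selection keeps fragments of 300–500 bp (inclusive) with one
sensitive end and one MseI end, reflecting two-adapter RAD chemistry in
which only sensitive-end adapters receive the sequencing primer. One
refinement follows from the blunt-cut model: a fragment end is only
*sequenceable* if a read taken inward from it begins with the enzyme's
remnant (the demultiplexer later requires that remnant after the barcode).
This is orientation-dependent: AciI (non-palindromic) reads only from the
side matching the site orientation; Fnu4HI only from the downstream side
(the upstream side would read `GC...`, not `NGC`); EcoT22I from both sides
(its remnant is the single base `T`, present on either side of the cut).
Without this restriction, simulated reads from the "wrong" side would fail
the remnant check and error-free demultiplexing could not recover 100% of
reads — an invariant the test suite enforces.

Reads are 1×150 bp single-end: a 7-bp sample barcode plus the fragment
sequence from the sensitive cut (reverse-complemented when that end is the
fragment's right end), truncated to 143 genomic bases. Per-fragment read
counts are Poisson(depth); substitution errors are i.i.d. per base
(default 0.001); qualities are constant Phred+33. Read ids encode the
origin fragment, forming the simulation truth log.

## Synthetic epigenome

The generator reproduces the study design the statistics are built for:
two phenotype groups (true-to-type TT, off-type OT), three biological
replicates each, three context libraries. Methylation is **bimodal**: each
sensitive-site blocking cytosine is either fully methylated (level 1) with
the context's baseline probability — identically in all samples — or
unmethylated. Defaults are CG 0.30, CHG 0.15, CHH 0.05, reflecting the
qualitative ordering of context methylation in plant genomes; they are
free parameters of the generator, not estimates for any real species.
Bimodal baselines keep non-differential loci Poisson-clean (a silenced
site is simply absent from every sample), which is what makes the
exact-test calibration check meaningful; a constant fractional level would
instead make every locus's presence a per-sample Bernoulli draw and
inflate between-sample variance at *all* loci.

Planted DML are placed only at *assayable* sites: the blocking cytosine of
a sensitive site that terminates a size-selectable mixed-end fragment
under the baseline digest. Methylation anywhere else never changes read
counts, so planting there would make recovery unmeasurable. Planted sites
are spaced ≥ 1 kb apart (within a context) so they do not interact through
fragment structure, and a cytosine is never planted for two contexts
(overlapping recognition sites can share one). Directions alternate
hypo/hyper: `hypo_in_TT` sets m = 0 in TT and m = effect in OT (TT less
methylated ⇒ more TT reads), `hyper_in_TT` the reverse. The default
effect is 1.0 (full switch).

Default scale is a 2 × 7 Mb genome at GC 0.40 with 200 planted DML per
context. The scale is set by locus density: selectable 300–500 bp
mixed-end fragments occur at roughly 130 (AciI), 80 (EcoT22I, both cut
sides) and 110 (Fnu4HI) per Mb at GC 0.40, so ~14 Mb yields ≥ 2000 catalog
loci across the three libraries and comfortably hosts 200 planted DML per
context. All randomness derives from one master seed through per-module
named streams, making every run byte-reproducible.

What the generator does **not** emulate: diploid phasing and epialleles,
transposable elements, chromatin segmentation, PCR duplicates and GC bias,
indels, partial methylation polymorphism within groups, and genome
repetitiveness (a random genome has almost no multi-mapping loci). Passing
recovery tests therefore demonstrate the pipeline's correctness under
clean presence/absence signal, not its robustness to repeat-rich genomes
or diffuse methylation differences.

## Statistical core

Counts are normalized to counts-per-million by library size (a column of
CPM sums to 1e6 whenever the library size equals the column total). The
per-locus log2 fold change uses a pseudo-count of 0.5 on mean CPM.

"Biased" loci are removed by a per-locus pooled-variance two-sample
t-test on CPM (TT vs OT) with Benjamini–Hochberg correction; loci with
q < 0.05 are retained for QC ordination (column-centered SVD; explained
variance fractions) and UPGMA clustering on Euclidean distances, and feed
the DML call. Degenerate t-tests (both groups zero-variance) give p = 1
when means agree and are flagged with p → 0 otherwise.

DML are called per locus by an exact test on per-group aggregated counts
at p < 0.01 (no further multiplicity correction, by design: the FDR
prefilter precedes it). Aggregation is by **group sums with summed
library sizes**: under Poisson sampling noise, Fisher's exact test on
sums is exactly calibrated, which was verified by simulation (empirical
type-I 0.008 at α = 0.01, inside the 95% binomial interval), whereas
rounded per-group means are strongly underdispersed relative to Fisher's
margins and give an empirical type-I near zero. Rounded-mean aggregation
remains available (`aggregate="mean"`) for comparability. Two test
methods are provided: Fisher's exact test (default) and a conditional
negative-binomial exact test given n = a + b with common dispersion φ
(means proportional to library sizes); at φ = 0 it reduces exactly to the
binomial conditional test, and a conditional-likelihood grid estimator
for φ across loci is included. Direction: mean CPM_TT > mean CPM_OT ⇒
`hypo_in_TT` (more reads = less methylation).

## Catalog construction

Reads of one library share a 5' anchor (the remnant), so clustering is
ungapped and 5'-anchored: unique sequences are processed longest-first
(ties lexicographic); a read joins the *first* centroid (creation order)
with identity ≥ 0.90 over the overlap, else founds a new centroid.
Consensus is the per-position weighted majority with ties resolved toward
the centroid base. Assignment takes the *best*-identity locus at the same
threshold, ties to the lowest locus id; reads below threshold are counted
unassigned. Loci with < 3 reads in total are dropped before statistics
(library sizes, being per-sample assigned totals, are kept as computed
before the drop). The clusterer is verified against an independently
coded brute-force re-implementation on random read sets.

## Annotation

Locus consensus sequences are placed by exact search of both strands;
multiple exact hits flag the locus multi-mapping (excluded), zero hits
trigger a pigeonhole one-mismatch rescue. Coordinates are 0-based
half-open internally; GFF3 I/O converts to 1-based inclusive. Location
categories are exclusive with precedence intragenic > upstream >
downstream > intergenic; upstream/downstream are 2000 bp windows before
the translational start / after the stop, strand-aware, clipped at
sequence bounds only. Among qualifying genes the largest overlap wins
(ties: nearest translational start, then lowest gene id). GO slim tallies
compare input genes to a user-supplied background with upper-tail
hypergeometric enrichment, BH-adjusted; genes absent from the gene→GO map
count as `unannotated`.

## Downstream analytics

The miRNA-target scorer is a deliberate simplification of plant target
predictors: ungapped antisense alignment over every window, penalties
mismatch 1.0 / G:U wobble 0.5 doubled at miRNA positions 2–13 (5'-based),
hit iff expectation E ≤ 5, and translational-inhibition mode when any
non-Watson–Crick pairing falls at positions 10–11. The penalty constants
are configurable; no bulges/gaps are modelled, so scores can diverge from
thermodynamics-aware web services on edge cases. Network statistics treat
the interactome as a simple undirected graph (self-loops rejected);
average degree is 2E/N. ΔΔCT quantification averages technical
replicates, takes the reference CT as the arithmetic mean of the two
reference-assay means (equivalent to a geometric mean of linear
quantities), computes ΔΔCT against the calibrator-group mean and fold
change `2^-ΔΔCT`; groups are compared by the same pooled t-test used for
locus prefiltering (single implementation).

## Numerical and design choices

- Quality trimming scans non-overlapping windows (step = window size,
  default 10 bp, mean Q < 20 truncates; < 40 bp after trimming discards).
- Barcode matching is exact by default; tolerance 1 requires a unique
  decode and the built-in barcode set has pairwise Hamming distance ≥ 3.
- Fisher two-sided p is the sum of table probabilities ≤ the observed one
  (with a 1 + 1e-12 tolerance for floating ties), matching hypergeometric
  enumeration exactly on all tables with N ≤ 40.
- UPGMA uses scipy's average linkage on Euclidean distances; merge
  heights are the tested artifact (heatmap rendering is out of scope).
- The size-selection bounds are inclusive; ~approximate lab size windows
  are modelled as a fixed, testable convention.
- The global-null calibration run uses baseline methylation 0 and no
  planted DML; with bimodal baselines the null holds at any baseline, but
  a methylation-free genome maximizes locus count for the rate estimate.

## Known limitations

- The exact test's calibration statement is for Poisson sampling noise;
  real libraries with biological overdispersion should use
  `method="nb_exact"` with an estimated common dispersion.
- Recovery's empirical FDR counts *neighbor* loci reshaped by a planted
  cut (a blocked site merges two fragments, sometimes creating a new
  selectable fragment present in one group only) as false positives, even
  though they are genuine consequences of the planted methylation; the
  measured FDR (~0.08 under default conditions) is therefore an upper
  bound on spurious statistical calls.
- Exact/one-mismatch placement assumes consensuses derive from the given
  genome; real-data users with divergent references should supply
  precomputed coordinates.
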