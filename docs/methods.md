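# Methods

`ervscan` implements an end-to-end procedure for finding polymorphic
endogenous-retrovirus (ERV/HERV-K-style) insertions in short-read
whole-genome sequencing, linking them to tagging SNPs, and testing those
tagging-SNP sets for annotation enrichment and for positional biases
relative to recombination hotspots.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## Insertion discovery from chimeric reads

A read that spans an insertion junction is *chimeric*: part of it
matches the element's LTR, the rest matches the host genome.  Detection
proceeds per individual:

1. **LTR alignment.** Every read is locally aligned to the LTR query.
   The built-in aligner uses exact k-mer seeds (k = 14) and exact
   ungapped extension: on each seeded diagonal, the maximal-scoring
   segment (match +1, mismatch −4) is found with a Kadane scan, which is
   the exact optimum for a substitution-only error model.  Gapped
   extension is deliberately omitted — the simulator emits no indels and
   the aligner is pluggable (any object with an `align(query)` method)
   for data where that assumption fails.  A vectorized pre-screen drops
   reads sharing no 12-mer with either LTR strand (sampling k-mer starts
   every 4 bases, which still guarantees a hit for any exact overlap
   ≥ 15 bp) before per-read work; its rare chance matches are rejected
   by the alignment stage, whose thresholds are a minimum aligned length
   of 20 bp and identity ≥ 0.9.
2. **Flank extraction.** Read portions extending ≥ 20 bp (default
   `min_flank_length`) past the LTR-aligned interval are extracted as
   flanks, each remembering which end abuts the LTR junction.
3. **Genome placement.** Flanks are mapped to the host genome with the
   same seed-and-extend machinery.  The junction-end base must itself be
   aligned, and multi-mapping flanks (a second locus tying the best
   score) are discarded by default.
4. **Insertion points.** The genomic coordinate of the flank base
   adjacent to the trimmed junction is the insertion point; forward and
   reverse-complement placements are tracked as separate streams.
5. **Clustering.** The streams are merged and points are grouped per
   chromosome by single-linkage chaining: consecutive sorted points
   ≤ 1,000 bp apart join one site, transitively.  The representative
   position is the median member position with ties to the lower
   coordinate.  Merging before grouping means a site's left- and
   right-junction evidence (and both strands) collapse to one locus;
   clustering is deterministic, idempotent on representatives, and a
   partition of the points.
6. **Presence/absence.** An individual carries a site if ≥ 1 of their
   chimeric reads supports it; absence is inferred from the lack of any
   supporting read.  Calls are deliberately binary — at low depth the
   carrier state is far more robust than an allele count, and absence
   can only be miscalled through coverage gaps (sensitivity loss with
   perfect specificity on clean data).
7. **Classification and filters.** Sites within ±100 bp of an annotated
   reference ERV interval are `reference`; otherwise within ±100 bp of a
   user-supplied list of previously reported non-reference insertions,
   `non_reference_known`; otherwise `unconfirmed` (in real data these
   are often SVA elements sharing LTR-derived sequence, which cannot be
   resolved computationally).  Sites overlapped (within ± the cluster
   window) by a deletion longer than 1,000 bp are flagged
   `excluded_by_deletion`: a large flanking deletion makes a
   presence/absence signal unreliable.  Prevalence is the carrier
   fraction, overall and as the unweighted mean of per-group
   prevalences.

Read quality filtering (mean Phred ≥ 20, configurable) applies when
quality strings are present; the simulator emits none.

## Tagging-SNP association (hiSNPs)

For each usable site, carrier status is regressed on every biallelic SNP
dosage with logistic models, stratified by population, adjusting for
ancestry with the first k = 6 classical-MDS coordinates.

* **MDS.** Genotypes are pruned (MAF > 0.05, greedy r² < 0.2 pruning in
  50-SNP windows stepped by 5) and randomly thinned to 10% with a seeded
  RNG, then the individual-by-individual identity-by-state distance
  (mean |gᵢ−gⱼ|/2 over shared non-missing SNPs) is double-centered and
  eigendecomposed.  Axis signs are fixed (largest-|loading| entry
  positive); numerically zero eigenvalues give zero columns.
* **Logistic fit.** Newton/IRLS to a step tolerance of 1e-10, Wald
  p-value on the dosage coefficient.  Missing dosages are dropped
  pairwise; within-population constant covariates are dropped.  A SNP in
  perfect LD with the insertion separates the outcome completely
  (carrier ⇔ dosage ≥ 1), so the MLE diverges by construction; the fit
  then falls back to Firth's bias-reduced likelihood with a penalized
  likelihood-ratio p-value (the `logistf` convention) and is flagged
  `method="firth"`.  Exclusion of separated fits was rejected because it
  would, by construction, throw away exactly the strongest (perfect-LD)
  signals the scan exists to find.  A cheap marginal separation check
  routes such SNPs directly to Firth; the dosage-free Firth fit is
  computed once per (site, population) and reused for every
  complete-data SNP.
* **hiSNP definition.** Within a 1 Mb window centered on the insertion
  (±500 kb; the window convention is recorded in the output metadata),
  the Bonferroni threshold is 0.05 / (SNPs tested in the window), and
  members are the converged records at or below it.  An empty window
  yields an undefined (NaN) threshold.  Sites fixed or absent within a
  population are skipped there; a site counts as "tagged" when it has
  hiSNPs in at least one population.
* **LD.** r² is the squared Pearson correlation of unphased dosages
  (composite LD), with pairwise missing deletion; zero variance gives
  NaN.  Tagging uses r² > 0.2.
* **Set comparison.** Directed overlap |A∩B|/|A| and Jaccard, with empty
  sets flagged NaN.

## Enrichment statistics

The 2×2 table for a query SNP set against an annotation set over an
explicit background universe is tested with a two-sided Fisher exact
test computed by full hypergeometric enumeration: the p-value is the sum
of probabilities of all tables with the observed margins whose point
probability is ≤ the observed one (relative tie tolerance 1e-9).  The
odds ratio is (a·d)/(c·b); zero cells report 0/∞/NaN with a flag rather
than a continuity correction (a corrected estimate can be layered on by
the caller).  The background universe is always explicit — there is no
implicit default, because enrichment against the wrong universe is the
canonical failure mode of this analysis.  Families of tests
(per-site × tissue matrices, generic annotation-set scans) are adjusted
with Benjamini–Hochberg FDR; significance means q < 0.05.

The GWAS-catalog step is an inner join on rsID with per-site counts of
annotated SNPs and distinct traits; malformed rsIDs are skipped with a
warning.  SNP density counts SNPs in 1 Mb / 500 kb / 100 kb windows
centered on each site by binary search and compares groups (sites with
hiSNPs vs common sites without) with an equal-variance two-sample
Student's t-test; groups smaller than 2 are flagged.

## Hotspot-distance resampling

The question is whether insertion sites sit farther from recombination
hotspots than matched random locations.  Distance is 0 inside a hotspot
interval, else the gap to the nearest contained base.  Each chromosome
is tiled into non-overlapping 2 kb segments anchored at coordinate 0;
each segment's GC percent (over non-N bases) is rounded half-up to 0.1.
A site's candidate pool is all same-chromosome segments whose rounded GC
equals the GC of the site's 2 kb flanking window; a site with no exact
match widens its tolerance in ±0.1 steps until a candidate exists, and
the tolerance used is recorded (dropping unmatched sites would silently
bias the null toward well-matched GC classes).  Each of 1,000 replicates
draws one candidate per site (with replacement across replicates) and
records the mean distance to the nearest hotspot; the empirical p-value
is (r+1)/(n+1) with r the count of null means at least as extreme, so
p ∈ [1/1001, 1] by construction.  The upper tail ("farther than
expected") is the primary output and the lower tail is reported
alongside.  Sites on chromosomes absent from a map are excluded;
contig allow-lists handle deliberate exclusions (e.g. chrY analogues).

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume and
nothing more.  Defaults are the package's standard study conditions:

| Parameter | Default | Notes |
|---|---|---|
| genome | 3 chromosomes, 5 Mb total | piecewise-constant GC landscape, 50 kb blocks, GC ~ N(0.41, 0.07) clipped to [0.2, 0.7] |
| LTR | 968 bp random sequence | the length of the youngest intact HERV-K LTR |
| insertions | 20, haplotype frequency U(0.1, 0.9) | ≥ 10 kb apart, ≥ 20 kb from chromosome ends |
| reference ERVs | 3 copies written into the reference | exercise the `reference` classification |
| cohort | 50 diploid individuals, 1 population | multi-population configs used where stratification itself is under test |
| SNPs | 2,000; founder-block LD (30 founders, 50 kb blocks), Balding–Nichols Fst 0.05 across populations | |
| tag SNPs | nearest SNP per insertion, target r² = 1 | correlated-Bernoulli construction at the haplotype level |
| reads | single-end 100 bp, depth 10×, error rate 0 | substitution errors only when enabled |
| hotspot maps | 40 (coarse) and 120 (dense) intervals of 1.5 kb | |
| annotations | 4 tissues at 10% base eQTL rate; one planted 5× (site, tissue) pair | |
| SV deletions | planted 1,500 bp and 800 bp spanning the first two sites | bracket the 1,000 bp exclusion threshold |

The insertion allele and its tag SNP are drawn per haplotype (a
correlated-Bernoulli pair hitting the target r² exactly in expectation),
not through founder copying: founder-level sampling would inflate the
variance of the realized frequency and r² beyond what binomial
confidence intervals assume, and the generator verifies the realized r²
by recomputation.  An unattainable r² for the given frequencies raises
an error naming the feasible bound.  Background SNPs do use founder
copying, so LD pruning has real structure to remove.

All randomness flows from one seed through named `SeedSequence` child
streams (genome, loci, haplotypes, reads, annotations; one child per
individual for reads), so any artifact regenerates identically and
independently of which others are produced.

What the synthetic data do **not** model: indels and structural
complexity at junctions (target-site duplications, truncated or solo
LTR variants), paired-end information, coverage biases, genotyping
error in the SNP panel, coalescent genealogies, and realistic
recombination-map or GC structure.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under their stated
assumptions, not detection performance on real sequencing data.

## Problem sizes used in tests

The standard fixture (5 Mb, 50 individuals, 10×, ≈ 25 M reads) runs the
full pipeline in about 3 minutes on one core; the test suite runs it
twice to check byte-level reproducibility.  Presence-call concordance is
measured on 1 Mb cohorts (25 individuals at 30×, 40 at 4×), association
properties on a read-free cohort of 500 individuals with 2,000 SNPs, and
resampling calibration on 200 meta-replicates of 1,000 resampling
replicates each.  These sizes are the package's chosen evaluation
conditions and are reported alongside each measured quantity by
`scripts/acceptance.py`.

## Numerical conventions

* Coordinates are 0-based half-open internally; 1-based only at the VCF
  boundary (SV deletions follow the padding-base convention: deleted
  bases are [POS, END) in 0-based terms).
* GC rounding is half-up (`floor(10x + 0.5)/10`), so 50.05 → 50.1.
* Alignment tie-breaks are deterministic: leftmost maximal segment on a
  diagonal, then lexicographic (chromosome, position, strand) across
  candidates; multi-mapping means a second locus ties the best score.
* Bernoulli/binomial draws, thinning, permutations and resampling all
  use `numpy.random.Generator` seeded from run parameters; output files
  avoid iterating over Python sets so byte-identity survives hash
  randomization.

## Known limitations

* The built-in aligner is exact and ungapped; real reads with indels or
  heavy error need an external aligner behind the `Aligner` protocol.
* Binary presence calls discard heterozygote/homozygote information by
  design; allele-count genotyping is out of scope.
* The Firth penalized-LRT p-value is computed per SNP against a shared
  dosage-free penalized fit; with missing genotypes the reduced model is
  refit per SNP, which is slower but exact.
* Enrichment treats annotation sets as flat SNP sets; ontology
  up-propagation is not implemented.
* The hotspot null assumes non-overlapping hotspot intervals per map
  (both simulated maps satisfy this; overlapping real maps should be
  merged first).
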