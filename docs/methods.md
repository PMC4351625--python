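# Methods

## Scope and data model

The pipeline operates on per-cytosine methylation count tables
(Bismark-style cytosine reports: chromosome, 1-based position, strand,
methylated count, unmethylated count, context, trinucleotide).  All
internal coordinates are 1-based inclusive; BED input/output converts at
the boundary.  The two strands of a CG dyad are never merged: every
(chrom, pos, strand) is an independent position, which is the literal
per-position reading of the test and keeps the counts exactly as the
aligner reported them.  Alignment and methylation extraction are
upstream and out of scope.

"Sample" means a single plant: pairwise comparisons contrast two
individual methylomes with no replicate pooling, and group-wise analyses
treat each sample as one observation.

## Pairwise DMP calling

A position is *eligible* when covered by ≥4 reads in both samples and by
≥2 methylated reads in at least one; everything else is reported as
`untested`.  Eligible positions are tested with the two-sided Fisher
exact test (point-probability rule, tie tolerance 1 + 1e-7, matching the
conventional implementation; no mid-p variant).  The bulk path
enumerates the hypergeometric support of each *unique* count table with
a log-factorial table — read-depth distributions repeat tables heavily
at genome scale — and agrees with the scalar routine to ~1e-12 relative
error (verified exhaustively for all tables with margins ≤30).

Multiple testing follows Storey–Tibshirani.  π̂₀(λ) = #{p>λ}/(m(1−λ)) is
smoothed with a cubic polynomial over λ ∈ {0, 0.05, …, 0.90} and read
off at λ = 0.90, clipped to (0, 1]; with m < 100, or when the fit is
degenerate (non-finite or ≤0), π̂₀ falls back to 1, which reduces the
q-values to the classic step-up adjustment.  Policies per context:

* **CG**: q-values over all eligible CG positions; DMP iff q < 0.05.
* **CHG/CHH (two-stage)**: only positions with raw p < 0.05 enter the
  adjustment; within that subset π̂₀ is fixed at 1 (no p-values exist
  above any λ of the grid, so the smoother is undefined there — the
  fallback is forced, not incidental); DMP iff q < 0.035.  Positions
  failing the prefilter are NDMPs.

Both thresholds, the prefilter, and a genome-wide (single-stage)
alternative for the non-CG contexts are exposed as parameters.

*Known property of the two-stage rule.*  On pure nulls the rule is very
conservative (the prefiltered subset is nearly empty and step-up within
it rarely rejects).  When true positives dominate the subset, however,
step-up rejects essentially the whole subset, so the realized false
discovery proportion can exceed the nominal 0.035 — in the default
synthetic study the CHH empirical FDR is ~0.18 while the CG policy sits
at ~0.02.  This is a faithful implementation of the stated two-stage
procedure, and the caveat is the reason the single-stage alternative
exists behind a flag.

Direction is reported relative to the declared reference: `hyper` means
the test sample's methylation proportion exceeds the reference's.  Every
position is exactly one of DMP / NDMP / untested.

## Feature annotation and profiles

DMPs are assigned to the containing feature — ties resolved by priority
TE-gene > transposon > gene, then by the smaller interval — or, outside
all features, to the nearest one by edge distance.  Offsets to the
feature's start and end are strand-oriented (upstream negative);
unstranded features are treated as plus-strand.

Boundary metaprofiles count DMPs in 100-bp bins spanning −2 to +2 kb
around feature starts and ends (offset 0, the boundary base, opens the
first interior bin).  Interior bins are corrected for feature length:
the raw count of a bin whose offsets require feature length ≥ L is
divided by the proportion of annotated features of that kind with
length ≥ L (a flag switches the denominator to DMP-bearing features);
external bins are uncorrected.  All length-adjusted values produced in
one call are then scaled by their joint maximum, so profiles are
comparable across samples, contexts and feature kinds and the global
peak is exactly 1.  The feature-based denominator was chosen because it
is deterministic given the annotation and matches the correction's
purpose — short features cannot host deep interior bins.

Chromosomal density tracks count DMPs and NDMPs in non-overlapping
windows (default 100 kb on the toy genome); each track is normalized by
its genome-wide maximum window count so all chromosomes of a comparison
share one scale.  TE-gene enrichment among DMR-associated transposons
is a two-sided Fisher test on the 2×2 table (DMR-associated vs not) ×
(contains TE gene vs not), with the odds ratio ad/bc (∞ permitted).

## Group-wise DMRs and tiling windows

The region caller is deliberately transparent rather than model-based
(no smoothing, no beta regression): candidate regions are maximal runs
of same-context sites that have coverage ≥4 in ≥75% of samples, with
consecutive sites ≤100 bp apart and ≥5 sites per run.  Each candidate is
tested by a two-sided Fisher exact test on the group-pooled
(methylated, unmethylated) totals; p-values are step-up adjusted across
candidates (π̂₀ = 1); significance additionally requires an absolute
difference of group mean levels ≥0.1 (group mean = mean of per-sample
pooled levels).  All candidates are emitted with a status flag.  Because
the procedure differs from smoothed beta-regression callers, region
counts from published studies are not comparable — the caller is
validated against planted truth instead.

Recovery against planted truth is measured at base level: a planted
region's Jaccard index is computed against the union of significant
calls overlapping it (same chromosome and context).  At realistic site
densities a run-based candidate definition occasionally splits one true
region at a chance ≥100-bp coverage gap into adjacent significant
fragments; the union metric scores boundary noise as boundary noise
rather than as a missed region.  The false-call rate remains per call:
the fraction of significant calls overlapping no planted region.

Tiling windows partition each chromosome into consecutive 340-bp windows
from position 1; a site is "covered" when its coverage is ≥1 (configurable)
in every sample, and windows with ≥20 covered sites emit per-sample
pooled levels.  This annotation-free representation feeds the same
multivariate analysis as the DMRs.

## Multivariate discrimination

Samples are represented as vectors of pooled methylation levels over the
selected regions; regions with zero coverage in any sample are dropped.
PCA centres columns without variance scaling (all variables already
share the [0,1] methylation scale; scaling is available by flag) and
retains the first four components.  Discriminant functions solve the
generalized eigenproblem of between- versus within-group scatter; the
within-scatter receives a ridge of 1e-6 · tr(E)/p when singular, which
is unavoidable at n ≈ p.  Two functions are reported (at most
min(groups−1, dims)), with loadings both in PC space and back-projected
to region space.  PCA and LDA axes carry a fixed sign convention
(largest-magnitude loading positive) so reports are identical across
runs and platforms.

Ward's minimum-variance agglomeration under squared Euclidean distance
clusters the LD coordinates; cutting the tree at k (default: the number
of declared groups) yields the sample partition.  Pillai's trace
V = tr(H(H+E)⁻¹) quantifies centroid separation, with the standard F
approximation for its p-value; V is bounded by min(groups−1, dims), and
a bound-saturating value simply means the planted group differences
dwarf the within-group noise.

Cross-validation is repeated stratified k-fold with k = min(folds,
smallest class size, n); with three samples per group this caps 10-fold
at 3-fold, and k = n would be leave-one-out — the faithful small-n
reading of "10-fold".  PCA and the classifier are refit inside every
training fold; the LDA classifier assigns test samples to the nearest
group centroid in discriminant space, and the corroborating SVM uses a
linear kernel with unit cost (one-vs-one for >2 groups).  Stratification
operates on whatever labels are supplied, so permutation nulls keep
class-balanced folds and score at chance level (1/#groups) without the
anti-learning bias unbalanced folds would induce.

## Synthetic methylome generator

The generator emulates the structure the analyses presume, not sequence:

* **Genome**: 2 chromosomes × 1 Mb, centromere at the midpoint,
  pericentromere ±150 kb.  200 genes (1–4 kb) on the arms; 150
  transposons (0.8–3 kb), 80% placed pericentromerically, 60% flagged as
  containing a TE gene.  Features are placed by rejection sampling with
  ≥600 bp spacing — enough, at the configured site densities, that
  candidate runs rarely bridge adjacent features.
* **Sites**: per-context, per-class Bernoulli placement; transposons are
  the densest compartment in the non-CG contexts (e.g. CHG 0.06/bp in
  transposons vs 0.003/bp intergenic), genes the densest in CG
  (0.06/bp).  The defaults yield ~120k sites.
* **Counts**: coverage ~ negative binomial with mean 30 and dispersion 5
  (the real studies' ≥50x would only add power; 30 keeps experiments
  fast and is configurable), methylated counts ~ Binomial(coverage,
  level), one draw per site and sample.
* **Baselines** (level by class × context): genes CG 0.20 / CHG 0.05 /
  CHH 0.03; transposons 0.85 / 0.60 / 0.15; intergenic 0.05 everywhere —
  the qualitative shape of a crucifer methylome.
* **Group profiles** (defaults; 3 samples each): *wildtype* — baseline.
  *mutant* — CHG +0.35 and CHH +0.40 at 10% of pericentromeric
  transposon sites, plus 15 whole-transposon CHG regions (+0.35).
  *epi* — CG +0.60 at 10% of genic sites, CG −0.60 and CHH +0.40 at 10%
  of transposon sites, plus 15 whole-gene CG regions (+0.50) and 10
  whole-transposon CG regions (−0.50).  Transposon effects prefer
  TE-gene-containing elements (selection weight 4:1), reproducing the
  enrichment of differential methylation at TE genes.  Effect sizes were
  chosen once so that no planted level clips the [0.01, 0.99] bounds
  (published studies do not quantify their real effect sizes; these are
  power-curve placeholders, not biological estimates).

Every planted site and region is recorded as ground truth, along with
the pre-noise per-group level of every site, so closure (planted level
difference = delta before sampling noise) is testable.  Identical
configuration and seed reproduce the matrix and truth bit for bit; all
randomness flows through one seed sequence.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level artefacts (bisulfite
non-conversion, mapping bias, strand asymmetries), spatial correlation
of methylation beyond the planted regions, biological replicate
variance, chromosome-scale methylation gradients, and repeat-family
structure.  Results on real methylomes additionally depend on upstream
alignment quality, which is out of scope here.

## Experiment sizes and numerical choices

The bundled experiments are sized for a laptop-class single CPU: the
null calibration uses a ~50k-site genome over 10–20 seeds; power
experiments use the full default genome over a few fixed seeds; repeated
cross-validation uses 50–100 repeats rather than 1,000 (the repeat count
only narrows the spread of an already-converged mean).  The exhaustive
Fisher validation covers every 2×2 table with margins ≤30.

Numerical details: q-values are clipped to [0, 1] and are monotone in p
by construction; Fisher tie comparison uses a 1 + 1e-7 relative factor;
the pooled-level of a zero-coverage sample-region is undefined and the
region is dropped from feature matrices; Ward merge order is
deterministic with index-order tie-breaking; eligible-but-empty
candidate sets simply produce empty result tables rather than errors.
An optional user-supplied exclusion list (BED) can remove regions such
as low-complexity or multi-mapping territory before testing; no attempt
is made to detect such regions computationally.
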