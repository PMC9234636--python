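# Methods

## The audit model

The package treats an ex situ conservation audit as four linked
measurements on one dataset.

**Reference catalog.**  The unit of genetic conservation is the allele, not
heterozygosity: alleles are what selection can act on, and a collection
either holds a wild allele or it does not.  All wild diploid individuals are
pooled; for each locus the copies of each allele are counted over non-missing
calls, and the pooled frequency divides by that locus's non-missing gene-copy
count (so loci with different missingness keep proper denominators).  Calls
are unordered pairs — microsatellites are unphased — and are stored as
multisets throughout.

Frequency classes are assigned half-open from below: rare [0, 0.01), low
frequency [0.01, 0.05), common [0.05, 0.10), very common [0.10, 1].  The
published interval conventions for such bins overlap at the 5% and 10%
boundaries; assigning the boundary to the upper class is applied uniformly
and matters only for alleles sitting exactly on a boundary.

The *reduced* view drops alleles present in ≤ 2 copies in the reference
cohort.  Class labels and frequencies are *not* recomputed after the drop:
the reduced view answers "of the alleles we believe are real and worth
conserving, how many are held?", and keeping full-data labels makes the
class structure comparable between views.  For regional audits the reference
is the region's own wild pool — copy counts, frequencies, classes, and the
≤ 2-copy drop all derive from that pool, since the question is "what fraction
of *this region's* alleles is captured by seedlings sourced *from it*".

**Capture.**  A reference allele is captured if it appears at least once
among the target cohort's non-missing calls.  Alleles found ex situ but
absent from the reference are ignored; the wild catalog fixes the
denominator.  The East-vs-West contrast builds the 2×2 table
[[captured, not captured]] per region from the "all" class and applies
Pearson's chi-square with Yates continuity correction (the default of the
statistical environment such analyses are typically run in); an uncorrected
variant is exposed via `correction=False`.  The table is over alleles, which
are not strictly independent draws (they share loci and individuals), so the
p-value is indicative rather than exact — the same caveat applies to any
published use of this test on allele counts.

**Sampling simulation.**  The collector model is uniform sampling of n of N
wild plants without replacement, one seed per plant, each sampled plant
contributing both allele copies (missing calls contribute nothing, but the
plant still spends one unit of sampling effort).  The implementation draws
one random permutation per replicate and scores the cumulative union of
carried alleles along it: the size-n prefix of a uniform permutation is
exactly a uniform n-subset, so one pass scores every n, each replicate's
curve is non-decreasing by construction, and the per-n marginal distribution
(hence mean and variance) is identical to independent per-n draws.  Only the
correlation *between* n values within a replicate differs, which no reported
statistic uses.

The exact expectation is available in closed form: an allele carried by m of
N plants is missed by an n-sample with probability C(N−m, n)/C(N, n).  The
closed form is the test oracle for the Monte-Carlo path; the Monte-Carlo
path exists because real audits ask for per-replicate quantiles and
class-conditional curves where enumerations get awkward.

The minimum sample size is the smallest n whose replicate-mean capture is
≥ the threshold (ties at exactly 95.0 count as reached).  Replicates default
to 75,000, the scale used for published minimum-sample-size estimates; the
bundled acceptance script runs curves at R = 2,000, where the Monte-Carlo
standard error of the mean at any n is well under 0.5 percentage points for
study-scale catalogs, and reported n_min values are stable to ±2.

**Garden structure.**  Weir & Cockerham's (1984) θ is computed per allele
per locus from the standard a, b, c variance components and combined as a
ratio of sums over all alleles and loci.  Negative single-locus components
are retained (no truncation): that is the canonical estimator and keeps θ
unbiased around zero for undifferentiated cohorts, at the cost of allowing
slightly negative estimates.  Monomorphic loci contribute zeros to both sums
and drop out naturally.  The estimator variant is fixed; the paired t-test
across gardens on the θ-vs-East and θ-vs-West vectors is two-sided.  The
capture-vs-size regressions are unweighted OLS on identity, √x, and log x
transforms of the predictor, with adjusted R² = 1 − (1−R²)(n−1)/(n−2);
the highest adjusted R² flags the best transform per allele class.

**Ecogeography.**  Points are projected with a spherical Albers equal-area
conic on the authalic radius (6371.0072 km), standard parallels set by the
1/6 rule on the data's latitude span.  Buffers are planar circles
(quad_segs = 64, polygon-vs-disc area error < 0.01%) dissolved with a
unary union; areas are in km².  Equal-area projection is the right choice
for a ratio of areas; the residual error is scale distortion of *distance*
away from the standard parallels, which for a range spanning ~10° of
latitude keeps buffer-area error well under 1%.  Ecoregion "overlap" means
any nonzero-area intersection — no minimum-overlap threshold — and the
conserved set is by construction a subset of the total set.  Duplicate
coordinates are deduplicated before buffering and zero-width-buffer repair
is applied before set operations.

## Clone filtering

Individuals with identical complete multilocus genotypes within one
population are collapsed to the first-encountered representative.  Matching
is strict: any missing call disqualifies an individual from clone matching
entirely.  This is conservative — a true clone pair with one dropout is
kept as two plants — but never merges non-clones, and downstream statistics
are barely sensitive to the handful of borderline cases.  The
within-population scope reflects that clonal spread in shrubs is local; a
dataset-wide scope would also merge identical-by-chance genotypes across
distant populations, which at 11 polymorphic loci is unlikely but not
impossible.

## The synthetic-data generator

The generator emulates the structure of a range-wide two-region study:

- **Wild cohort** — 667 diploids in 36 populations (19 × 19 + 17 × 18),
  11 loci.  Ancestral per-locus frequencies are Dirichlet(0.5) over 30
  candidate alleles; each region drifts from the ancestor and each
  population from its region by Dirichlet draws with concentration 1/d
  (E[F_ST] ≈ d/(1+d)); defaults d_region = 0.05, d_population = 0.03.
  These values give a realized wild catalog of ~240 alleles with a
  substantial rare tail and between-region θ near 0.04, the magnitudes a
  range-wide microsatellite study of an outcrossing shrub typically
  reports.  Missing calls are injected at 2.6%; 15 extra alleles are
  planted as exact single copies so the singleton/doubleton boundary of the
  reduced view is exercised deterministically.
- **Gardens** — 8 gardens holding 66 half-sib maternal families from 26
  source populations (~294 seedlings), East-weighted (48 East families of 5
  seeds, 18 West families of 3) with an order-of-magnitude spread in garden
  sizes, as real metacollections show.  Each seed takes one maternal allele
  uniformly and a paternal allele from the source population's pooled
  frequencies; loci where the mother's call is missing are missing in the
  seed.  A germination rate thins families binomially.
- **Landscape** — one locality per population in two disjoint clusters plus
  scattered extra wild records; source localities snapped to sampled
  populations; a rectangular Level-III grid with Level-IV subdivisions.

All randomness flows from a single seed through named substreams, so each
stage is reproducible in isolation.  What the generator does *not* emulate:
isolation-by-distance within regions (populations are exchangeable within a
region), linkage, null alleles and allele-size homoplasy, non-random mother
selection, genuine ecoregion geometry, and occurrence-record noise.
Passing tests therefore demonstrate correctness of the accounting and
estimators under the stated sampling models, not robustness to those
real-data pathologies.

## Numerical and testing choices

- Missing calls use allele code 0; allele codes are strictly positive.
- GENEPOP 2- vs 3-digit encoding is auto-detected per file and mixed
  encodings rejected; individual IDs must be globally unique because the
  metadata join is keyed on them.
- The curve's per-n Monte-Carlo SE is estimated from the across-replicate
  standard deviation.  When every replicate captures everything the sample
  SE is zero while the true expectation may sit just under 100%; tests
  therefore allow an additional 100·(3/R) percentage points, the
  three-sigma bound consistent with a zero count in R Bernoulli trials.
- Paired t on identical θ vectors is reported as t = 0, p = 1 (zero
  difference with zero variance carries no evidence); zero-variance nonzero
  differences propagate scipy's infinite t.
- Test and acceptance problem sizes: curve-vs-oracle checks run a
  60-individual cohort at R = 10,000 plus five 20-individual cohorts at
  R = 3,000; divergence recovery uses 5 levels × 20 replicates of a
  90-per-region cohort; the acceptance script runs the full 667-plant
  preset with R = 2,000 curves.  These sizes put Monte-Carlo noise an order
  of magnitude below every asserted tolerance.

## Limitations

- Reproduction of the published study's numbers requires its deposited
  genotype and occurrence files; the corresponding end-to-end test runs
  only when a user supplies them under `data/deposited/` (they are
  third-party research data and not bundled).
- The chi-square on allele counts inherits the non-independence caveat
  above.
- θ is estimated for cohort pairs only (r = 2); hierarchical F-statistics
  are out of scope.
- Buffering is planar post-projection; for ranges spanning continents the
  fixed standard parallels would need revisiting.
- The multi-taxon log-regression reference takes the comparison taxa's
  (collection size, percent conserved) points as user input; it does not
  re-derive them from their genotypes.
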