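# Methods

`imgtx` implements a transcriptome–neuroimaging association workflow: it
builds a parcellated region × gene expression matrix from donor-level
microarray data, relates it to a cortical case–control effect-size map
with partial least squares, assesses significance against spatially
constrained nulls, and runs downstream enrichment and network analyses.
This note records the models, the parameters that matter, the numerical
conventions, and what the synthetic experiments do and do not show.

## Expression assembly

Input is one table set per donor: sample coordinates (mm), a samples ×
probes intensity matrix, a boolean above-background matrix, a probe →
gene annotation, and optionally a genes × samples RNA-seq reference.
Processing follows the standard multi-donor microarray workflow:

1. **Probe noise filter.** Samples are pooled across donors; a probe is
   removed iff it is below background intensity in strictly more than
   half of the pooled samples (retained at exactly one half). Pooling
   rather than per-donor filtering matches common practice and keeps
   the retained probe set identical across donors.
2. **Probe selection.** For each gene with several surviving probes, the
   probe with the highest Spearman correlation against the RNA-seq
   reference (pooled over the donors that carry one) is kept; exact ties
   go to the lexicographically smallest probe id. Without any reference,
   an explicit fallback flag selects the probe with the highest mean
   intensity instead — the default refuses to guess.
3. **Sample assignment.** Each sample maps to its nearest parcel
   centroid (Euclidean, in the raw mm coordinates, not the unit-sphere
   projection used for spins) iff that distance is ≤ 2 mm; ties go to
   the lowest parcel index; everything else is unassigned.
4. **Scaled robust sigmoid (SRS).** Per gene, within donor, across that
   donor's assigned samples: `y = 1 / (1 + exp(−(x − median) /
   (IQR/1.35)))`, then min–max rescaled to [0, 1]. The IQR/1.35 factor
   makes the scale comparable to a standard deviation under normality;
   the transform is invariant to positive affine changes of the input.
   A zero IQR maps the gene to a constant 0.5 with a warning.
5. **Aggregation.** SRS values are averaged within parcels per donor,
   then averaged across the donors covering each parcel. Parcels with no
   coverage are flagged (`n_donors_per_region = 0`) and excluded from
   all downstream regression, with the exclusion recorded in the run
   manifest. Averaging donor matrices (rather than concatenating samples
   before parcel averaging) keeps each donor's weight equal regardless
   of its sampling density; the alternative would up-weight densely
   sampled donors.
6. **Differential stability (DS).** DS(g) is the mean over donor pairs
   of the Spearman correlation of gene g's regional profile across the
   parcels both donors cover (Pearson available behind a flag; the DS
   literature uses rank correlation). The top 50 % of genes by DS are
   retained by default, with ties at the cutoff all kept and logged;
   0.4/0.6 are the conventional sensitivity settings and retained sets
   are nested by construction.

## PLS1 association

Predictor columns (genes) and the response map (Cohen's d per parcel)
are z-scored. With one response, the first PLS weight vector has the
closed form **w = Xᵀy / ‖Xᵀy‖**; region scores are Xw. We use this
closed form rather than an iterative NIPALS solver — for a single
component and single response they coincide, and the closed form is
exactly testable (the test suite also cross-checks against the NIPALS
implementation in scikit-learn). The component is oriented so scores
correlate positively with the response; weights and scores flip
together, so the convention is inference-neutral.

*Variance explained* is reported as the squared score–map correlation
(the share of response variance the component captures); the
predictor-side share is also computed and written to the manifest, since
"variance explained" is ambiguous between the two in common usage.

**Spin significance.** The score–map correlation is compared against
refits on spin-rotated responses (below), one-sided on r (non-negative
by convention), with the add-one permutation estimator
`(1 + #{r_null ≥ r_obs}) / (1 + n_perm)`.

**Bootstrap gene inference.** Regions are resampled with replacement;
each replicate is re-z-scored and refitted; replicate weight vectors are
sign-aligned to the point estimate (without alignment the SE of every
gene is corrupted by global sign flips). z = weight / bootstrap SE, with
two-sided normal p-values, BH-FDR across genes, and a split of the
significant genes by sign of z into PLS1+ and PLS1− lists sorted by
|z|. A replicate with a degenerate response (zero variance or Xᵀy = 0)
is redrawn up to 10 times. The bootstrap treats regions as exchangeable;
under strong spatial autocorrelation this understates standard errors —
see *Limitations*.

Two cohorts are combined by sign-wise intersection of their significant
lists (PLS1+ ∩ PLS1+, PLS1− ∩ PLS1−), never by meta-analysis.

## Spin permutation nulls

Parcellated cortical maps are spatially autocorrelated, so unconstrained
permutation tests of map–map association are anti-conservative. The spin
test draws a Haar-uniform proper rotation (QR of a Gaussian 3×3 with
sign correction, det = +1), applies it to the left-hemisphere unit-norm
centroids and its mirror conjugate diag(−1,1,1)·R·diag(−1,1,1) to the
right hemisphere, and rebuilds a surrogate map from the rotated
geometry. Hemispheres never mix.

Original parcels are matched to rotated parcels by **greedy
nearest-neighbour assignment without replacement**: (original, rotated)
pairs are claimed in order of increasing centroid distance, ties going
to the lowest index pair. This makes every surrogate an exact
permutation of the original values (the value multiset is preserved and
the identity rotation yields the identity map). Plain nearest-centroid
lookup with duplication — an apparent simplification — was measured to
produce a bijection in 0 of 200 random rotations on 50–180-point
lattices, which silently changes the surrogate value distribution; it is
therefore not used. Optimal-transport (Hungarian) matching was also
evaluated and gave statistically indistinguishable test calibration, so
the cheaper greedy rule is kept.

Map–map correlation p-values are two-sided on |r| by default (a
one-sided flag exists); map A is the permuted one by convention. Parcels
without expression coverage are excluded pairwise from the observed and
every null correlation.

## Enrichment statistics

All tests are computed against an explicit gene universe — by default
the DS-retained analysis set — and BH correction is applied within each
analysis family (one GMT collection, one condition panel), never across
families.

* **Over-representation:** one-sided hypergeometric upper tail, the
  convention of functional-annotation tools.
* **Marker and disease tests:** two-sided Fisher exact, so depletion is
  visible; odds ratio `ad/bc` with ∞ when `bc = 0, ad > 0`.
* **Specificity (pSI):** for gene g and condition c the observed
  statistic is the mean, over the other conditions c′, of the
  competition rank (1 + number strictly greater, among all genes) of the
  fold change expr(g,c)/expr(g,c′), with a 1e-9 pseudo-count for zeros.
  The null applies one shared permutation of the condition labels to the
  whole matrix and pools the resulting statistics across genes; pSI is
  the add-one-corrected fraction of pooled null statistics at or below
  the observed value. Two properties motivated this construction: the
  permutation space (K! relabelings) is small enough to enumerate
  exhaustively, giving an exact oracle for the Monte-Carlo estimator,
  and pooling across genes gives the p-value a resolution of
  1/(n_perm·n_genes), so thresholds like pSI < 0.05 are attainable with
  as few as 4 conditions (a per-gene K! null cannot go below ≈ 1/K!).
  This is a reimplementation of the specificity-index idea, not a
  byte-match of any published tool. Because the add-one estimator can
  equal exactly 1, "every gene specific" requires a threshold strictly
  above 1, not 1.0.

## PPI hubs

Edges below the confidence threshold (default 0.4) and self-loops are
dropped; duplicate undirected edges collapse keeping the highest score.
MCC(v) = Σ (|C| − 1)! over maximal cliques C ∋ v with |C| ≥ 2, via
Bron–Kerbosch enumeration; a degree-1 node scores 1 (its edge is its
maximal clique) and isolated nodes score 0 (flag-switchable to 1, since
the singleton convention differs between tools). A configurable size
guard (default 5000 nodes) protects against the exponential worst case.

## Synthetic data model

The generator produces every input the pipeline consumes, from seeds
only (byte-identical reruns):

* **Geometry:** a Fibonacci lattice on a half-sphere of radius 80 mm per
  hemisphere, mirrored through the midline plane; 180 parcels per
  hemisphere at full scale.
* **Expression:** each gene's regional ground truth is an independent
  draw from a Gaussian process on the unit sphere with covariance
  exp(−θ²/2ℓ²) in great-circle angle; ℓ defaults to 0.3 rad, enough to
  make naive permutation tests visibly anti-conservative while leaving
  ~20 effective independent patches on a 100-parcel sphere. Donors
  (default 6, the usual post-mortem atlas size) get samples jittered
  < 2 mm around centroids plus a configurable off-parcel fraction at
  3–6 mm to exercise the rejection rule; probe intensities are affine
  transforms of truth plus Gaussian noise, with probe 0 designated best
  (half the noise of the others), a fraction of non-best probes failing
  the background filter by construction, and an RNA-seq reference
  (first 2 donors) tightly correlated with the best probe. Gene–gene
  correlation beyond the shared smoothness model is deliberately not
  simulated.
* **Effect maps:** y = z(X)·w + ε with w sparse (±weight_scale on
  `n_planted` genes, random signs) and ε i.i.d. Gaussian; the noise SD
  can be solved from a target generative R². A second cohort reuses the
  planted w with fresh noise.
* **Gene sets / PPI:** one GMT set enriched from the planted list among
  uniform decoys; an Erdős–Rényi background plus planted cliques whose
  edges sit above the confidence threshold.

What passing synthetic tests shows: the estimators compute what they
claim (closed forms, brute-force agreement), the spin null preserves
value multisets and hemisphere structure, planted structure is recovered
when power permits, and the pipeline is deterministic. What it does not
show: behavior under real transcriptome covariance (co-expression
modules), inter-donor batch structure beyond noise, registration error,
or non-spherical geometry.

## Validation experiments and their observed limits

`imgtx.validation` packages the quantitative experiments the tests and
`scripts/acceptance.py` run. Two deserve honest caveats:

* **Planted-gene recovery at desk scale.** With 200 regions, 1000 genes,
  30 equal-weight planted genes and generative R² ≈ 0.5, each planted
  gene's marginal correlation with the response is √(R²/30) ≈ 0.13, so
  its bootstrap z sits near 2 — below any BH threshold at m = 1000 —
  while the spatial smoothness of the maps inflates the z of null genes
  (the i.i.d. bootstrap understates SEs under autocorrelation). Measured
  sensitivity ≈ 0.5 and false-discovery proportion ≈ 0.9 at that scale;
  the identical generative model at 4000 regions yields sensitivity 1.0
  and FDP ≈ 0.1, confirming a power limit rather than an estimator
  defect. Cross-cohort intersection inherits this (its sensitivity is
  roughly the square of the per-cohort one). The practical reading: at
  atlas-scale n, single-gene bootstrap inference is only powered for
  genes whose signal is concentrated, or for co-expressed modules whose
  correlations compound — which is precisely the regime of real
  transcriptomes and is outside the generator's scope.
* **Spin-test calibration.** On strongly smooth null map pairs the
  rotation test's empirical type-I error at α = 0.05 is ≈ 0.08 (pooled
  over ~1500 replicates): mildly anti-conservative, consistent with
  published evaluations of this null-model family, and far below the
  naive shuffle's ≈ 0.19. Individual 200-replicate estimates scatter by
  ±0.02 around that value.

## Numerical conventions

z-scoring uses population (ddof = 0) scaling; bootstrap SEs use ddof = 1
across replicates. Constant gene columns are detected by zero range (not
a floating-point sd == 0 test) and dropped with a warning before PLS.
The GP sampler factorizes covariances by eigendecomposition with
negative-eigenvalue clipping, since long length scales are numerically
rank-deficient. All permutation p-values use the add-one estimator, so
the attainable minimum is 1/(n+1). All tie-breaks (probe ids, parcel
indices, matching pairs, ranking) are deterministic and documented at
the operation. File formats are UTF-8 TSV with header rows, GMT for
gene sets, JSON for manifests; every writer/reader pair round-trips.

The analysis drivers under `analysis/` run the whole story at a reduced
scale (60 parcels, 120 genes, 6 donors) chosen so the full chain
completes in seconds while leaving every stage's behavior visible; the
validation experiments use the reference sizes stated above.
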