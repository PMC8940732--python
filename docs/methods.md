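# Methods

This note documents the models, conventions and numerical choices behind
`morphosim`, and what the synthetic-data experiments do and do not show.

## Morphometric similarity

Each subject contributes a region × feature table (68 Desikan–Killiany
cortical regions × 5 structural features). Features are z-scored with the
sample SD (n−1 denominator) before correlation; two scopes are offered
because "normalized for sample mean and standard deviation" is ambiguous
at the dataset level:

- `within_subject` (default): each feature standardized over the
  subject's own 68 regions;
- `dataset_pooled`: standardized over all regions of all subjects.

Both are valid readings; outputs record the scope used. The MS matrix is
the Pearson correlation between regions' normalized feature vectors. The
diagonal is stored as 1 but excluded from every average. A region whose
feature vector is constant has no defined correlation: its edges are NaN,
it is reported, and regional means are taken over available edges only —
nothing is imputed. Region order is validated against the shipped DK-68
manifest (left then right hemisphere); mismatching input is rejected
rather than silently reordered.

## Case–control inference

Per region, ordinary least squares of regional MS on group + age + sex +
ICV; the group coefficient's t and two-sided p are reported with
Benjamini–Hochberg FDR over the 68 regions (BH, not BY — the standard
default). Two derived quantities have no canonical formula in this
literature, so the conventions are fixed and recorded in every output:

- Cohen's d from the adjusted contrast: d = t·√(1/n₁ + 1/n₂);
- the regional "z-score" is the inverse-normal transform of the
  two-sided p carrying the sign of t (monotone in t).

The implementation is vectorised linear algebra (one pseudo-inverse for
all regions); statsmodels OLS serves as an independent oracle in the
tests. Rank-deficient designs are a hard error naming the collinear
columns. Subjects missing a region's value are dropped from that region's
model with a warning.

The cross-condition pattern is a PCA of the region × condition matrix of
z-maps with standardized columns (correlation-matrix PCA), so eigenvalues
sum to the number of conditions and explained-variance percentages to
100. This scale is forced by the convention that an eigenvalue > 1 marks
a retained component. PC1's sign is fixed so its region scores correlate
positively with the mean input map.

Hub-susceptibility quadrants use the sign of the mean control regional MS
and the sign of the case–control change (Cohen's d; any monotone choice
gives identical labels). Zero values count as positive — a measure-zero
tie-break. Significance of the hub correlation is delegated to the spin
test.

The von Economo aggregation averages regional MS within
cytoarchitectonic classes per subject and reuses the same model
machinery per class. The shipped DK-68 → class CSV is an approximate,
editable default; analyses of real data should substitute their
preferred atlas mapping.

## Expression processing

Probes below background in ≥ 50 % of samples are discarded; the boundary
is read literally (exactly half → discarded) and the pooling is across
donors by default (per-donor mode behind a flag) because the source
convention does not qualify "samples" by donor. One probe per gene is
kept by maximal differential stability — the mean over donor pairs of
the Spearman correlation between the donors' region-aggregated profiles
— with ties broken by lexicographically smallest probe id for
reproducibility. Donor pairs sharing fewer than 3 regions are skipped
with a warning.

Sample assignment is two-pass: nearest same-hemisphere, same-division
region representative point within 2 mm, then any empty region takes its
nearest compatible sample (which may serve several regions). The
"nearest region" contract accepts any per-region representative point
set; the package ships only synthetic geometries.

Normalization per donor and gene across regions: robust sigmoid
x′ = 1/(1 + exp(−(x − median)/(IQR/1.35))) — the 1.35 factor makes the
IQR-based scale consistent with an SD under normality — followed by
min–max rescaling to [0, 1], then averaging across donors. A zero-IQR
gene collapses to 0.5 with a warning. Because the center and scale are
median/IQR-based, the output is exactly invariant under positive affine
maps of the raw intensities (asserted in tests). Association analyses
use the 34 left-hemisphere regions, matching the practice forced by
donors with right-hemisphere data missing.

## PLS gene ranking

X columns (genes) and y are z-scored before fitting so weights are
comparable across genes (raw-scale mode behind a flag). The fitting
engine is scikit-learn's `PLSRegression`; two independent oracles guard
it in the tests — the analytic identity that the first X-weight vector
of a univariate-response PLS is proportional to X′y, and a hand-written
NIPALS. Variance explained in y is the incremental R² of y on the first
c x-scores; the permutation test (add-one estimator, never exactly 0)
compares cumulative R² per component count against response-permuted
refits. Components 1–15 are examined by default; only PLS1 feeds
enrichment. Bootstrap inference resamples the regions with replacement,
sign-aligns each refit weight vector to the original, uses the bootstrap
SD as the SE (a robust-spread variant was considered and rejected as
nonstandard), and maps Z = w/SE to a two-sided normal p with BH-FDR.
Degenerate resamples (constant response) are redrawn, counted, and
capped at 10 × n_boot attempts. PLS1's sign is fixed so its region
scores correlate positively with y.

## Spin test

Null maps are generated by Haar-uniform 3-D rotations (QR of a Gaussian
matrix with determinant fix) of the left-hemisphere parcel centroids on
the unit sphere, with the x-mirrored rotation applied to the right
hemisphere to preserve hemispheric symmetry. Rotated parcels are matched
to original slots one-to-one, greedily by ascending distance: unlike
independent nearest-neighbour lookup this keeps every null map a
permutation of the data (value-preserving), at the cost of occasionally
deviating from the minimal-cost matching; this is a deliberate,
documented choice. The p-value is two-tailed by default (one-tailed flag
available) with the add-one estimator, so p ∈ [1/(n+1), 1]. For
34-region left-hemisphere analyses only the left rotation is used.

No real fsaverage centroid manifest ships with the package (none is
derivable from text sources); the bundled geometry is a synthetic
Fibonacci-lattice sphere carrying DK labels, adequate for the
machinery's contract and for calibration testing, and any real centroid
CSV can be supplied instead.

## Enrichment

One-sided (greater) Fisher exact test — the null is that the odds ratio
is no larger than 1 — whose p equals the hypergeometric upper tail
(verified against exhaustive summation). The primary odds-ratio estimate
is the conditional MLE; the sample OR (ad/bc, Haldane 0.5 correction on
zero cells) is also reported because published ORs rarely state their
estimator. FDR is applied within each panel of sets tested in one call.
Empty sets or empty targets yield OR = NaN with a `degenerate` flag.

## Synthetic data: what it emulates, and what it does not

**Cohorts.** Subjects share a latent region × feature template plus
i.i.d. Gaussian feature noise (default SD 0.4 in template units — a
moderate individual-variability level chosen once). The template places
half the regions in a tight cluster around a common profile and half
diffusely around the opposite profile; this asymmetry survives feature
standardization and yields a realistic spread of baseline regional MS
(clearly positive for the coherent bulk, negative for differentiated
regions). Covariates are age ~ U(25, 65), sex ~ Bernoulli(0.5),
ICV ~ N(1.5·10⁶, 1.5·10⁵) mm³, with planted coefficients acting on all
regions identically in both groups.

There is no closed form from feature perturbations to regional-MS
shifts, so planted effects are calibrated empirically: case templates
are perturbed along each region's steepest-ascent similarity direction,
the full delta → shift response matrix is measured by probing each
region on paired noise draws, and damped Newton iterations against
freshly measured shifts drive the realised case-minus-control difference
to the requested map. Tolerance: 10 % of the requested shift or 0.001 MS
units, whichever is larger (the absolute floor covers requests at the
Monte-Carlo measurement scale); regions that cannot reach it are
warned about and the achieved shifts always live in the truth record.
Two structural limits matter: a region's MS cannot move past what the
coherence of the remaining cortex supports, and near-uniform shift
patterns are almost unattainable (the network's total similarity budget
is nearly conserved) — `plantable_effect_map` therefore draws a signed
map in a 0.005–0.014 band, caps magnitudes by each region's measured
own-slope, and projects onto the attainable response subspace.

**Expression.** Signal genes' true regional profiles are
a·z(target) + √(1−a²)·noise with alignment a ∈ [0, 1]; donors are noisy
replicates (additive Gaussian, default SD 0.5) with one sample placed at
each region's representative point, one probe per gene, all probes above
background. This exercises every pipeline stage's arithmetic but is
deliberately simpler than real atlas data: no spatial autocorrelation
within hemispheres beyond the planted gradient, no misplaced samples, no
probe-level annotation noise, uniform sampling density. Passing tests
therefore demonstrate the correctness and calibration of the
*computations*, not robustness to every artefact of real microarray
data.

**Gene sets.** The overlap between the planted set and the target list
is drawn from Fisher's noncentral hypergeometric distribution with the
planted odds ratio, so at OR = 1 a Fisher test on the output is exactly
calibrated (to the discrete test's attainable size) and at planted
OR = 5 the conditional-MLE estimate concentrates around 5.

Each generator draws from its own RNG stream derived from the root seed
(`default_rng([seed, tag, …])`), so adding one generator never perturbs
another's draws, and fixed seeds are bit-reproducible.

## Problem sizes in the test suite and acceptance script

Monte-Carlo checks run at sizes chosen for tight-enough standard errors:
type-I calibration at 500 (direct t-test path) and 120 (full covariate
path) replicates of small cohorts; PLS permutation and spin-test
uniformity at 200–250 replicates with 99–199 permutations each;
enrichment calibration at 1000 replicates; planted-gene recovery at 20
replicates of 2000 genes × 34 regions; effect-map recovery at one
200 + 200 cohort. The acceptance script uses the chronic-pain studies'
published sample sizes for the three condition cohorts (56/20, 29/33,
20/20) and the comparison cohort (19/20), 1000 permutations and
bootstraps for PLS, and 1000 spin rotations.

## Known limitations

- The cohort generator plants *mean* shifts in regional MS; it does not
  model site effects, scanner differences, or age × group interactions.
- Calibration accuracy is bounded by the Monte-Carlo measurement floor
  (~2–4·10⁻⁴ MS units) and the attainable-subspace projection; requested
  maps far outside the plantable band are honestly warned about, not
  silently rescaled.
- The von Economo manifest and spherical geometry are synthetic/
  approximate stand-ins for atlas files the user should supply for real
  analyses.
- PLS explained variance on the synthetic data is far higher than in
  real imaging-transcriptomics (the planted signal is strong and the
  gene count exceeds the region count); the permutation test, not the
  raw percentage, carries the inferential weight.
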