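# Methods

## The statistical model

Spicule element tables are compositions: each row is a vector of
atomic percentages (C, O, Ca, Mg and traces) closed to 100%. All
analysis happens in Aitchison geometry. The package's canonical scale
is percent (κ = 100); proportions are accepted and rescaled. Closure is
always explicit — tables read from CSV keep their raw row sums until
`close` is called.

Low-abundance elements (Cl, F, P) are amalgamated into a single part
`Traces` on the raw percent scale, *before* any log transform. An
amalgamated trace part can still be exactly zero (an element below the
detection limit in all three channels); zeros are then replaced
multiplicatively with δ = 0.005 percent — half the resolution at which
element tables are conventionally printed (0.01%) — shrinking the
remaining parts of the row so its sum is preserved. δ is configurable
and the pipeline logs how many cells were replaced. Multiplicative
replacement keeps all other log-ratios of the row unchanged, which is
the property that matters downstream.

### Transforms and metrics

- CLR: `ln(x_j / g(x))`; rows sum to zero; scale-invariant.
- ILR: balances from a sequential binary partition (SBP). The default
  is the pivot SBP in the table's part order; any SBP can be supplied
  as ±1/0 sign vectors. All global and pairwise test statistics are
  invariant to this choice (orthonormal bases differ by rotation), but
  per-coordinate interpretation is not, so reports print the balances
  used.
- Weighted log-ratio metric: `d_w(x,y)² = Σ_j w_j (ℓx_j − ℓy_j)²` on
  weighted-CLR coordinates `ℓx_j = ln x_j − Σ_k w_k ln x_k`, default
  weights = column mean proportions of the analyzed table. Uniform
  weights reduce this to the classic Aitchison distance divided by
  √D. Natural logs everywhere.

### Descriptive statistics

Centers are closed columnwise geometric means; the key identity
`center_i / center_j = exp(mean ln(x_i/x_j))` makes the "mean" column
of a min–mean–max pairwise ratio table equal the ratio of center
components exactly. That identity is how the geometric-mean reading of
published ratio tables is verified: the arithmetic mean of sample
ratios would systematically exceed the center ratios. The variation
matrix is `T_ij = var(ln x_i/x_j)`; the unweighted total variance
equals both `Σ_j var(clr_j)` and `(1/2D) Σ_ij T_ij`.

Variance denominator: sample variance (n − 1) by default, configurable
to n (`ddof=0`) for cross-checking against toolchains that use the
biased form; at cluster sizes of 14–45 the difference appears in the
second decimal. Log-ratio biplots use the SVD of the double-centred
(optionally weighted) log matrix with row weight 1/n, so the explained
variances sum to the `ddof=0` total variance; axis signs are fixed by
making each axis's largest-magnitude loading positive.

The pipeline reports per-cluster total variances in the *unweighted*
convention — the weighted metric is a clustering-distance choice, not a
reporting convention. Both are computable via `total_variance`.

### Clustering

Samples are embedded in weighted log-ratio coordinates and merged by
Ward's minimum-variance criterion in the Ward.D2 convention (squared
distances in the Lance–Williams update; heights are the square roots
of merge costs and are monotone on metric inputs). The agglomeration
itself is scipy's; a brute-force minimum-ESS agglomeration written
independently in the test suite confirms the merge sequences for small
n. Tie-breaking on exactly equal merge costs follows scipy's
deterministic nearest-neighbor-chain order; on continuous data ties
have probability zero, and runs are bit-reproducible given the input
order.

The number of clusters is user-supplied when reproducing a known
grouping (k = 3 for section data, k = 4 for fractures); `select_k`
offers advisory silhouette (in the clustering metric) or
Calinski–Harabasz scores over a k range and returns the full score
table rather than hiding it.

Dendrograms serialize to Newick with node heights at half the merge
height (the convention R's `as.phylo(hclust)` uses), so two leaves
merged at height h appear as `(A:h/2,B:h/2);` and leaf-to-leaf path
distances equal cophenetic distances.

### Group comparison

A one-way multivariate linear model on ILR coordinates. Global null:
Wilks' Λ with Rao's F approximation (exact for up to three groups),
or a permutation mode that recomputes Λ under label shuffles with
p = (1 + #{Λ* ≤ Λ}) / (1 + n_perm); the permutation mode refuses to run
without an explicit seed. "ANOVA on compositions" is deliberately
interpreted as this MANOVA: Λ is the standard basis-invariant global
statistic for a multivariate response. Pairwise contrasts are
Hotelling's T² with the pooled within-group covariance (residual df
n − g), F-transformed; the pooled covariance is inverted by
pseudo-inverse so degenerate inputs (identical groups) give T² = 0,
p = 1 rather than an error. Holm adjustment by default (Bonferroni and
none available); adjusted p-values are monotone in the raw ones.

## The synthetic-data generator

`generate_clusters` draws additive logistic-normal clusters: ILR
coordinates from a spherical normal centred at `ilr(center)` with
per-coordinate variance `total_variance / (D − 1)`, so the expected
total metric variance equals the specification. This is the minimal
generative model consistent with analysing data in Aitchison geometry,
and its one spread parameter maps directly onto published per-cluster
total variances. Defaults encode the study conditions: three section
clusters (n = 14/41/45, total variances 0.1063/0.2553/0.2567) and four
fracture clusters (n = 19/27/19/40, total variances 0.33–0.99) at the
published centers over (C, O, Ca, Mg, Traces). Seven-element specs
additionally zero Cl/F/P with per-element non-detection probabilities
and re-close, exercising the zero-replacement path (e.g. phosphorus
present in every spicule of the small cluster, absent elsewhere).

What the generator does **not** emulate — and hence what passing tests
do not show about real data:

- **Anisotropic within-cluster covariance.** Real clusters almost
  certainly have correlated log-ratios; spherical ILR noise spreads the
  published total variance equally in all directions. Consequence: the
  two layered-spicule section clusters, whose centers are only 0.712
  apart in Aitchison distance, overlap heavily under spherical noise
  (≈2.8σ separation). Even assigning each sample to its true nearest
  center yields median ARI ≈ 0.8 over 20 seeds, and silhouette
  selection prefers k = 2. High-fidelity recovery of all three section
  clusters is therefore not achievable under these conditions, and the
  corresponding acceptance check records that gap rather than loosening
  it.
- **Preparation batch effects.** Fracture-preparation artefacts
  (surface roughness, detector geometry) are emulated only as shifted
  centers and inflated variances. That is not enough to reproduce a
  clean section-vs-fracture top split when both tables are clustered
  jointly: the fracture centers straddle the section region, so the
  best cluster-to-preparation agreement at k = 2–3 is ≈0.70. A
  systematic between-batch perturbation would be needed; it is out of
  scope.
- **EDX physics** (ZAF biases, topography, detector response).

`generate_raman_spectrum` sums pseudo-Voigt bands (η = 0.5), a
polynomial baseline and Gaussian noise on a regular shift grid; the
default calcite-like scenario places bands at 282/712/1087 cm⁻¹ with
relative amplitudes 0.35/0.2/1.0 and noise such that the weakest band
has SNR ≈ 20.

## Raman identification

Baseline: rolling-minimum envelope smoothed by a moving average
(window 2·half_window + 1 points, default half_window 50) —
parameter-light and adequate for smooth fluorescence baselines;
asymmetric-least-squares alternatives were deliberately not added.
Peak detection estimates the noise as the robust (MAD-based) scale of
the first differences, finds local maxima on a lightly
Savitzky–Golay-smoothed copy (quadratic, 9 points), and requires both
prominence and height ≥ 5 × noise; the height floor matters because on
long grids pure-noise maxima can reach prominences of ~6 × the noise
scale while their heights stay near 3σ. Positions are refined by
3-point parabolic interpolation. Matching widens the three calcite
windows (281–283, 707–720, 1087–1088 cm⁻¹) by a 4 cm⁻¹ tolerance
(grating resolution plus the natural ν4 spread); a spectrum is
`calcite_family` iff the ν1 window is hit, with `partial` flagging
missing lattice/ν4 peaks. Calcite and magnesian calcite are not
distinguished — at this resolution that distinction belongs to the
elemental Mg data, not the Raman shift.

## Numerical choices and degenerate inputs

- Orthonormality/zero-sum of ILR bases enforced to 1e-10; closure
  idempotent to 1e-12.
- Scatter-matrix determinants via `slogdet`; singular within-group
  scatter raises a clear error pointing at n vs D − 1.
- Quartiles: linear interpolation (type-7), documented because plotting
  conventions differ; whiskers at 1.5·IQR capped at observed extremes.
- Identical samples: distance 0 is fine; cluster-number criteria raise
  (no silent default); biplots on zero-variance data raise.
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; identical seeds give bit-identical outputs.

## Problem sizes

Simulation-based checks use the study's own sample sizes (100 section
samples, 105 fracture samples) with 20 seeds for recovery rates, 500
replicates for type-I calibration, n = 2000 for generator parameter
recovery, and 50 spectra for Raman recall; the full suite and the
reproduction script each run in well under a minute.
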