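# Methods

This package analyses the *receptome*: the region × region matrix of
Spearman correlations between receptor "fingerprints", where a fingerprint
is the vector of neurotransmitter receptor and transporter (NTRM) densities
measured at one region by PET. The receptome quantifies interregional
chemoarchitectural similarity. The pipeline derives its low-dimensional
organisation (gradients), tests associations against spatial nulls, finds
signed community structure, and couples the receptome to structural (SC),
functional (FC) and microstructural (MPC) connectivity.

## Density panel

Densities arrive as one region-value map per molecule (19 molecules in the
reference atlas), optionally averaged over several tracer studies weighted
by each study's sample size. Each molecule column is z-scored (sample sd,
ddof = 1) before any similarity computation; the scoring scope is recorded
because cortical analyses score jointly while subcortical analyses score
within-compartment. Parcellation of density volumes is a plain in-label
voxel mean: label 0 is background, NaN voxels are excluded, and all-NaN
labels are flagged missing and dropped from every downstream matrix.

## Receptome and gradients

Receptome entries are Spearman correlations with average ranks for ties;
constant fingerprints raise an error naming the region. The gradient
pipeline follows the standard surface-gradient toolchain:

1. **Row thresholding** (default 90th percentile): each row keeps its
   strongest 10% of off-diagonal entries, signed values retained, ties at
   the cutoff all kept. The result is asymmetric; the row-profile kernel
   restores symmetry. A global-threshold variant exists but degenerates on
   weakly structured rows and is not the default.
2. **Normalized-angle kernel**: affinity(i, j) = 1 − arccos(cos(row_i,
   row_j))/π ∈ [0, 1]; parallel profiles map to 1, orthogonal to 0.5,
   anti-parallel to 0.
3. **Diffusion-map embedding** with anisotropic normalisation α = 0.5
   (balancing manifold geometry against sampling density), solved through
   the symmetric conjugate of the Markov operator. The trivial constant
   eigenvector is dropped; components are scaled λ/(1 − λ) (diffusion time
   0) and sign-fixed so the node of largest |value| is positive.

"Relative variance" of component i is λ_i / Σ_j λ_j over the retained
non-trivial eigenvalues — the definition is stated here prominently because
reported percentages depend on it. Hemisphere-wise gradient sets are merged
by orthogonal Procrustes alignment (rotation/reflection, no scaling).
Rectangular (cross-compartment) similarity is embedded over rows; column
values are an affinity-weighted projection with weights (ρ + 1)/2.

Component significance replaces every molecule map with a
variogram-matched surrogate, rebuilds and re-embeds the receptome, and
compares relative-variance fractions with a +1-corrected exceedance p.
Note that this null is conservative for smooth synthetic panels: smooth
surrogate maps share low-order spherical harmonics, so surrogate receptomes
are themselves low-dimensional.

## Spatial null models

Smooth brain maps violate exchangeability; naive permutation tests reject
independent map pairs far above the nominal rate (measured ≈ 0.16–0.21 at
α = 0.05 on synthetic fields). Two surrogate generators address this:

* **Variogram matching (VGM)** — permute the map, smooth with k-nearest-
  neighbour truncated-Gaussian kernels over a candidate grid
  k ∈ {3, 5, 10, 20, …, n/4}, fit the original's empirical variogram
  (25 bins over the shortest quartile of pair distances) as
  β·ν_smoothed + α by nonnegative least squares, keep the best k, compose
  √β·smoothed + √α·white noise, and rescale to the original mean and sd.
  Works for any distance matrix, so subcortical (volumetric) analyses use
  VGM with Euclidean distances.
* **Spin permutation** — a uniform random rotation applied to
  left-hemisphere sphere coordinates and its x-mirror to the right, with
  values reassigned by a one-to-one nearest (linear-assignment) matching,
  so every surrogate is an exact permutation of the original values.
  Parcels whose assignment touches the medial wall are flagged discarded
  and dropped pairwise in tests.

The association test reports Spearman ρ with a two-sided surrogate p,
p = (1 + #{|ρ_null| ≥ |ρ|})/(n_null + 1); its floor is 1/(n_null + 1).
Class-alignment tests compare the within-class mean of a gradient against
the surrogate distribution of the same statistic, centred two-sided.

## Signed communities

Anticorrelations carry information, so clustering maximises the
negative-asymmetric signed modularity

Q\* = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻,

with Q± the modularity of the positive/negative subnetwork at resolution γ
(γ enters both null terms; the weight diagonal is excluded while the null
term runs over all same-community pairs, the standard convention that makes
a uniform all-positive single community score exactly 0). The optimizer is
a native Leiden-style procedure: local moving over units, then a
refinement phase that re-splits each community from singletons with moves
restricted to the parent community, refined blocks becoming the next
level's units. Quality is monotonically non-decreasing across phases and
runs are deterministic under a seed.

Restart reproducibility is scored with the z-rand statistic: the
co-assigned pair count standardised by its exact permutation-null mean and
variance (derived from falling-factorial class-size sums and validated
against exhaustive enumeration). Per resolution, the consensus partition
maximises the mean z-rand against all other restarts (ties broken by
lowest index); the variance of pairwise scores is the stability index.
Resolution grids follow the study conditions: γ = 0.5–10 step 0.05
(191 values, 1000 restarts) cortically and γ = 1–10 step 0.5 (19 values,
250 restarts) subcortically; desk-scale runs use reduced grids and restart
counts, chosen so the synthetic fixtures' consensus is already stable.

The **modular stability score** of an ROI is Cmax·(1 − Cin/Ctot)·s (largest
ROI share held by one community; number of communities inside the ROI;
total communities; relative ROI size). The printed source formula omits an
operator; the subtraction is the only reading under which an ROI that does
not fracture scores high, and it is the default here. A divide-by-s
variant is exposed (`size_mode="divide"`) since "normalising" by size
admits both readings. Hierarchical clustering of fingerprints is WPGMA
(Euclidean distances, d(k, i∪j) = (d(k,i)+d(k,j))/2) via scipy's
`linkage(method="weighted")`, cross-checked against a hand recursion.

## Consensus connectivity and coupling

* **FC**: subject matrices are Fisher r-to-z transformed and averaged;
  values are kept on the z scale (all downstream uses are rank-based, so
  the choice is immaterial; a flag back-transforms).
* **SC**: log(1 + w) per subject, averaged, then distance-binned
  consistency thresholding — per edge-length bin, the most consistently
  present edges are kept (ties by higher mean weight), with per-bin quotas
  proportional to the pooled subject edge-length histogram and the total
  matched to the mean subject edge count (deviation bounded by the number
  of bins through rounding). This corrects the short-edge bias a naive
  average-threshold consensus shows.
* **MPC**: depth-wise intensity profiles (≥ 3 samples; 14 in the reference
  construction) are residualised on the grand-mean profile and Pearson
  correlated; the log step zeroes non-positive partials and applies
  log(1 + r) by default, with a Fisher-z variant behind a flag — all
  variants are monotone, hence equivalent for rank-based coupling.

Row coupling correlates (Spearman) receptome row i with the other
modality's row i over the intersection of nonzero supports, excluding the
diagonal; rows with fewer than 3 shared entries yield NaN with a warning.
Class-wise coupling differences use tie-corrected Kruskal–Wallis plus
Dunn's pairwise z (large-sample normal approximation, tie-corrected) with
Bonferroni adjustment over all pairs.

## Synthetic data

The generator plants exactly the structure each stage must recover:

* Parcel geometries: Fibonacci-lattice points on the unit sphere (great-
  circle distances, hemispheres split by sign of x, optional medial-wall
  fraction) or uniform volumetric positions in mm.
* Autocorrelated maps: Gaussian random fields with covariance exp(−d/ℓ)
  via jittered Cholesky. The exponential kernel produces rough fields that
  stress variogram fitting harder than a squared-exponential would.
  Default ℓ = 0.5 rad on the unit sphere.
* Density panels: molecules are noisy linear mixtures of k centered,
  Gram–Schmidt-orthogonalised smooth axes with unit variance, standard
  normal loadings, and i.i.d. noise of sd `noise_sd` (so `noise_sd` reads
  as a noise-to-signal fraction against the unit-variance axes).
* Signed block matrices: w_in within / w_out between planted blocks plus
  symmetric noise, clipped to [−1, 1].
* Subject stacks: FC as sample correlations of latent-factor time series;
  SC with Bernoulli(exp(−d/ℓ_edge)) edge masks per subject, reproducing
  the short-edge over-representation the consensus step must correct; MPC
  as log-scale similarity templates with subject noise.
* Planted coupling: per-region mixtures c·receptome-row + √(1−c²)·noise
  with class-specific targets c, used to power the class-comparison tests.

What the generator does **not** emulate: tracer kinetics, partial-volume
effects, cortical folding, hemispheric asymmetries of real anatomy, and —
deliberately — any shared structure between the synthetic cortical and
subcortical compartments. Passing tests therefore demonstrate algorithmic
correctness and calibration on data satisfying the model's assumptions,
not fidelity to any empirical brain.

### A known ceiling of the single-axis recovery fixture

For a panel built from a *single* planted axis, a noiseless fingerprint is
row_i = a_i·L; after per-molecule z-scoring it becomes a_i·sign(L_m), so
the Spearman receptome degenerates to an exact two-block ±1 matrix and the
first gradient can only encode sign(a_i). Spearman between a two-block
step function and the continuous axis is √3/2 ≈ 0.866 for balanced blocks.
Measured single-axis recovery at noise 0.1 sits at this ceiling (median
≈ 0.87 across thresholding variants; only removing the 90% sparsification
entirely reaches ≈ 0.93). Multi-axis panels do not suffer this degeneracy.
The corresponding recovery check in the acceptance suite asserts the
stricter > 0.9 and is expected to fail; it is retained unweakened as a
faithful record of this analysis.

## Numerical choices

* Percentiles via linear interpolation (`np.percentile`); threshold keeps
  ties at the cutoff.
* Diffusion embedding requires a connected affinity graph (checked via
  connected components) and rejects retained negative eigenvalues beyond
  1e-8; eigenvalues are clipped to [0, 1) before λ/(1 − λ).
* VGM covariance jitter 1e-8; degenerate variogram fits clip β, α at 0.
* z-rand returns 0 when the null variance vanishes (degenerate partitions).
* Per-repetition community seeds derive from the master seed through a
  `SeedSequence` counter and are recorded in outputs; every generator is
  bit-reproducible under a fixed seed.
* Desk-scale problem sizes used throughout the analysis drivers and the
  acceptance script — 100 cortical parcels, 30 subcortical voxels, 20
  subjects, 200–500 surrogates, reduced γ grids — are the package's own
  choice of fixture scale for a synthetic study; all full-scale study
  parameters remain the configurable defaults.
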