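# Methods

This note documents the models behind `diatomid`, the parameter choices that
matter, what the synthetic data does and does not emulate, and the numerical
conventions — the things a maintainer would otherwise have to reverse-engineer
from the code.

## The identification problem

A pennate diatom taxon is not one shape but a life-cycle series: each asexual
division produces one daughter smaller than the mother, so valve length
shrinks over generations (until sexual auxospore formation restores full
size) while ornamentation — the periodic striae — stays characteristic.
Descriptors must therefore separate *between-taxon* differences from
*within-taxon* life-cycle variation. The package combines a scale-invariant
contour spectrum (shape) with filter-bank texture statistics (ornamentation),
and lets a supervised projection (LDA) concentrate what discriminates taxa.

## Segmentation

Six fixed steps: Otsu binarization, dilation, hole filling, erosion, largest
8-connected component, boundary tracing.

* **Structuring element**: disc, radius 3 px (both dilation and erosion).
  Large enough to close the gaps that dark striae cut into the binarized
  valve at the default synthetic scale (striae periods 5–12 px), small
  enough not to merge the valve with nearby debris. Exposed as
  `struct_radius`.
* **Polarity**: Otsu yields a threshold, not a foreground side, and valves
  may be brighter or darker than the background. `auto` processes both
  sides and keeps the one whose largest raw-binarization component does not
  touch the image border (the background side practically always does);
  compactness (area / bounding-box area) breaks ties. This makes the mask
  invariant to intensity inversion. An earlier compactness-only rule was
  rejected: a frame-filling background component has bounding-box
  compactness near 1 and beats any elongated valve.
* **Connectivity** is 8 throughout, matching the Freeman 8-code downstream.
  Border-touching masks are allowed but warned about.
* The traced contour is the Moore neighborhood walk (clockwise in display
  orientation, Jacob's stopping criterion) from the topmost-then-leftmost
  boundary pixel. Guarantees: consecutive points 8-adjacent, closed, no
  immediate back-stepping; the Freeman chain of any traced contour satisfies
  ΣΔx = ΣΔy = 0.

## Elliptical Fourier descriptors

Computed in closed form from the chain code with t_0 = 0, p = 1..K,
t_K = T (closed-chain convention). The descriptor is the amplitude spectrum
amp_n = ½√(a_n² + b_n² + c_n² + d_n²), n = 1..30 by default:

* Amplitudes never see the DC terms, so translation invariance is exact.
* A quarter-turn rotation and a cyclic shift of the chain start act as
  orthogonal rotations within each harmonic quadruple, so amplitudes are
  invariant to machine precision (tests assert 1e−9). Arbitrary-angle
  rotations of a *digital* contour are only approximately invariant because
  re-rasterization changes the chain.
* Scale invariance is obtained by dividing by amp_1; a zero first harmonic
  (degenerate contour) raises instead of silently normalizing. Whether the
  30-amplitude block could instead be left unnormalized is a genuine design
  fork; normalization was chosen so that life-cycle size reduction moves a
  sample *along* the within-class manifold rather than radially in feature
  space.
* 30 harmonics suffice: for rectifiable contours coefficients decay like
  1/n², and reconstruction error on smooth synthetic outlines is below one
  pixel well before n = 30.

Reconstruction (`reconstruct_contour`) carries the DC offsets A0/C0 so the
truncated synthesis overlays the source contour; with one harmonic the curve
is exactly an ellipse.

A note on circles: for x = r·cos, y = r·sin the first-harmonic quadruple is
(r, 0, 0, r), hence amp_1 = r/√2, not r — relevant when eyeballing amplitude
magnitudes.

## Phase congruency

Per orientation θ, S log-Gabor quadrature pairs give amplitudes A_n and
phases φ_n; the congruency map is

    PC_θ = w_θ · max(Σ_n A_n·ΔΦ_n − T_θ, 0) / (Σ_n A_n + ε),
    ΔΦ_n = cos(φ_n − φ̄_θ) − |sin(φ_n − φ̄_θ)|,

with the combined map dividing the summed oriented energy by the total
amplitude over all orientations. The per-orientation map is normalized by
that orientation's own amplitude sum — normalizing by the all-orientation
total would make "the congruency at orientation θ" depend on energy at
every other orientation, which contradicts its use in the moment equations.

Parameters (all in `PCParams`):

* 4 scales × 6 orientations, wavelengths 4–32 px — the same geometry as the
  texture bank, covering striae periods the generator produces.
* ε = 1e−4 guards the division; values are clamped to [0, 1].
* Noise floor T_θ = k · median(A_smallest-scale)/0.6745 with k = 2: the
  standard robust noise estimate from the highest-frequency band. Because
  T_θ scales linearly with image contrast, PC stays contrast-robust even
  with the floor active. k = 0 disables it (used by the closed-form tests).
* Weighting w_θ: sigmoid (gain 10, cutoff 0.5) of the filter-response
  spread, down-weighting points where only one scale responds.

The moment images M ≥ m ≥ 0 derive pointwise from the oriented stack
(a, b, c quadratic forms); m ≥ 0 follows from Cauchy–Schwarz over
orientations. The 4-vector descriptor is (mean M, std M, mean m, std m)
computed over the **full frame** by default; a mask-restricted variant is
available (`mask=` argument) since either convention is defensible — the
full frame includes the valve edge response, which is itself informative.

## Log-Gabor texture block

The bank is built directly in the frequency domain: radial Gaussian in
log-frequency (σ/f₀ = 0.65, about two octaves per filter), angular Gaussian
(σ_θ = π/7.2 rad), 4 scales (λ = 4, 8, 16, 32 px) × 6 orientations, unit
peak, exactly zero DC. The angular factor covers a single half-plane, so the
complex spatial response is analytic and its modulus is the sub-band
envelope.

Per sub-band, statistics run over mask pixels only (background replaced by
the interior mean before filtering to suppress edge ringing):

* first order: mean, std, skewness, kurtosis (biased sample moments),
  energy, 32-bin Shannon entropy;
* second order: contrast, correlation, homogeneity, uniformity of the
  symmetric 32-level co-occurrence matrix at 1-px offsets 0° and 90°,
  quantized min–max inside the mask, background pairs excluded via a
  sentinel level.

That is 14 statistics × 24 bands = 336 raw features. Redundancy is removed
by correlation: either a greedy in-order pass dropping columns whose |r|
with a retained column reaches a threshold, or a target-dimension mode that
repeatedly deletes the later member of the most-correlated remaining pair
until a requested count (default 177, giving the 30+4+177 = 211 combined
layout) remains. Column 0 is never dropped; constant columns are treated as
r = 0 and retained. The reducer is fitted on training rows only.

A single image cannot fit a correlation reducer, so `extract_features`
without a fitted selection truncates the raw block order-preservingly to the
target length — the layout contract holds for one image, and experiments
always refit the data-driven selection (per fold in CV; on the full table
for clustering, which has no folds — a deliberate asymmetry, since
clustering "training" is the entire dataset).

## Classification and validation

* **Scaling**: z-score standardization precedes every reducer/classifier/
  clusterer, fitted on training folds; the blocks mix units (normalized
  amplitudes vs co-occurrence statistics), so this is not optional.
* **LDA**: eigen solver with shrinkage 1e−4 — collinear features (e.g. the
  near-zero even EFD amplitudes of symmetric valves) otherwise make the
  within-class scatter singular. Components capped at N−1.
* **KNN**: K = 5, Euclidean, in LDA space; a tied vote falls back to the
  single nearest neighbor, keeping predictions deterministic.
* **SVM**: RBF, C = 10, one-vs-one. The kernel width is the variance-scaled
  γ = 1/(d·Var(X)): a fixed γ = 1/d collapses to majority voting when the
  LDA-space scale is far from 1, which is the normal case.
* **Cross-validation**: seeded stratified 10-fold; pooled confusion matrix;
  every data-dependent step refitted per fold (a spy-based test asserts
  fitting never sees held-out rows). Exhaustively repeating over all
  C(n, 10) validation subsets is combinatorially impossible; seeded
  stratified folding is the tractable equivalent.
* **Clustering**: k-means (10 restarts), Ward agglomerative, BIRCH
  (branching 50, threshold 0.5, no outlier phase, plus a k-means refinement
  seeded at the BIRCH centroids), all at k = N on the LDA projection.
  Cluster labels are matched to classes by Hungarian assignment on the
  contingency table (verified against k! brute force in tests), then scored
  with ARI, AMI, homogeneity, completeness and silhouette. Silhouette is
  undefined for one cluster and reported as missing with a warning.
* **ReliefF** ranks features by nearest-hit/nearest-miss separation with
  range-normalized differences (weights in [−1, 1], k = 10 neighbors,
  class-prior-weighted misses); it detects interacting features (XOR pairs)
  that univariate scores miss. Used diagnostically, not in the pipeline.

## Synthetic data: what it emulates, and what it does not

The generator renders one valve per 512×384 8-bit canvas: a closed-form
outline (ellipse, pointed superellipse "lanceolate", Gaussian-bulbed
"capitate", or Cassini oval with a central constriction), a cosine striae
grating clipped to the interior (period > 1 px, orientation and contrast per
taxon), an optional darker raphe line, a linear illumination ramp
(±5% by default), and additive Gaussian noise (σ = 1% of range by default).
Masks are the exact analytic raster, which gives closed-form oracles
(ellipse area, striae spectral peak) for free.

The life cycle is a geometric caricature: length ×0.93 per stage, width
×0.985, plus a morph parameter that eases the outline toward a rounder
senescent form, with ±2% per-sample size jitter. No published per-stage
size statistics exist for the real taxa, so these ratios are a modeling
choice, not a fit.

Default catalogs stride classes through the four outline families, disjoint
size slots, striae periods 5–12.5 px and orientations 0–0.36 rad, so any two
classes differ in at least two parameters. This makes the default datasets
*separable by construction* — deliberately. Passing end-to-end tests
(accuracy ≥ 0.95, ARI ≥ 0.9 at 8 classes × 50 images × 5 stages) therefore
demonstrates that the pipeline preserves and concentrates the information
the generator puts in; it does **not** demonstrate field performance on real
micrographs, where debris, focus variation, girdle views, overlapping
valves and genuinely similar congeners dominate the error budget. Real
collections of comparable size report near-perfect but not perfect accuracy;
on the synthetic study conditions this package measures 100% for both
supervised classifiers and all three clusterers — the ceiling the
generator's separability implies.

Everything is a pure function of its arguments: identical (parameters, seed)
give bit-identical images, catalogs, datasets and experiment reports.

## Numerical conventions and degenerate inputs

* Display frame x = +col, y = −row; Freeman code 0 = East, 2 = North.
* Chain convention t_0 = 0, t_K = T; open chains are rejected by the EFD.
* Constant images fail segmentation with a dedicated error; empty or
  single-pixel masks fail contour tracing.
* Degenerate (constant) filter bands report zero skewness/kurtosis and zero
  co-occurrence correlation rather than NaN.
* Seeds: every stochastic step (catalog jitter, noise, fold shuffling,
  k-means restarts) derives from an explicit integer seed; per-sample seeds
  are spawned from the dataset seed via `numpy` SeedSequence.

## Known limitations

* Single valve per frame; no debris rejection beyond largest-component, no
  multi-specimen scenes, no focus fusion.
* Girdle-view and teratological (environmentally deformed) valves are out of
  scope.
* The Gabor block's statistic set is an explicit, documented choice; other
  statistic sets of different raw dimensionality would change the reduced
  block's composition (though not its 177 length under target-dim mode).
* Arbitrary-angle rotation invariance of the full pipeline is approximate
  (digital re-rasterization); exact invariance holds for quarter-turns.
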