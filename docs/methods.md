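# Methods

This note documents the statistical models implemented in `ncd`, the
conventions and defaults chosen where the field has no single standard,
what the synthetic-data generators do and do not emulate, and the known
limitations of each stage. Coordinates are continuous nanometres with
the origin at the lower-left corner of a rectangular observation window;
densities are molecules per μm².

## Localization preprocessing

A fluorophore blinks, so one molecule appears as several localizations in
nearby frames. Grouping merges records that are chainable by links with
spatial distance ≤ `max_distance` and at most `max_off_frames` dark
frames between appearances (frame gap ≤ `max_off_frames` + 1). The
linkage is **transitive single linkage in (space, time)**: this makes the
partition independent of record order, at the cost of possible chaining
between genuinely distinct molecules that blink close together. The
merged record takes the **mean position** of its members (the mean is the
maximum-likelihood position under isotropic Gaussian localization noise
of equal precision), the first frame, the mean uncertainty and the summed
intensity. Shipped defaults — `max_off_frames = 3`, `max_distance =
50 nm` — are configuration values, not constants of nature: the correct
thresholds depend on the fluorophore's blinking statistics and on the
localization precision (a link threshold of roughly 5× the pairwise
jitter scale, i.e. 5·σ·√2, keeps split-molecule errors rare). With
exactly coincident consecutive-frame records the zero-threshold limit
still merges them; for continuous coordinates this limit is the identity.

Live acquisitions are cut into consecutive, non-overlapping blocks of
`frames_per_window` camera frames (default workflow: 12,000 frames at
50 fps, 250 frames per window → 48 windows of 5 s). A trailing partial
block is dropped rather than kept as a shorter window, so every window
estimates densities over the same exposure.

## Pair-correlation statistics

For a pattern of n points in a window of area A the binned estimator is

    ĝ(bin) = W(bin) · A / (n (n − 1) · area(annulus)),

with W(bin) the edge-corrected count of ordered pairs in the annulus.
The bivariate version normalizes by n₁ n₂ and counts each cross pair
once; both are 1 in expectation under complete spatial randomness /
cross-species independence. Self-pairs are excluded from the univariate
statistic; coincident cross pairs (distance 0) are allowed in the
bivariate one, which is what makes the perfect-colocalization fixtures
exact. Edge handling:

- `periodic` — toroidal minimum-image distances; the natural match for
  the synthetic generators, which wrap cluster offspring periodically.
  Valid for r below half the shorter window side.
- `translation` — the standard translation correction for rectangular
  windows (pair weight A / ((W−|dx|)(H−|dy|))); the default for real data.
- `none` — raw counts, negatively biased near the boundary.

Default bins are 10 nm wide from 0 to 1000 nm; the scalar self-clustering
summary g(0–100) is the unweighted mean of ĝ over bins with centres in
(0, 100] (a bin mean, not an integral — with equal-width bins the two
differ only through the area weighting, and the bin mean is what the
per-window state features use).

**Random-labeling envelope.** The null model for co-organization keeps
the n₁ + n₂ observed positions fixed and reshuffles the species labels,
preserving counts. With 19 relabelings the per-bin minimum/maximum
bracket a one-sided 95% band: by exchangeability the observed g₁₂ exceeds
the maximum of 19 null draws with probability exactly 1/20. Min/max are
used, not quantiles. The implementation enumerates the pooled pair list
once and re-bins it per relabeling, so envelopes cost little more than a
single BPCF evaluation.

**Extent of mixing.** EOM(r) = (g₁₂(r) − 1) / (ḡ₁₂ᴿᴸ(r) − 1), where
ḡ₁₂ᴿᴸ is the mean over the random-labeling simulations. This linear
normalization maps the two anchor cases exactly: independence
(g₁₂ = 1) → 0 and agreement with the random-labeling expectation → +1.
The normalizer is the envelope *mean* rather than its midpoint; the two
differ negligibly at 19 simulations and the mean is the lower-variance
choice. Bins where |ḡ₁₂ᴿᴸ − 1| < 0.05 carry no mixing information (the
null itself is flat there, typically beyond the cluster scale) and are
reported as undefined rather than divided through; values are reported
unclipped, with an optional clip to [0, 1]. Cell averages (`eom_average`)
take per-bin means over the curves in which the bin is defined and retain
the per-bin contributor count.

## Coordinate-based colocalization

For each reference molecule the cumulative neighbor counts of its own
species and of the target species are taken at 50 radii, 20–1000 nm in
20-nm steps (the 20-nm step matches typical two-color PALM localization
uncertainty; the 1 μm ceiling covers the largest cluster structures).
Each profile is normalized by its count at the largest radius and by ring
area, D(r) = N(r)/N(r_max) · r_max²/r², and the CBC value is the Spearman
rank correlation (average ranks on ties) of the two profiles, multiplied
by exp(−E/r_max) with E the distance to the nearest target molecule.

Convention: the reference point itself is included in its own-species
counts, and a coincident target point counts as a target neighbor at
distance 0. This symmetric choice is the one under which a target channel
that duplicates the reference coordinates gives **exactly** +1 for every
reference point (identical profiles → Spearman 1; E = 0 → weight 1);
with self-exclusion the two profiles differ by a rank-distorting +1 and
the limit is only approximate. Reference points with no target neighbor
within r_max — or a degenerate rank correlation — yield missing values,
not 0: zero encodes "no correlation", absence encodes "no data".

The positional null redraws the target positions uniformly over the
window (complete spatial randomness), 19 times by default. Histograms
use 21 equal bins over [−1, 1]; the tail-heaviness summary is the
**non-excess** kurtosis (fourth standardized moment, so a Gaussian gives
3) of the defined CBC values. Both colocalization directions
(A around B, B around A) are supported; neither is canonical.

## Nanodomain enrichment

Domain detection is a pure fixed-radius chaining rule: two molecules
belong to one cluster iff connected by links each ≤ d_th (default 80 nm,
with 60 and 100 nm as standard sensitivity values). This is single
linkage cut at d_th — there is no min-points core condition, so the
result is exactly the partition a range-search flood fill produces.
Clusters are tallied into size classes (1, 2, 3, 4, 5, ≥6).

Polygonal domains are built for clusters of ≥ 3 points (configurable):
the convex hull dilated by a `buffer` of 40 nm = d_th/2, so boundaries
extend half a link beyond member molecules; monomers, dimers and
collinear clusters fall back to unions of discs of radius `buffer`.
Convex hulls (not alpha-shapes) are a deliberate simplification: they are
deterministic, parameter-free and easy to test, at the cost of
overestimating the area of strongly non-convex domains. Polygons are
clipped to the window and their union area is used, so overlapping
domains are not double-counted and domain area never exceeds window area.
Enrichment of a second species reports densities inside and outside the
union (boundary points count as inside), their fold ratio, the fraction
of molecules inside, and the domain area fraction.

## Cluster-state dynamics

For one cluster ROI (1.5 × 1.5 μm) each 5-s window yields per-species
density and g(0–100), plus the mean short-range EOM. Windows with fewer
than two molecules have no defined g and are reported missing; missing
values break feature series rather than being imputed, and transitions
across missing windows are simply not counted.

Synchrony between species is the Pearson correlation of their per-window
series (density or g), over pairwise-complete windows.

States are defined by a 3-component Gaussian mixture on the 2D
(density, g(0–100)) cloud. The two features differ by orders of
magnitude, so they are z-scored before fitting (full covariances, 10
restarts, fixed seed). Components are relabeled deterministically:
state 1 = lowest mean density (dispersed molecules), and of the two
denser components state 2 has the lower and state 3 the higher mean g
(dense-unclustered vs dense-clustered). The mixture is fit on both
species' observations pooled by default; per-species fits are available.

The transition matrix is the maximum-likelihood estimate pooling
transition counts between consecutive windows across all cluster
trajectories (the study scale is 41 clusters × 48 windows), row
normalized; probabilities are per 5-s step. A state never left in the
data gets a uniform row and is flagged. The stationary distribution is
the unit left eigenvector.

Group comparisons use the classic two-tailed two-sample Student's t test
(pooled variance); Welch's correction is available via a flag.

## Synthetic data

The generators produce exactly the structures the analyses assume, with
ground truth retained:

- **Poisson** backgrounds (CSR) at programmed density.
- **Thomas** nanoclusters: Poisson parents, Poisson(μ) offspring displaced
  by an isotropic Gaussian σ. Chosen as the canonical cluster model
  because its pair correlation is available in closed form,
  g(r) = 1 + exp(−r²/4σ²)/(4πσ²κ), which serves as an independent oracle
  for the estimator. Defaults (σ = 30 nm, μ = 20, κ = 2 μm⁻², 10 × 10 μm
  windows) put overall densities in the tens per μm², the regime of
  membrane signaling proteins.
- **Mixing sweep**: a fraction f of clusters is co-labeled by per-point
  random labeling, the rest are single-label; f = 1 is exact random
  labeling (EOM → 1), f = 0 independent cluster sets (EOM → 0).
- **Periphery**: species B on annuli around the cluster centres of
  species A plus a uniform background fraction — the regime where CBC
  histograms grow heavy tails relative to their randomization null.
- **Domain enrichment**: B drawn with intensity fold× higher inside A's
  domain polygons than outside (by rejection sampling); the realized fold
  is recorded as truth.
- **Blinking movies**: fixed emitters with on-bursts, off-gaps and
  per-appearance Gaussian jitter; emitter ids are kept for grouping
  validation.
- **Dynamic assembly**: a latent 3-state Markov chain per cluster drives
  state-dependent density/clustering for both species in each window;
  latent labels are returned. A separate bivariate-normal series
  generator provides exactly programmed synchrony for estimator
  calibration.

Offspring and annulus points are wrapped periodically into the window, so
the generators are stationary on the torus and calibrate exactly against
the periodic edge mode. What the generators do **not** emulate: camera
noise and PSF shape, localization-uncertainty heterogeneity, drift,
anisotropic or non-convex cluster shapes, inter-cluster interactions, and
detection-efficiency differences between channels. Passing tests
therefore demonstrate correctness of the statistics under the stated
point-process models, not robustness to every instrumental artifact of
real data.

## Numerical choices and problem sizes

Neighbor searches use k-d trees throughout (periodic boxes where
applicable); envelopes re-bin a precomputed pair list; point-in-polygon
uses prepared geometries with closed boundaries. Degenerate inputs raise
typed errors rather than returning silent NaN: fewer than 2 points for a
PCF, zero-variance series for correlations and t tests, zero domain area
for in/out densities, near-zero variance (< 10⁻¹²) for CBC kurtosis.
Calibration tests and the acceptance script use 50 replicates for
Poisson/EOM means, 500 trials for envelope coverage, 41 × 48 windows for
Markov recovery, and ≤ 500-point patterns for brute-force oracle
equivalence — sizes at which the Monte Carlo standard errors are well
below the tolerances being checked while the whole suite runs in well
under a minute on one CPU.

## Known limitations

- The grouping rule can chain distinct molecules in very dense scenes;
  thresholds must be set per fluorophore.
- Translation edge correction assumes a rectangular observation window;
  irregular cell footprints are not masked.
- Convex-hull domains overestimate concave domain areas.
- EOM is undefined wherever the random-labeling null is itself flat;
  cell averages over few cells can be noisy in those bins.
- State labels come from a mixture fit in feature space, not a hidden
  Markov model; no temporal smoothing is applied, and the number of
  states is fixed at three.
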