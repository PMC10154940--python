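# Methods

## The scientific question and the pipeline's shape

Sexually dimorphic ornaments of male sepsid flies (modified fore femora,
fourth abdominal sternite brushes, genital claspers) vary from simple to
extravagantly complex across species. Because all adult cuticular structures
are built from a fixed energy budget during pupal metamorphosis, a natural
question is whether building a *more complex* ornament — over and above a
larger one — costs development time. `ornametrics` implements the full
analysis chain needed to ask that question comparatively:

1. quantify the structural complexity of a trait from its closed 2-D outline
   (a Fourier-congruence score);
2. reduce per-individual morphometric panels (development times, body and
   trait sizes) to sex-specific species means and male − female differences;
3. test those differences across species (one-sample t-tests, Pearson
   correlations of trait size with development time);
4. regress development-time differences on complexity differences with
   body-size covariates under phylogenetic generalized least squares (PGLS)
   with Pagel's λ.

Everything is exercised end to end on synthetic data with known ground
truth; the generators are first-class, tested code.

## The congruence complexity score

A closed outline is expanded in elliptic Fourier descriptors: both
coordinate functions of the closed curve are Fourier series, harmonic *n*
contributing a quadruple (a_n, b_n, c_n, d_n). Harmonic 1 alone is an
ellipse; each added harmonic contributes finer detail. The score compares a
coarse truncation (h_low = 8 harmonics) with an effectively exact one
(h_high = 1000): both truncated curves are filled regions in the outline's
own pixel frame, and

    complexity = area(symmetric difference) / area(intersection),

i.e. non-congruent over congruent area. A shape fully captured by 8
harmonics scores 0; the more outline detail lives above the low band, the
larger the mismatch fringe and the score. Because both reconstructions
transform together, the ratio is invariant under translation, rotation and
uniform scaling (verified to 1e-6 absolute in the tests).

### Parameterization — a deliberate choice

Classical elliptic Fourier analysis (Kuhl–Giardina) parameterizes the curve
by arc length, and `compute_efa` does exactly that by default, integrating
the piecewise-linear trace chord by chord in closed form (no sampling-grid
Fourier transform; the coefficients are properties of the polygon itself).
Arc length has one under-appreciated consequence: an eccentric ellipse is
*not* band-limited in arc length — reparameterizing x = a·cos t from angle
to arc length leaks energy into odd higher harmonics (for a 2:1 ellipse,
about 4e-6 of total power sits above harmonic 8, which translates into a
congruence score of roughly 3e-3 rather than 0).

A complexity score in which a perfect ellipse is not "perfectly simple" is
awkward, so `complexity_score` instead fits the series in the outline's own
vertex parameterization (`parameterization="uniform"`: equal parameter step
per vertex). Under that convention any curve that is band-limited in its
generating parameter — every exact ellipse in particular — scores 0 to
numerical precision, and the synthetic generator's injected spectra are
exact by construction. For digitized traces, whose vertices are
near-equally spaced, the two parameterizations coincide for practical
purposes; the choice only matters for idealized analytic shapes. Both
options are exposed.

### Filling and boolean areas

Low-harmonic reconstructions of spiky shapes can curl over and
self-intersect. Both area modes therefore fill regions under the even-odd
rule — the region a plotted closed curve visually encloses:

* vector mode (canonical): the ring is noded, faces are extracted
  (`shapely.polygonize`), and faces whose ray-casting parity against the
  original curve is odd are kept; intersection and symmetric difference are
  then exact polygon clipping.
* raster mode (cross-check): a hand-written vectorized scanline even-odd
  fill on a 2048-wide pixel lattice spanning the joint bounding box;
  congruent/non-congruent areas are AND/XOR pixel counts. (Library
  rasterizers were unsuitable: point-in-polygon fillers are
  O(pixels × vertices) — minutes per 4096-vertex curve — and path-based
  ones use the non-zero winding rule, which disagrees with even-odd exactly
  on the curl-overs that matter.)

The two modes agree within 0.5% of total area across random perturbed
shapes; reconstructions are sampled at 4096 points so chord error is far
below that tolerance.

### Normalization across sexes

Male sternite and fore-femur scores are normalized by the conspecific
female score (male/female), the female being the baseline sex. Claspers
occur only in males and are never normalized. One documented exception:
*Perochaeta dikowi* females lack sclerotized fourth sternites, so their
baseline is fixed at 1 and the male score passes through unchanged.

## Outline input conventions

Coordinates are 0-based, y-down (image convention); signed area is taken in
the y-up frame so counter-clockwise is positive, and all outlines are
normalized to counter-clockwise. Self-intersecting traces are accepted but
flagged. Mask tracing follows the largest 8-connected foreground component
with Moore-neighbour tracing (Jacob's stopping criterion) and returns the
polygon through boundary *pixel centers*: a filled n×n block has polygon
area (n−1)², while its pixel count — the trait-size measure used in the
statistics — is n². For a digitized disc of radius r the pixel-center
polygon consequently tracks π(r−1/2)², not πr²; the pixel count tracks πr².

## Morphometrics

Pupal volume uses the perfect-ellipsoid proxy (π/6)·width²·length (mm³).
Growth rate is adult scutum width over total (larval + pupal) development
time, mm·h⁻¹ — a proxy chosen for its units; other definitions (e.g. from
oviposition) would shift absolute values but not sex contrasts. Species
means are the unit of replication in every cross-species test (n = species,
unweighted by per-species sample size); percent differences use the female
mean as denominator. t-tests and correlations are two-sided; the 95% CI
half-width is t₀.₉₇₅,ₙ₋₁·sd/√n, and the correlation p-value comes from the
t transform r·√((n−2)/(1−r²)). Degenerate inputs (n < 2, zero variance) are
rejected rather than returning infinities.

## PGLS with Pagel's λ

Under Brownian trait evolution on a rooted tree, residual covariance
between species i, j is the shared root-to-ancestor path length V[i,j];
Pagel's λ multiplies the off-diagonal of V (λ=0: no phylogenetic signal;
λ=1: pure Brownian). The model is fitted by GLS after Cholesky whitening,
with λ estimated by maximum likelihood over [0,1] (bounded scalar
optimization, 1e-6 tolerance, near-ties broken toward smaller λ; boundary
values are always checked). Standard errors use the unbiased σ̂²
(RSS_gls/(n−p)); the log-likelihood uses the ML σ̂². The ANOVA is
sequential (type I) in the user-given term order, computed in the whitened
space, so term SS plus residual SS equal the total generalized SS about the
GLS intercept-only fit. A tiny relative jitter (1e-10 of the mean diagonal)
stabilizes the Cholesky factor when very recent splits make two rows of V
numerically identical. Species absent from the tree are pruned with a
warning, mirroring how comparative studies drop species missing from a
published phylogeny.

Estimator checks: on star phylogenies, or at λ=0 on ultrametric trees, the
fit equals OLS to 1e-8 (statsmodels as the independent oracle); β̂ is
invariant to rescaling all branch lengths; simulated-λ recovery is sharp
(λ̂ ≤ 0.2 / ≥ 0.8 in ≥90% of replicates for data generated at λ=0 / λ=1).

In the slope-recovery simulations the covariate itself evolves as Brownian
motion on the tree. This matters: with an iid covariate, sister species
separated by tiny branches provide nearly noise-free contrasts and the
estimator becomes degenerate (CI coverage → 1). With a Brownian covariate
— the realistic comparative setting — empirical 95% CI coverage sits near
0.93–0.96, slightly below nominal because λ and σ² are estimated.

## Synthetic data — what it emulates, and what it does not

`make_shape` builds an ellipse plus perturbations injected directly into
chosen harmonics' quadruples, so the energy above any band is exact and the
zero-law/monotonicity tests are analytic. Amplitudes beyond minor/(2n) can
self-intersect the curve; that conservative bound raises unless the caller
opts in (the scorer handles such shapes via even-odd repair). These shapes
are spectrally controlled abstractions, not clasper silhouettes.

`make_tree` draws ultrametric pure-birth (Yule) trees, depth normalized
to 1; `simulate_brownian` draws tip values with covariance
σ²·pagel(V(tree), λ) — exactly the model PGLS assumes.

`make_species_panel` generates an 18-species × 2-sex panel (10 individuals
per cell by default). Species-level baselines and sex effects receive
phylogenetic structure via Brownian deviations (λ configurable, default 0,
matching the reported absence of phylogenetic signal); individuals are
drawn around their species × sex mean. The default effect magnitudes are
the study-scale values: scutum-width difference −0.134 mm (sd 0.085 across
species, back-computed from the ±0.042 95% CI at n=18), pupal-duration
difference +7.42 h (sd 9.0), larval difference −0.55 h (sd 4.6), male-biased
complexity differences (sternite 0.029, fore femur 0.024, clasper 0.231),
female baselines near 1.05 mm scutum / 210 h larval / 158 h pupal, and
trait areas scaling log-log with body size (slope 2, residual sd 0.25,
giving moderate-to-strong area–size correlations). These are configuration
defaults that make the synthetic study resemble the real design, not truth
claims. An optional `complexity_cost_slope` injects a known
complexity→pupal-duration effect for power analyses.

What passing tests show: the estimators recover the effects the generator
put in, at the study's sample sizes and noise levels. What they cannot
show: anything about measurement error in real traces, non-Gaussian
residuals, or model misspecification on real data — the generator is the
assumed model.

## Problem sizes and numerical choices

Default densities: 4096-point internal refinement for the Fourier fit
(Nyquist bound 2048, so "1000 harmonics" is representable), 4096-point
reconstructions, 2048-wide raster grid. Reconstruction/oracle tolerances:
1e-6 relative for band-limited round-trips, 0.5% for vector/raster area
agreement. The standing simulations use 100-tip trees with 100 replicates
for slope recovery and coverage (200 in the acceptance script, purely to
shrink the Monte-Carlo error of the coverage estimate), 100 seeds for the
power property with 5 individuals per species × sex, and 40 seeds for null
calibration of the panel t-tests. Every generator and analysis stage is
deterministic under a fixed seed; pipeline reruns are byte-identical.

## Known limitations

* Strictly 2-D: complexity is scored from outlines, not surfaces or volumes.
* The score depends (mildly) on h_low; 8 vs 1000 is the convention adopted
  here, and no sensitivity analysis over h_low is built in.
* Only Brownian/λ error structures; no Ornstein–Uhlenbeck or multi-rate
  models, no tree inference.
* The uniform-parameterization choice in the scorer means scores for
  sparse, very unevenly sampled analytic curves can differ from the
  arc-length convention; dense traces are unaffected.
* REML estimation of λ is not implemented (ML only, fixed-λ fits exposed).
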