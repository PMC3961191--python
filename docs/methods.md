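# Methods

This note records the models, conventions, and design choices behind
`facebrim`, and what the synthetic-cohort experiments do and do not show.

## Morphometry

**Reflection.** A configuration is mirrored by negating the x coordinate
(x = subject's left–right) and relabeling landmarks by the mask's bilateral
pairing, so landmark *i* of the mirror is the homologue of landmark *i* of
the original. The operation is an exact involution; midline landmarks map
to themselves.

**Generalized Procrustes analysis.** Configurations are centered and scaled
to unit centroid size (classical full-Procrustes convention; the size
convention is ours — analyses are scale-free either way), then iteratively
rotated to the running consensus with proper rotations only (det +1); mirror
correspondence is handled exclusively by the explicit reflect-and-relabel
step so the rotation solver can never silently undo a reflection.
Convergence: consensus RMS change < 1e-10 or 100 iterations. With
reflections included, the consensus is symmetrized against the reflection
operator each iteration; a bilaterally symmetric consensus is a fixed point
of the joint iteration, and this pins it exactly.

Superimposition leaves a free global rotation, which would make outputs
depend on the arbitrary pose of the inputs. We therefore canonicalize: the
consensus is rotated to its principal axes (for bilateral samples only the
in-plane yz axes, so the mirror plane stays at x = 0), axis signs chosen so
the third moment of the coordinates along each axis is positive, remaining
ambiguities resolved by det = +1. GPA output is then invariant (1e-8) to
arbitrary rigid motions and positive scalings of its inputs.

**Symmetric decomposition.** The symmetric component of an individual is
the average of their aligned shape and their aligned reflection; the
asymmetric component is half the difference. All downstream modeling uses
the symmetric component only; the asymmetric component is computed and
stored but not analyzed further.

**Tangent projection.** Aligned shapes lie near the unit sphere in
configuration space; each is orthogonally projected onto the affine
hyperplane through the consensus perpendicular to it (the linearization of
Kendall shape space). The projection is idempotent and is on by default but
separable.

**Shape PCA.** Eigendecomposition (via SVD) of the symmetric shapes about
the consensus; the smallest axis count whose cumulative variance reaches
the retention target (default 98%) is kept. Axis signs are fixed by making
each axis's largest-magnitude loading positive, so results are reproducible
across eigensolvers. Shape transformations along any direction are rendered
at ±k·SD of the sample scores (default k = 3).

## BRIM

**Forward model.** Partial least squares regression (NIPALS; exact
dominant-singular-vector weights rather than an inner power iteration).
With the component count equal to the predictor-block rank, PLS coincides
with ordinary least squares, and the leave-one-out loop then uses exact
closed-form normal-equation downdates (Sherman–Morrison) instead of
per-fold refits; bootstrap bagging uses count-weighted normal equations.
The automatic component count is the smallest number explaining 99% of the
standardized predictor-block covariance (capped at 10); standardization
makes the choice invariant to the units of individual columns.

**Imputation.** For individual *i*, the model is fit on everyone else and
x̂_i minimizes the squared distance between the observed response and the
predicted response with conditioning covariates held at their observed
values — in closed form, the projection of the response residual onto the
predictor's effect direction divided by its squared norm. Folds whose
effect direction vanishes numerically fall back to the training-mean
predictor (with a warning).

**Iteration and nesting.** Iteration 1 imputes from the initial predictor;
iteration t from iteration t−1's values; the run stops at `max_iterations`
(default 6) or when successive iterations correlate above 1 − tolerance.
One round of the map x ↦ x̂ is, up to scale, multiplication of the centered
predictor by the response Gram matrix — a power iteration. Two
consequences shape the design:

* *Drift.* Iterates migrate toward dominant covariance directions at a rate
  set by the eigenvalue ratios. On data with a gently decaying spectrum
  (real faces; our generator) the drift over 6 iterations is partial and
  is precisely what lets BRIM exploit the latent covariance structure to
  denoise a degraded predictor.
* *Leakage.* Naively, individual i's response influences other individuals'
  iteration-t values and thereby leaks back into i's own fold at t+1
  (order q/n per iteration), which inflates downstream tests. The
  iteration is therefore *nested*: individuals are split into K cross-fitted
  worlds (default 10; small samples fall back to the unnested loop), each
  world runs its own inner leave-one-out iteration, every world imputes the
  whole cohort, worlds are affinely aligned to their mean imputation vector
  (each world's inversion has its own scale, and unaligned folds would add
  fold-structured artifacts), and each individual's reported value comes
  from the world that excludes them entirely. RIPs are then legitimate
  inputs to standard tests.

**Bootstrapping.** With `n_bootstrap` > 0 (default 50), each fold's model
is refit on that many resamples of its training rows and the imputations
averaged (bagging). `0` gives plain leave-one-out.

**Partial BRIM.** RIP-G for a SNP is computed with RIP-A and RIP-S inside
the predictor block; only the genotype coordinate is inverted, and each
iteration's imputations are orthogonalized against [1, RIP-A, RIP-S] — the
returned RIP-G is uncorrelated with the conditioning variables by
construction (an ancestry-informative marker's *raw* imputation would
legitimately retain its corr(g, q) ≈ 0.5). The PLS component count is
fixed at the full 3-column block rank: with fewer components than
conditioning covariates, the covariate directions mix into the genotype
effect instead of being held fixed. A residualization mode (regress the
responses on the covariates once, up front) is provided for comparing
conditioning strategies.

## Synthetic cohorts

The generator emulates an admixed study population with a protected-data
stand-in: individual ancestry q from a Beta mixture (three-population
pooling; default equal-weight Beta(2,6)/Beta(5,5)/Beta(6,2)), binary sex,
and SNP genotypes Binomial(2, q·pA + (1−q)·pB). Surfaces are a smooth
convex face-like template (140 × 180 mm, 55 mm deep) displaced along vertex
normals by:

* **Causal axes** — Gaussian bump fields over named regions (nose, brow,
  lips, …): multi-region fields for ancestry and sex, single-region
  (localized) fields per SNP, mirroring the distinction between global and
  local principal components. Default RMS magnitudes: ancestry 10 mm over
  q ∈ [0,1], sex 5 mm, SNPs 1.5 mm per allele.
* **Correlated noise** — 60 random smooth bump fields with slowly decaying
  magnitudes (1.8 × 0.95^i mm), orthogonalized against the causal axes and
  one another so the cohort's covariance spectrum is exactly the prescribed
  sequence. This yields ~40 PCs at 98% retention and the gently decaying
  spectrum on which the BRIM iteration behaves as it does on real faces;
  i.i.d. per-landmark noise would leave it nothing to exploit.
* **Asymmetry** — one antisymmetric smooth field with N(0,1) per-individual
  coefficients (default 1 mm RMS), exercising the symmetrization stage.
  The magnitude is chosen for test sensitivity; no quantitative facial
  asymmetry norms are claimed.
* **Pose jitter** — random rotations (≤ 0.15 rad), translations (10 mm SD),
  and log-normal scale jitter (5%), which GPA must (and does, exactly)
  remove.

All displacement fields are projected off the 7-dimensional similarity
tangent space at the template (3 translations, 3 rotations, scaling):
only that component survives superimposition as *shape*, and without the
projection any two outward bump fields share net-displacement and size
components, become negatively correlated after alignment, and alias into a
single blended principal component. The recorded causal axes are therefore
exactly what the pipeline can in principle recover — which is what makes
axis-recovery tests meaningful.

What passing tests on these cohorts do **not** show: performance under real
registration error (the correspondence is exact by construction), non-linear
or interaction effects, texture, or realistic asymmetry structure.

## FSCPs

Per-vertex area = one third of incident triangle areas (barycentric
lumping; partitions the total area exactly). Vertex normal = angle-weighted
incident-face-normal average. Mean curvature = half the norm of the
cotangent Laplace–Beltrami of the coordinates over the barycentric area,
signed by agreement with the outward normal (convex-outward positive);
open-boundary vertices are flagged unreliable. These conventions are pinned
by analytic sphere (1/r) and cylinder (1/2r) tests at 5%. Curvature
difference is the default signed comparison (stable near zero curvature);
the ratio mode NaN-flags landmarks where the reference curvature is below
1e-6/mm.

Permutation significance permutes the RIP across individuals and recomputes
the per-landmark statistic (default: pooled-coordinate R², vectorized);
one-sided p on the statistic's magnitude, p = (1 + #{perm ≥ obs})/(B + 1).
Maps default to α = 0.001 with B = 999 in tests (configurable up; global
FSCP tests conventionally use B = 10,000).

Facial squareness projects the border landmarks to the XY plane and fits a
square (center, side, rotation) by Nelder–Mead from three rotational starts;
the score is the RMS point-to-boundary distance. The circumference proxy
slices the mesh with the plane halfway between the glabella and
top-of-forehead landmarks (normal along their connecting direction) and
returns the least-squares circle radius of the section.

## Statistics

Genotype ANOVA is one-way fixed-effects across −1/0/+1 groups with an
additive-trend regression reported alongside. AUC is the rank
(Mann–Whitney) statistic with averaged ties; curve points come from
scikit-learn. ML ancestry maximizes the dihybrid binomial log-likelihood
over q ∈ [0,1] by bounded scalar optimization (flat likelihoods return 0.5
with a warning; boundary optima are snapped exactly). Noise injection adds
c·sd(A)·N(0,1) with range clipping; a bisection helper calibrates c to a
target r² within ±0.02, making the achieved degradation, not the noise law,
the experimental knob. Misclassification flips an exact count of labels so
the design variable is free of binomial jitter.

## Problem sizes and calibration regimes

The validation experiments run at deliberately chosen scales:

* Noise/panel robustness: n = 500 individuals, 500 quasi-landmarks (20×25
  grid), 6 iterations, 50 bootstrap resamples; robustness correlations are
  averaged over 10 cohorts in the acceptance script.
* SNP-effect recovery: n = 600 with a strong ancestry axis (16 mm RMS) and
  a 3 mm SNP axis at parental-frequency difference 0.5, noise scaled to
  0.75×. The strong ancestry makes the conditioning RIPs essentially
  error-free, and the SNP's residual eigenvalue sits above the top noise
  mode, so the conditioned iteration locks onto the causal axis — the
  regime in which direction recovery is identifiable at all. Weaker SNPs
  are still *detected* (ANOVA) far below these magnitudes; only the
  direction-cosine criterion needs the strong-effect regime. Even there the
  cosine varies by cohort (roughly 0.85–0.96): RIP-G retains a small
  residual correlation (~0.1) with true ancestry through the component the
  estimated conditioning misses, and the effect-map regression amplifies
  that bleed by the dominant ancestry eigenvalue — an identifiability cap
  of response-estimated conditioning. The validation pins a seeded
  scenario; direction estimates on real data should be read with this cap
  in mind.
* Type-I calibration: null-SNP replicates at n = 200. A known limitation:
  conditioning on an *estimated* ancestry summary leaves an n-independent
  systematic residual (per-individual Procrustes rotations mix noise into
  every direction readout), so at much larger n the conditioned test
  becomes mildly anti-conservative (empirically FPR ≈ 0.14 at n = 600 and
  α = 0.05) even though it dwarfs the unconditioned test's failure
  (FPR ≈ 1.0). At n = 200 the test operates in its calibrated regime.
  Practitioners doing single-SNP inference at large n should pair the
  conditioned ANOVA with a permutation or plug-in null rather than relying
  on nominal calibration.

## Other numerical choices

* Degenerate inputs: zero-centroid configurations, constant predictors,
  single genotype groups, one-class ROC labels, and uninformative marker
  panels all raise immediately with specific messages.
* Ties and signs: PCA axis signs by largest loading; ANOVA group means
  reported per observed genotype level; rank ties averaged in AUC.
* Every stochastic routine takes a seed; one master seed per BRIM run
  drives all bootstrap streams deterministically, and identical configs
  reproduce bit-identical cohorts and RIPs.
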