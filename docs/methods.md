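# Methods

This note documents the models and procedures implemented in
`phenorosette`, the parameters that matter, the numerical choices, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Segmentation and shape descriptors

Plant tissue is separated from a dark background by color thresholding:
the RGB image is inverted, converted to HSV, and pixels whose saturation
(8-bit scale) lies in `[saturation_low, saturation_high]` are kept. The
defaults (35–255) suit green tissue on dark soil under even illumination;
they are configuration, not constants — different cameras and lighting
need re-tuning on template images, and both bounds are exposed in
`SegmentationConfig` and on the CLI.

Cleaning has two steps. A median-style outlier filter (disk footprint,
default radius 1 px) replaces pixels that deviate from their local median,
iterated to a fixed point; the iteration makes segmentation idempotent
(segmenting a rendering of its own output reproduces it exactly). The
radius trades speck removal against erosion of thin organs: radius 1
removes isolated pixels while preserving 3-px-wide inflorescence stems and
pedicels; larger radii progressively erode thin structures and are only
appropriate for compact rosettes. Components smaller than
`min_object_area_px` (default 10 px) are then dropped. Connectivity is
8-connected throughout.

Per labeled plant the descriptors are:

- **RA** — pixel count, scaled to cm² when a calibration is supplied
  (`px_per_cm = sqrt(calibrator_pixel_area / known_area_cm2)`).
- **Perim** — crack-boundary perimeter: the number of pixel edges between
  foreground and background. This convention is exact on axis-aligned
  rectangles (an n×n square has perimeter 4n) and bit-stable, which the
  test suite relies on. Its known bias is that smooth curved outlines are
  measured along axis-aligned steps: a digitized disc has crack perimeter
  ≈ 8r, so its circularity plateaus near π²/16 ≈ 0.62 rather than 1.
  Circularity values are therefore comparable between shapes measured with
  this package, but not directly against tools using polygon- or
  corner-corrected perimeter estimators.
- **Circ** = 4π·RA/Perim², clipped to ≤ 1.
- **AR, Round** — from the major/minor axis lengths of the ellipse with
  the same second central moments as the region (the standard
  particle-analysis convention); these do not involve the perimeter and
  are ≈ 1 for discs.

Regions under 3 px are skipped (second moments are undefined at that
size). Components are assigned to the pot-grid cell with the nearest
center; ties break deterministically to the lowest row, then column;
components sharing a cell are merged (overlapping plants are merged, not
resolved — there is no interactive separation mode).

## Skeleton analysis

Segmented inflorescences are thinned with a homotopy-preserving 2D
thinning (scikit-image); loops are preserved, never pruned. On the
1-px-wide skeleton:

- a pixel with ≤ 1 8-neighbors is an **end pixel**, with 2 a **slab
  pixel**, with ≥ 3 a **junction pixel**;
- 8-connected junction pixels merge into one **actual junction**; its
  degree is the number of distinct branch stubs leaving the cluster
  (counted during branch tracing, so thick crossings are well-defined);
  degree 3 = triple point, degree 4 = quadruple point;
- a **branch** is a slab path between two end/junction nodes; its length
  sums steps of 1 (orthogonal) and √2 (diagonal). A cycle attached to a
  cluster is one branch contributing two stubs; an isolated cycle is one
  branch of its full circumference; an isolated pixel is an end pixel
  forming one zero-length branch.

The nine per-plant descriptors (branches, actual junctions, end pixels,
junction pixels, slab pixels, average and maximum branch length, triple
and quadruple points) are sums over all skeleton components of the plant;
the average branch length is total length over total branches. The column
names emitted to CSV are fixed (`n_branches`, …, `max_branch_length`) and
match the predictors of the reference fruit equation.

## Predictive models and cross-validation

Families: ordinary least squares; per-predictor raw quadratic polynomials
(no cross-terms); ridge (L2) and lasso (L1) with predictors standardized
internally and coefficients reported on the original scale. When no
penalty is given it is chosen by inner 5-fold cross-validation over a
log-spaced grid (10⁻⁴–10³, 30 points); no one-standard-error rule.
Rank-deficient least-squares designs raise an error naming the aliased
columns by default; the cross-validation driver and the pipelines instead
drop aliased columns with a log message (the behavior of pivoting
least-squares implementations), which matters because the nine skeleton
descriptors are exactly collinear on single-component loop-free skeletons
(branches = ends + junctions − 1; triple + quadruple = junctions).

The accuracy protocol: per permutation the rows are shuffled once; the
first `s` rows train the model and the last `holdout_size` rows (disjoint
by construction) are scored. Accuracy is the **squared Pearson
correlation** between observed and predicted holdout values — not
1 − SSE/SST; the two differ for biased predictions, and the correlation
form is deliberately insensitive to affine miscalibration. Means and
2.5/97.5 percentiles are aggregated across permutations (default 100),
all reproducible from one seed. Defaults: 100-plant holdout; a
300-individual final-test mode is available by setting `holdout_size`.

Stepwise selection is bidirectional AIC descent from the full additive
model (`AIC = n·ln(RSS/n) + 2k` up to constants), scanning candidate
drops/adds in column order for determinism; the result never has higher
AIC than the full model.

The two shipped reference equations store the published coefficients
exactly; the dry-mass model's metadata records its assumed units (grams,
RA in cm² — inferred from coefficient magnitudes, since mass elsewhere in
the protocol is reported in mg).

## Logistic growth model

`M(t) = A / (1 + exp((t_inf − t)/B))`. **A is fixed to the dry mass
measured at maturity** — the central identifiability choice: with short,
noisy series the asymptote and steepness are poorly jointly identified,
and the destructive final measurement is the better estimate of A. Only
(B, t_inf) are fitted, by trust-region nonlinear least squares with
B > 0 enforced; initialization takes t_inf from the interpolated first
crossing of A/2 and B from the slope of logit(M/A) against t; convergence
at relative RSS change < 1e−10, at most 500 function evaluations
(non-convergence returns the best iterate, flagged). Observations below
1% of A are retained; the growth-start rule already trims pre-growth days.

The growth start t0 of each plant is the earliest day its size reaches
the size of the largest plant measured on the common first day, which
normalizes trajectories across germination speeds; plants never reaching
the threshold are excluded with a warning. The rule operates on whatever
size column is supplied (projected area or estimated mass) — the
threshold is defined by ranking, so any monotone size proxy serves.
Duration = maturity day − t0.

Derived quantities are exact closed forms of the fit: `r = 1/B`,
`GR(t) = r·M(1 − M/A)`, `RGR(t) = r·(1 − M/A)` in day⁻¹ (multiply by 1000
for mg g⁻¹ day⁻¹, the reporting convention of the growth pipeline CSV),
and at the inflection `M = A/2`, `GR = r·A/4`, `RGR = r/2`.

## Heritability

One-way random-effects model `y_ik = μ + G_i + e_ik` with genotype as the
only random factor (tray/position effects are out of scope). The Gibbs
sampler uses conjugate updates for genotype effects, the grand mean (flat
prior) and both variances, with weakly-informative inverse-gamma(0.001,
0.001) priors; chain settings 13000 iterations, 3000 burn-in, thinning 10
(1000 retained samples) mirror the customary defaults of Bayesian
mixed-model software. The point estimate is the **posterior mean of the
per-sample ratio** σ_G²/(σ_G² + σ_E²) — not the ratio of posterior means,
which differs — with the central 95% interval from the same samples. The
ANOVA cross-check uses σ_G² = (MS_between − MS_within)/k̄ with k̄ the mean
replicate count, truncated at zero and flagged; it assumes balanced or
near-balanced designs. The inverse-gamma priors are not exactly
scale-free, so H² is invariant to affine trait transforms only up to a
small prior effect (≲ 0.02 at realistic sample sizes); the ANOVA
estimator is exactly invariant.

## Synthetic data: what it emulates, and what it does not

The generators define the test conditions end to end. Rosettes are radial
green ellipses on dark soil — they reproduce the segmentation geometry
(compact green objects, pot grid, occasional empty pots) but not leaf
occlusion, specular highlights, moss, or color gradients, so passing
segmentation tests demonstrates correctness of the thresholding/labeling
machinery, not robustness to difficult field images. Inflorescences are
3-px-thick stems with up to three 45° side branches and one short lateral
stub per fruit, attachments ≥ 7 px apart; by construction each fruit
yields exactly one skeleton triple point, which is what makes fruit number
learnable from junction counts — real inflorescences violate this when
pedicels overlap or cross, so the synthetic r² (≈ 99%) is an upper bound
on what real images give (the protocol's validated regime on real plants
is > 90%). Mass series use multiplicative (CV-parameterized) Gaussian
noise, matching how biological mass error scales; trait tables use
additive Gaussian components. Every generator is bit-deterministic given
its seed and returns its ground truth for independent verification.

Problem sizes in the test suite and acceptance script (400-row dry-mass
tables, 300 inflorescence images, 200 growth-recovery replicates,
100-dataset coverage checks with shortened 4000-iteration chains) were
chosen as the smallest sizes at which the Monte-Carlo error is well below
the tolerances being checked.

## Known limitations

- No interactive separation of overlapping rosettes (merged per cell and
  flagged by the assignment); no leaf-level segmentation or counting.
- Crack-boundary circularity is not comparable with corner-corrected
  estimators (see above).
- 2D skeletons only; no branch angles, internodes, or silique-level
  instance segmentation.
- Single growth law (logistic); no Gompertz/power-law alternatives and no
  mixed-effects joint fitting across individuals.
- Broad-sense heritability only; no kinship/marker-based models.
- Reference equations are only valid for imaging setups matching their
  training calibration (units, resolution); retrain on local data
  otherwise.
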