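# phenorosette

Image-based phenotyping of rosette plants (*Arabidopsis thaliana* and other
rosette-forming species) from low-cost top-view photography. The package
estimates two traits that are otherwise expensive to measure at scale —
**biomass accumulation** (and relative growth rate through the life cycle)
and **fruit number** (a fitness proxy) — and quantifies how much of their
variation is genetic.

It is written for experimentalists running tray- or pot-based phenotyping:
a small *training* subset of plants is sacrificed (weighed, or its fruits
hand-counted), a predictive model is trained and validated by
cross-validation, and the trait is then estimated non-destructively for the
whole *focal* population from images alone.

## What it computes

**Rosette shape descriptors.** Tray/pot images are segmented by saturation
thresholding of the inverted RGB image (default band 35–255, configurable —
thresholds depend on light conditions), despeckled, and labeled per pot.
Per plant, the five descriptors are measured: projected rosette area RA,
crack-boundary perimeter, circularity `Circ = 4π·RA/Perim²`, aspect ratio
`AR = major/minor axis` of the moment-equivalent ellipse, and roundness
`Round = 4·RA/(π·major²)`. A surface calibrator converts px → cm.

**Dry mass.** Linear, per-predictor quadratic, ridge and lasso models map
descriptors to measured dry mass. Accuracy is assessed with the
cross-validation protocol (disjoint train/holdout draws across 100 random
permutations per training size; accuracy = squared Pearson correlation r²
between observed and predicted on the holdout). A stepwise-AIC-selected
reference equation ships with the package:

    rosette DM (g) = −0.00133 + 0.00134·RA + 0.00274·Circ      (RA in cm²)

**Fruit number.** Harvested inflorescences are skeletonized; each skeleton
pixel is classified by its 8-neighbor count (end / slab / junction),
adjacent junction pixels are merged into *actual junctions* whose degree
(3 = triple point, 4 = quadruple point) is the number of branch stubs, and
slab paths are traced into branches with a diagonal-aware length metric.
The nine per-plant descriptors feed the models; the shipped reference
equation is

    fruit number = 0.181·n_actual_junctions + 0.003·n_slab_pixels + 0.226·n_triple_points

**Growth dynamics.** Per individual, mass over time follows the
three-parameter logistic `M(t) = A / (1 + exp((t_inf − t)/B))` with A fixed
to the dry mass measured at maturity; B and t_inf are fitted by nonlinear
least squares. Derived dynamics: `GR(t) = r·M·(1 − M/A)` with `r = 1/B`,
`RGR(t) = r·(1 − M/A)`, and the inflection-point traits `M(t_inf) = A/2`,
`GR(t_inf) = r·A/4`, `RGR(t_inf) = r/2`.

**Heritability.** For genotype/replicate trait tables, the one-way
random-effects model `y_ik = μ + G_i + e_ik` gives broad-sense heritability
`H² = σ_G²/(σ_G² + σ_E²)`, estimated with a conjugate Gibbs sampler
(inverse-gamma(0.001, 0.001) priors, 13000 iterations) and cross-checked by
the ANOVA moment estimator.

**Synthetic data.** Every stage has a seed-deterministic generator with
ground truth: rosette/tray images with known pixel areas, inflorescence
images in which every fruit is a lateral stub that becomes exactly one
skeleton triple point, logistic mass series, calibrated descriptor tables,
and trait tables with known variance components. The whole pipeline is
therefore testable end to end without any external dataset.

## Worked example

`examples/` holds one short script per capability. Fitting growth dynamics
(`python examples/03_growth_dynamics.py`):

```
true  B = 4.000 d,  t_inf = 18.00 d
fitted B = 3.936 d,  t_inf = 17.96 d (r = 1/B = 0.2541 per day, converged=True)
M(t_inf)   = 60.0 mg   (half the final mass)
GR(t_inf)  = 7.62 mg/day (maximal growth rate)
RGR(t_inf) = 127 mg g^-1 day^-1
```

The fitted steepness B and inflection day t_inf recover the generating
values from a 5%-noise series; the inflection traits follow in closed form
— mass is half the final mass, absolute growth rate is at its maximum
r·A/4, and relative growth rate has declined to half its early-life
maximum r.

Estimating heritability (`python examples/04_heritability.py`):

```
true H^2          = 0.750
MCMC posterior    = 0.757  (95% CI 0.716-0.796, 1000 samples)
ANOVA moments     = 0.758
```

A command-line interface wraps the same functions for shell use:

```bash
phenorosette simulate inflorescence out/ --n 5 --fruits 20 --seed 1
phenorosette measure-skeletons out/ skeletons.csv
phenorosette h2 traits.csv --method mcmc --seed 1
phenorosette pipeline dry-mass trays/ results/ --grid-rows 2 --grid-cols 3
```

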