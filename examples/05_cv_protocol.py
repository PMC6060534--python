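"""Cross-validated prediction accuracy versus training population size.

Generates a descriptor table calibrated to the reference dry-mass
equation with 5% multiplicative noise, then sweeps training sizes for the
linear and ridge families: each point is the mean squared Pearson
correlation between observed and predicted mass on a disjoint 100-plant
holdout, across 100 random permutations.
"""

from phenorosette import models, synthetic
from phenorosette.models import CVConfig, cross_validate

ref = models.reference_dry_mass_model()
table, _ = synthetic.gen_training_table(
    400,
    ref.coefficients,
    noise_cv=0.05,
    predictor_ranges={"RA": (1, 20), "Circ": (0.3, 0.9)},
    intercept=ref.intercept,
    seed=1,
)
result = cross_validate(
    table[["RA", "Circ"]],
    table.response,
    families=["linear", "ridge"],
    cfg=CVConfig(
        training_sizes=[10, 20, 60, 150],
        n_permutations=100,
        holdout_size=100,
        seed=1,
    ),
)
print(result.table.to_string(index=False))
print(
    "\nmean_r2 is the holdout prediction accuracy; with ~60 training "
    "plants the simple linear model already explains >90% of the "
    "variance, matching the accuracy regime this protocol is designed "
    "to verify before a model is applied to the unharvested population."
)
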