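"""Area-adjusted k-fold cross-validation of a seasonal model.

Whole birds are withheld (~20% of used locations per fold), the model is
refit, and the withheld locations are binned by predicted relative
probability.  The area-adjusted frequency of a bin is its share of withheld
use divided by its share of the mapped area: flat near 1 for an uninformative
model, increasing with bin rank for a good one.  The Spearman correlation
between bin rank and adjusted frequency (r_s) and the used-vs-available rank
AUC summarize each fold.
"""

from sagersf.covariates import extract_covariates
from sagersf.design import build_design
from sagersf.fitting import assign_available_groups
from sagersf.synthetic import (STUDY_INTERVAL, DEFAULT_TRUTH, LandscapeConfig,
                               generate_energy_field, generate_landscape,
                               simulate_telemetry)
from sagersf.validation import cross_validate

landscape = generate_landscape(LandscapeConfig(shape=(110, 110)), seed=7)
energy = generate_energy_field(landscape, n_wells=16, n_clusters=2, seed=8)
telemetry = simulate_telemetry(landscape, energy, DEFAULT_TRUTH,
                               n_birds=30, relocations_per_bird=90, seed=9)
design, _ = build_design(telemetry, landscape.extent,
                         n_available={"breeding": 2500, "summer": 100,
                                      "winter": 100}, seed=11)
sub = design[design.season == "breeding"].reset_index(drop=True)
table = extract_covariates(sub, 150.8, landscape, energy=energy,
                           study_interval=STUDY_INTERVAL)
table = assign_available_groups(table, seed=11)

result = cross_validate(table, list(DEFAULT_TRUTH.coefficients), k=5, seed=13)
print(result.folds.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\naverage r_s = {result.average_rs:.3f}   "
      f"average AUC = {result.average_auc:.3f}   "
      f"full-data AUC = {result.full_auc:.3f}")
print("r_s near 1: withheld birds use high-ranked habitat far above its "
      "areal share - the map generalizes across individuals")
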