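"""Model-averaged relative-probability habitat map.

Every model in the 95% cumulative-weight set is turned into a wall-to-wall
surface (moving-window covariates at the season's buffer radius, logistic of
the fixed-effects linear predictor), and the surfaces are averaged with the
renormalized Akaike weights.  Values are relative probabilities of presence
in [0, 1], read ordinally: higher = better breeding habitat.
"""

from pathlib import Path

import numpy as np

from sagersf.covariates import extract_covariates
from sagersf.design import build_design
from sagersf.fitting import assign_available_groups, fit_all_subsets
from sagersf.surfaces import model_averaged_surface
from sagersf.synthetic import (STUDY_INTERVAL, DEFAULT_TRUTH, LandscapeConfig,
                               generate_energy_field, generate_landscape,
                               simulate_telemetry)

landscape = generate_landscape(LandscapeConfig(shape=(100, 100)), seed=7)
energy = generate_energy_field(landscape, n_wells=16, n_clusters=2, seed=8)
telemetry = simulate_telemetry(landscape, energy, DEFAULT_TRUTH,
                               n_birds=18, relocations_per_bird=80, seed=9)
design, _ = build_design(telemetry, landscape.extent,
                         n_available={"breeding": 1200, "summer": 100,
                                      "winter": 100}, seed=11)
sub = design[design.season == "breeding"].reset_index(drop=True)
table = extract_covariates(sub, 150.8, landscape, energy=energy,
                           study_interval=STUDY_INTERVAL)
table = assign_available_groups(table, seed=11)

model_set = fit_all_subsets(table, ["sagebrush", "sagebrush_grassland",
                                    "dist_water"], season="breeding")
surface = model_averaged_surface(model_set, landscape, radius_m=150.8,
                                 energy=energy)

vals = surface.values
print(f"breeding surface on a {vals.shape[0]}x{vals.shape[1]} grid")
print(f"  range  [{vals.min():.3f}, {vals.max():.3f}]  mean {vals.mean():.3f}")
print("  contributing models (renormalized weight):")
for formula, w in surface.provenance:
    print(f"    {w:6.3f}  {formula}")

sage = landscape.vegetation.values == landscape.code_of("sagebrush")
print(f"\nmean relative probability in sagebrush cells: {vals[sage].mean():.3f}")
print(f"                        elsewhere:             {vals[~sage].mean():.3f}")

out = Path("scratch")
out.mkdir(exist_ok=True)
surface.grid.to_ascii(out / "surface_breeding.asc")
print(f"\nwrote {out / 'surface_breeding.asc'} (ESRI ASCII grid)")
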