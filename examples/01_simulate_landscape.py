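"""Generate a synthetic sagebrush basin with energy development.

Builds the landscape stack (vegetation mosaic, elevation, NDVI, streams) and a
clustered well field with access roads, then prints the realized composition.
The class shares mirror the availability-side composition of a semi-arid
sagebrush basin; wells concentrate in a few compact fields, as oil/gas
development does in practice.
"""

import numpy as np

from sagersf.layers import CLASS_CODES
from sagersf.synthetic import (LandscapeConfig, generate_energy_field,
                               generate_landscape)

landscape = generate_landscape(LandscapeConfig(shape=(120, 120)), seed=7)
energy = generate_energy_field(landscape, n_wells=24, n_clusters=2, seed=8)

veg = landscape.vegetation.values
print("landscape: %d x %d cells of %.0f m" % (*veg.shape, landscape.vegetation.cell))
for code, name in CLASS_CODES.items():
    share = float((veg == code).mean())
    print(f"  {name:<20s} {share:6.1%}")
print(f"streams: {len(landscape.streams)}  wells: {len(energy.wells)}  "
      f"oil/gas roads: {len(energy.oil_roads)}")
print(f"development index range: 0 to {energy.dev_index.values.max():.2f} "
      "(0 = none, 2 = densest wells and roads)")
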