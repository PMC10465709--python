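#!/usr/bin/env python
"""Generate the synthetic inputs used throughout the analysis: a seeded
irregular inter-cellular-space mask, planted hexagonal lattices with known
ground truth, and a five-time-point protein abundance table.

Outputs under results/inputs/.
"""

from pathlib import Path

import numpy as np

from fibrilpfc import GridSpec
from fibrilpfc.io import write_mask
from fibrilpfc.synthetic import (
    SyntheticAbundanceSpec,
    SyntheticDomainSpec,
    gen_abundance_table,
    gen_domain_mask,
    gen_hex_lattice,
    plant_defects,
)

OUT = Path("results/inputs")
OUT.mkdir(parents=True, exist_ok=True)

# --- domain mask: lobed blob ~880 nm across at 10 nm/px -------------------
grid = GridSpec(112, 112, dx=10.0)
mask = gen_domain_mask(grid, SyntheticDomainSpec(420.0, 0.30, 8, seed=1))
write_mask(mask, OUT / "domain_mask.png")
print(
    f"domain mask: {mask.n_inside} px inside "
    f"({mask.area_nm2 / 1e6:.3f} um^2), single component, "
    f"written to {OUT/'domain_mask.png'}"
)

# --- planted lattices with oracle ground truth ----------------------------
lattices = {
    "lattice_perfect": gen_hex_lattice(60.0, 420.0, jitter_sd=0.0, seed=0),
    "lattice_jittered": gen_hex_lattice(60.0, 420.0, jitter_sd=4.8, seed=3),
}
lattices["lattice_vacancy"] = plant_defects(
    gen_hex_lattice(60.0, 420.0, jitter_sd=0.6, seed=12), vacancies=1, seed=5
)
for name, lat in lattices.items():
    path = OUT / f"{name}.csv"
    with open(path, "w") as fh:
        fh.write("x_nm,y_nm,neighbor_count\n")
        for (x, y), c in zip(lat.points, lat.ground_truth_neighbor_counts):
            fh.write(f"{x!r},{y!r},{c}\n")
    print(
        f"{name}: {lat.n} points, ground-truth defect proportion "
        f"{lat.defect_proportion():.3f} -> {path}"
    )

# --- abundance table -------------------------------------------------------
out = gen_abundance_table(
    SyntheticAbundanceSpec(n_proteins=500, noise_cv=0.2, missing_rate=0.1, seed=2)
)
out.table.to_csv(OUT / "abundance.csv")
out.trends.to_csv(OUT / "abundance_trends.csv")
n_missing = int(out.table.isna().sum().sum())
print(
    f"abundance table: {len(out.table)} proteins x 5 time points, "
    f"{n_missing} missing cells -> {OUT/'abundance.csv'}"
)
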