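#!/usr/bin/env python
"""Geography of threat: clumping and its (non-)drivers on the cell grid.

Moran's I of richness-corrected mean threat (is threat spatially clumped
beyond what richness explains?), then spatially corrected Pearson
correlations of threat with habitat impact (generated independently, so the
expected answer is "no association") and with mean diversification rate
(coupled by construction, so the expected answer is "yes").
"""

import json
from pathlib import Path

import pandas as pd

from caperisk.spatial import (SpatialGrid, clifford_corrected_correlation,
                              lattice_weights, morans_i,
                              richness_corrected_threat)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    grid = SpatialGrid(pd.read_csv(ROOT / "data" / "grid.csv"))
    w = lattice_weights(grid.coords, scheme="queen")
    resid = richness_corrected_threat(grid)
    moran = morans_i(resid, w, n_perm=999, seed=1)
    print(f"Moran's I of richness-corrected threat = {moran['I']:.3f} "
          f"(z = {moran['z']:.2f}, p = {moran['p']:.2g})")

    threat = grid.cells["mean_threat"].to_numpy(float)
    habitat = grid.cells["habitat_index"].to_numpy(float)
    rate = grid.cells["mean_div_rate"].to_numpy(float)
    hab = clifford_corrected_correlation(threat, habitat, grid.coords)
    div = clifford_corrected_correlation(threat, rate, grid.coords)
    print(f"threat vs habitat impact:    r = {hab['r']:+.3f}, "
          f"n_eff = {hab['n_eff']:.1f}, p = {hab['p']:.3g}")
    print(f"threat vs diversification:   r = {div['r']:+.3f}, "
          f"n_eff = {div['n_eff']:.1f}, p = {div['p']:.3g}")
    (ROOT / "spatial.json").write_text(json.dumps(
        {"moran_threat_richness_corrected": moran,
         "threat_vs_habitat": hab, "threat_vs_diversification": div},
        indent=2, default=float) + "\n")


if __name__ == "__main__":
    main()
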