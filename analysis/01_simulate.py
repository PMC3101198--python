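#!/usr/bin/env python
"""Generate the synthetic study dataset every later stage consumes.

Writes a species Red List table, genus summaries, species-level trees for a
subset of genera, a quarter-degree-style grid of cell aggregates, and a
paired pair of Red List snapshots, all under results/data/.
"""

from pathlib import Path

from caperisk.redlist import is_threatened
from caperisk.synthetic import (SimulationConfig, synth_cape_like_dataset,
                                write_dataset)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2026


def main():
    cfg = SimulationConfig(seed=SEED)
    data = synth_cape_like_dataset(cfg)
    paths = write_dataset(data, OUT)
    n_threat = sum(is_threatened(r.category) for r in data["species"])
    print(f"simulated {cfg.n_genera} genera, {len(data['species'])} listed "
          f"species ({n_threat} threatened), {len(data['genus_trees'])} "
          f"species-level trees, {len(data['grid'])} grid cells")
    print(f"wrote {len(paths)} files under {OUT}")


if __name__ == "__main__":
    main()
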