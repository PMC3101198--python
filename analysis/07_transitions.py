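#!/usr/bin/env python
"""Are the most threatened genera still deteriorating fastest?

Pairs the two simulated Red List snapshots, sums per-species +1/-1 status
changes within genera, and runs the tertile G-test: species transitions
pooled within the top vs bottom third of genera ranked by old-snapshot
threat, testing the top tertile's increase:non-increase counts against the
bottom tertile's proportions.
"""

import json
from pathlib import Path

import pandas as pd

from caperisk.redlist import (read_species_csv, status_change_index,
                              status_transitions, tertile_transition_gtest)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    old = read_species_csv(ROOT / "data" / "snapshot_old.csv")
    new = read_species_csv(ROOT / "data" / "snapshot_new.csv")
    index, pairing = status_change_index(old, new)
    pd.DataFrame(sorted(index.items()), columns=["genus", "change_index"]) \
        .to_csv(ROOT / "change_index.csv", index=False)
    print(f"{pairing['n_shared']} species shared between snapshots "
          f"({pairing['n_only_old']} dropped, {pairing['n_only_new']} added)")

    transitions, _ = status_transitions(old, new)
    genus_of = {r.species_name: r.genus for r in old}
    res = tertile_transition_gtest(transitions, genus_of)
    top, bot = res["top_counts"], res["bottom_counts"]
    print(f"increase:non-increase = {top[0]}:{top[1]} (top tertile) vs "
          f"{bot[0]}:{bot[1]} (bottom tertile)")
    print(f"G = {res['G']:.2f}, p = {res['p']:.3g} -> the most threatened "
          f"genera deteriorate fastest" if res["p"] < 0.05 else
          f"G = {res['G']:.2f}, p = {res['p']:.3g} -> no tertile contrast")
    (ROOT / "transitions.json").write_text(json.dumps(res, indent=2) + "\n")


if __name__ == "__main__":
    main()
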