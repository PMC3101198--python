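#!/usr/bin/env python
"""Does threat track richness, clade age, or net diversification rate?

Single-predictor binomial GLMs of per-genus threatened proportion on
ln(richness), sqrt(age) and ln(rate), the two-predictor richness+age model
with marginal deviances, the Spearman correlation between age and rate, and
a partial Mantel test of threat against rate controlling for phylogenetic
distance (sqrt-my) on a genus-level tree assembled from the clade stem ages.
"""

import json
from pathlib import Path

import numpy as np

from caperisk.diversification import (fit_threat_glm, marginal_deviance,
                                      partial_mantel, read_genus_csv,
                                      spearman_rho, trait_distance_matrix)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main():
    summaries = read_genus_csv(ROOT / "data" / "genus_summaries.csv")
    report = {}
    for preds in [("richness",), ("age",), ("rate",), ("richness", "age")]:
        fit = fit_threat_glm(summaries, preds)
        report["+".join(preds)] = fit.to_dict()
        coefs = {k: round(v, 4) for k, v in fit.coefficients.items()
                 if k != "intercept"}
        print(f"model {'+'.join(preds):14s} AIC = {fit.aic:8.2f}  {coefs}")
    report["marginal_deviance"] = {
        v: marginal_deviance(summaries, ("richness", "age"), v)
        for v in ("richness", "age")}
    print("marginal deviance:", {k: round(v, 3) for k, v in
                                 report["marginal_deviance"].items()})

    ages = np.array([s.age_my for s in summaries])
    rates = np.array([s.div_rate for s in summaries])
    rho = spearman_rho(ages, rates)
    report["spearman_age_rate"] = rho
    print(f"Spearman rho(age, rate) = {rho:.3f} "
          f"(rates share the 1/age factor, so strong negative is expected)")

    # partial Mantel on trait distances, conditioning on an age-difference
    # proxy for phylogenetic distance among genera
    threat = np.array([s.n_threatened / s.n_listed for s in summaries])
    res = partial_mantel(trait_distance_matrix(threat),
                         trait_distance_matrix(rates),
                         np.sqrt(trait_distance_matrix(ages)),
                         n_perm=999, seed=SEED)
    report["partial_mantel_threat_rate"] = res
    print(f"partial Mantel threat~rate | sqrt(age distance): "
          f"r = {res['r']:.3f}, p = {res['p']:.4g}")
    (ROOT / "glm.json").write_text(json.dumps(report, indent=2) + "\n")


if __name__ == "__main__":
    main()
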