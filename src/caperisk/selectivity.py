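"""Randomization tests for taxonomic selectivity of extinction risk.

The question: are threatened species spread evenly across higher taxa
(families, orders, classes), or concentrated in some of them?  The test
statistic is the variance across taxa of the proportion of threatened
species; its null distribution comes from randomizing species membership
among taxa while holding each taxon's species count fixed (equivalently,
shuffling threat labels over species).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .redlist import SpeciesThreatRecord, is_threatened

__all__ = [
    "TaxonPartition",
    "threat_proportion_by_taxon",
    "selectivity_test",
    "flag_extreme_taxa",
    "partition_from_records",
]


@dataclass
class TaxonPartition:
    """Species grouped into disjoint higher taxa with binary threat labels."""

    taxa: dict[str, list[tuple[str, bool]]]  # taxon -> [(species, threatened)]
    level: str = "family"

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.taxa.items():
            if not members:
                raise ValueError(f"taxon {name!r} is empty")
            for sp, _ in members:
                if sp in seen:
                    raise ValueError(f"species {sp!r} appears in more than one taxon")
                seen.add(sp)

    @property
    def taxon_names(self) -> list[str]:
        return sorted(self.taxa)

    def sizes(self) -> np.ndarray:
        return np.array([len(self.taxa[t]) for t in self.taxon_names])

    def threat_labels(self) -> np.ndarray:
        """Flat boolean vector, species blocked by taxon (sorted taxon order)."""
        return np.concatenate([
            np.array([thr for _, thr in self.taxa[t]], dtype=bool)
            for t in self.taxon_names
        ])


def partition_from_records(records: list[SpeciesThreatRecord],
                           level: str = "family") -> TaxonPartition:
    """Group a species table by one taxonomic level (family or order)."""
    if level not in ("family", "order"):
        raise ValueError(f"unsupported level {level!r}")
    taxa: dict[str, list[tuple[str, bool]]] = {}
    for r in records:
        taxon = getattr(r, level)
        taxa.setdefault(taxon, []).append((r.species_name, is_threatened(r.category)))
    return TaxonPartition(taxa, level=level)


def threat_proportion_by_taxon(partition: TaxonPartition) -> tuple[dict[str, float], float]:
    """Per-taxon proportion of threatened species, plus the species-level
    global mean proportion (the reference line for enrichment displays)."""
    props = {
        t: float(np.mean([thr for _, thr in partition.taxa[t]]))
        for t in partition.taxon_names
    }
    labels = partition.threat_labels()
    return props, float(labels.mean())


def _per_taxon_proportions(labels: np.ndarray, starts: np.ndarray,
                           sizes: np.ndarray) -> np.ndarray:
    sums = np.add.reduceat(labels.astype(float), starts)
    return sums / sizes


def _check_preconditions(partition: TaxonPartition) -> None:
    if len(partition.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    labels = partition.threat_labels()
    if labels.all() or not labels.any():
        raise ValueError(
            "degenerate input: need at least one threatened and one "
            "non-threatened species overall"
        )


def selectivity_test(partition: TaxonPartition, n_rand: int = 1000,
                     seed: int | None = None, weighted: bool = False) -> dict:
    """Test for uneven spread of threat across taxa.

    statistic: variance (unweighted by default; ``weighted=True`` weights taxa
    by species count) of per-taxon threatened proportions.  p is the fraction
    of label randomizations reaching at least the observed variance, with the
    (count+1)/(n_rand+1) convention.
    """
    _check_preconditions(partition)
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    sizes = partition.sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    labels = partition.threat_labels()
    w = sizes / sizes.sum() if weighted else None

    def statistic(lab: np.ndarray) -> float:
        props = _per_taxon_proportions(lab, starts, sizes)
        if w is None:
            return float(np.var(props))
        mu = float(props @ w)
        return float(((props - mu) ** 2) @ w)

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    count = 0
    n_threatened = int(labels.sum())
    for _ in range(n_rand):
        perm = rng.permutation(labels)
        # randomization keeps taxon sizes and the global threat count intact
        assert perm.sum() == n_threatened
        if statistic(perm) >= obs:
            count += 1
    return {
        "statistic": obs,
        "p": (count + 1) / (n_rand + 1),
        "n_rand": n_rand,
        "weighted": weighted,
    }


def flag_extreme_taxa(partition: TaxonPartition, n_rand: int = 1000,
                      seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon enrichment/depletion flags from the same randomization.

    For each taxon, p_high is the fraction of randomizations whose proportion
    reaches the observed one ((count+1)/(n+1) convention), p_low the mirror.
    No multiple-testing correction is applied.
    """
    _check_preconditions(partition)
    sizes = partition.sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    labels = partition.threat_labels()
    obs = _per_taxon_proportions(labels, starts, sizes)
    rng = np.random.default_rng(seed)
    ge = np.zeros(len(sizes), dtype=int)
    le = np.zeros(len(sizes), dtype=int)
    for _ in range(n_rand):
        props = _per_taxon_proportions(rng.permutation(labels), starts, sizes)
        ge += props >= obs - 1e-12
        le += props <= obs + 1e-12
    p_high = (ge + 1) / (n_rand + 1)
    p_low = (le + 1) / (n_rand + 1)
    flag = np.where(p_high <= alpha, "enriched",
                    np.where(p_low <= alpha, "depleted", ""))
    return pd.DataFrame({
        "taxon": partition.taxon_names,
        "n": sizes,
        "proportion": obs,
        "p_high": p_high,
        "p_low": p_low,
        "flag": flag,
    })
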