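"""Synthetic datasets with the statistical structure the analyses assume.

Nothing here imitates the real Cape flora; the generators produce inputs
whose *mechanisms* match the modelling assumptions — birth–death trees,
peripatric range-size evolution, range-threshold Red List categories,
family-level clustering of threat, spatially autocorrelated cell fields,
and paired Red List snapshots in which already-threatened genera
deteriorate faster — so every pipeline stage can run and be calibrated
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .diversification import GenusSummary, write_genus_csv
from .dtt import PunctuatedParams, simulate_punctuated
from .phylo import PhyloTree, _from_nested, write_newick
from .redlist import (SpeciesThreatRecord, ThreatCategory, is_threatened,
                      threat_score, write_species_csv)
from .spatial import SpatialGrid

__all__ = [
    "SimulationConfig",
    "simulate_birth_death_tree",
    "assign_categories_from_range",
    "simulate_glm_dataset",
    "smoothed_field",
    "synth_cape_like_dataset",
    "write_dataset",
]


# ----------------------------------------------------------- birth-death

def simulate_birth_death_tree(birth_rate: float, death_rate: float = 0.0,
                              n_tips: int | None = None,
                              duration: float | None = None,
                              seed: int | None = None, rng=None,
                              max_retries: int = 100) -> PhyloTree:
    """Forward-time birth–death tree of extant tips (extinct lineages pruned).

    Simulation starts from the two crown lineages at time 0, so under pure
    birth the expected tip count after duration t is 2*exp(birth_rate*t).
    Exactly one of ``n_tips`` / ``duration`` sets the stopping rule.  With
    ``n_tips`` the simulation stops when the extant count first reaches the
    target and the tree is cut at a random point before the next event, so
    terminal branches stay positive.  Whole-clade extinction triggers a
    retry, up to ``max_retries``.
    """
    if birth_rate <= 0 or death_rate < 0:
        raise ValueError("need birth_rate > 0 and death_rate >= 0")
    if (n_tips is None) == (duration is None):
        raise ValueError("specify exactly one of n_tips or duration")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng

    for _ in range(max_retries):
        tree = _bd_attempt(birth_rate, death_rate, n_tips, duration, rng)
        if tree is not None:
            return tree
    raise RuntimeError(
        f"clade went extinct in all {max_retries} attempts; lower death_rate"
    )


def _bd_attempt(lam, mu, n_tips, duration, rng) -> PhyloTree | None:
    # lineage records: parent index, birth time, death time (None = extant)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    death: list[float | None] = [0.0, None, None]  # root splits immediately
    extant = [1, 2]
    t = 0.0
    while True:
        k = len(extant)
        if k == 0:
            return None
        if n_tips is not None and k >= n_tips:
            # cut uniformly inside the waiting time to the next event
            t += rng.exponential(1.0 / ((lam + mu) * k)) * rng.uniform(0.2, 0.8)
            break
        wait = rng.exponential(1.0 / ((lam + mu) * k))
        if duration is not None and t + wait >= duration:
            t = duration
            break
        t += wait
        idx = extant[rng.integers(k)]
        if rng.uniform() < lam / (lam + mu):
            death[idx] = t
            for _ in range(2):
                parent.append(idx)
                birth.append(t)
                death.append(None)
            extant.remove(idx)
            extant.extend([len(parent) - 2, len(parent) - 1])
        else:
            death[idx] = t
            extant.remove(idx)
    if len(extant) < 2:
        return None
    end = {i: t for i in extant}

    children: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(i)

    def survives(i: int) -> bool:
        if death[i] is None:
            return True
        return any(survives(c) for c in children.get(i, []))

    label = iter(f"t{j}" for j in range(1, len(extant) + 1))

    def build(i: int, stem_start: float):
        stop = end.get(i, death[i])
        kids = [c for c in children.get(i, []) if death[c] is None or survives(c)]
        if death[i] is None:  # extant tip
            return (next(label), stop - stem_start, [])
        if len(kids) == 2:
            return ("", stop - stem_start, [build(c, stop) for c in kids])
        if len(kids) == 1:  # suppress unifurcation left by pruning
            return build(kids[0], stem_start)
        return None

    nested = build(0, 0.0)
    if nested is None or not nested[2]:
        return None
    tree = _from_nested(nested)
    return tree if tree.n_tips >= 2 else None


# ------------------------------------------------------------- categories

def assign_categories_from_range(qds_counts, thresholds=(1, 3, 10),
                                 nt_threshold: int | None = None) -> list[ThreatCategory]:
    """Map range sizes (occupied QDS counts) to Red List categories.

    ``thresholds`` = (t_CR, t_EN, t_VU), strictly increasing: a count at or
    below t_CR is CR, at or below t_EN is EN, at or below t_VU is VU; larger
    counts are LC, or NT when an optional ``nt_threshold`` band applies.
    Category severity is non-increasing in range size by construction.
    """
    t_cr, t_en, t_vu = thresholds
    if not (t_cr < t_en < t_vu):
        raise ValueError("thresholds must be strictly increasing (t_CR < t_EN < t_VU)")
    if nt_threshold is not None and nt_threshold <= t_vu:
        raise ValueError("nt_threshold must exceed t_VU")
    out = []
    for c in qds_counts:
        if c <= t_cr:
            out.append(ThreatCategory.CR)
        elif c <= t_en:
            out.append(ThreatCategory.EN)
        elif c <= t_vu:
            out.append(ThreatCategory.VU)
        elif nt_threshold is not None and c <= nt_threshold:
            out.append(ThreatCategory.NT)
        else:
            out.append(ThreatCategory.LC)
    return out


# -------------------------------------------------------------- GLM truth

def simulate_glm_dataset(n_genera: int = 200, beta_age: float = -0.5,
                         beta_rate: float = 0.0, intercept: float = 1.0,
                         seed: int | None = None) -> list[GenusSummary]:
    """Genus summaries with a planted logit-linear threat model.

    logit(p_threatened) = intercept + beta_age*sqrt(age) + beta_rate*ln(rate);
    richness and age are drawn independently (log-uniform 2..200 species,
    uniform 1..40 my), so any age–rate association in the output comes from
    the shared 1/age factor, as in the field definition of the rate.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_genera):
        n = int(round(math.exp(rng.uniform(math.log(2), math.log(200)))))
        age = rng.uniform(1.0, 40.0)
        rate = math.log(n) / age
        eta = intercept + beta_age * math.sqrt(age)
        if beta_rate and rate > 0:
            eta += beta_rate * math.log(rate)
        p = 1.0 / (1.0 + math.exp(-eta))
        listed = max(1, int(round(n * rng.uniform(0.7, 1.0))))
        k = int(rng.binomial(listed, p))
        out.append(GenusSummary(genus=f"G{i:03d}", richness_n=n, age_my=age,
                                n_threatened=k, n_listed=listed))
    return out


# ------------------------------------------------------------ grid fields

def smoothed_field(shape: tuple[int, int], smooth: float, rng) -> np.ndarray:
    """Spatially autocorrelated Gaussian field: white noise under a uniform
    moving-average filter of half-width ``smooth`` (0 = white noise),
    re-standardized to unit variance."""
    z = rng.standard_normal(shape)
    if smooth > 0:
        z = ndimage.uniform_filter(z, size=int(2 * smooth + 1), mode="reflect")
    z = (z - z.mean()) / z.std()
    return z


# -------------------------------------------------------------- full pack

@dataclass
class SimulationConfig:
    """Knobs of the end-to-end synthetic dataset.

    Defaults are the package's standing study conditions: 200 genera of 5–200
    species, stem ages 2–40 my, peripatric range evolution with the standard
    punctuated parameters, range thresholds (1, 3, 10) QDS, 25 families whose
    identity shifts the root range (clustering), a 40x40 grid with
    moving-average autocorrelation, and snapshot transitions in which threat
    deepens fastest in already-threatened genera.
    """

    seed: int = 0
    n_genera: int = 200
    richness_range: tuple[int, int] = (5, 200)
    age_range_my: tuple[float, float] = (2.0, 40.0)
    birth_rate: float = 1.0
    death_rate: float = 0.0
    n_tree_genera: int = 12  # genera that also get species-level trees
    punctuated: PunctuatedParams = field(
        default_factory=lambda: PunctuatedParams(asymmetry_factor=2.0,
                                                 drift_sd=2.0, trend=0.3,
                                                 root_value=8.0))
    range_scale: float = 20.0  # multiplies exp(trait deviation) into QDS counts
    thresholds: tuple[int, int, int] = (1, 3, 10)
    n_families: int = 25
    clustering: float = 0.8  # sd of the family effect on log root range
    listed_fraction: float = 0.9
    grid_shape: tuple[int, int] = (40, 40)
    grid_smooth: float = 2.0
    threat_div_coupling: float = 0.6
    snapshot_base_up: float = 0.08
    snapshot_up_slope: float = 0.25  # extra P(up) per unit genus mean score
    snapshot_base_down: float = 0.10


def _simulate_genus(cfg: SimulationConfig, rng, genus: str, family_effect: float,
                    with_tree: bool):
    """One genus: tree shape, peripatric ranges, categories."""
    lo, hi = cfg.richness_range
    n = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    age = rng.uniform(*cfg.age_range_my)
    tree = simulate_birth_death_tree(cfg.birth_rate, cfg.death_rate,
                                     n_tips=n, rng=rng)
    tree = tree.scale_branches(age / tree.crown_age())
    # family identity shifts the ancestral range on the log scale: strong
    # clustering makes whole families range-restricted, hence threat-clustered
    root = cfg.punctuated.root_value * math.exp(cfg.clustering * family_effect)
    params = PunctuatedParams(asymmetry_factor=cfg.punctuated.asymmetry_factor,
                              drift_sd=cfg.punctuated.drift_sd,
                              trend=cfg.punctuated.trend, root_value=root)
    trait = simulate_punctuated(tree, params, rng=rng)
    labels = [f"{genus}_sp{i + 1}" for i in range(tree.n_tips)]
    relabel = dict(zip(tree.labels, labels))
    tree.tip_labels = {k: relabel[v] for k, v in tree.tip_labels.items()}
    # trait is log-range-like: exponentiate into occupied-cell counts
    qds = {relabel[t]: max(1, int(round(cfg.range_scale * math.exp(
        (v - params.root_value) / 4.0)))) for t, v in trait.items()}
    cats = dict(zip(qds, assign_categories_from_range(qds.values(),
                                                      cfg.thresholds)))
    return {"n": n, "age": age, "tree": tree if with_tree else None,
            "qds": qds, "cats": cats}


def _snapshot_pair(records: list[SpeciesThreatRecord], cfg: SimulationConfig,
                   rng) -> tuple[list[SpeciesThreatRecord], list[SpeciesThreatRecord]]:
    """Old/new Red List pair: P(step up) grows with the genus' old mean score."""
    by_genus: dict[str, list[SpeciesThreatRecord]] = {}
    for r in records:
        by_genus.setdefault(r.genus, []).append(r)
    mean_score = {g: float(np.mean([threat_score(r.category) for r in rs]))
                  for g, rs in by_genus.items()}
    new = []
    for r in records:
        p_up = min(0.9, cfg.snapshot_base_up
                   + cfg.snapshot_up_slope * mean_score[r.genus] / 5.0)
        u = rng.uniform()
        cat = int(r.category)
        if u < p_up and cat < int(ThreatCategory.EW):
            cat += 1
        elif u < p_up + cfg.snapshot_base_down and cat > 0:
            cat -= 1
        new.append(SpeciesThreatRecord(r.species_name, r.genus, r.family,
                                       r.order, ThreatCategory(cat), r.qds_count))
    return records, new


def synth_cape_like_dataset(config: SimulationConfig | None = None) -> dict:
    """End-to-end synthetic dataset for the full pipeline.

    Returns a dict with ``species`` (records with taxonomy, categories, QDS
    counts), ``genus_summaries``, ``genus_trees`` (species-level trees for a
    subset of genera), ``grid`` (SpatialGrid with autocorrelated mean threat
    and rate fields, habitat index independent of threat), and ``snapshots``
    (paired old/new Red List record sets).  Deterministic under the seed.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    fam_effect = rng.standard_normal(cfg.n_families)
    fam_order = [f"Order{j % 8 + 1}" for j in range(cfg.n_families)]

    species: list[SpeciesThreatRecord] = []
    summaries: list[GenusSummary] = []
    trees: dict[str, PhyloTree] = {}
    for i in range(cfg.n_genera):
        genus = f"Genus{i:03d}"
        fam = int(rng.integers(cfg.n_families))
        g = _simulate_genus(cfg, rng, genus, fam_effect[fam],
                            with_tree=i < cfg.n_tree_genera)
        if g["tree"] is not None:
            trees[genus] = g["tree"]
        names = sorted(g["qds"])
        listed = [s for s in names if rng.uniform() < cfg.listed_fraction]
        if not listed:
            listed = [names[0]]
        for s in listed:
            species.append(SpeciesThreatRecord(
                species_name=s, genus=genus, family=f"Family{fam:02d}",
                order=fam_order[fam], category=g["cats"][s],
                qds_count=g["qds"][s]))
        n_thr = sum(1 for s in listed if is_threatened(g["cats"][s]))
        summaries.append(GenusSummary(genus=genus, richness_n=g["n"],
                                      age_my=g["age"], n_threatened=n_thr,
                                      n_listed=len(listed)))

    # grid: diversification field and a coupled threat field, both smoothed;
    # habitat impact is an independent field (the no-correlation control)
    shape = cfg.grid_shape
    div_f = smoothed_field(shape, cfg.grid_smooth, rng)
    noise = smoothed_field(shape, cfg.grid_smooth, rng)
    c = cfg.threat_div_coupling
    threat_f = c * div_f + math.sqrt(max(1 - c ** 2, 0.0)) * noise
    habitat_f = smoothed_field(shape, cfg.grid_smooth, rng)
    rows, cols = np.indices(shape)
    rates = [s.div_rate for s in summaries]
    cells = pd.DataFrame({
        "row": rows.ravel(), "col": cols.ravel(),
        "mean_threat": _squash01(threat_f.ravel()),
        "mean_div_rate": np.maximum(
            np.mean(rates) + np.std(rates) * div_f.ravel(), 0.0),
        "habitat_index": habitat_f.ravel(),
        "genus_count": rng.poisson(25, size=shape[0] * shape[1]) + 1,
    })
    old, new = _snapshot_pair(species, cfg, rng)
    return {"species": species, "genus_summaries": summaries,
            "genus_trees": trees, "grid": SpatialGrid(cells),
            "snapshots": (old, new), "config": cfg}


def _squash01(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def write_dataset(dataset: dict, outdir) -> dict[str, Path]:
    """Write a synthetic dataset in the package's own file formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_species_csv(dataset["species"], out / "species.csv")
    paths["species"] = out / "species.csv"
    write_genus_csv(dataset["genus_summaries"], out / "genus_summaries.csv")
    paths["genus_summaries"] = out / "genus_summaries.csv"
    dataset["grid"].cells.to_csv(out / "grid.csv", index=False)
    paths["grid"] = out / "grid.csv"
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for genus, tree in dataset["genus_trees"].items():
        p = tree_dir / f"{genus}.nwk"
        p.write_text(write_newick(tree) + "\n")
        paths[f"tree:{genus}"] = p
    old, new = dataset["snapshots"]
    write_species_csv(old, out / "snapshot_old.csv")
    write_species_csv(new, out / "snapshot_new.csv")
    paths["snapshot_old"] = out / "snapshot_old.csv"
    paths["snapshot_new"] = out / "snapshot_new.csv"
    return paths
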