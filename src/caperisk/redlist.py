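"""IUCN Red List category semantics and status-transition tests.

Categories follow the standard ordered scale LC < NT < VU < EN < CR < EW < EX.
Species at VU or above count as threatened.  For trait-style analyses threat
is scored on a continuous 0 (LC) to 5 (EW) scale; extinct (EX) species fall
outside that scale and must be excluded by the caller.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThreatCategory",
    "SpeciesThreatRecord",
    "StatusTransition",
    "is_threatened",
    "threat_score",
    "status_transitions",
    "status_change_index",
    "g_statistic",
    "tertile_transition_gtest",
    "read_species_csv",
    "write_species_csv",
]


class ThreatCategory(enum.IntEnum):
    """Ordered Red List categories; comparison follows increasing risk."""

    LC = 0
    NT = 1
    VU = 2
    EN = 3
    CR = 4
    EW = 5
    EX = 6

    @classmethod
    def parse(cls, code: str) -> "ThreatCategory":
        code = code.strip().upper()
        if code in ("DD", "NE"):
            raise ValueError(
                f"category {code!r} (data deficient / not evaluated) is not an "
                "assessment; drop these records before analysis"
            )
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown Red List category {code!r}") from None


@dataclass(frozen=True)
class SpeciesThreatRecord:
    """One assessed species: taxonomy, category, optional range occupancy (QDS)."""

    species_name: str
    genus: str
    family: str
    order: str
    category: ThreatCategory
    qds_count: int | None = None

    def __post_init__(self):
        if not self.species_name:
            raise ValueError("species_name must be nonempty")
        if self.qds_count is not None and self.qds_count < 0:
            raise ValueError("qds_count must be >= 0")


@dataclass(frozen=True)
class StatusTransition:
    """A species' change between two Red List snapshots; delta in {-1, 0, +1}."""

    species_name: str
    category_old: ThreatCategory
    category_new: ThreatCategory

    @property
    def delta(self) -> int:
        return int(np.sign(int(self.category_new) - int(self.category_old)))


def is_threatened(category: ThreatCategory) -> bool:
    """True for VU, EN, CR, EW, EX; False for LC and NT."""
    return category >= ThreatCategory.VU


def threat_score(category: ThreatCategory) -> int:
    """Continuous-scale threat score: LC=0 up to EW=5; EX is not scorable."""
    if category == ThreatCategory.EX:
        raise ValueError("EX is not scorable on the 0-5 scale; exclude extinct "
                         "species from trait analyses")
    return int(category)


# ------------------------------------------------------------- transitions

def status_transitions(old_list, new_list):
    """Pair two Red List snapshots by species name.

    Returns (transitions, report) where report counts species present in only
    one snapshot (excluded from the index).
    """
    old = {r.species_name: r for r in old_list}
    new = {r.species_name: r for r in new_list}
    shared = sorted(set(old) & set(new))
    if not shared:
        raise ValueError("no shared species between the two listings")
    transitions = [
        StatusTransition(s, old[s].category, new[s].category) for s in shared
    ]
    report = {
        "n_shared": len(shared),
        "n_only_old": len(set(old) - set(new)),
        "n_only_new": len(set(new) - set(old)),
    }
    return transitions, report


def status_change_index(old_list, new_list) -> tuple[dict[str, int], dict]:
    """Per-genus sum of +1/-1/0 species status changes between snapshots."""
    transitions, report = status_transitions(old_list, new_list)
    genus_of = {r.species_name: r.genus for r in old_list}
    index: dict[str, int] = {}
    for t in transitions:
        g = genus_of[t.species_name]
        index[g] = index.get(g, 0) + t.delta
    return index, report


# ------------------------------------------------------------------ G-test

def g_statistic(observed, expected) -> float:
    """Likelihood-ratio goodness-of-fit statistic G = 2*sum O*ln(O/E).

    Zero observed counts contribute nothing.  Totals must match (the expected
    vector describes the same n observations).
    """
    o = np.asarray(observed, float)
    e = np.asarray(expected, float)
    if o.shape != e.shape or o.size < 2:
        raise ValueError("observed and expected must have equal length >= 2")
    if np.any(o < 0) or np.any(e <= 0):
        raise ValueError("counts must be >= 0 and expectations > 0")
    if not math.isclose(o.sum(), e.sum(), rel_tol=1e-9, abs_tol=1e-6):
        raise ValueError(
            f"totals differ (observed {o.sum():g}, expected {e.sum():g})"
        )
    nz = o > 0
    return float(2.0 * np.sum(o[nz] * np.log(o[nz] / e[nz])))


def _mean_old_score(transitions) -> float:
    return float(np.mean([threat_score(t.category_old) for t in transitions]))


def tertile_transition_gtest(transitions, genus_of: dict[str, str],
                             framing: str = "goodness_of_fit") -> dict:
    """Do the most-threatened genera keep deteriorating fastest?

    Genera are ranked by the mean old-snapshot threat score of their species
    (ties broken by genus name); species transitions are pooled within the top
    and bottom tertiles of that ranking and classified as increased vs
    unchanged-or-decreased.  The default framing tests the top-tertile counts
    as a goodness-of-fit against the proportions observed in the bottom
    tertile (1 df).  ``framing="independence"`` instead runs the 2x2 G-test of
    independence on the same counts.

    Genera contributing a single assessed species are included in the ranking
    and flagged in the output.
    """
    by_genus: dict[str, list] = {}
    for t in transitions:
        by_genus.setdefault(genus_of[t.species_name], []).append(t)
    if len(by_genus) < 3:
        raise ValueError("need at least 3 genera to form tertiles")
    ranked = sorted(by_genus, key=lambda g: (-_mean_old_score(by_genus[g]), g))
    k = len(ranked) // 3
    top, bottom = ranked[:k], ranked[-k:]

    def counts(genera):
        ts = [t for g in genera for t in by_genus[g]]
        inc = sum(1 for t in ts if t.delta > 0)
        return np.array([inc, len(ts) - inc], float)

    top_counts = counts(top)
    bottom_counts = counts(bottom)
    if top_counts.sum() == 0 or bottom_counts.sum() == 0:
        raise ValueError("a tertile contains no species transitions")
    g = transition_g(top_counts, bottom_counts, framing=framing)
    return {
        "G": g,
        "p": float(stats.chi2.sf(g, df=1)),
        "top_counts": tuple(int(c) for c in top_counts),
        "bottom_counts": tuple(int(c) for c in bottom_counts),
        "framing": framing,
        "singleton_genera": sorted(
            g for g, ts in by_genus.items() if len(ts) == 1
        ),
    }


def transition_g(top_counts, bottom_counts, framing: str = "goodness_of_fit") -> float:
    """G statistic comparing increase:non-increase counts between tertiles."""
    top = np.asarray(top_counts, float)
    bottom = np.asarray(bottom_counts, float)
    if framing == "goodness_of_fit":
        expected = top.sum() * bottom / bottom.sum()
        return g_statistic(top, expected)
    if framing == "independence":
        table = np.vstack([top, bottom])
        g, _, _, _ = stats.chi2_contingency(table, correction=False,
                                            lambda_="log-likelihood")
        return float(g)
    raise ValueError(f"unknown framing {framing!r}")


# --------------------------------------------------------------------- I/O

_REQUIRED_COLS = ["species", "genus", "family", "order", "category"]


def read_species_csv(path) -> list[SpeciesThreatRecord]:
    """Read a species threat table (species, genus, family, order, category
    [, qds_count]) into records; categories validated at parse time."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"species CSV missing columns {missing}")
    has_qds = "qds_count" in df.columns
    records = []
    for row in df.itertuples(index=False):
        qds = None
        if has_qds and not pd.isna(row.qds_count):
            qds = int(row.qds_count)
        records.append(SpeciesThreatRecord(
            species_name=str(row.species), genus=str(row.genus),
            family=str(row.family), order=str(row.order),
            category=ThreatCategory.parse(str(row.category)), qds_count=qds,
        ))
    return records


def write_species_csv(records, path) -> None:
    rows = [{
        "species": r.species_name, "genus": r.genus, "family": r.family,
        "order": r.order, "category": r.category.name,
        "qds_count": "" if r.qds_count is None else r.qds_count,
    } for r in records]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
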