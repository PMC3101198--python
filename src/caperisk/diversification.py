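"""Genus-level diversification rates and their relationship to threat.

Net diversification rate for a genus with n species and age t my is
ln(n)/t.  The association between threat and richness/age/rate is modelled
with binomial GLMs (logit link) on per-genus threatened counts, with the
predictor transforms ln(richness), sqrt(age) and ln(rate), optional
per-genus weights, AIC comparison and marginal deviance; phylogenetic
non-independence is handled separately by partial Mantel tests on distance
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenusSummary",
    "GlmFit",
    "diversification_rate",
    "fit_threat_glm",
    "marginal_deviance",
    "spearman_rho",
    "partial_mantel",
    "trait_distance_matrix",
    "read_genus_csv",
    "write_genus_csv",
]

PREDICTOR_TRANSFORMS = {
    "richness": ("ln_richness", lambda s: np.log(s.richness_n)),
    "age": ("sqrt_age", lambda s: math.sqrt(s.age_my)),
    "rate": ("ln_rate", lambda s: np.log(s.div_rate)),
}


def diversification_rate(n: int, age_my: float) -> float:
    """Net diversification rate ln(n)/age (per my)."""
    if n < 1:
        raise ValueError("richness must be >= 1")
    if age_my <= 0:
        raise ValueError("age must be > 0")
    return math.log(n) / age_my


@dataclass(frozen=True)
class GenusSummary:
    """Per-genus richness, age, rate, and Red List counts."""

    genus: str
    richness_n: int
    age_my: float
    n_threatened: int
    n_listed: int
    endemic: bool = True

    def __post_init__(self):
        if not (0 <= self.n_threatened <= self.n_listed <= self.richness_n):
            raise ValueError(
                f"{self.genus}: need 0 <= n_threatened <= n_listed <= richness"
            )
        if self.age_my <= 0:
            raise ValueError(f"{self.genus}: age must be > 0")

    @property
    def div_rate(self) -> float:
        return diversification_rate(self.richness_n, self.age_my)


@dataclass
class GlmFit:
    """A fitted binomial GLM of per-genus threatened proportion."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    aic: float
    null_deviance: float
    deviance: float
    n_genera: int
    weighting: str = "none"
    n_dropped_rate_zero: int = 0

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "z": self.z,
            "p": self.p,
            "AIC": self.aic,
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "n_genera": self.n_genera,
            "weighting": self.weighting,
        }


def _design(summaries: list[GenusSummary], predictors) -> tuple[np.ndarray, list[str], list[GenusSummary], int]:
    for p in predictors:
        if p not in PREDICTOR_TRANSFORMS:
            raise ValueError(f"unknown predictor {p!r}")
    kept = list(summaries)
    dropped = 0
    if "rate" in predictors:
        kept = [s for s in kept if s.div_rate > 0]
        dropped = len(summaries) - len(kept)
    cols, names = [np.ones(len(kept))], ["intercept"]
    for p in predictors:
        name, fn = PREDICTOR_TRANSFORMS[p]
        cols.append(np.array([fn(s) for s in kept]))
        names.append(name)
    return np.column_stack(cols), names, kept, dropped


def _weights(kept: list[GenusSummary], weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones(len(kept))
    if weighting == "log_records":
        return np.array([math.log(s.n_listed + 1) for s in kept])
    if weighting == "listed_ratio":
        return np.array([s.n_listed / s.richness_n for s in kept])
    raise ValueError(f"unknown weighting {weighting!r}")


def fit_threat_glm(summaries: list[GenusSummary],
                   predictors: tuple[str, ...] = ("rate",),
                   weighting: str = "none",
                   endemic_only: bool = True) -> GlmFit:
    """Binomial GLM of per-genus threatened proportion on transformed predictors.

    Response: (n_threatened, n_listed - n_threatened) per genus, logit link.
    Predictors drawn from {richness, age, rate} with transforms ln, sqrt, ln.
    Genera with zero rate (monotypic, ln undefined) are dropped from
    rate models and counted.  Weighting: ``log_records`` uses ln(n_listed+1),
    ``listed_ratio`` uses n_listed/richness; weights multiply the binomial
    denominators in the working likelihood (R glm convention).
    """
    if not predictors and predictors != ():
        raise ValueError("predictors must be a (possibly empty) tuple")
    data = [s for s in summaries if (s.endemic or not endemic_only) and s.n_listed >= 1]
    if len(data) < 2:
        raise ValueError("need at least 2 genera with listed species")
    X, names, kept, dropped = _design(data, predictors)
    y = np.array([s.n_threatened / s.n_listed for s in kept])
    trials = np.array([s.n_listed for s in kept], float)
    w = _weights(kept, weighting)
    if np.all(w == 0):
        raise ValueError("all weights are zero")
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=trials * w)
    try:
        res = model.fit()
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise RuntimeError(f"GLM failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("GLM produced non-finite coefficients "
                           "(possible complete separation)")
    null = sm.GLM(y, np.ones((len(kept), 1)), family=sm.families.Binomial(),
                  var_weights=trials * w).fit()
    return GlmFit(
        predictors=tuple(predictors),
        coefficients=dict(zip(names, map(float, res.params))),
        z=dict(zip(names, map(float, res.tvalues))),
        p=dict(zip(names, map(float, res.pvalues))),
        aic=float(res.aic),
        null_deviance=float(null.deviance),
        deviance=float(res.deviance),
        n_genera=len(kept),
        weighting=weighting,
        n_dropped_rate_zero=dropped,
    )


def marginal_deviance(summaries: list[GenusSummary],
                      full_predictors: tuple[str, ...], variable: str,
                      weighting: str = "none", endemic_only: bool = True) -> float:
    """Share of null deviance explained only by ``variable``.

    (deviance(full without variable) - deviance(full)) / null deviance, the
    additional percent deviance the variable contributes to the reduced model.
    """
    if variable not in full_predictors:
        raise ValueError(f"{variable!r} is not in the full model")
    reduced = tuple(p for p in full_predictors if p != variable)
    full = fit_threat_glm(summaries, full_predictors, weighting, endemic_only)
    red = fit_threat_glm(summaries, reduced, weighting, endemic_only)
    return (red.deviance - full.deviance) / full.null_deviance


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------- Mantel testing

def trait_distance_matrix(values) -> np.ndarray:
    """Distance matrix |x_i - x_j| from a per-object scalar."""
    x = np.asarray(values, float)
    return np.abs(x[:, None] - x[None, :])


def _check_dist(name: str, d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _residual_upper(vec: np.ndarray, z: np.ndarray) -> np.ndarray:
    zc = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(zc, vec, rcond=None)
    return vec - zc @ beta


def partial_mantel(dx, dy, dz, n_perm: int = 999, seed: int | None = None,
                   tail: str = "greater") -> dict:
    """Partial Mantel test: correlation of dX and dY controlling for dZ.

    r is the Pearson correlation between the upper-triangle entries of dX and
    dY after each is residualized on dZ.  Significance permutes the object
    labels of dX; p = (count+1)/(n_perm+1), one-tailed on r >= observed by
    default (``tail`` in {greater, less, two-sided}).
    """
    dx = _check_dist("dX", dx)
    dy = _check_dist("dY", dy)
    dz = _check_dist("dZ", dz)
    if not dx.shape == dy.shape == dz.shape:
        raise ValueError("matrices must have matching shapes")
    n = dx.shape[0]
    iu = np.triu_indices(n, 1)
    for name, d in (("dX", dx), ("dY", dy), ("dZ", dz)):
        if np.ptp(d[iu]) == 0:
            raise ValueError(f"{name} is constant off the diagonal")
    zvec = dz[iu]
    rx = _residual_upper(dx[iu], zvec)
    ry = _residual_upper(dy[iu], zvec)
    if np.ptp(rx) <= 1e-10 * max(np.ptp(dx[iu]), 1e-300):
        raise ValueError("conditioning matrix explains dX entirely")
    if np.ptp(ry) <= 1e-10 * max(np.ptp(dy[iu]), 1e-300):
        raise ValueError("conditioning matrix explains dY entirely")

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(rx, ry)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rxp = _residual_upper(dx[np.ix_(perm, perm)][iu], zvec)
        r = corr(rxp, ry)
        if tail == "greater":
            hit = r >= r_obs
        elif tail == "less":
            hit = r <= r_obs
        elif tail == "two-sided":
            hit = abs(r) >= abs(r_obs)
        else:
            raise ValueError(f"unknown tail {tail!r}")
        count += hit
    return {"r": r_obs, "p": (count + 1) / (n_perm + 1),
            "n_perm": n_perm, "tail": tail}


# --------------------------------------------------------------------- I/O

def read_genus_csv(path) -> list[GenusSummary]:
    df = pd.read_csv(path)
    need = ["genus", "richness", "age_my", "n_threatened", "n_listed"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"genus CSV missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(GenusSummary(
            genus=str(row.genus), richness_n=int(row.richness),
            age_my=float(row.age_my), n_threatened=int(row.n_threatened),
            n_listed=int(row.n_listed),
            endemic=bool(getattr(row, "endemic", True)),
        ))
    return out


def write_genus_csv(summaries: list[GenusSummary], path) -> None:
    pd.DataFrame([{
        "genus": s.genus, "richness": s.richness_n, "age_my": s.age_my,
        "div_rate": s.div_rate, "n_threatened": s.n_threatened,
        "n_listed": s.n_listed, "endemic": s.endemic,
    } for s in summaries]).to_csv(Path(path), index=False)
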