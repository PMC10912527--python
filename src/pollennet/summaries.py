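"""Per-species and community-level stigma pollen-deposition statistics.

A stigma load records, for one stigma of a focal plant species, the number
of conspecific pollen grains (CP), heterospecific grains (HP), and the
number of distinct HP donor species (HP diversity).  Stigmas that received
no pollen at all are excluded from analysis; means, standard errors and
coefficients of variation treat each analyzed stigma as one observation.
The HP proportion is HP / (CP + HP) x 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "exclude_empty",
    "SpeciesPollenSummary",
    "summarize_species",
    "summarize_all_species",
    "CommunityPollenSummary",
    "summarize_community",
    "flower_area",
    "hp_threshold_census",
]

STIGMA_COLUMNS = ["stigma_id", "species", "cp", "hp", "hp_diversity"]


def exclude_empty(loads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop stigmas with no pollen at all (cp + hp = 0) from the analysis set.

    Returns the analyzed subset and the number excluded.
    """
    empty = (loads["cp"] + loads["hp"]) == 0
    return loads.loc[~empty].copy(), int(empty.sum())


def _mean_se_cv(x: np.ndarray) -> tuple[float, float, float | None]:
    """Mean, SE (sample SD / sqrt(n)) and CV% (100 SD / mean, None if mean 0)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n) if n > 0 else float("nan")
    cv = 100.0 * sd / mean if mean != 0 else None
    return mean, se, cv


@dataclass(frozen=True)
class SpeciesPollenSummary:
    species: str
    n_stigmas_total: int
    n_stigmas_analyzed: int
    mean_cp: float
    se_cp: float
    cv_cp: float | None
    mean_hp: float
    se_hp: float
    cv_hp: float | None
    mean_hp_div: float
    se_hp_div: float
    cv_hp_div: float | None
    hp_proportion: float  # percent


def summarize_species(
    loads: pd.DataFrame,
    hp_prop_mode: Literal["pooled", "per_stigma"] = "pooled",
) -> SpeciesPollenSummary:
    """Summary statistics for the stigma loads of a single species.

    ``hp_prop_mode='pooled'`` (default) computes the HP proportion from the
    species' pooled grain totals, 100 * sum HP / (sum CP + sum HP);
    ``'per_stigma'`` averages each stigma's own proportion instead.  Empty
    stigmas are excluded before any statistic is computed.
    """
    species = loads["species"].unique()
    if len(species) != 1:
        raise ValueError("summarize_species expects loads of exactly one species")
    analyzed, _ = exclude_empty(loads)
    if len(analyzed) == 0:
        raise ValueError(f"species {species[0]!r} has no non-empty stigmas")
    mean_cp, se_cp, cv_cp = _mean_se_cv(analyzed["cp"].to_numpy())
    mean_hp, se_hp, cv_hp = _mean_se_cv(analyzed["hp"].to_numpy())
    mean_hd, se_hd, cv_hd = _mean_se_cv(analyzed["hp_diversity"].to_numpy())
    if hp_prop_mode == "pooled":
        tot_cp = float(analyzed["cp"].sum())
        tot_hp = float(analyzed["hp"].sum())
        hp_prop = 100.0 * tot_hp / (tot_cp + tot_hp)
    elif hp_prop_mode == "per_stigma":
        per = analyzed["hp"] / (analyzed["cp"] + analyzed["hp"])
        hp_prop = float(100.0 * per.mean())
    else:
        raise ValueError("hp_prop_mode must be 'pooled' or 'per_stigma'")
    return SpeciesPollenSummary(
        species=str(species[0]),
        n_stigmas_total=len(loads),
        n_stigmas_analyzed=len(analyzed),
        mean_cp=mean_cp,
        se_cp=se_cp,
        cv_cp=cv_cp,
        mean_hp=mean_hp,
        se_hp=se_hp,
        cv_hp=cv_hp,
        mean_hp_div=mean_hd,
        se_hp_div=se_hd,
        cv_hp_div=cv_hd,
        hp_proportion=hp_prop,
    )


def summarize_all_species(
    loads: pd.DataFrame,
    hp_prop_mode: Literal["pooled", "per_stigma"] = "pooled",
) -> pd.DataFrame:
    """Per-species summary table (one row per species with >= 1 non-empty stigma).

    CV columns hold NaN where the mean is zero (the statistic is undefined);
    table-style output prints those entries as 0.
    """
    rows = []
    for sp, grp in loads.groupby("species", sort=True):
        analyzed, _ = exclude_empty(grp)
        if len(analyzed) == 0:
            continue
        s = summarize_species(grp, hp_prop_mode=hp_prop_mode)
        rows.append(
            {
                "species": s.species,
                "n_stigmas_total": s.n_stigmas_total,
                "n_stigmas_analyzed": s.n_stigmas_analyzed,
                "mean_cp": s.mean_cp,
                "se_cp": s.se_cp,
                "cv_cp": np.nan if s.cv_cp is None else s.cv_cp,
                "mean_hp": s.mean_hp,
                "se_hp": s.se_hp,
                "cv_hp": np.nan if s.cv_hp is None else s.cv_hp,
                "mean_hp_div": s.mean_hp_div,
                "se_hp_div": s.se_hp_div,
                "cv_hp_div": np.nan if s.cv_hp_div is None else s.cv_hp_div,
                "hp_proportion": s.hp_proportion,
            }
        )
    return pd.DataFrame(rows).set_index("species")


@dataclass(frozen=True)
class CommunityPollenSummary:
    n_stigmas: int
    n_species: int
    total_grains: int
    total_cp: int
    total_hp: int
    pct_cp: float
    pct_hp: float
    pct_stigmas_with_hp: float
    n_empty: int
    pct_empty: float
    mean_stigmas_per_species: float
    se_stigmas_per_species: float


def summarize_community(loads: pd.DataFrame) -> CommunityPollenSummary:
    """Community-level pollen accounting pooled over ALL examined stigmas.

    Grain totals include pre-exclusion (empty) stigmas, which contribute
    zero; the shares of conspecific and heterospecific grains are computed
    with exact rational arithmetic before conversion to percent, so
    pct_cp + pct_hp == 100 exactly.
    """
    tot_cp = int(loads["cp"].sum())
    tot_hp = int(loads["hp"].sum())
    total = tot_cp + tot_hp
    if total > 0:
        pct_cp = float(Fraction(100 * tot_cp, total))
        pct_hp = float(Fraction(100 * tot_hp, total))
    else:
        pct_cp = pct_hp = float("nan")
    n = len(loads)
    n_empty = int(((loads["cp"] + loads["hp"]) == 0).sum())
    counts = loads.groupby("species").size().to_numpy(dtype=float)
    mean_n, se_n, _ = _mean_se_cv(counts)
    return CommunityPollenSummary(
        n_stigmas=n,
        n_species=int(loads["species"].nunique()),
        total_grains=total,
        total_cp=tot_cp,
        total_hp=tot_hp,
        pct_cp=pct_cp,
        pct_hp=pct_hp,
        pct_stigmas_with_hp=100.0 * float((loads["hp"] > 0).sum()) / n if n else float("nan"),
        n_empty=n_empty,
        pct_empty=100.0 * n_empty / n if n else float("nan"),
        mean_stigmas_per_species=mean_n,
        se_stigmas_per_species=se_n,
    )


_SHAPE_DIMS = {
    "circle": ("r",),
    "flat_rect": ("L", "W"),
    "circle_plus_tube": ("r", "B", "D"),
    "rect_plus_tube": ("L", "W", "B", "D"),
    "legume": ("L", "W", "l", "w"),
}


def flower_area(shape_class: str, **dims: float) -> float:
    """Flower (visual-unit) area in mm^2 from shape class and linear dimensions.

    circle: pi r^2; flat_rect: L*W; circle_plus_tube: pi r^2 + pi B D;
    rect_plus_tube: L*W + pi B D (flat corolla plus tubular part);
    legume: L*W + l*w (banner plus wing).  Dimensions in mm.
    """
    if shape_class not in _SHAPE_DIMS:
        raise ValueError(
            f"unknown shape class {shape_class!r}; expected one of {sorted(_SHAPE_DIMS)}"
        )
    required = _SHAPE_DIMS[shape_class]
    for name in required:
        if name not in dims:
            raise ValueError(f"shape {shape_class!r} requires dimension {name!r}")
        if dims[name] <= 0:
            raise ValueError(f"dimension {name!r} must be positive")
    d = dims
    if shape_class == "circle":
        return math.pi * d["r"] ** 2
    if shape_class == "flat_rect":
        return d["L"] * d["W"]
    if shape_class == "circle_plus_tube":
        return math.pi * d["r"] ** 2 + math.pi * d["B"] * d["D"]
    if shape_class == "rect_plus_tube":
        return d["L"] * d["W"] + math.pi * d["B"] * d["D"]
    return d["L"] * d["W"] + d["l"] * d["w"]


def hp_threshold_census(
    hp_proportions: pd.Series | np.ndarray,
    threshold: float = 10.0,
    decimals: int = 1,
) -> float:
    """Percent of species whose HP proportion is at or below ``threshold``.

    Values are rounded to ``decimals`` (the precision of a printed summary
    table) before the inclusive comparison, so a species tabulated at
    exactly the threshold counts as at-or-below.
    """
    vals = np.round(np.asarray(hp_proportions, dtype=float), decimals)
    if len(vals) == 0:
        raise ValueError("no species to census")
    return 100.0 * float((vals <= threshold).mean())
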