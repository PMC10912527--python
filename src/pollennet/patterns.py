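"""Within-species CP-HP accrual pattern classification.

For each plant species the numbers of conspecific (CP) and heterospecific
(HP) pollen grains per stigma are related by one of three accrual patterns:

* increasing linearly — every pollinator visit delivers both CP and HP, so
  HP rises proportionally with CP (an HP-tolerance signature);
* no relationship — a few high-quality pollinators deliver nearly pure CP
  and HP arrives only occasionally, so HP varies independently of CP (an
  HP-avoidance signature);
* increasing or decreasing exponentially — high- and low-quality
  pollinators visit the same species, coupling HP to CP multiplicatively.

The classifier fits an ordinary least squares line HP = b0 + b1 CP and a
single-exponential curve HP = exp(c0 + c1 CP) to the per-stigma loads and
applies a significance-then-fit decision rule: if only one model is
significant at level alpha it wins; if both are, the larger adjusted R^2
wins (ties go to the linear model); if neither is, the species shows no
pattern.  Species that received no HP at all are flagged separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .summaries import exclude_empty

__all__ = [
    "FitResult",
    "fit_linear",
    "fit_exponential",
    "CPHPPatternModel",
    "CPHPPatternResults",
    "classify_species",
    "classify_all",
    "pattern_tallies",
]

Pattern = Literal[
    "increasing_linear",
    "decreasing_linear",
    "increasing_exponential",
    "decreasing_exponential",
    "no_pattern",
    "no_hp",
]

#: detailed pattern -> three-way group used in cross-species comparisons
PATTERN_GROUPS = {
    "increasing_linear": "linear",
    "decreasing_linear": "linear",
    "increasing_exponential": "exponential",
    "decreasing_exponential": "exponential",
    "no_pattern": "no_pattern",
    "no_hp": "no_pattern",
}


@dataclass(frozen=True)
class FitResult:
    """One candidate regression of HP on CP.

    ``coef`` is the slope (linear) or rate constant c1 (exponential);
    ``intercept`` is b0 or c0.  Significance is the overall F test of the
    fitted model against the intercept-only model.
    """

    model: Literal["linear", "exponential"]
    coef: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    fvalue: float
    pvalue: float
    n: int
    converged: bool = True
    message: str = ""

    def significant(self, alpha: float) -> bool:
        return self.converged and np.isfinite(self.pvalue) and self.pvalue < alpha


def _f_test_vs_intercept(sse: float, sst: float, n: int) -> tuple[float, float]:
    """Overall F (1 numerator df, n-2 denominator df) and its p value."""
    if sst <= 0 or n < 3:
        return 0.0, 1.0
    if sse <= 0:
        return float("inf"), 0.0
    f = (sst - sse) / (sse / (n - 2))
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, 1, n - 2))


def _adj_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_linear(cp: np.ndarray, hp: np.ndarray) -> FitResult:
    """Ordinary least squares HP = b0 + b1 CP.

    Requires n >= 3 stigmas and non-constant CP.
    """
    cp = np.asarray(cp, dtype=float)
    hp = np.asarray(hp, dtype=float)
    n = len(cp)
    if n < 3:
        raise ValueError("linear fit requires at least 3 stigmas")
    if np.ptp(cp) == 0:
        raise ValueError("degenerate fit: CP is constant across stigmas")
    slope, intercept = np.polyfit(cp, hp, 1)
    resid = hp - (intercept + slope * cp)
    sse = float(resid @ resid)
    sst = float(((hp - hp.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    f, p = _f_test_vs_intercept(sse, sst, n)
    return FitResult("linear", float(slope), float(intercept), r2, _adj_r2(r2, n), f, p, n)


def fit_exponential(
    cp: np.ndarray,
    hp: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FitResult:
    """Nonlinear least squares HP = exp(c0 + c1 CP).

    Initialized from the log-linear fit of ln(HP + 1) on CP; significance
    is an F test of the converged model against the intercept-only model.
    A non-converged fit is returned flagged (``converged=False``) and is
    treated as non-significant downstream.
    """
    cp = np.asarray(cp, dtype=float)
    hp = np.asarray(hp, dtype=float)
    n = len(cp)
    if n < 3:
        raise ValueError("exponential fit requires at least 3 stigmas")

    c1_0, c0_0 = np.polyfit(cp, np.log(hp + 1.0), 1)

    def residuals(theta: np.ndarray) -> np.ndarray:
        expo = np.clip(theta[0] + theta[1] * cp, -700, 700)
        return np.exp(expo) - hp

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = optimize.least_squares(
                residuals,
                x0=np.array([c0_0, c1_0]),
                ftol=tol,
                xtol=tol,
                gtol=tol,
                max_nfev=max_iter,
            )
        converged = bool(sol.success) and np.all(np.isfinite(sol.x))
        c0, c1 = (sol.x if converged else (float("nan"), float("nan")))
        message = sol.message
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        converged, c0, c1, message = False, float("nan"), float("nan"), str(exc)

    if not converged:
        return FitResult(
            "exponential", float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), n, converged=False, message=message,
        )
    resid = residuals(np.array([c0, c1]))
    sse = float(resid @ resid)
    sst = float(((hp - hp.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    f, p = _f_test_vs_intercept(sse, sst, n)
    return FitResult(
        "exponential", float(c1), float(c0), r2, _adj_r2(r2, n), f, p, n,
        converged=True, message=message,
    )


class CPHPPatternModel:
    """Accrual-pattern model for one species' per-stigma CP and HP loads.

    Parameters
    ----------
    cp, hp : array-like of non-negative per-stigma grain counts (empty
        stigmas, cp + hp = 0, are dropped before fitting).
    species : optional label carried through to the results.

    ``fit(alpha)`` fits both candidate regressions and applies the
    decision rule; the returned :class:`CPHPPatternResults` carries both
    fits, the chosen one, and the pattern label.
    """

    def __init__(self, cp, hp, species: str | None = None) -> None:
        cp = np.asarray(cp, dtype=float)
        hp = np.asarray(hp, dtype=float)
        if cp.shape != hp.shape or cp.ndim != 1:
            raise ValueError("cp and hp must be 1-d arrays of equal length")
        if (cp < 0).any() or (hp < 0).any():
            raise ValueError("pollen counts must be non-negative")
        keep = (cp + hp) > 0
        self.n_total = len(cp)
        self.cp = cp[keep]
        self.hp = hp[keep]
        self.species = species

    @classmethod
    def from_loads(cls, loads: pd.DataFrame, species: str | None = None) -> "CPHPPatternModel":
        if species is None:
            uniq = loads["species"].unique()
            if len(uniq) != 1:
                raise ValueError("loads contain multiple species; pass `species`")
            species = str(uniq[0])
        else:
            loads = loads[loads["species"] == species]
        return cls(loads["cp"].to_numpy(), loads["hp"].to_numpy(), species=species)

    def fit(self, alpha: float = 0.05) -> "CPHPPatternResults":
        n = len(self.cp)
        if n < 3:
            raise ValueError(
                f"species {self.species!r}: need >= 3 analyzed stigmas, have {n}"
            )
        if self.hp.sum() == 0:
            return CPHPPatternResults(
                species=self.species, pattern="no_hp", chosen=None,
                linear=None, exponential=None, alpha=alpha,
                n_analyzed=n, n_total=self.n_total,
            )
        try:
            lin: Optional[FitResult] = fit_linear(self.cp, self.hp)
        except ValueError as exc:
            warnings.warn(f"species {self.species!r}: linear fit degenerate ({exc})")
            lin = None
        exp_ = fit_exponential(self.cp, self.hp)
        lin_sig = lin is not None and lin.significant(alpha)
        exp_sig = exp_.significant(alpha)
        if lin_sig and exp_sig:
            # model choice by adjusted R^2, exact ties to the simpler line
            chosen = lin if lin.adj_r_squared >= exp_.adj_r_squared else exp_
        elif lin_sig:
            chosen = lin
        elif exp_sig:
            chosen = exp_
        else:
            chosen = None
        if chosen is None:
            pattern: Pattern = "no_pattern"
        elif chosen.model == "linear":
            pattern = "increasing_linear" if chosen.coef >= 0 else "decreasing_linear"
        else:
            pattern = "increasing_exponential" if chosen.coef >= 0 else "decreasing_exponential"
        return CPHPPatternResults(
            species=self.species, pattern=pattern, chosen=chosen,
            linear=lin, exponential=exp_, alpha=alpha,
            n_analyzed=n, n_total=self.n_total,
        )


@dataclass(frozen=True)
class CPHPPatternResults:
    """Classification outcome with both candidate fits."""

    species: str | None
    pattern: Pattern
    chosen: Optional[FitResult]
    linear: Optional[FitResult]
    exponential: Optional[FitResult]
    alpha: float
    n_analyzed: int
    n_total: int

    @property
    def pattern_group(self) -> str:
        """Three-way grouping: linear / exponential / no_pattern."""
        return PATTERN_GROUPS[self.pattern]

    def summary(self) -> str:
        lines = [
            f"CP-HP accrual pattern{f' for {self.species}' if self.species else ''}",
            f"  stigmas: {self.n_analyzed} analyzed of {self.n_total} collected",
            f"  pattern: {self.pattern} (alpha = {self.alpha:g})",
        ]
        for fit in (self.linear, self.exponential):
            if fit is None:
                continue
            mark = " <- chosen" if fit is self.chosen else ""
            if fit.converged:
                lines.append(
                    f"  {fit.model:<12} b = {fit.coef: .5g}  adjR2 = {fit.adj_r_squared: .3f}"
                    f"  F = {fit.fvalue: .3f}  p = {fit.pvalue: .4g}{mark}"
                )
            else:
                lines.append(f"  {fit.model:<12} did not converge ({fit.message})")
        if self.pattern == "no_hp":
            lines.append("  no heterospecific grains received; fits not applicable")
        return "\n".join(lines)


def classify_species(
    loads: pd.DataFrame, alpha: float = 0.05, species: str | None = None
) -> CPHPPatternResults:
    """Classify one species' CP-HP accrual pattern from its stigma loads."""
    return CPHPPatternModel.from_loads(loads, species=species).fit(alpha=alpha)


def classify_all(loads: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pattern table over every species in a stigma-load table.

    Species with fewer than 3 non-empty stigmas are skipped with a warning.
    Returns one row per species: collected and analyzed stigma counts, the
    pattern label and group, and the chosen fit's statistics (NaN for
    species with no pattern; the pooled-zero-HP species print as
    'no_hp').
    """
    rows = []
    for sp, grp in loads.groupby("species", sort=True):
        analyzed, _ = exclude_empty(grp)
        if len(analyzed) < 3:
            warnings.warn(f"species {sp!r}: fewer than 3 analyzed stigmas; skipped")
            continue
        res = classify_species(grp, alpha=alpha, species=str(sp))
        chosen = res.chosen
        rows.append(
            {
                "species": sp,
                "n_total": res.n_total,
                "n_analyzed": res.n_analyzed,
                "pattern": res.pattern,
                "pattern_group": res.pattern_group,
                "adj_r_squared": chosen.adj_r_squared if chosen else np.nan,
                "b": chosen.coef if chosen else np.nan,
                "F": chosen.fvalue if chosen else np.nan,
                "p": chosen.pvalue if chosen else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def pattern_tallies(table: pd.DataFrame) -> dict[str, int]:
    """Counts of species per three-way pattern group."""
    out = {"linear": 0, "exponential": 0, "no_pattern": 0}
    for grp in table["pattern_group"]:
        out[grp] += 1
    return out
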