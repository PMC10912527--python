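"""Cross-species analyses: trait transforms, standardized-coefficient
multiple regression, and one-way ANOVAs across pattern or strategy groups.

Predictors follow the conventions of the cross-species analysis this
package supports: floral symmetry coded bilateral = 1, radial = 2; flower
size and HP proportion log10-transformed; plant specialization d', species
strength and closeness centrality square-root-transformed.  Species with
zero HP are excluded from any analysis using log10(HP%) (the transform is
undefined; no offset is added) but retained everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "apply_transforms",
    "RegressionResult",
    "fit_multiple_regression",
    "AnovaResult",
    "one_way_anova",
    "pattern_group_comparison",
]

SYMMETRY_CODES = {"bilateral": 1, "radial": 2, "B": 1, "R": 2}


def apply_transforms(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the standard cross-species transforms applied.

    Expects per-species columns among ``symmetry, flower_size,
    hp_proportion, d_prime, strength, closeness`` (missing ones are left
    out) plus any response columns, which are passed through untouched.
    Adds ``symmetry_code, log10_flower_size, log10_hp_proportion, sqrt_d_prime,
    sqrt_strength, sqrt_closeness``.  Zero HP proportions produce NaN in
    ``log10_hp_proportion`` (flagged via the ``zero_hp`` column); negative
    inputs to a log or root raise with the species named.
    """
    out = table.copy()
    if "symmetry" in out:
        bad = ~out["symmetry"].isin(SYMMETRY_CODES)
        if bad.any():
            raise ValueError(f"unknown symmetry codes for species {list(out.index[bad])}")
        out["symmetry_code"] = out["symmetry"].map(SYMMETRY_CODES)
    for col, new, fn, domain in [
        ("flower_size", "log10_flower_size", np.log10, "positive"),
        ("d_prime", "sqrt_d_prime", np.sqrt, "non-negative"),
        ("strength", "sqrt_strength", np.sqrt, "non-negative"),
        ("closeness", "sqrt_closeness", np.sqrt, "non-negative"),
    ]:
        if col not in out:
            continue
        vals = out[col].astype(float)
        bad = vals < 0 if domain == "non-negative" else vals <= 0
        if bad.any():
            raise ValueError(f"column {col!r} invalid for species {list(out.index[bad])}")
        out[new] = fn(vals)
    if "hp_proportion" in out:
        vals = out["hp_proportion"].astype(float)
        if (vals < 0).any():
            raise ValueError(
                f"negative HP proportion for species {list(out.index[vals < 0])}"
            )
        out["zero_hp"] = vals == 0
        with np.errstate(divide="ignore"):
            out["log10_hp_proportion"] = np.where(vals > 0, np.log10(vals), np.nan)
    return out


@dataclass(frozen=True)
class RegressionResult:
    """Multiple-regression table with raw and standardized coefficients."""

    response: str
    terms: pd.DataFrame  # index: predictor; columns: coef, std_coef, t, p
    r_squared: float
    f_pvalue: float
    n: int

    def summary(self) -> str:
        lines = [
            f"OLS regression of {self.response} (n = {self.n})",
            f"  model R^2 = {self.r_squared:.3f}, model p = {self.f_pvalue:.4g}",
            self.terms.to_string(float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)


def fit_multiple_regression(
    table: pd.DataFrame, response: str, predictors: list[str]
) -> RegressionResult:
    """OLS with intercept; reports raw and standardized coefficients.

    Standardized coefficient of predictor x is b * SD(x) / SD(y) — the
    slope the regression would have with x and y scaled to unit variance.
    Rows with NaN in the response or any predictor are dropped.  Rank
    deficiency raises with the collinear terms named.
    """
    cols = [response] + list(predictors)
    data = table[cols].dropna()
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need n > {len(predictors) + 1} complete rows for {len(predictors)} predictors, have {n}"
        )
    y = data[response].astype(float)
    X = data[list(predictors)].astype(float)
    constant = [c for c in predictors if X[c].nunique() == 1]
    if constant:
        raise ValueError(f"constant predictor(s): {constant}")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient design; near-collinear terms {worst}")
    fit = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    terms = pd.DataFrame(
        {
            "coef": fit.params[predictors],
            "std_coef": [
                fit.params[c] * X[c].std(ddof=1) / sd_y for c in predictors
            ],
            "t": fit.tvalues[predictors],
            "p": fit.pvalues[predictors],
        }
    )
    return RegressionResult(response, terms, float(fit.rsquared), float(fit.f_pvalue), n)


@dataclass(frozen=True)
class AnovaResult:
    """Classic one-way between/within decomposition."""

    grouping: str
    groups: pd.DataFrame  # index: group; columns: n, mean, se
    fvalue: float
    pvalue: float
    df_between: int
    df_within: int

    def summary(self) -> str:
        return (
            f"One-way ANOVA across {self.grouping}: "
            f"F({self.df_between}, {self.df_within}) = {self.fvalue:.3f}, "
            f"p = {self.pvalue:.4g}\n" + self.groups.to_string()
        )


def one_way_anova(values, labels, grouping: str = "group") -> AnovaResult:
    """One-way ANOVA of ``values`` across the groups in ``labels``.

    F = MS(between) / MS(within) with p from the F distribution; per-group
    n, mean and SE are reported alongside.  NaN values are dropped first.
    """
    s = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(labels)})
    s = s.dropna(subset=["value"])
    grouped = s.groupby("group")["value"]
    k = grouped.ngroups
    if k < 2:
        raise ValueError("ANOVA requires at least two groups")
    N = len(s)
    df_b, df_w = k - 1, N - k
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = s["value"].mean()
    ssb = float((grouped.size() * (grouped.mean() - grand) ** 2).sum())
    ssw = float(((s["value"] - grouped.transform("mean")) ** 2).sum())
    if ssw <= 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    groups = pd.DataFrame(
        {
            "n": grouped.size(),
            "mean": grouped.mean(),
            "se": grouped.std(ddof=1) / np.sqrt(grouped.size()),
        }
    )
    return AnovaResult(grouping, groups, float(f), p, df_b, df_w)


#: variables compared across pattern groups and the transform each uses
_GROUP_COMPARISON_TRANSFORMS = {
    "mean_hp": None,
    "cv_hp": None,
    "mean_hp_div": None,
    "cv_hp_div": None,
    "visitor_diversity": None,
    "hp_proportion": "log10",
    "d_prime": "sqrt",
    "flower_size": "log10",
}


def pattern_group_comparison(
    table: pd.DataFrame,
    patterns: pd.Series,
    variables: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, AnovaResult]]:
    """Compare per-species variables across the three CP-HP pattern groups.

    ``table`` holds per-species columns; ``patterns`` maps species to
    'linear' / 'exponential' / 'no_pattern' (species with no HP are part
    of no_pattern).  Variables with a registered transform are transformed
    first (log10 drops zero values).  Returns a long-form table of group
    mean +- SE per variable and the ANOVA per variable; a variable whose
    groups collapse to fewer than two is reported without an F (warning).
    """
    if variables is None:
        variables = [v for v in _GROUP_COMPARISON_TRANSFORMS if v in table.columns]
    joined = table.join(patterns.rename("pattern_group"), how="inner")
    rows = []
    anovas: dict[str, AnovaResult] = {}
    for var in variables:
        transform = _GROUP_COMPARISON_TRANSFORMS.get(var)
        vals = joined[var].astype(float)
        if transform == "log10":
            with np.errstate(divide="ignore"):
                vals = pd.Series(
                    np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), np.nan),
                    index=vals.index,
                )
        elif transform == "sqrt":
            vals = np.sqrt(vals)
        sub = pd.DataFrame({"value": vals, "group": joined["pattern_group"]}).dropna()
        try:
            res = one_way_anova(sub["value"], sub["group"], grouping=f"{var} pattern groups")
            anovas[var] = res
            for grp, r in res.groups.iterrows():
                rows.append(
                    {
                        "variable": var,
                        "transform": transform or "none",
                        "group": grp,
                        "n": int(r["n"]),
                        "mean": r["mean"],
                        "se": r["se"],
                        "F": res.fvalue,
                        "p": res.pvalue,
                    }
                )
        except ValueError as exc:
            warnings.warn(f"{var}: {exc}; groups reported without F")
            for grp, g in sub.groupby("group")["value"]:
                rows.append(
                    {
                        "variable": var,
                        "transform": transform or "none",
                        "group": grp,
                        "n": len(g),
                        "mean": g.mean(),
                        "se": g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan,
                        "F": np.nan,
                        "p": np.nan,
                    }
                )
    return pd.DataFrame(rows), anovas
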