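"""Per-feature group-difference statistics.

For every extracted feature: a one-way ANCOVA (linear model
``feature ~ group + age``) with an F test on the group term, Benjamini-
Hochberg false-discovery-rate adjustment across the feature family, and
Tukey HSD pairwise comparisons on age-adjusted values.  These screens are
deliberately independent of the classification framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class FeatureStatResult:
    """ANCOVA + Tukey summary for one feature."""

    feature: str
    f_stat: float
    p_value: float
    p_adjusted: float = np.nan
    excluded: bool = False              # constant feature: F undefined
    tukey: pd.DataFrame | None = field(default=None, repr=False)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tukey_age_adjusted(y: np.ndarray, groups: np.ndarray, age: np.ndarray,
                        age_coef: float) -> pd.DataFrame:
    """Tukey HSD on values with the fitted linear age effect removed."""
    adjusted = y - age_coef * (age - age.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pairwise_tukeyhsd(adjusted, groups, alpha=ALPHA)
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])


def ancova_by_feature(table: pd.DataFrame, feature_cols: list[str] | None = None,
                      group_col: str = "group", age_col: str = "age",
                      with_tukey: bool = True) -> list[FeatureStatResult]:
    """ANCOVA (feature ~ group + age) per feature with BH adjustment.

    Rows with a missing feature value are dropped per feature.  Constant
    features are flagged ``excluded`` and kept out of the FDR family.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in (group_col, age_col)]
    groups = table[group_col]
    if groups.nunique() < 2 or groups.value_counts().min() < 2:
        raise ValueError("need at least 2 groups with at least 2 subjects each")
    results: list[FeatureStatResult] = []
    for feat in feature_cols:
        sub = pd.DataFrame({
            "y": pd.to_numeric(table[feat], errors="coerce"),
            "g": groups,
            "age": table[age_col],
        }).dropna()
        if sub["y"].nunique() <= 1:
            results.append(FeatureStatResult(feature=feat, f_stat=np.nan,
                                             p_value=np.nan, excluded=True))
            continue
        model = smf.ols("y ~ C(g) + age", data=sub).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        f_stat = float(anova.loc["C(g)", "F"])
        p = float(anova.loc["C(g)", "PR(>F)"])
        tukey = None
        if with_tukey:
            tukey = _tukey_age_adjusted(sub["y"].to_numpy(),
                                        sub["g"].to_numpy(),
                                        sub["age"].to_numpy(),
                                        float(model.params.get("age", 0.0)))
        results.append(FeatureStatResult(feature=feat, f_stat=f_stat,
                                         p_value=p, tukey=tukey))
    tested = [r for r in results if not r.excluded]
    if tested:
        adj = bh_adjust([r.p_value for r in tested])
        for r, a in zip(tested, adj):
            r.p_adjusted = float(a)
    return results


def stats_table(results: list[FeatureStatResult]) -> pd.DataFrame:
    """Tidy one-row-per-feature summary of ANCOVA results."""
    return pd.DataFrame([
        {"feature": r.feature, "F": r.f_stat, "p": r.p_value,
         "p_fdr": r.p_adjusted, "excluded": r.excluded,
         "significant": (not r.excluded) and r.p_adjusted < ALPHA}
        for r in results
    ])


def tukey_table(results: list[FeatureStatResult]) -> pd.DataFrame:
    """Long-format Tukey pairwise comparisons across all features."""
    frames = []
    for r in results:
        if r.tukey is not None:
            t = r.tukey.copy()
            t.insert(0, "feature", r.feature)
            frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
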