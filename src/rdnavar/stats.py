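"""Decision-gated statistical battery used throughout the analysis.

One auditable home for: the Shapiro-gated ANOVA/Kruskal–Wallis location
test (with optional square-root transform, explicit logged sample
exclusions, and Tukey HSD post hoc after a significant ANOVA), the
one-sample t test, the 1:1 direction goodness-of-fit χ² (no continuity
correction, df = 1 — this is the arithmetic that reproduces classic
direction-count statistics such as 17-vs-11 → χ² = 1.286), and plain OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


def one_sample_t(values: Sequence[float], mu: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t test of mean(values) against ``mu``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("one-sample t needs n >= 2")
    if np.var(values, ddof=1) == 0:
        raise ValueError("zero variance: t statistic undefined")
    res = sps.ttest_1samp(values, mu)
    return float(res.statistic), float(res.pvalue)


def chisq_direction(n_inc: int, n_dec: int) -> tuple[float, float, int]:
    """Goodness-of-fit χ² of increase/decrease counts against 1:1.

    No continuity correction: chi2 = (n_inc-E)^2/E + (n_dec-E)^2/E with
    E = (n_inc+n_dec)/2, df = 1. Symmetric in its two arguments.
    """
    if n_inc < 0 or n_dec < 0:
        raise ValueError("counts must be non-negative")
    n = n_inc + n_dec
    if n < 1:
        raise ValueError("need at least one non-tied change")
    expected = n / 2.0
    chi2 = (n_inc - expected) ** 2 / expected + (n_dec - expected) ** 2 / expected
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p, 1


def ols(x: Sequence[float], y: Sequence[float]) -> dict:
    """Ordinary least squares of y on x with a two-sided slope test.

    Returns slope, intercept, r_squared, r_squared_adj and the slope
    p-value. Adjusted R² is reported because small-n diversity-vs-copy-
    number regressions are conventionally summarised with it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("OLS needs n >= 3")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "r_squared_adj": float(model.rsquared_adj),
        "p": float(model.pvalues[1]),
        "n": int(x.size),
    }


@dataclass
class GatedTestResult:
    """Outcome of a Shapiro-gated location test across treatment groups."""

    shapiro_p: float
    branch: str  # "anova" | "kruskal"
    statistic: float
    p: float
    transform: str
    excluded_samples: list[str] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None


def _apply_transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "sqrt":
        if (values < 0).any():
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(values)
    raise ValueError(f"unknown transform {transform!r}")


def gated_location_test(groups: Mapping[str, Sequence[float]],
                        transform: str = "none",
                        alpha_gate: float = 0.05,
                        alpha: float = 0.05,
                        exclude: Mapping[str, Sequence[str]] | None = None,
                        sample_ids: Mapping[str, Sequence[str]] | None = None,
                        shapiro_on: str = "residuals") -> GatedTestResult:
    """Normality-gated comparison of group locations.

    The transform (if any) is applied first; excluded samples (by id, via
    ``exclude`` and ``sample_ids``) are removed and logged in the result —
    exclusion is always explicit, never silent. Shapiro–Wilk then runs on
    pooled within-group residuals (default) or per group (gate = smallest
    p). If shapiro_p >= alpha_gate the branch is one-way ANOVA, followed
    by Tukey HSD when significant; otherwise Kruskal–Wallis on the group
    medians' behalf.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    excluded_log: list[str] = []
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if exclude and name in exclude:
            if not sample_ids or name not in sample_ids:
                raise ValueError("exclude requires sample_ids for the same groups")
            ids = list(sample_ids[name])
            keep = [i for i, sid in enumerate(ids) if sid not in set(exclude[name])]
            excluded_log.extend(sid for sid in ids if sid in set(exclude[name]))
            vals = vals[keep]
        if vals.size < 3:
            raise ValueError(f"group {name!r} has n < 3 after exclusions")
        arrays[name] = _apply_transform(vals, transform)
    if shapiro_on == "residuals":
        residuals = np.concatenate([v - v.mean() for v in arrays.values()])
        shapiro_p = float(sps.shapiro(residuals).pvalue)
    elif shapiro_on == "group":
        shapiro_p = float(min(sps.shapiro(v).pvalue for v in arrays.values()))
    else:
        raise ValueError("shapiro_on must be 'residuals' or 'group'")
    values = list(arrays.values())
    if shapiro_p >= alpha_gate:
        stat, p = sps.f_oneway(*values)
        posthoc = None
        if p < alpha:
            flat = np.concatenate(values)
            labels = np.concatenate([
                np.full(v.size, name) for name, v in arrays.items()])
            tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
            posthoc = pd.DataFrame(tk.summary().data[1:],
                                   columns=tk.summary().data[0])
        return GatedTestResult(shapiro_p=shapiro_p, branch="anova",
                               statistic=float(stat), p=float(p),
                               transform=transform,
                               excluded_samples=excluded_log, posthoc=posthoc)
    stat, p = sps.kruskal(*values)
    return GatedTestResult(shapiro_p=shapiro_p, branch="kruskal",
                           statistic=float(stat), p=float(p),
                           transform=transform, excluded_samples=excluded_log)
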