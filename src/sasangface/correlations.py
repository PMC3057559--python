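"""Pearson correlations and Fisher-z comparison of two correlations.

Fisher's z transformation z = atanh(r) renders a sample correlation
approximately normal with variance 1/(n − 3), so two independent sample
correlations (r1, n1) and (r2, n2) can be compared with the standardized
difference

    z_stat = (atanh(r1) − atanh(r2)) / sqrt(1/(n1−3) + 1/(n2−3))

and a two-sided standard-normal p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

__all__ = [
    "CorrelationComparison",
    "pearson_r",
    "fisher_compare",
    "significance_stars",
    "correlation_table",
]


@dataclass(frozen=True)
class CorrelationComparison:
    """Two (r, n) pairs with their Fisher-z statistic and two-sided p-value."""

    r1: float
    n1: int
    r2: float
    n2: int
    z1: float
    z2: float
    z_stat: float
    p: float


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value (t, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlations via Fisher's z transformation."""
    for r, n, tag in ((r1, n1, "first"), (r2, n2, "second")):
        if not abs(r) < 1:
            raise ValueError(f"{tag} correlation must satisfy |r| < 1, got {r}")
        if n <= 3:
            raise ValueError(f"{tag} sample size must exceed 3, got {n}")
    z1 = math.atanh(r1)
    z2 = math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z_stat))
    return CorrelationComparison(r1, n1, r2, n2, z1, z2, z_stat, float(p))


def significance_stars(p: float) -> str:
    """Star code at the conventional .05 / .01 / .001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(
    records: pd.DataFrame,
    external: pd.DataFrame | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """BMI–metric correlation report per sex, with Fisher comparisons.

    ``records`` must carry sex, age_group ('20s'/'60s'), bmi and the metric
    columns.  ``external`` (optional) carries published comparison pairs
    with columns metric, sex, r, n; the comparison is made against the 20s
    stratum, matching the design of the published table.

    Returns one row per (metric, sex) with r, n, p and stars for both age
    strata, the 20s-vs-60s Fisher p, and the 20s-vs-external Fisher p where
    an external pair exists.  Strata below ``min_n`` give missing cells.
    """
    rows = []
    for metric in METRIC_NAMES:
        for sex in ("M", "F"):
            row: dict = {"metric": metric, "sex": sex}
            by_age: dict[str, tuple[float, int]] = {}
            for age in ("20s", "60s"):
                sub = records[(records["sex"] == sex) & (records["age_group"] == age)]
                if len(sub) < min_n:
                    row[f"r_{age}"] = np.nan
                    row[f"n_{age}"] = len(sub)
                    row[f"p_{age}"] = np.nan
                    row[f"stars_{age}"] = ""
                    continue
                r, p = pearson_r(sub["bmi"].to_numpy(), sub[metric].to_numpy())
                by_age[age] = (r, len(sub))
                row[f"r_{age}"] = r
                row[f"n_{age}"] = len(sub)
                row[f"p_{age}"] = p
                row[f"stars_{age}"] = significance_stars(p)
            if "20s" in by_age and "60s" in by_age:
                cmp_ages = fisher_compare(*by_age["20s"], *by_age["60s"])
                row["p_20s_vs_60s"] = cmp_ages.p
            else:
                row["p_20s_vs_60s"] = np.nan
            row["p_20s_vs_external"] = np.nan
            if external is not None and "20s" in by_age:
                match = external[(external["metric"] == metric) & (external["sex"] == sex)]
                if len(match) == 1:
                    ext = match.iloc[0]
                    cmp_ext = fisher_compare(
                        *by_age["20s"], float(ext["r"]), int(ext["n"])
                    )
                    row["p_20s_vs_external"] = cmp_ext.p
            rows.append(row)
    return pd.DataFrame(rows)
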