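"""One-way ANOVA across Sasang types with Duncan multiple-range lettering.

Duncan's multiple range test compares spans of p adjacent ordered group
means against the critical range

    R_p = q(α_p; p, df) · sqrt(MSE / n_h),   α_p = 1 − (1 − α)^(p−1),

where q is the studentized-range quantile, MSE the ANOVA within-group mean
square, and n_h the harmonic mean of the group sizes (the unequal-n
convention used here).  A range is declared non-significant only together
with every range containing it (protection), and groups inside a
non-significant range share a letter; letters a, b, c, … are assigned in
descending order of the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "duncan_letters",
    "studentized_range_quantile",
    "group_table",
]


@dataclass
class AnovaResult:
    """One-way ANOVA summary with per-group statistics."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_names: list[str]
    group_means: np.ndarray
    group_sds: np.ndarray
    group_ns: np.ndarray
    mse: float
    duncan_letters: dict[str, str] | None = field(default=None)


def _check_groups(groups, names):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    if names is None:
        names = [f"group{i}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("names must match the number of groups")
    return arrays, list(names)


def one_way_anova(groups, names=None) -> AnovaResult:
    """Standard one-way ANOVA: between/within mean-square ratio, F p-value."""
    arrays, names = _check_groups(groups, names)
    ns = np.array([len(g) for g in arrays], dtype=float)
    means = np.array([g.mean() for g in arrays])
    sds = np.array([g.std(ddof=1) if len(g) > 1 else 0.0 for g in arrays])
    N = ns.sum()
    k = len(arrays)
    if N - k < 1:
        raise ValueError("not enough observations for a within-group df")
    grand = float(np.sum(ns * means) / N)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in arrays))
    df_b, df_w = k - 1, int(N - k)
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0:
        F = 0.0 if ms_between == 0 else np.inf
    else:
        F = ms_between / mse
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), df_between=df_b, df_within=df_w, p=p,
        group_names=names, group_means=means, group_sds=sds,
        group_ns=ns.astype(int), mse=mse,
    )


@lru_cache(maxsize=4096)
def studentized_range_quantile(alpha: float, p: int, df: float) -> float:
    """Upper-α quantile of the studentized range with p means and df error df.

    Computed by scipy's numerical integration of the studentized-range
    distribution; memoized because the quantile is expensive and post-hoc
    letterings reuse the same (α, p, df) triples.
    """
    q = stats.studentized_range.isf(alpha, p, df)
    if not np.isfinite(q):
        raise ValueError(f"studentized-range quantile failed for p={p}, df={df}")
    return float(q)


def duncan_letters(groups, alpha: float = 0.05, names=None) -> dict[str, str]:
    """Duncan multiple-range letter assignment for the given groups.

    Groups that are not separated at the protected significance level share
    a letter; letters run a, b, c, … in descending order of the means.
    """
    res = one_way_anova(groups, names=names)
    k = len(res.group_names)
    order = np.argsort(-res.group_means)
    means = res.group_means[order]
    ordered_names = [res.group_names[i] for i in order]
    n_h = k / float(np.sum(1.0 / res.group_ns))

    crit = {}
    for p in range(2, k + 1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        q = studentized_range_quantile(alpha_p, p, res.df_within)
        crit[p] = q * np.sqrt(res.mse / n_h)

    # top-down protected scan: a window inside a non-significant window is
    # itself non-significant and never tested
    blocks: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(bi <= i and j <= bj for bi, bj in blocks):
                continue
            if means[i] - means[j] <= crit[span]:
                blocks.append((i, j))
    covered = set()
    for bi, bj in blocks:
        covered.update(range(bi, bj + 1))
    intervals = sorted(blocks + [(i, i) for i in range(k) if i not in covered])

    letters = {name: "" for name in ordered_names}
    for letter_idx, (bi, bj) in enumerate(intervals):
        letter = chr(ord("a") + letter_idx)
        for i in range(bi, bj + 1):
            letters[ordered_names[i]] += letter
    return letters


def group_table(
    records: pd.DataFrame,
    variables=None,
    by=("sex", "age_group"),
    group_col: str = "sasang_type",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum mean (SD), ANOVA p, and Duncan letters for each variable.

    Mirrors the published group-summary layout: one row per
    (stratum, variable), with per-type ``mean``, ``sd``, ``n`` and
    ``letter`` columns plus the ANOVA F and p.
    """
    if variables is None:
        variables = ["bmi", *METRIC_NAMES]
    rows = []
    for stratum_key, sub in records.groupby(list(by), sort=True):
        types = sorted(sub[group_col].unique())
        for var in variables:
            groups = [sub.loc[sub[group_col] == t, var].to_numpy() for t in types]
            res = one_way_anova(groups, names=types)
            letters = duncan_letters(groups, alpha=alpha, names=types)
            row = {
                "stratum": "".join(str(v) for v in stratum_key),
                "variable": var,
                "F": res.F,
                "p": res.p,
            }
            for t, m, s, n in zip(types, res.group_means, res.group_sds, res.group_ns):
                row[f"mean_{t}"] = m
                row[f"sd_{t}"] = s
                row[f"n_{t}"] = int(n)
                row[f"letter_{t}"] = letters[t] if res.p < alpha else ""
            rows.append(row)
    return pd.DataFrame(rows)
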