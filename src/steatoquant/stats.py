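"""Cohort-level statistics: KS test, one-way ANOVA, correlation.

Conventions: the two-sample Kolmogorov--Smirnov test uses the asymptotic
two-sided p-value; ANOVA is the classical between/within decomposition;
correlation defaults to a rank (Spearman) coefficient because grades and
burden readouts are ordinal, with Pearson available by flag. Significance
defaults to alpha = 0.05 and no multiple-testing correction; a Holm option
exists for users who want family-wise control.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import SteatosisProfile, parameter_names

ALPHA = 0.05


def ks_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]):
    """One-way ANOVA: F = MSB/MSW with p from the F distribution.

    Degenerate inputs (zero within-group variance) yield ``(nan, nan)``
    when the means are also equal, and ``(inf, 0.0)`` otherwise.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    n_total = sum(a.size for a in arrays)
    if n_total <= len(arrays):
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        return (math.nan, math.nan) if ssb == 0.0 else (math.inf, 0.0)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "spearman"
) -> tuple[float, float]:
    """Rank (default) or linear correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlate requires paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan  # undefined for constant input
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method}")
    return float(r), float(p)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _profile_values(profiles: Sequence) -> pd.DataFrame:
    rows = []
    for pr in profiles:
        if isinstance(pr, SteatosisProfile):
            rows.append(pr.values)
        else:
            rows.append({k: pr[k] for k in parameter_names() if k in pr})
    return pd.DataFrame(rows)


def compare_cohort(
    profiles: Mapping[str, Sequence],
    diameters: Mapping[str, Sequence[float]] | None = None,
    alpha: float = ALPHA,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-parameter ANOVA across groups plus pairwise KS on diameters.

    Returns a tidy table with columns ``parameter``, ``comparison``,
    ``test``, ``statistic``, ``p`` and ``significant`` (p < alpha). With
    ``holm=True`` an ``p_adjusted`` column drives significance instead.
    """
    names = list(profiles)
    if len(names) < 2:
        raise ValueError("compare_cohort requires >= 2 groups")
    tables = {g: _profile_values(profiles[g]) for g in names}
    rows = []
    for param in parameter_names():
        series = {g: tables[g][param].dropna().to_numpy() for g in names}
        if any(v.size == 0 for v in series.values()):
            continue
        try:
            f, p = one_way_anova(series)
        except ValueError:
            continue
        rows.append(
            {
                "parameter": param,
                "comparison": "|".join(names),
                "test": "anova",
                "statistic": f,
                "p": p,
            }
        )
    if diameters is not None:
        for g1, g2 in itertools.combinations(diameters, 2):
            a, b = np.asarray(diameters[g1]), np.asarray(diameters[g2])
            if a.size == 0 or b.size == 0:
                continue
            d, p = ks_test(a, b)
            rows.append(
                {
                    "parameter": "diameter_distribution",
                    "comparison": f"{g1}|{g2}",
                    "test": "ks",
                    "statistic": d,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if holm:
        table["p_adjusted"] = holm_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
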