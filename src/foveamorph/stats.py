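"""Cohort statistics: normality, correlation structure, layer proportions
and two-group comparisons.

These are the standard analyses applied to per-eye metrics tables:
Shapiro–Wilk normality per parameter, pairwise Pearson correlation
matrices with significance flags at α = 0.001, per-eye layer proportions
of central retinal thickness, and independent two-sample t-tests with
optional Welch correction (from raw data or from published summary
statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "CorrelationMatrix",
    "normality_test",
    "correlation_matrix",
    "layer_proportions",
    "group_compare",
    "group_compare_from_summary",
]


class NormalityResult(NamedTuple):
    W: float
    p: float
    n: int


def normality_test(values) -> NormalityResult:
    """Shapiro–Wilk test of normality (3 ≤ n ≤ 5000, non-constant input)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = sps.shapiro(x)
    return NormalityResult(W=float(w), p=float(p), n=int(x.size))


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values.

    ``significant`` flags p < alpha (default 0.001).  Pairs are computed
    on pairwise-complete observations; pairs with fewer than 3 complete
    rows or a zero-variance member are reported as missing.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.001

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha

    def to_long(self) -> pd.DataFrame:
        rows = []
        params = list(self.r.index)
        for a, b in combinations(params, 2):
            rows.append(
                {
                    "param_a": a,
                    "param_b": b,
                    "r": self.r.loc[a, b],
                    "p": self.p.loc[a, b],
                    "n": self.n.loc[a, b],
                    "significant": bool(self.p.loc[a, b] < self.alpha)
                    if np.isfinite(self.p.loc[a, b])
                    else False,
                }
            )
        return pd.DataFrame(rows)


def correlation_matrix(
    metrics: pd.DataFrame, params: list[str], alpha: float = 0.001
) -> CorrelationMatrix:
    """Pairwise Pearson correlation matrix over the given parameters."""
    for p in params:
        if p not in metrics.columns:
            raise ValueError(f"metrics table lacks parameter column {p!r}")
    k = len(params)
    r = np.eye(k)
    pmat = np.zeros((k, k))
    nmat = np.full((k, k), len(metrics))
    for (i, a), (j, b) in combinations(enumerate(params), 2):
        sub = metrics[[a, b]].dropna()
        nmat[i, j] = nmat[j, i] = len(sub)
        if len(sub) < 3:
            r[i, j] = r[j, i] = np.nan
            pmat[i, j] = pmat[j, i] = np.nan
            warnings.warn(f"fewer than 3 complete rows for pair ({a}, {b})")
            continue
        if sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r[i, j] = r[j, i] = np.nan
            pmat[i, j] = pmat[j, i] = np.nan
            warnings.warn(f"zero variance in pair ({a}, {b}); correlation undefined")
            continue
        res = sps.pearsonr(sub[a], sub[b])
        r[i, j] = r[j, i] = res.statistic
        pmat[i, j] = pmat[j, i] = res.pvalue
    idx = pd.Index(params)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        alpha=alpha,
    )


#: per-eye ratio columns added by layer_proportions
PROPORTION_COLUMNS = ("prop_inner_plus_onl", "prop_onl", "prop_gclp")


def layer_proportions(
    metrics: pd.DataFrame, by: str = "group_label"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-eye layer proportions of central retinal thickness and their
    group summaries.

    Ratios per eye: (GCL+ + ONL)/RT, ONL/RT and GCL+/RT, all at the
    foveal centre; the first equals the sum of the other two exactly.
    Rows with non-positive RT@FC are rejected (dropped with a warning
    naming the eyes).  Returns ``(per_eye, summary)`` where ``summary``
    has group-wise mean and SD of each ratio.
    """
    required = ("GCLp_FC", "ONL_FC", "RT_FC")
    for c in required:
        if c not in metrics.columns:
            raise ValueError(f"metrics table lacks column {c!r}")
    bad = metrics["RT_FC"] <= 0
    if bad.any():
        ids = (
            metrics.loc[bad, "eye_id"].tolist()
            if "eye_id" in metrics.columns
            else metrics.index[bad].tolist()
        )
        warnings.warn(f"rejecting {int(bad.sum())} row(s) with non-positive RT_FC: {ids}")
        metrics = metrics.loc[~bad]
    per_eye = metrics.copy()
    per_eye["prop_inner_plus_onl"] = (per_eye["GCLp_FC"] + per_eye["ONL_FC"]) / per_eye["RT_FC"]
    per_eye["prop_onl"] = per_eye["ONL_FC"] / per_eye["RT_FC"]
    per_eye["prop_gclp"] = per_eye["GCLp_FC"] / per_eye["RT_FC"]
    if by in per_eye.columns:
        grouped = per_eye.groupby(by)[list(PROPORTION_COLUMNS)]
    else:
        grouped = per_eye.assign(_all="all").groupby("_all")[list(PROPORTION_COLUMNS)]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{ratio}_{stat}" for ratio, stat in summary.columns]
    return per_eye, summary


def _welch_or_student(mean1, sd1, n1, mean2, sd2, n2, welch: bool):
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 == 0 and sd2 == 0:
        # degenerate: no within-group variability
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        return np.inf, float(n1 + n2 - 2), 0.0
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    return float(res.statistic), float(df), float(res.pvalue)


def group_compare(
    data: pd.DataFrame,
    variables: list[str],
    group_col: str,
    welch: bool = True,
) -> pd.DataFrame:
    """Two-sided independent t-test per variable between two groups.

    Listwise deletion per variable; Welch–Satterthwaite correction by
    default (``welch=False`` for the pooled-variance Student test).
    """
    groups = data[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}, got {list(groups)}")
    g1, g2 = groups
    rows = []
    for var in variables:
        a = data.loc[data[group_col] == g1, var].dropna().to_numpy(dtype=float)
        b = data.loc[data[group_col] == g2, var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"each group needs at least 2 observations for {var!r}")
        t, df, p = _welch_or_student(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, welch
        )
        rows.append(
            {
                "variable": var,
                "group1": g1,
                "mean1": a.mean(),
                "sd1": a.std(ddof=1),
                "n1": a.size,
                "group2": g2,
                "mean2": b.mean(),
                "sd2": b.std(ddof=1),
                "n2": b.size,
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def group_compare_from_summary(rows: Iterable[dict], welch: bool = True) -> pd.DataFrame:
    """Reconstruct two-group comparisons from summary statistics.

    Each row dict needs ``variable, mean1, sd1, n1, mean2, sd2, n2``;
    extra keys (e.g. a published p-value) are carried through.
    """
    out = []
    for row in rows:
        t, df, p = _welch_or_student(
            row["mean1"], row["sd1"], row["n1"], row["mean2"], row["sd2"], row["n2"], welch
        )
        rec = dict(row)
        rec.update({"t": t, "df": df, "p": p})
        out.append(rec)
    return pd.DataFrame(out)
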