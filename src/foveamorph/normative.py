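"""Normative control limits (mean ± 2 SD) and within/outside classification.

The limit for each parameter is the control-cohort sample mean plus twice
the sample SD (upper limit, thickness parameters) or minus twice the SD
(lower limit, foveal depth).  An eye is *outside* the limit on strict
exceedance; a value exactly on the limit counts as within.  Outside
proportions carry exact (Clopper–Pearson) binomial 95 % confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import reference as ref

__all__ = [
    "DEFAULT_DIRECTIONS",
    "NormativeLimits",
    "ClassificationResult",
    "compute_limits",
    "classify",
    "compare_with_published",
    "summarize_cohorts",
]

#: foveal depth shrinks in immaturity, thicknesses grow
DEFAULT_DIRECTIONS = {
    "GCLp_FC": "upper",
    "GCLp_Q2Q": "upper",
    "ONL_FC": "upper",
    "RT_FC": "upper",
    "FD": "lower",
}


@dataclass
class NormativeLimits:
    """Per-parameter control mean, SD, direction and limit (full precision)."""

    table: pd.DataFrame  # index: parameter; columns: control_mean, control_sd, direction, limit
    n_controls: int
    k: float = 2.0

    def limit(self, param: str) -> float:
        return float(self.table.loc[param, "limit"])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["limit_printed"] = out["limit"].round(1)
        out["n_controls"] = self.n_controls
        return out


@dataclass
class ClassificationResult:
    """Per-eye outside flags and per-parameter outside proportions."""

    outside: pd.DataFrame  # bool, index eye_id, columns parameters
    summary: pd.DataFrame  # index parameter; n_eyes, n_outside, proportion_outside, ci_low, ci_high

    @property
    def n_eyes(self) -> int:
        return len(self.outside)


def compute_limits(
    control_metrics: pd.DataFrame,
    params: list[str] | None = None,
    directions: dict[str, str] | None = None,
    k: float = 2.0,
) -> NormativeLimits:
    """Compute mean ± k·SD control limits from a control metrics table.

    Sample SD uses the n−1 denominator.  Requires at least two control
    eyes and no missing values in the used columns; a zero-variance
    parameter yields limit = mean with a warning.
    """
    params = list(params or ref.REPORTED_PARAMS)
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    n = len(control_metrics)
    if n < 2:
        raise ValueError(f"need at least 2 control eyes to compute limits, got {n}")
    rows = []
    for p in params:
        if p not in control_metrics.columns:
            raise ValueError(f"control metrics table lacks column {p!r}")
        values = control_metrics[p].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError(f"missing values in control column {p!r}")
        d = directions.get(p)
        if d not in ("upper", "lower"):
            raise ValueError(f"no limit direction for parameter {p!r}")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if sd == 0.0:
            warnings.warn(f"zero variance in control parameter {p!r}; limit equals the mean")
        limit = mean + k * sd if d == "upper" else mean - k * sd
        rows.append((p, mean, sd, d, limit))
    table = pd.DataFrame(
        rows, columns=["parameter", "control_mean", "control_sd", "direction", "limit"]
    ).set_index("parameter")
    return NormativeLimits(table=table, n_controls=n, k=k)


def classify(metrics: pd.DataFrame, limits: NormativeLimits) -> ClassificationResult:
    """Classify each eye as within/outside each parameter's control limit.

    Outside means strictly beyond the limit in the abnormal direction;
    boundary equality is within.
    """
    params = list(limits.table.index)
    missing = [p for p in params if p not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table lacks parameter column(s) {missing}")
    index = metrics["eye_id"] if "eye_id" in metrics.columns else metrics.index
    outside = pd.DataFrame(index=pd.Index(index, name="eye_id"))
    for p in params:
        v = metrics[p].to_numpy(dtype=float)
        lim = limits.limit(p)
        if limits.table.loc[p, "direction"] == "upper":
            outside[p] = v > lim
        else:
            outside[p] = v < lim
    n = len(outside)
    rows = []
    for p in params:
        count = int(outside[p].sum())
        lo, hi = proportion_confint(count, n, alpha=0.05, method="beta")
        rows.append((p, n, count, count / n, float(lo), float(hi)))
    summary = pd.DataFrame(
        rows,
        columns=["parameter", "n_eyes", "n_outside", "proportion_outside", "ci95_low", "ci95_high"],
    ).set_index("parameter")
    return ClassificationResult(outside=outside, summary=summary)


def compare_with_published(
    limits: NormativeLimits,
    published: dict[str, float] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Check recomputed limits against published one-decimal limits.

    A limit is consistent when it matches the published value at the
    printed precision (|Δ| ≤ half a unit in the last printed digit).
    Inconsistent entries — e.g. a published limit that cannot be the
    printed mean + 2 SD — are flagged rather than adopted.
    """
    published = dict(ref.PUBLISHED_LIMITS if published is None else published)
    tol = 0.5 * 10.0**-decimals + 1e-9
    rows = []
    for p, pub in published.items():
        if p not in limits.table.index:
            continue
        computed = limits.limit(p)
        rows.append((p, computed, pub, abs(computed - pub) <= tol))
    return pd.DataFrame(
        rows, columns=["parameter", "computed_limit", "published_limit", "consistent"]
    ).set_index("parameter")


def summarize_cohorts(
    control_metrics: pd.DataFrame,
    test_metrics: pd.DataFrame,
    limits: NormativeLimits,
    classification: ClassificationResult,
) -> pd.DataFrame:
    """Normative summary table: per-parameter range and mean ± SD for both
    cohorts, the control limit and the test-cohort outside percentage."""
    rows = []
    for p in limits.table.index:
        c = control_metrics[p].to_numpy(dtype=float)
        t = test_metrics[p].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": p,
                "control_min": c.min(),
                "control_max": c.max(),
                "control_mean": c.mean(),
                "control_sd": c.std(ddof=1),
                "test_min": t.min(),
                "test_max": t.max(),
                "test_mean": t.mean(),
                "test_sd": t.std(ddof=1),
                "direction": limits.table.loc[p, "direction"],
                "limit": limits.limit(p),
                "pct_test_outside": 100.0 * classification.summary.loc[p, "proportion_outside"],
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
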