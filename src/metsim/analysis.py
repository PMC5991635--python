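"""Ranking, summarizing and comparing trajectory ensembles.

The standard workflow keeps the best-fitting fraction of the ensemble
(top 10% by total WSSE), summarizes a quantity by its per-day median
with a central inter-quantile band (45th–55th percentiles by default,
i.e. the 10% range around the median) and the per-day mean, and
compares group summaries by their median difference.  A one-way ANOVA
with Fisher's LSD post-hoc test is provided for terminal endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .adapt import Ensemble, ParameterTrajectory

__all__ = [
    "select_top_fraction",
    "summarize",
    "compare_groups",
    "endpoint_stats",
    "AnovaResult",
]


def select_top_fraction(ensemble: Ensemble, fraction: float = 0.10
                        ) -> Ensemble:
    """Keep the ⌊fraction·N⌋ members with the lowest total WSSE.

    Ties are broken by member seed for determinism.  ``fraction=1``
    keeps everything.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    k = math.floor(fraction * len(ensemble))
    if k < 1:
        raise ValueError(
            f"fraction {fraction} of {len(ensemble)} members keeps none")
    ranked = sorted(ensemble.members,
                    key=lambda m: (m.wsse_total, m.seed))
    return Ensemble(ranked[:k], list(ensemble.failures), ensemble.config)


def summarize(ensemble: Ensemble | list[ParameterTrajectory],
              quantity: str,
              band: tuple[float, float] = (45.0, 55.0)) -> pd.DataFrame:
    """Per-day median, central band and mean of a named quantity.

    ``quantity`` is ``"state:<pool>"``, ``"flux:<name>"`` or
    ``"param:<name>"``; the band defaults to the central 10%
    inter-quantile range around the median.
    """
    members = ensemble.members if isinstance(ensemble, Ensemble) \
        else list(ensemble)
    if not members:
        raise ValueError("empty ensemble")
    values = np.stack([m.series(quantity) for m in members])  # (N, nt)
    lo, hi = band
    return pd.DataFrame({
        "day": members[0].days,
        "median": np.median(values, axis=0),
        "lo": np.percentile(values, lo, axis=0),
        "hi": np.percentile(values, hi, axis=0),
        "mean": np.mean(values, axis=0),
    })


def compare_groups(summary_a: pd.DataFrame, summary_b: pd.DataFrame
                   ) -> pd.DataFrame:
    """Per-day difference of two group summaries (A − B).

    Returns a frame with the median difference per day; its attrs carry
    the fraction of days on which the sign of the difference is
    consistent with the endpoint, and the endpoint ratio A/B.
    """
    if len(summary_a) != len(summary_b) or \
            not np.allclose(summary_a["day"], summary_b["day"]):
        raise ValueError("summaries are on different day grids")
    diff = summary_a["median"].to_numpy() - summary_b["median"].to_numpy()
    out = pd.DataFrame({"day": summary_a["day"], "median_diff": diff})
    end = diff[-1]
    sign = np.sign(end) if end != 0 else 1.0
    out.attrs["sign_consistency"] = float(np.mean(np.sign(diff) == sign)) \
        if len(diff) else float("nan")
    b_end = summary_b["median"].to_numpy()[-1]
    out.attrs["endpoint_ratio"] = float(
        summary_a["median"].to_numpy()[-1] / b_end) if b_end != 0 \
        else float("inf")
    out.attrs["endpoint_diff"] = float(end)
    return out


@dataclass
class AnovaResult:
    """One-way ANOVA with Fisher's LSD pairwise post-hoc tests."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, t, p


def endpoint_stats(groups: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA over per-individual terminal values,
    with Fisher's LSD (unadjusted pairwise t-tests on the pooled
    within-group variance) as post-hoc comparison.
    """
    names = sorted(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 individuals each")
    if all(np.allclose(s, np.mean(np.concatenate(samples))) for s in samples):
        raise ValueError("degenerate data: zero variance everywhere")
    f_stat, p_val = stats.f_oneway(*samples)
    n_total = sum(len(s) for s in samples)
    k = len(samples)
    df_b, df_w = k - 1, n_total - k
    # pooled within-group mean square for the LSD tests
    msw = sum(((len(s) - 1) * np.var(s, ddof=1) for s in samples)) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = float(np.mean(a) - np.mean(b))
            se = math.sqrt(msw * (1 / len(a) + 1 / len(b)))
            t = diff / se if se > 0 else math.inf
            p = 2 * stats.t.sf(abs(t), df_w)
            rows.append({"group_a": names[i], "group_b": names[j],
                         "diff": diff, "t": t, "p": p})
    return AnovaResult(
        float(f_stat), float(p_val), df_b, df_w,
        {n: float(np.mean(s)) for n, s in zip(names, samples)},
        {n: float(np.std(s, ddof=1)) for n, s in zip(names, samples)},
        {n: int(len(s)) for n, s in zip(names, samples)},
        pd.DataFrame(rows))
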