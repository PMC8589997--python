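"""Group summaries and contrasts for the UVA1 stress-response study.

The unit of inference is the basal-layer ROI or the single dermal fibroblast
— never the pixel.  Groups are summarized as mean ± s.e.m.; pairwise
contrasts default to the two-sided Mann-Whitney rank-sum test (robust to the
skew of bounded fractions; Welch's t is available) and significance is
reported in the conventional tiers ns / * / ** / *** at p thresholds
0.05, 0.01 and 0.001.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Condition, Layer, Timepoint

__all__ = [
    "ContrastResult", "significance_tier", "summarize", "contrast",
    "dynamics_report", "dose_response",
]

TIER_THRESHOLDS = (0.05, 0.01, 0.001)


def significance_tier(p: float) -> str:
    """Map a p-value to its printed tier: ns, *, **, ***.

    A pure step function of p against the thresholds 0.05 / 0.01 / 0.001.
    """
    if not np.isfinite(p) or not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ContrastResult:
    """Two-group comparison on the study-unit scale."""

    group_a: dict
    group_b: dict
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    statistic: float
    p_value: float
    tier: str
    method: str
    low_n: bool = False

    @property
    def direction(self) -> int:
        """Sign of (b - a) if significant, else 0."""
        if self.tier == "ns":
            return 0
        return int(np.sign(self.mean_b - self.mean_a))


def summarize(table: pd.DataFrame, grouping: list[str],
              value: str = "f_bound") -> pd.DataFrame:
    """Per-group mean, s.e.m. (sd / sqrt(n) over units) and unit count.

    A single-unit group has an undefined s.e.m., reported as missing.
    """
    missing = [c for c in grouping if c not in table.columns]
    if missing:
        raise KeyError(f"grouping columns not in table: {missing}")
    out = (table.groupby(grouping, observed=True)[value]
           .agg(mean="mean", sem="sem", n="count").reset_index())
    out.loc[out["n"] < 2, "sem"] = np.nan
    return out


def _select(table: pd.DataFrame, descriptor: dict) -> pd.DataFrame:
    sel = table
    for col, val in descriptor.items():
        sel = sel[sel[col] == val]
    return sel


def contrast(table: pd.DataFrame, group_a: dict, group_b: dict,
             method: str = "ranksum", value: str = "f_bound") -> ContrastResult:
    """Two-sided contrast between two groups described by column filters.

    ``method`` is ``"ranksum"`` (Mann-Whitney U, default) or ``"welch"``.
    Groups with fewer than 3 units are flagged ``low_n``.
    """
    a = _select(table, group_a)[value].dropna().to_numpy()
    b = _select(table, group_b)[value].dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty contrast group: n_a={len(a)}, n_b={len(b)}")
    if method == "ranksum":
        if np.array_equal(a, b) or (np.ptp(np.concatenate([a, b])) == 0):
            stat, p = 0.0, 1.0  # identical samples: no evidence of a shift
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    elif method == "welch":
        res = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(p):
            stat, p = 0.0, 1.0
    else:
        raise ValueError(f"unknown contrast method {method!r}")
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    return ContrastResult(
        group_a=group_a, group_b=group_b, n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem(a), sem_b=sem(b), statistic=stat, p_value=p,
        tier=significance_tier(p), method=method,
        low_n=(len(a) < 3 or len(b) < 3),
    )


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def dynamics_report(table: pd.DataFrame, value: str = "f_bound",
                    method: str = "ranksum", baseline: str = "T0",
                    correction: str = "none") -> pd.DataFrame:
    """Directional change vs the pre-exposure baseline for every
    (layer, biomarker, condition, post-exposure timepoint) cell.

    Each cell contrasts that arm's units at the timepoint against the same
    arm's units at ``baseline`` and reports the signed direction (+/0/-)
    together with its significance tier — a machine-readable version of the
    per-panel time-course matrices.  ``correction="holm"`` adjusts the
    p-values across all cells of the report before assigning tiers
    (off by default, matching per-panel reporting).
    """
    needed = {"layer", "biomarker", "condition", "timepoint", value}
    if not needed.issubset(table.columns):
        raise KeyError(f"table lacks columns {needed - set(table.columns)}")
    timepoints = [t for t in table["timepoint"].unique() if t != baseline]
    if baseline not in set(table["timepoint"]):
        raise ValueError(f"baseline timepoint {baseline!r} absent from table")
    if not timepoints:
        raise ValueError("table has no post-exposure timepoint")
    rows = []
    for layer in sorted(table["layer"].unique()):
        for biomarker in sorted(table["biomarker"].unique()):
            for condition in sorted(table["condition"].unique()):
                for timepoint in timepoints:
                    base_desc = dict(layer=layer, biomarker=biomarker,
                                     condition=condition, timepoint=baseline)
                    post_desc = base_desc | dict(timepoint=timepoint)
                    if (len(_select(table, base_desc)) == 0
                            or len(_select(table, post_desc)) == 0):
                        continue
                    res = contrast(table, base_desc, post_desc,
                                   method=method, value=value)
                    rows.append(dict(
                        layer=layer, biomarker=biomarker, condition=condition,
                        timepoint=timepoint, delta=res.mean_b - res.mean_a,
                        p_value=res.p_value, n_baseline=res.n_a,
                        n_timepoint=res.n_b,
                    ))
    report = pd.DataFrame(rows)
    pvals = report["p_value"].tolist()
    if correction == "holm":
        report["p_adjusted"] = _holm(pvals)
    elif correction == "none":
        report["p_adjusted"] = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")
    report["tier"] = report["p_adjusted"].map(significance_tier)
    report["direction"] = np.where(
        report["tier"] == "ns", 0, np.sign(report["delta"]).astype(int))
    return report


def dose_response(table: pd.DataFrame, layer: str | Layer,
                  biomarker: str, timepoint: str | Timepoint,
                  method: str = "ranksum",
                  value: str = "f_bound") -> ContrastResult:
    """Contrast the 25 vs 40 J/cm^2 arms at a fixed layer/biomarker/timepoint."""
    layer = layer.value if isinstance(layer, Layer) else layer
    timepoint = timepoint.value if isinstance(timepoint, Timepoint) else timepoint
    a = dict(layer=layer, biomarker=biomarker, timepoint=timepoint,
             condition=Condition.uva1_25.value)
    b = a | dict(condition=Condition.uva1_40.value)
    return contrast(table, a, b, method=method, value=value)
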