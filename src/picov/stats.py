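"""Nonparametric group statistics for cohort-level PICoV analysis.

Severity groups are compared per vascular layer with Kruskal–Wallis
omnibus tests; significant omnibus results gate all-pairs post-hoc
Nemenyi comparisons (rank-based, studentized range, the appropriate
follow-up to Kruskal–Wallis at small sample sizes).  Pooled quadrant
comparisons use Kruskal–Wallis followed by Tukey HSD.  PICoV is related
to the established perfusion/vessel density metrics through Pearson
correlations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "kruskal_wallis",
    "nemenyi_posthoc",
    "tukey_posthoc",
    "pearson_corr",
    "run_cohort_stats",
]

QUADRANTS = ("ST", "SN", "IT", "IN")


@dataclass
class StatResult:
    """Outcome of one test: omnibus statistic and/or pairwise matrix."""

    test: str
    statistic: float = float("nan")
    p_value: float = float("nan")
    pairwise: Optional[pd.DataFrame] = None  # adjusted p-values
    alpha: float = 0.05
    notes: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _check_groups(groups: Sequence[np.ndarray], min_groups: int,
                  min_per_group: int = 1) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    for i, a in enumerate(arrs):
        if a.size < min_per_group:
            raise ValueError(f"group {i} has fewer than {min_per_group} "
                             "observations")
    return arrs


def kruskal_wallis(groups: Sequence[np.ndarray], alpha: float = 0.05
                   ) -> StatResult:
    """Kruskal–Wallis rank test with tie correction.

    All-identical observations are a degenerate but legal input and give
    H = 0, p = 1.
    """
    arrs = _check_groups(groups, min_groups=2)
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal-wallis", statistic=0.0, p_value=1.0,
                          alpha=alpha, notes="all observations identical")
    h, p = sps.kruskal(*arrs)
    return StatResult("kruskal-wallis", statistic=float(h), p_value=float(p),
                      alpha=alpha)


def _mid_ranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def nemenyi_posthoc(groups: Sequence[np.ndarray], alpha: float = 0.05,
                    names: Optional[Sequence[str]] = None) -> StatResult:
    """All-pairs Nemenyi comparisons on the Kruskal–Wallis ranks.

    For groups i, j with mean ranks R_i, R_j over the pooled mid-ranks of
    N observations, the statistic

        q_ij = |R_i - R_j| / sqrt( C * N(N+1)/12 * (1/n_i + 1/n_j) )

    (C the Kruskal tie correction) is referred to the studentized range
    distribution with k groups and infinite degrees of freedom as
    ``p = P(Q_{k,inf} >= q * sqrt(2))``.  Adjusted p-values are never
    smaller than the unadjusted pairwise rank-sum p-values.
    """
    arrs = _check_groups(groups, min_groups=3, min_per_group=1)
    k = len(arrs)
    names = list(names) if names is not None else [str(i) for i in range(k)]
    sizes = np.array([a.size for a in arrs])
    n = int(sizes.sum())
    pooled = np.concatenate(arrs)
    ranks = _mid_ranks(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    mean_ranks = np.asarray(mean_ranks)

    # Kruskal tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    tie = max(tie, np.finfo(float).tiny)

    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        se = np.sqrt(tie * n * (n + 1) / 12.0
                     * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
        p = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0.0, 1.0))
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return StatResult("nemenyi", pairwise=pmat, alpha=alpha)


def tukey_posthoc(groups: Sequence[np.ndarray], alpha: float = 0.05,
                  names: Optional[Sequence[str]] = None) -> StatResult:
    """All-pairs Tukey HSD on group means (pooled within-group variance).

    q_ij = |m_i - m_j| / sqrt( s2 / 2 * (1/n_i + 1/n_j) ) referred to the
    studentized range distribution with k groups and N - k degrees of
    freedom.  Degenerate zero-variance input with unequal means reports
    p -> 0 and is flagged.
    """
    arrs = _check_groups(groups, min_groups=2, min_per_group=2)
    k = len(arrs)
    names = list(names) if names is not None else [str(i) for i in range(k)]
    sizes = np.array([a.size for a in arrs])
    n = int(sizes.sum())
    means = np.array([a.mean() for a in arrs])
    df = n - k
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    s2 = ss_within / df
    notes = ""
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        diff = abs(means[i] - means[j])
        if s2 == 0:
            p = 1.0 if diff == 0 else 0.0
            if diff != 0:
                notes = "zero pooled variance with unequal means"
        else:
            q = diff / np.sqrt(s2 / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            p = float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return StatResult("tukey-hsd", pairwise=pmat, alpha=alpha, notes=notes)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-test p-value.

    Zero variance in either input makes r undefined; NaNs are returned
    (reported missing, never zero).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------------
# cohort-level orchestration
# --------------------------------------------------------------------------

@dataclass
class CohortStatsReport:
    """Per-layer omnibus + gated post-hoc results and correlations."""

    layers: dict = field(default_factory=dict)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        def conv(val):
            if isinstance(val, StatResult):
                return {
                    "test": val.test,
                    "statistic": None if np.isnan(val.statistic)
                    else val.statistic,
                    "p_value": None if np.isnan(val.p_value)
                    else val.p_value,
                    "pairwise": None if val.pairwise is None
                    else val.pairwise.to_dict(),
                    "notes": val.notes,
                }
            if isinstance(val, dict):
                return {k: conv(v) for k, v in val.items()}
            if isinstance(val, float) and np.isnan(val):
                return None
            return val

        return {"alpha": self.alpha,
                "layers": {layer: conv(res)
                           for layer, res in self.layers.items()}}


REQUIRED_COLUMNS = ("eye_id", "layer", "group", "picov",
                    "picov_ST", "picov_SN", "picov_IT", "picov_IN",
                    "mean_PD", "sd_PD", "mean_VD", "sd_VD")


def run_cohort_stats(table: pd.DataFrame, alpha: float = 0.05,
                     group_order: Optional[Sequence[str]] = None
                     ) -> CohortStatsReport:
    """Run the full statistical layer on a cohort metrics table.

    Per layer: Kruskal–Wallis across severity groups on the eye-level
    PICoV, with Nemenyi pairwise comparisons only when the omnibus is
    significant; pooled quadrant Kruskal–Wallis with Tukey HSD gated the
    same way (reported both with and without the control group, since
    either pooling is defensible); Pearson correlations of PICoV with
    mean/SD of PD and VD; and a group-mean PD/VD table.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    report = CohortStatsReport(alpha=alpha)
    for layer, sub in table.groupby("layer"):
        groups = list(group_order) if group_order is not None \
            else list(pd.unique(sub["group"]))
        samples = [sub.loc[sub["group"] == g, "picov"].to_numpy()
                   for g in groups]
        if any(s.size == 0 for s in samples):
            raise ValueError(f"empty group in layer {layer}")
        res: dict = {"groups": groups}
        kw = kruskal_wallis(samples, alpha=alpha)
        res["kruskal_wallis"] = kw
        res["nemenyi"] = (nemenyi_posthoc(samples, alpha=alpha, names=groups)
                          if kw.significant and len(groups) >= 3 else None)

        for tag, pool in (("all_groups", sub),
                          ("dr_only", sub[sub["group"] != groups[0]])):
            quad_samples = [pool[f"picov_{q}"].dropna().to_numpy()
                            for q in QUADRANTS]
            if any(s.size < 2 for s in quad_samples):
                res[f"quadrant_{tag}"] = None
                continue
            qkw = kruskal_wallis(quad_samples, alpha=alpha)
            qtk = (tukey_posthoc(quad_samples, alpha=alpha, names=QUADRANTS)
                   if qkw.significant else None)
            res[f"quadrant_{tag}"] = {"kruskal_wallis": qkw, "tukey": qtk}

        corr = {}
        for metric in ("mean_PD", "mean_VD", "sd_PD", "sd_VD"):
            r, p = pearson_corr(sub["picov"], sub[metric])
            corr[metric] = {"r": r, "p": p}
        res["picov_correlations"] = corr
        res["group_means"] = (sub.groupby("group")[["mean_PD", "mean_VD"]]
                              .mean().reindex(groups).to_dict())
        report.layers[layer] = res
    return report
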