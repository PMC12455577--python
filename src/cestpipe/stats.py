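"""ROI aggregation and group statistics.

Reproduces the study's statistical surface: per-subject ROI means of
the per-pool AUC contrast maps, Tukey 1.5*IQR outlier exclusion applied
within group per (region, pool), ordinary one-way ANOVA plus two-tailed
pairwise Student t-tests with no multiple-comparison adjustment, and
mean +/- SEM summaries flagged '*' for p < 0.05 and '#' for
0.05 < p < 0.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import ContrastMaps
from .io import RoiLabelMap, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_roi",
    "flag_outliers_iqr",
    "apply_outlier_exclusion",
    "one_way_anova",
    "pairwise_ttests",
    "flag_for_p",
    "summarize",
    "DEFAULT_COMPARISONS",
]

# the comparisons the study reports: each treatment vs control, plus
# co-treatment vs the single treatments
DEFAULT_COMPARISONS = (
    ("ART", "vehicle"),
    ("nicotine", "vehicle"),
    ("cotreat", "vehicle"),
    ("cotreat", "ART"),
    ("cotreat", "nicotine"),
)


def aggregate_roi(
    contrast_maps: Mapping[str, ContrastMaps],
    label_map: RoiLabelMap,
    design: StudyDesign,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """ROI-mean AUC per subject, region and pool.

    ``contrast_maps`` maps subject_id to its ContrastMaps.  The mean is
    taken over converged (finite) voxels only; voxel counts and the
    number excluded as non-converged are recorded.  A region with zero
    converged voxels yields an excluded row with a reason.
    """
    regions = list(regions) if regions is not None else label_map.region_names
    rows = []
    group_of = dict(zip(design.table["subject_id"], design.table["group"]))
    for sid, cmaps in contrast_maps.items():
        for region in regions:
            rmask = label_map.region_mask(region)
            for pool, auc_map in cmaps.auc.items():
                vals = auc_map[rmask]
                finite = np.isfinite(vals)
                n_conv = int(finite.sum())
                row = {
                    "subject_id": sid, "group": group_of[sid], "region": region,
                    "pool": pool, "n_voxels": int(rmask.sum()),
                    "n_excluded_voxels": int(rmask.sum()) - n_conv,
                    "excluded": False, "reason": "",
                }
                if n_conv == 0:
                    row.update(value=np.nan, excluded=True,
                               reason="no converged voxels")
                else:
                    row["value"] = float(vals[finite].mean())
                rows.append(row)
    return pd.DataFrame(rows)


def _tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Quartiles as Tukey hinges: medians of the lower/upper half, each
    half including the overall median when n is odd."""
    v = np.sort(values)
    half = (v.size + 1) // 2
    return float(np.median(v[:half])), float(np.median(v[v.size - half:]))


def flag_outliers_iqr(values, k: float = 1.5, quartile_method: str = "hinges") -> np.ndarray:
    """Tukey fence rule: exclude x outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles default to Tukey hinges (medians of the two halves); any
    numpy ``quantile`` method name selects interpolation between order
    statistics instead.  Small-n behaviour is the reason for the
    default: hinge fences keep the two-sample t-test calibrated at
    n = 4 per group, where linearly interpolated quartiles trim about a
    fifth of Gaussian samples and inflate the false-positive rate.  If
    the IQR is zero, nothing is excluded (guard against excluding an
    entire near-constant group).  Returns a boolean exclusion mask.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        return np.zeros(values.shape, dtype=bool)
    if quartile_method == "hinges":
        q1, q3 = _tukey_hinges(values)
    else:
        q1, q3 = np.quantile(values, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    if iqr == 0:
        if np.ptp(values) > 0:
            warnings.warn("IQR is zero with non-constant values; skipping "
                          "outlier exclusion", stacklevel=2)
        return np.zeros(values.shape, dtype=bool)
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def apply_outlier_exclusion(
    table: pd.DataFrame, k: float = 1.5, quartile_method: str = "hinges"
) -> pd.DataFrame:
    """Single-pass fence exclusion within group per (region, pool);
    returns a copy with ``excluded``/``reason`` updated."""
    table = table.copy()
    for _, idx in table.groupby(["group", "region", "pool"]).groups.items():
        sub = table.loc[idx]
        usable = ~sub["excluded"] & np.isfinite(sub["value"])
        vals = sub.loc[usable, "value"].to_numpy()
        if vals.size < 3:
            continue
        out = flag_outliers_iqr(vals, k=k, quartile_method=quartile_method)
        out_idx = sub.loc[usable].index[out]
        table.loc[out_idx, "excluded"] = True
        table.loc[out_idx, "reason"] = "IQR outlier"
    return table


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Ordinary (fixed-effects) one-way ANOVA: F = MS_between/MS_within,
    p from the F distribution on (k-1, N-k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = [g.mean() for g in groups]
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if within == 0:
        if np.ptp(means) == 0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means", stacklevel=2)
        return np.inf, 0.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def pairwise_ttests(
    groups: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
    welch: bool = False,
) -> dict[tuple[str, str], float]:
    """Two-tailed t-test per requested pair; Student (pooled-variance)
    by default, Welch optional.  No multiple-comparison adjustment."""
    out: dict[tuple[str, str], float] = {}
    for a, b in comparisons:
        if a not in groups or b not in groups:
            continue
        x = np.asarray(groups[a], dtype=float)
        y = np.asarray(groups[b], dtype=float)
        if x.size < 2 or y.size < 2:
            logger.info("skipping comparison %s vs %s: a group has < 2 values", a, b)
            continue
        pooled_var = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        if pooled_var == 0:
            if x.mean() == y.mean():
                out[(a, b)] = 1.0
            else:
                warnings.warn(f"{a} vs {b}: zero variance with unequal means",
                              stacklevel=2)
                out[(a, b)] = 0.0
            continue
        res = sps.ttest_ind(x, y, equal_var=not welch)
        out[(a, b)] = float(res.pvalue)
    return out


def flag_for_p(p: float) -> str:
    """'*' for statistical significance (p < 0.05), '#' for a trend
    (0.05 < p < 0.1), empty otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.05:
        return "*"
    if 0.05 < p < 0.1:
        return "#"
    return ""


def summarize(
    table: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]] = DEFAULT_COMPARISONS,
    welch: bool = False,
) -> pd.DataFrame:
    """Per (region, pool): group mean +/- SEM, ANOVA F and p, pairwise
    p per comparison with its flag.  Exclusions must already be applied;
    excluded rows do not enter any mean or test.
    """
    rows = []
    for (region, pool), sub in table.groupby(["region", "pool"], sort=True):
        use = sub[~sub["excluded"] & np.isfinite(sub["value"])]
        groups = {g: d["value"].to_numpy() for g, d in use.groupby("group")}
        row: dict = {"region": region, "pool": pool}
        for g, vals in groups.items():
            row[f"mean_{g}"] = float(vals.mean())
            row[f"sem_{g}"] = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
            row[f"n_{g}"] = int(vals.size)
        testable = {g: v for g, v in groups.items() if v.size >= 2}
        if len(testable) >= 2:
            f, p = one_way_anova(list(testable.values()))
            row["anova_F"], row["anova_p"] = f, p
        else:
            row["anova_F"] = row["anova_p"] = np.nan
        for (a, b), p in pairwise_ttests(testable, comparisons, welch=welch).items():
            row[f"p_{a}_vs_{b}"] = p
            row[f"flag_{a}_vs_{b}"] = flag_for_p(p)
        rows.append(row)
    return pd.DataFrame(rows)
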