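"""ROI summarisation and the study's derived quantities.

Nerve volume is ROI voxel count times voxel volume; axon volume is
nerve volume times fiber fraction (an axonal-content marker that is
robust to nerve swelling because edema dilutes the fiber fraction while
inflating the volume).  Group statistics: percent changes between group
means (with an explicit denominator convention, because published usage
varies), Pearson correlation with the t-transform p-value, Welch's
t-test, and a fixed-effects two-way ANOVA (group x day, Type II sums of
squares) on per-eye records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROISpec",
    "roi_mean",
    "nerve_volume",
    "axon_volume",
    "percent_change",
    "round_percent",
    "pearson_r2",
    "welch_ttest",
    "two_way_anova",
    "summarize_cohort",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROISpec:
    """A set of voxel coordinates with their physical volume.

    ``kind`` distinguishes the small central ROI used for metric means
    (``metric_roi``) from the larger whole-nerve ROI used for volume
    (``whole_nerve_roi``); the two are never inferred from one another.
    """

    voxel_indices: tuple[tuple[int, int, int], ...]
    voxel_volume: float
    kind: str = "metric_roi"

    def __post_init__(self) -> None:
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        if self.kind not in ("metric_roi", "whole_nerve_roi"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        idx = tuple(tuple(int(c) for c in v) for v in self.voxel_indices)
        if len(set(idx)) != len(idx):
            raise ValueError("ROI voxel indices must be unique")
        object.__setattr__(self, "voxel_indices", idx)

    @classmethod
    def from_mask(cls, mask: np.ndarray, voxel_volume: float, kind: str = "metric_roi"):
        idx = tuple(map(tuple, np.argwhere(np.asarray(mask).astype(bool))))
        return cls(idx, voxel_volume, kind)

    def __len__(self) -> int:
        return len(self.voxel_indices)


def roi_mean(metric_map: np.ndarray, roi: ROISpec) -> float:
    """Arithmetic mean of a 3-D metric map over the ROI, skipping
    flagged-invalid (NaN) voxels; the skipped count is logged."""
    metric_map = np.asarray(metric_map, dtype=float)
    if roi.kind != "metric_roi":
        raise ValueError("roi_mean expects a metric_roi")
    if len(roi) == 0:
        raise ValueError("empty ROI")
    vals = []
    for v in roi.voxel_indices:
        if any(c < 0 or c >= s for c, s in zip(v, metric_map.shape)):
            raise IndexError(f"ROI voxel {v} outside map shape {metric_map.shape}")
        vals.append(metric_map[v])
    vals = np.array(vals)
    invalid = np.isnan(vals)
    if invalid.all():
        raise ValueError("all ROI voxels are invalid")
    if invalid.any():
        log.warning("roi_mean: ignoring %d invalid voxel(s) of %d", invalid.sum(), len(vals))
    return float(vals[~invalid].mean())


def nerve_volume(roi: ROISpec) -> float:
    """Whole-nerve volume in mm3: voxel count x voxel volume."""
    if roi.kind != "whole_nerve_roi":
        raise ValueError("nerve_volume expects a whole_nerve_roi")
    if len(roi) == 0:
        raise ValueError("empty whole-nerve ROI")
    return len(roi) * roi.voxel_volume


def axon_volume(nerve_vol: float, fiber_fraction: float) -> float:
    """Axon (fiber) volume in mm3: nerve volume x fiber fraction."""
    if not 0.0 <= fiber_fraction <= 1.0:
        raise ValueError(f"fiber fraction must be in [0, 1], got {fiber_fraction}")
    if nerve_vol < 0:
        raise ValueError("nerve volume must be >= 0")
    return nerve_vol * fiber_fraction


def percent_change(
    reference_mean: float, comparison_mean: float, denominator: str = "reference"
) -> float:
    """Signed percent change ``100 * (comparison - reference) / denom``.

    ``denominator`` is one of ``reference``, ``comparison`` or
    ``larger``; the choice is explicit because published percent-change
    statements use more than one convention.
    """
    denoms = {
        "reference": reference_mean,
        "comparison": comparison_mean,
        "larger": max(reference_mean, comparison_mean, key=abs),
    }
    if denominator not in denoms:
        raise ValueError(f"denominator must be one of {sorted(denoms)}")
    denom = denoms[denominator]
    if denom == 0:
        raise ZeroDivisionError("percent_change denominator is zero")
    return 100.0 * (comparison_mean - reference_mean) / denom


def round_percent(pct: float) -> int:
    """Round to the nearest integer percent, halves away from zero
    (report style of the source tables)."""
    return int(np.sign(pct) * np.floor(abs(pct) + 0.5))


def pearson_r2(x, y) -> tuple[float, float, float]:
    """Sample Pearson correlation: returns (r, r^2, two-sided p).

    p comes from the t transform with n - 2 degrees of freedom; constant
    input is rejected (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(r**2), float(p)


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test: returns (t, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def two_way_anova(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (group x day, Type II SS) on per-eye
    records of one metric from a tidy cohort table.

    Returns a frame indexed by effect (group, day, group:day, residual)
    with sum_sq, df, F and p columns.  Requires >= 2 levels per factor
    and >= 2 observations per cell; empty cells are reported by name.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    sub = table[table["metric"] == metric].copy()
    if sub.empty:
        raise ValueError(f"no records for metric {metric!r}")
    groups = sub["group"].unique()
    days = sub["day"].unique()
    if len(groups) < 2 or len(days) < 2:
        raise ValueError("two_way_anova needs >= 2 levels of group and day")
    counts = sub.groupby(["group", "day"]).size()
    missing = [
        (g, d) for g in groups for d in days
        if (g, d) not in counts.index or counts[(g, d)] < 2
    ]
    if missing:
        raise ValueError(f"cells with < 2 observations: {missing}")
    model = ols("value ~ C(group) * C(day)", data=sub).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(
        index={
            "C(group)": "group",
            "C(day)": "day",
            "C(group):C(day)": "group:day",
            "Residual": "residual",
        },
        columns={"PR(>F)": "p"},
    )
    return aov


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD per metric x group x day, table-style."""
    g = table.groupby(["metric", "group", "day"])["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["mean_sd"] = out.apply(lambda r: f"{r['mean']:.2f} ± {r['std']:.3f}", axis=1)
    return out
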