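"""Fit a simulated cohort and tabulate per-eye ROI metrics."""

from __future__ import annotations

import pandas as pd

from .dbsi import DBSIFitConfig, fit_volume
from .metrics import ROISpec, axon_volume, nerve_volume, roi_mean
from .phantom import Cohort

__all__ = ["fitted_cohort_table"]

#: per-voxel map metrics averaged over the nerve ROI
_MAP_METRICS = (
    "fiber_fraction", "restricted_fraction", "nonrestricted_fraction",
    "dbsi_lambda_par", "dbsi_lambda_perp",
    "dti_lambda_par", "dti_lambda_perp", "dti_fa", "dti_md",
)


def fitted_cohort_table(cohort: Cohort, cfg: DBSIFitConfig | None = None) -> pd.DataFrame:
    """Fit every scan of a simulated cohort and summarise per eye.

    Each scan's masked voxels are fitted with both the spectrum model
    and the single tensor; the nerve mask serves both as the metric ROI
    (per-voxel map means) and as the whole-nerve ROI (volume, hence axon
    volume).  Returns a tidy frame: one row per scan x metric.
    """
    if cfg is None:
        cfg = DBSIFitConfig.for_mode(cohort.spec.mode)
    rows = []
    for scan in cohort.scans:
        maps = fit_volume(scan.dwi, cohort.scheme, scan.mask, cfg, progress_every=0)
        metric_roi = ROISpec.from_mask(scan.mask, scan.voxel_volume, "metric_roi")
        nerve_roi = ROISpec.from_mask(scan.mask, scan.voxel_volume, "whole_nerve_roi")
        values = {m: roi_mean(maps[m], metric_roi) for m in _MAP_METRICS}
        values["nerve_volume"] = nerve_volume(nerve_roi)
        values["axon_volume"] = axon_volume(
            values["nerve_volume"], values["fiber_fraction"]
        )
        for metric, value in values.items():
            rows.append(
                {"animal": scan.animal, "group": scan.group, "eye": scan.eye,
                 "day": scan.day, "metric": metric, "value": value}
            )
    return pd.DataFrame(rows)
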