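"""Group-contrast reproduction and desk-scale replication experiments.

Two levels of reproduction are provided:

* :func:`reproduce_printed_contrasts` recomputes the headline sham-vs-TBI
  percent changes directly from the published group means (a pure
  worked-example check of the percent-change arithmetic and its
  denominator conventions);

* :func:`run_day30_replication` re-enacts the day-30 comparison on
  simulated cohorts: generate a sham and a TBI cohort at scan SNR,
  fit every nerve voxel with both models, take ROI means per eye, and
  test the group contrast per seed with Welch's t-test.  It also checks
  the single-tensor confound: the DTI axial-diffusivity decrease should
  exceed the spectrum-model decrease, because restricted-water
  (cellularity) contamination drags the single-tensor fit down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_fit import fitted_cohort_table
from .metrics import percent_change, round_percent, welch_ttest
from .phantom import PRINTED_GROUP_STATS, CohortSpec, simulate_cohort

__all__ = [
    "PrintedContrast",
    "PRINTED_CONTRASTS",
    "reproduce_printed_contrasts",
    "run_day30_replication",
]


@dataclass(frozen=True)
class PrintedContrast:
    """One published sham-vs-TBI percent change and its convention."""

    name: str
    mode: str
    metric: str
    day: int
    denominator: str
    printed_pct: int


#: the published percent changes that reproduce exactly from the printed
#: group means (means are printed to 2 decimals; a few other published
#: percentages were evidently computed from unrounded means and are not
#: reproducible from the tables).
PRINTED_CONTRASTS: tuple[PrintedContrast, ...] = (
    PrintedContrast("restricted_fraction_day1", "invivo", "restricted_fraction", 1, "reference", 300),
    PrintedContrast("restricted_fraction_day3", "invivo", "restricted_fraction", 3, "reference", 267),
    PrintedContrast("restricted_fraction_day7", "invivo", "restricted_fraction", 7, "reference", 200),
    PrintedContrast("restricted_fraction_day30", "invivo", "restricted_fraction", 30, "reference", 260),
    PrintedContrast("dbsi_lambda_par_day1", "invivo", "dbsi_lambda_par", 1, "reference", -22),
    PrintedContrast("exvivo_restricted_fraction_day3", "exvivo", "restricted_fraction", 3, "comparison", 47),
    PrintedContrast("exvivo_dbsi_lambda_par_day3", "exvivo", "dbsi_lambda_par", 3, "reference", -28),
    PrintedContrast("exvivo_dbsi_lambda_perp_day3", "exvivo", "dbsi_lambda_perp", 3, "reference", 50),
    PrintedContrast("exvivo_fiber_fraction_day3", "exvivo", "fiber_fraction", 3, "reference", -9),
    PrintedContrast("exvivo_axon_volume_day3", "exvivo", "axon_volume", 3, "reference", -14),
)


def reproduce_printed_contrasts() -> pd.DataFrame:
    """Recompute every contrast in :data:`PRINTED_CONTRASTS` from the
    published group means (sham as reference, TBI as comparison)."""
    rows = []
    for c in PRINTED_CONTRASTS:
        sham = PRINTED_GROUP_STATS[(c.mode, "sham", c.day)][c.metric][0]
        tbi = PRINTED_GROUP_STATS[(c.mode, "TBI", c.day)][c.metric][0]
        pct = percent_change(sham, tbi, c.denominator)
        rows.append(
            {"name": c.name, "mode": c.mode, "metric": c.metric, "day": c.day,
             "sham_mean": sham, "tbi_mean": tbi, "denominator": c.denominator,
             "computed_pct": round_percent(pct), "computed_pct_raw": pct,
             "printed_pct": c.printed_pct}
        )
    return pd.DataFrame(rows)


def run_day30_replication(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_per_group: int = 5,
    snr: float = 30.0,
    voxels_per_nerve: int | None = None,
    mode: str = "invivo",
    animal_variance_share: float = 0.15,
) -> pd.DataFrame:
    """Desk-scale re-enactment of the day-30 group comparison.

    For each of ``n_seeds`` independently seeded cohorts (``n_per_group``
    animals, two eyes each, day 30 only): simulate, fit, take per-eye ROI
    means, then record Welch p-values for the restricted-fraction and
    axial-diffusivity contrasts and the percent decrease of the axial
    diffusivity under both models.  Returns one row per seed; seeds are
    derived deterministically from ``base_seed``.

    By default each nerve ROI holds the full voxel count implied by the
    drawn nerve volume at the reconstructed voxel size (~35-41 voxels);
    ``voxels_per_nerve`` can shrink it for quick exploratory runs at the
    cost of noisier per-eye means.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    rows = []
    for i, seed in enumerate(seeds):
        spec = CohortSpec(
            mode=mode,
            n_per_group=n_per_group,
            days=(30,),
            snr=snr,
            seed=int(seed),
            voxels_per_nerve=voxels_per_nerve,
            animal_variance_share=animal_variance_share,
        )
        cohort = simulate_cohort(spec)
        table = fitted_cohort_table(cohort)

        def eye_values(metric, group, t=table):
            sub = t[(t["metric"] == metric) & (t["group"] == group)]
            return sub["value"].to_numpy()

        restr_sham = eye_values("restricted_fraction", "sham")
        restr_tbi = eye_values("restricted_fraction", "TBI")
        ax_sham = eye_values("dbsi_lambda_par", "sham")
        ax_tbi = eye_values("dbsi_lambda_par", "TBI")
        dti_sham = eye_values("dti_lambda_par", "sham")
        dti_tbi = eye_values("dti_lambda_par", "TBI")

        _, p_restr = welch_ttest(restr_sham, restr_tbi)
        _, p_ax = welch_ttest(ax_sham, ax_tbi)
        dbsi_drop = -percent_change(ax_sham.mean(), ax_tbi.mean(), "reference")
        dti_drop = -percent_change(dti_sham.mean(), dti_tbi.mean(), "reference")
        rows.append(
            {"seed": int(seed), "replicate": i,
             "restricted_sham": restr_sham.mean(), "restricted_tbi": restr_tbi.mean(),
             "lambda_par_sham": ax_sham.mean(), "lambda_par_tbi": ax_tbi.mean(),
             "p_restricted": p_restr, "p_lambda_par": p_ax,
             "restricted_higher": restr_tbi.mean() > restr_sham.mean(),
             "lambda_par_lower": ax_tbi.mean() < ax_sham.mean(),
             "dbsi_lambda_par_drop_pct": dbsi_drop,
             "dti_lambda_par_drop_pct": dti_drop,
             "dti_exaggerates": dti_drop > dbsi_drop}
        )
    out = pd.DataFrame(rows)
    out.attrs["welch_pass_fraction"] = float(
        (
            (out["p_restricted"] < 0.05) & out["restricted_higher"]
            & (out["p_lambda_par"] < 0.05) & out["lambda_par_lower"]
        ).mean()
    )
    out.attrs["dti_exaggeration_fraction"] = float(out["dti_exaggerates"].mean())
    return out
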