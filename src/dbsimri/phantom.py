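"""Synthetic optic-nerve phantom generator.

Builds single voxels, nerve cross-sections and full longitudinal
sham/TBI cohorts with the statistical structure the analysis assumes:

* tissue compositions taken from the study's published group tables
  (in vivo days 1-30 and ex vivo day 3, sham and TBI), with the printed
  fraction triplets renormalised to sum to 1 so they partition the
  signal;
* the isotropic ground truth as two delta components (a restricted
  diffusivity for cellularity, default 0.3 um2/ms, and a non-restricted
  one for edema, default 1.8 um2/ms);
* between-animal biological variability as a per-animal perturbation of
  the preset means, shared across that animal's two eyes and across
  timepoints (which is what induces within-mouse correlation);
* Rician magnitude noise at a configurable SNR.

Everything is reproducible from a single cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import GradientScheme, make_scheme
from .signal_model import (
    FiberComponent,
    IsotropicSpectrum,
    PartitionConfig,
    VoxelModel,
    forward_signal,
)

__all__ = [
    "PRINTED_GROUP_STATS",
    "TissuePreset",
    "CohortSpec",
    "Scan",
    "Cohort",
    "get_preset",
    "add_rician_noise",
    "simulate_voxel",
    "simulate_cohort",
    "nerve_roi_offsets",
    "DEFAULT_VOXEL_SIZE",
]

#: reconstructed (zero-filled) voxel size in mm: 22.5 mm FOV / 384 in-plane,
#: 1 mm slice.  ROIs in the source study were drawn on reconstructed images.
DEFAULT_VOXEL_SIZE = (0.0586, 0.0586, 1.0)

#: acquisition-grid alternative (22.5 mm FOV / 192).
ACQUISITION_VOXEL_SIZE = (0.1172, 0.1172, 1.0)

# Published group means +/- SD per (mode, group, day).  Fractions and FA are
# dimensionless; diffusivities in um2/ms; volumes in mm3.
_IV = {  # (sham tuple, tbi tuple) per metric, days (1, 3, 7, 30)
    "nonrestricted_fraction": (
        ((0.03, 0.043), (0.05, 0.043), (0.06, 0.035), (0.06, 0.054)),
        ((0.03, 0.029), (0.05, 0.025), (0.07, 0.054), (0.10, 0.048)),
    ),
    "restricted_fraction": (
        ((0.03, 0.014), (0.03, 0.018), (0.04, 0.036), (0.05, 0.014)),
        ((0.12, 0.050), (0.11, 0.046), (0.12, 0.056), (0.18, 0.069)),
    ),
    "axon_volume": (
        ((0.11, 0.009), (0.10, 0.006), (0.11, 0.009), (0.11, 0.007)),
        ((0.10, 0.009), (0.11, 0.009), (0.09, 0.014), (0.08, 0.022)),
    ),
    "dbsi_lambda_par": (
        ((1.89, 0.128), (1.89, 0.092), (1.84, 0.088), (1.84, 0.210)),
        ((1.47, 0.178), (1.59, 0.163), (1.55, 0.161), (1.61, 0.211)),
    ),
    "dbsi_lambda_perp": (
        ((0.15, 0.038), (0.17, 0.056), (0.15, 0.039), (0.14, 0.024)),
        ((0.18, 0.029), (0.22, 0.041), (0.21, 0.044), (0.23, 0.053)),
    ),
    "dti_lambda_par": (
        ((1.72, 0.124), (1.75, 0.058), (1.68, 0.066), (1.62, 0.183)),
        ((1.19, 0.229), (1.21, 0.220), (1.20, 0.199), (1.07, 0.184)),
    ),
    "dti_lambda_perp": (
        ((0.17, 0.046), (0.20, 0.051), (0.19, 0.040), (0.20, 0.058)),
        ((0.20, 0.025), (0.26, 0.039), (0.28, 0.046), (0.34, 0.060)),
    ),
    "dti_fa": (
        ((0.88, 0.040), (0.86, 0.039), (0.87, 0.032), (0.85, 0.062)),
        ((0.81, 0.042), (0.75, 0.059), (0.71, 0.089), (0.61, 0.0117)),
    ),
    "dti_md": (
        ((0.23, 0.012), (0.24, 0.008), (0.23, 0.009), (0.22, 0.015)),
        ((0.18, 0.027), (0.19, 0.024), (0.20, 0.019), (0.19, 0.013)),
    ),
    "fiber_fraction": (
        ((0.81, 0.060), (0.77, 0.031), (0.76, 0.044), (0.81, 0.082)),
        ((0.76, 0.038), (0.76, 0.024), (0.72, 0.065), (0.61, 0.107)),
    ),
    "nerve_volume": (
        ((0.13, 0.011), (0.13, 0.006), (0.15, 0.011), (0.14, 0.018)),
        ((0.14, 0.011), (0.15, 0.011), (0.12, 0.017), (0.12, 0.016)),
    ),
}

_EV = {  # ex vivo, day 3 only: (sham, tbi)
    "nonrestricted_fraction": ((0.06, 0.026), (0.07, 0.058)),
    "restricted_fraction": ((0.10, 0.042), (0.19, 0.055)),
    "axon_volume": ((0.07, 0.009), (0.06, 0.015)),
    "dbsi_lambda_par": ((0.74, 0.090), (0.53, 0.070)),
    "dbsi_lambda_perp": ((0.06, 0.026), (0.09, 0.017)),
    "dti_lambda_par": ((0.61, 0.090), (0.42, 0.075)),
    "dti_lambda_perp": ((0.08, 0.071), (0.12, 0.036)),
    "dti_fa": ((0.85, 0.071), (0.68, 0.102)),
    "dti_md": ((0.09, 0.015), (0.07, 0.013)),
    "fiber_fraction": ((0.68, 0.050), (0.62, 0.096)),
    "nerve_volume": ((0.10, 0.012), (0.09, 0.018)),
}

_IV_DAYS = (1, 3, 7, 30)

#: PRINTED_GROUP_STATS[(mode, group, day)][metric] -> (mean, sd)
PRINTED_GROUP_STATS: dict[tuple[str, str, int], dict[str, tuple[float, float]]] = {}
for _metric, (_sham, _tbi) in _IV.items():
    for _d, _day in enumerate(_IV_DAYS):
        PRINTED_GROUP_STATS.setdefault(("invivo", "sham", _day), {})[_metric] = _sham[_d]
        PRINTED_GROUP_STATS.setdefault(("invivo", "TBI", _day), {})[_metric] = _tbi[_d]
for _metric, (_sham, _tbi) in _EV.items():
    PRINTED_GROUP_STATS.setdefault(("exvivo", "sham", 3), {})[_metric] = _sham
    PRINTED_GROUP_STATS.setdefault(("exvivo", "TBI", 3), {})[_metric] = _tbi


@dataclass(frozen=True)
class TissuePreset:
    """Ground-truth tissue composition for one group x timepoint.

    ``fiber_fraction``, ``restricted_fraction`` and
    ``nonrestricted_fraction`` are the printed triplet renormalised to
    sum to 1 (``renorm_scale`` records the applied factor; the published
    triplets sum to 0.84-0.97 and the remainder is unexplained in the
    source tables).  ``sds`` keeps the printed per-metric standard
    deviations for cohort-level variability draws.
    """

    label: str
    mode: str
    fiber_fraction: float
    restricted_fraction: float
    nonrestricted_fraction: float
    lambda_par: float
    lambda_perp: float
    nerve_volume: float
    restricted_D: float = 0.3
    nonrestricted_D: float = 1.8
    sds: dict = field(default_factory=dict)
    renorm_scale: float = 1.0

    def __post_init__(self) -> None:
        total = self.fiber_fraction + self.restricted_fraction + self.nonrestricted_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"preset fractions must sum to 1, got {total}")
        if min(self.lambda_par, self.lambda_perp, self.restricted_D, self.nonrestricted_D) < 0:
            raise ValueError("diffusivities must be non-negative")

    @classmethod
    def from_fractions(
        cls, label: str, mode: str, fiber: float, restricted: float,
        nonrestricted: float, lambda_par: float, lambda_perp: float,
        nerve_volume: float, sds: dict | None = None, **kw,
    ) -> "TissuePreset":
        total = fiber + restricted + nonrestricted
        if total <= 0:
            raise ValueError("fraction triplet sums to zero")
        return cls(
            label=label, mode=mode,
            fiber_fraction=fiber / total,
            restricted_fraction=restricted / total,
            nonrestricted_fraction=nonrestricted / total,
            lambda_par=lambda_par, lambda_perp=lambda_perp,
            nerve_volume=nerve_volume, sds=sds or {},
            renorm_scale=1.0 / total, **kw,
        )

    def to_voxel_model(self, orientation=(0.0, 0.0, 1.0), s0: float = 1.0) -> VoxelModel:
        limits = (0.0, PartitionConfig.for_mode(self.mode).nonrestricted_max)
        fiber = FiberComponent(
            self.fiber_fraction, self.lambda_par, self.lambda_perp, np.asarray(orientation)
        )
        spectrum = IsotropicSpectrum(
            np.array([self.restricted_D, self.nonrestricted_D]),
            np.array([self.restricted_fraction, self.nonrestricted_fraction]),
            limits,
        )
        return VoxelModel(fiber, spectrum, s0)


def get_preset(mode: str, group: str, day: int) -> TissuePreset:
    """Preset parameterised from the published group table."""
    key = (mode, group, day)
    if key not in PRINTED_GROUP_STATS:
        raise KeyError(f"no published stats for {key}")
    stats = PRINTED_GROUP_STATS[key]
    return TissuePreset.from_fractions(
        label=f"{mode}-{group}-day{day}",
        mode=mode,
        fiber=stats["fiber_fraction"][0],
        restricted=stats["restricted_fraction"][0],
        nonrestricted=stats["nonrestricted_fraction"][0],
        lambda_par=stats["dbsi_lambda_par"][0],
        lambda_perp=stats["dbsi_lambda_perp"][0],
        nerve_volume=stats["nerve_volume"][0],
        sds={m: sd for m, (_, sd) in stats.items()},
    )


def add_rician_noise(values: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-image (Rician) corruption: sqrt((S+e1)^2 + e2^2)."""
    values = np.asarray(values, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return values.copy()
    e1 = rng.normal(0.0, sigma, size=values.shape)
    e2 = rng.normal(0.0, sigma, size=values.shape)
    return np.sqrt((values + e1) ** 2 + e2**2)


def simulate_voxel(
    preset: TissuePreset,
    scheme: GradientScheme,
    snr: float | None = 30.0,
    seed: int = 0,
    orientation=(0.0, 0.0, 1.0),
    s0: float = 1.0,
) -> np.ndarray:
    """Noise-free forward signal from the preset, then Rician corruption
    at SNR = s0/sigma.  ``snr=None`` (or inf) disables noise; deterministic
    for a given seed."""
    signal = forward_signal(preset.to_voxel_model(orientation, s0), scheme)
    if snr is None or np.isinf(snr):
        return signal
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    return add_rician_noise(signal, s0 / snr, rng)


def nerve_roi_offsets(n_voxels: int) -> np.ndarray:
    """(n, 2) in-plane integer offsets forming a compact disc of n voxels.

    Grid offsets are ranked by distance from the centre (ties by (dx, dy))
    so the shape is deterministic and as round as a square grid allows.
    """
    if n_voxels < 1:
        raise ValueError("nerve ROI needs at least one voxel")
    r = int(np.ceil(np.sqrt(n_voxels))) + 1
    xs, ys = np.mgrid[-r : r + 1, -r : r + 1]
    offs = np.column_stack([xs.ravel(), ys.ravel()])
    d2 = (offs**2).sum(axis=1)
    order = np.lexsort((offs[:, 1], offs[:, 0], d2))
    return offs[order[:n_voxels]]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated sham/TBI cohort.

    ``animal_variance_share`` is the fraction of each metric's published
    variance attributed to the between-animal (biological) level; the
    remainder is regarded as measurement-level and arises in the
    simulation from scan noise and fitting.  ``voxels_per_nerve``
    overrides the ROI size derived from the preset nerve volume (for
    small, fast studies).
    """

    mode: str = "invivo"
    n_per_group: int = 5
    eyes_per_animal: int = 2
    days: tuple[int, ...] = (1, 3, 7, 30)
    snr: float | None = 30.0
    seed: int = 0
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    voxels_per_nerve: int | None = None
    animal_variance_share: float = 0.15
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noise-free)")
        if not 0.0 <= self.animal_variance_share <= 1.0:
            raise ValueError("animal_variance_share must be in [0, 1]")
        for d in self.days:
            if (self.mode, "sham", d) not in PRINTED_GROUP_STATS:
                raise ValueError(f"no preset available for {self.mode} day {d}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class Scan:
    """One simulated nerve acquisition (animal x eye x timepoint)."""

    animal: str
    group: str
    eye: str
    day: int
    dwi: np.ndarray          # (nx, ny, 1, K)
    mask: np.ndarray         # (nx, ny, 1) bool
    truth: dict              # drawn generator parameters for this nerve
    voxel_volume: float


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    scheme: GradientScheme
    scans: tuple[Scan, ...]

    @property
    def truth_table(self) -> pd.DataFrame:
        """Tidy ground truth: one row per scan x metric."""
        rows = []
        for s in self.scans:
            for metric, value in s.truth.items():
                rows.append(
                    {"animal": s.animal, "group": s.group, "eye": s.eye,
                     "day": s.day, "metric": metric, "value": value}
                )
        return pd.DataFrame(rows)


# metrics perturbed at the animal level, in draw order
_DRAWN = ("fiber_fraction", "restricted_fraction", "nonrestricted_fraction",
          "dbsi_lambda_par", "dbsi_lambda_perp", "nerve_volume")


def _draw_animal_params(
    base: dict[int, TissuePreset], z: np.ndarray, share: float
) -> dict[int, TissuePreset]:
    """Perturb per-day preset means by a shared per-animal z-score vector.

    The same z applies at every timepoint, giving each animal a coherent
    longitudinal trajectory; the perturbation SD per metric is
    printed_SD * sqrt(share).
    """
    out = {}
    for day, preset in base.items():
        sds = preset.sds
        scale = np.sqrt(share)
        # perturb the printed (un-renormalised) table values
        stats = PRINTED_GROUP_STATS[(preset.mode, preset.label.split("-")[1], day)]
        raw = {m: stats[m][0] + z[i] * stats[m][1] * scale for i, m in enumerate(_DRAWN)}
        # keep the draw physical
        fiber = max(raw["fiber_fraction"], 0.05)
        restricted = max(raw["restricted_fraction"], 0.0)
        nonrestricted = max(raw["nonrestricted_fraction"], 0.0)
        lam_perp = max(raw["dbsi_lambda_perp"], 0.02)
        lam_par = max(raw["dbsi_lambda_par"], lam_perp + 0.25)
        nerve_volume = max(raw["nerve_volume"], 1e-3)
        out[day] = TissuePreset.from_fractions(
            label=preset.label, mode=preset.mode,
            fiber=fiber, restricted=restricted, nonrestricted=nonrestricted,
            lambda_par=lam_par, lambda_perp=lam_perp,
            nerve_volume=nerve_volume, sds=sds,
            restricted_D=preset.restricted_D, nonrestricted_D=preset.nonrestricted_D,
        )
    return out


def simulate_cohort(spec: CohortSpec, scheme: GradientScheme | None = None) -> Cohort:
    """Simulate the full cohort; fully reproducible from ``spec.seed``.

    Every animal gets one biological parameter draw shared by both eyes
    and all timepoints; every scan gets independent Rician noise.  The
    nerve is a compact disc of voxels in one axial slice whose count
    matches the drawn nerve volume at the configured voxel size (or
    ``voxels_per_nerve`` when set).
    """
    if scheme is None:
        scheme = make_scheme(spec.mode, seed=0)
    rng = np.random.default_rng(spec.seed)
    scans: list[Scan] = []
    for group in ("sham", "TBI"):
        base_presets = {day: get_preset(spec.mode, group, day) for day in spec.days}
        for a in range(spec.n_per_group):
            animal_id = f"{group}{a + 1:02d}"
            z = rng.standard_normal(len(_DRAWN))
            drawn = _draw_animal_params(base_presets, z, spec.animal_variance_share)
            for eye in ("L", "R")[: spec.eyes_per_animal]:
                for day in spec.days:
                    preset = drawn[day]
                    if spec.voxels_per_nerve is not None:
                        n_vox = spec.voxels_per_nerve
                    else:
                        n_vox = max(1, int(round(preset.nerve_volume / spec.voxel_volume)))
                        if preset.nerve_volume < spec.voxel_volume:
                            raise ValueError(
                                f"nerve volume {preset.nerve_volume} mm3 is smaller "
                                f"than one voxel ({spec.voxel_volume} mm3); "
                                "override voxel_size or voxels_per_nerve"
                            )
                    offsets = nerve_roi_offsets(n_vox)
                    half = int(np.abs(offsets).max()) + 2
                    nx = ny = 2 * half + 1
                    dwi = np.zeros((nx, ny, 1, len(scheme)))
                    mask = np.zeros((nx, ny, 1), dtype=bool)
                    clean = forward_signal(
                        preset.to_voxel_model((0.0, 0.0, 1.0), spec.s0), scheme
                    )
                    sigma = 0.0 if spec.snr is None or np.isinf(spec.snr) else spec.s0 / spec.snr
                    for dx, dy in offsets:
                        x, y = half + dx, half + dy
                        mask[x, y, 0] = True
                        dwi[x, y, 0] = (
                            add_rician_noise(clean, sigma, rng) if sigma else clean
                        )
                    truth = {
                        "fiber_fraction": preset.fiber_fraction,
                        "restricted_fraction": preset.restricted_fraction,
                        "nonrestricted_fraction": preset.nonrestricted_fraction,
                        "dbsi_lambda_par": preset.lambda_par,
                        "dbsi_lambda_perp": preset.lambda_perp,
                        "nerve_volume": preset.nerve_volume,
                        "axon_volume": preset.nerve_volume * preset.fiber_fraction,
                        "n_voxels": float(n_vox),
                    }
                    scans.append(
                        Scan(animal_id, group, eye, day, dwi, mask, truth, spec.voxel_volume)
                    )
    return Cohort(spec=spec, scheme=scheme, scans=tuple(scans))
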