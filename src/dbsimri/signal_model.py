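"""Forward signal model for coherent white-matter voxels.

The voxel signal is modelled as one axially symmetric anisotropic tensor
(the fiber bundle) plus a spectrum of isotropic diffusion components:

    S_k / S_0 = f * exp(-b_k lam_perp) * exp(-b_k (lam_par - lam_perp) cos^2 Phi_k)
                + sum_i w_i * exp(-b_k D_i)

where Phi_k is the angle between the k-th gradient and the fiber axis,
f is the signal-intensity fraction of the fiber, and the weights w_i
discretize the isotropic diffusivity spectrum f(D) on a grid between the
low and high diffusivity limits.  Fractions partition the b = 0 signal:
f + sum_i w_i = 1.

The isotropic spectrum is summarized by two bands: the *restricted*
fraction (ADC <= 0.6 um2/ms, a cellularity marker) and the
*non-restricted* fraction (0.6 < ADC <= 3 um2/ms in vivo, <= 2 ex vivo;
an edema/CSF marker).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .schemes import GradientScheme

__all__ = [
    "FiberComponent",
    "IsotropicSpectrum",
    "VoxelModel",
    "PartitionConfig",
    "forward_signal",
    "partition_spectrum",
    "iso_grid",
]

log = logging.getLogger(__name__)

#: default grid step for discretizing the isotropic spectrum (um2/ms);
#: chosen so the 0.6 um2/ms restricted/non-restricted boundary falls
#: exactly on a grid point.
ISO_GRID_STEP = 0.05


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector")
    if abs(np.linalg.norm(v) - 1.0) > 1e-6:
        raise ValueError(f"{name} must have unit norm, got |v|={np.linalg.norm(v):.6f}")
    return v


@dataclass(frozen=True)
class FiberComponent:
    """Anisotropic (fiber) compartment: fraction, diffusivities, axis."""

    fraction: float
    lambda_par: float
    lambda_perp: float
    orientation: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fiber fraction must be in [0, 1], got {self.fraction}")
        if self.lambda_par < 0 or self.lambda_perp < 0:
            raise ValueError("diffusivities must be non-negative")
        if self.lambda_perp > self.lambda_par + 1e-12:
            raise ValueError(
                f"lambda_perp ({self.lambda_perp}) exceeds lambda_par "
                f"({self.lambda_par}); a coherent tract requires axial >= radial"
            )
        object.__setattr__(self, "orientation", _check_unit(self.orientation, "orientation"))


@dataclass(frozen=True)
class IsotropicSpectrum:
    """Discretized isotropic diffusivity spectrum f(D) on [a, b]."""

    diffusivities: np.ndarray
    weights: np.ndarray
    limits: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.diffusivities, dtype=float).ravel()
        w = np.asarray(self.weights, dtype=float).ravel()
        a, b = self.limits
        if d.size != w.size:
            raise ValueError(
                f"spectrum grid ({d.size}) and weights ({w.size}) length mismatch"
            )
        if d.size and np.any(np.diff(d) <= 0):
            raise ValueError("diffusivity grid must be strictly increasing")
        if not (0 <= a < b):
            raise ValueError(f"invalid spectrum limits {self.limits}")
        if d.size and (d[0] < a - 1e-12 or d[-1] > b + 1e-12):
            raise ValueError("diffusivities fall outside the spectrum limits")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("spectrum weights must be finite and non-negative")
        object.__setattr__(self, "diffusivities", d)
        object.__setattr__(self, "weights", w)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class VoxelModel:
    """One voxel: fiber compartment + isotropic spectrum + b = 0 signal."""

    fiber: FiberComponent
    spectrum: IsotropicSpectrum
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        total = self.fiber.fraction + self.spectrum.total_weight
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"signal fractions must sum to 1 (fiber + isotropic = {total:.8f})"
            )


@dataclass(frozen=True)
class PartitionConfig:
    """Band limits splitting the isotropic spectrum into restricted /
    non-restricted fractions."""

    restricted_max: float = 0.6
    nonrestricted_max: float = 3.0
    mode: str = "invivo"

    def __post_init__(self) -> None:
        if not 0 < self.restricted_max < self.nonrestricted_max:
            raise ValueError(
                f"need 0 < restricted_max < nonrestricted_max, got "
                f"({self.restricted_max}, {self.nonrestricted_max})"
            )

    @classmethod
    def invivo(cls) -> "PartitionConfig":
        return cls(restricted_max=0.6, nonrestricted_max=3.0, mode="invivo")

    @classmethod
    def exvivo(cls) -> "PartitionConfig":
        return cls(restricted_max=0.6, nonrestricted_max=2.0, mode="exvivo")

    @classmethod
    def for_mode(cls, mode: str) -> "PartitionConfig":
        if mode == "invivo":
            return cls.invivo()
        if mode == "exvivo":
            return cls.exvivo()
        raise ValueError(f"unknown mode {mode!r}")


def iso_grid(nonrestricted_max: float, step: float = ISO_GRID_STEP) -> np.ndarray:
    """Isotropic diffusivity grid from 0 to the non-restricted limit."""
    n = int(round(nonrestricted_max / step))
    return np.linspace(0.0, n * step, n + 1)


def forward_signal(model: VoxelModel, scheme: GradientScheme) -> np.ndarray:
    """Evaluate the noise-free mixture signal for every measurement.

    Returns an array of length K in the units of ``model.s0``; entries at
    b = 0 equal ``s0`` exactly.
    """
    b = scheme.b_ms_um2
    fiber = model.fiber
    cos_phi = scheme.directions @ fiber.orientation
    aniso = np.exp(-b * fiber.lambda_perp) * np.exp(
        -b * (fiber.lambda_par - fiber.lambda_perp) * cos_phi**2
    )
    iso = np.exp(-np.outer(b, model.spectrum.diffusivities)) @ model.spectrum.weights
    return model.s0 * (fiber.fraction * aniso + iso)


def partition_spectrum(
    spectrum: IsotropicSpectrum, cfg: PartitionConfig
) -> tuple[float, float]:
    """Split spectrum mass into (restricted, non-restricted) fractions.

    Restricted collects weights at D <= ``restricted_max`` (boundary
    inclusive); non-restricted collects ``restricted_max`` < D <=
    ``nonrestricted_max``.  Mass above the non-restricted limit is
    excluded from both and reported via the module logger; the three
    parts always sum exactly to the total weight.
    """
    d, w = spectrum.diffusivities, spectrum.weights
    restricted = float(w[d <= cfg.restricted_max].sum())
    nonrestricted = float(
        w[(d > cfg.restricted_max) & (d <= cfg.nonrestricted_max)].sum()
    )
    excluded = spectrum.total_weight - restricted - nonrestricted
    if excluded > 1e-12:
        log.info(
            "partition_spectrum: %.4g spectrum weight above D=%.3g um2/ms excluded",
            excluded,
            cfg.nonrestricted_max,
        )
    return restricted, nonrestricted
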