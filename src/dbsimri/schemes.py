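"""Diffusion gradient schemes (directions + b-values).

A scheme pairs one unit gradient direction with one b-value per
measurement.  The two built-in layouts mirror the small-animal optic-nerve
protocols this package targets: a 25-measurement in vivo acquisition
(1 reference at b = 0 plus 24 weighted directions, max b = 2,200 s/mm2)
and a 99-measurement ex vivo acquisition (1 + 98, max b = 3,000 s/mm2).

Directions are laid out by electrostatic repulsion on the hemisphere
(antipodally symmetric Coulomb energy), deterministic for a given seed.
Weighted b-values cycle through four shells at 25/50/75/100 % of the
maximum so the isotropic spectrum inversion sees several decay scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["GradientScheme", "make_scheme", "B0_THRESHOLD"]

#: b-values (s/mm2) below this are treated as b = 0 reference measurements.
B0_THRESHOLD = 10.0

#: conversion from s/mm2 to ms/um2 so that b*D is dimensionless when D is
#: expressed in um2/ms.
B_TO_MS_PER_UM2 = 1e-3

_MODES = {"invivo": (25, 2200.0), "exvivo": (99, 3000.0)}


@dataclass(frozen=True)
class GradientScheme:
    """Acquisition design: one direction and b-value per measurement.

    Parameters
    ----------
    directions : (K, 3) array
        Gradient directions; rows with b > 0 must be unit vectors.
    bvalues : (K,) array
        Non-negative b-values in s/mm2.  At least one entry must be a
        b = 0 reference (b < ``B0_THRESHOLD``).
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.asarray(self.bvalues, dtype=float).ravel()
        if d.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {d.shape} incompatible with "
                f"{b.size} b-values"
            )
        if b.size < 7:
            raise ValueError(
                "need at least 7 measurements (6 directions + 1 reference), "
                f"got {b.size}"
            )
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("b-values must be finite and non-negative")
        weighted = b >= B0_THRESHOLD
        if not np.any(~weighted):
            raise ValueError("scheme has no b = 0 reference measurement")
        norms = np.linalg.norm(d[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted gradient directions must be unit vectors")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues < B0_THRESHOLD

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values converted to ms/um2 (zeroing the b = 0 references)."""
        b = np.where(self.b0_mask, 0.0, self.bvalues)
        return b * B_TO_MS_PER_UM2

    @property
    def n_weighted_levels(self) -> int:
        """Number of distinct nonzero b-value shells."""
        return np.unique(self.bvalues[~self.b0_mask]).size

    def cache_key(self) -> tuple:
        return (self.directions.tobytes(), self.bvalues.tobytes())


def _repulsion_directions(n: int, seed: int, n_iter: int = 400) -> np.ndarray:
    """n roughly uniform hemisphere directions via antipodal Coulomb descent."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for it in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]          # x_i - x_j
        asum = x[:, None, :] + x[None, :, :]          # x_i + x_j (antipode)
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(asum, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            asum / d2[..., None] ** 3
        ).sum(axis=1)
        # project force onto the tangent plane and take a decaying step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        x += step * force / max(1.0, np.abs(force).max())
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        if it and it % 100 == 0:
            step *= 0.5
    # canonical hemisphere: non-negative z (then y, then x at the equator)
    flip = (x[:, 2] < 0) | ((x[:, 2] == 0) & (x[:, 1] < 0))
    x[flip] *= -1.0
    return x


@lru_cache(maxsize=8)
def _cached_scheme(mode: str, seed: int) -> GradientScheme:
    n_total, bmax = _MODES[mode]
    n_weighted = n_total - 1
    dirs = _repulsion_directions(n_weighted, seed)
    levels = np.array([0.25, 0.5, 0.75, 1.0]) * bmax
    bvals = levels[np.arange(n_weighted) % 4]
    directions = np.vstack([np.zeros(3), dirs])
    bvalues = np.concatenate([[0.0], bvals])
    return GradientScheme(directions, bvalues)


def make_scheme(mode: str = "invivo", seed: int = 0) -> GradientScheme:
    """Build the built-in acquisition layout for ``mode``.

    ``invivo`` gives 25 measurements with max b = 2,200 s/mm2; ``exvivo``
    gives 99 with max b = 3,000 s/mm2.  Deterministic for a given
    ``(mode, seed)`` pair.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}, got {mode!r}")
    return _cached_scheme(mode, int(seed))
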