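"""Spectrum inversion: estimate the fiber compartment and the isotropic
diffusivity spectrum from one voxel's diffusion-weighted signal.

The fit is a nested optimisation.  The fiber axis is fixed first from
the DTI principal eigenvector (adequate for a coherent tract and fully
deterministic).  An outer bounded search over the fiber diffusivity pair
(lam_par, lam_perp) -- coarse grid followed by Nelder-Mead refinement --
wraps an inner non-negative least-squares solve over the column basis
[anisotropic signature at (lam_par, lam_perp); exp(-b_k D_i) for each
isotropic grid diffusivity D_i], with a small ridge penalty on the
isotropic weights to stabilise the near-collinear basis.  Fitted weights
are normalised by their sum, so compartment fractions are
signal-intensity fractions by construction; restricted / non-restricted
fractions then follow from the spectrum partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import nnls

from .dti import DTIModel, _sign_normalize
from .schemes import GradientScheme
from .signal_model import (
    ISO_GRID_STEP,
    IsotropicSpectrum,
    PartitionConfig,
    iso_grid,
    partition_spectrum,
)

__all__ = [
    "DBSIFitConfig",
    "DBSIResults",
    "DBSIModel",
    "estimate_orientation",
    "fit_dbsi",
    "fit_volume",
    "nnls_spectrum",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DBSIFitConfig:
    """Numerical configuration of the spectrum inversion.

    ``ridge_penalty`` is relative: the absolute Tikhonov weight is
    ``ridge_penalty * mean(signal^2) / (K * n_iso)``, which keeps the
    penalty a small, scale-invariant fraction of the least-squares
    objective.  ``min_anisotropy`` keeps the fiber compartment genuinely
    anisotropic (lam_par - lam_perp >= min_anisotropy); without it the
    degenerate lam_par = lam_perp fiber column duplicates an isotropic
    basis column and, being ridge-exempt, would absorb isotropic mass.
    """

    partition: PartitionConfig = field(default_factory=PartitionConfig.invivo)
    lambda_par_bounds: tuple[float, float] = (0.1, 4.0)
    lambda_perp_bounds: tuple[float, float] = (0.0, 1.5)
    ridge_penalty: float = 0.1
    outer_grid_step: float = 0.25
    refine_tolerance: float = 1e-4
    min_anisotropy: float = 0.2
    iso_grid_step: float = ISO_GRID_STEP
    refine_orientation: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.lambda_par_bounds
        lo2, hi2 = self.lambda_perp_bounds
        if not (lo < hi and lo2 < hi2):
            raise ValueError("empty diffusivity bounds")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be >= 0")
        if self.outer_grid_step <= 0 or self.iso_grid_step <= 0:
            raise ValueError("grid steps must be positive")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "DBSIFitConfig":
        return cls(partition=PartitionConfig.for_mode(mode), **overrides)


@dataclass(frozen=True)
class DBSIResults:
    """Per-voxel spectrum-inversion estimates.

    Fractions are signal-intensity fractions and, together with any
    spectrum mass above the non-restricted limit (``excluded_fraction``),
    sum to 1.  ``residual_norm`` is the unpenalised fit residual.
    """

    fiber_fraction: float
    lambda_par: float
    lambda_perp: float
    restricted_fraction: float
    nonrestricted_fraction: float
    spectrum: IsotropicSpectrum
    orientation: np.ndarray
    residual_norm: float
    s0: float
    valid: bool = True

    @property
    def excluded_fraction(self) -> float:
        return 1.0 - (
            self.fiber_fraction + self.restricted_fraction + self.nonrestricted_fraction
        )

    def summary(self) -> str:
        lines = [
            "DBSI spectrum-inversion fit",
            "---------------------------",
            f"  fiber fraction          : {self.fiber_fraction: .4f}",
            f"  fiber axial diffusivity : {self.lambda_par: .4f} um2/ms",
            f"  fiber radial diffusivity: {self.lambda_perp: .4f} um2/ms",
            f"  restricted fraction     : {self.restricted_fraction: .4f}",
            f"  non-restricted fraction : {self.nonrestricted_fraction: .4f}",
            f"  orientation             : ({self.orientation[0]: .3f}, "
            f"{self.orientation[1]: .3f}, {self.orientation[2]: .3f})",
            f"  residual norm           : {self.residual_norm: .3e}",
            f"  valid                   : {self.valid}",
        ]
        return "\n".join(lines)

    def plot_spectrum(self, ax=None):
        """Bar plot of the fitted isotropic spectrum plus the fiber fraction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d, w = self.spectrum.diffusivities, self.spectrum.weights
        ax.bar(d, w, width=0.8 * np.diff(d).min() if d.size > 1 else 0.04,
               label="isotropic spectrum")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("isotropic ADC (um2/ms)")
        ax.set_ylabel("signal-intensity fraction")
        ax.set_title(f"fiber fraction = {self.fiber_fraction:.3f}")
        ax.legend()
        return ax


def estimate_orientation(signal: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Fiber axis estimate: DTI principal eigenvector, sign-normalised to
    non-negative z (ties broken by non-negative y, then x)."""
    res = DTIModel(signal, scheme).fit()
    return _sign_normalize(res.principal_direction.copy())


def nnls_spectrum(
    A: np.ndarray, y: np.ndarray, ridge: float = 0.0, penalized: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Non-negative least squares with optional Tikhonov penalty.

    Minimises ``||A w - y||^2 + ridge * ||w[penalized]||^2`` subject to
    w >= 0 and returns ``(w, unpenalised residual norm)``.  ``penalized``
    is a boolean column mask; by default every column is penalised.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if ridge > 0:
        if penalized is None:
            penalized = np.ones(A.shape[1], dtype=bool)
        idx = np.flatnonzero(penalized)
        aug = np.zeros((idx.size, A.shape[1]))
        aug[np.arange(idx.size), idx] = np.sqrt(ridge)
        A_solve = np.vstack([A, aug])
        y_solve = np.concatenate([y, np.zeros(idx.size)])
    else:
        A_solve, y_solve = A, y
    w, _ = nnls(A_solve, y_solve)
    return w, float(np.linalg.norm(A @ w - y))


@lru_cache(maxsize=16)
def _iso_basis_cached(scheme_key: tuple, nonrestricted_max: float, step: float):
    # reconstruct b from the key to avoid holding scheme references
    bvalues = np.frombuffer(scheme_key[1])
    from .schemes import B0_THRESHOLD

    b = np.where(bvalues < B0_THRESHOLD, 0.0, bvalues) * 1e-3
    grid = iso_grid(nonrestricted_max, step)
    return grid, np.exp(-np.outer(b, grid))


class DBSIModel:
    """Spectrum-inversion model for one voxel.

    Parameters
    ----------
    signal : (K,) array
        Measured signal (arbitrary units), same order as ``scheme``.
    scheme : GradientScheme
        Must provide b-value diversity (>= 3 distinct nonzero shells).
    config : DBSIFitConfig, optional
        Numerical settings; defaults to the in vivo partition.
    """

    def __init__(
        self,
        signal: np.ndarray,
        scheme: GradientScheme,
        config: DBSIFitConfig | None = None,
    ):
        signal = np.asarray(signal, dtype=float).ravel()
        if signal.size != len(scheme):
            raise ValueError(
                f"signal length {signal.size} does not match scheme length {len(scheme)}"
            )
        if not np.any(signal > 0):
            raise ValueError("all-zero (or non-positive) signal cannot be fitted")
        if scheme.n_weighted_levels < 3:
            raise ValueError(
                "spectrum inversion needs >= 3 distinct nonzero b-value shells, "
                f"scheme has {scheme.n_weighted_levels}"
            )
        self.signal = signal
        self.scheme = scheme
        self.config = config or DBSIFitConfig()
        self._grid, self._iso_basis = _iso_basis_cached(
            scheme.cache_key(),
            self.config.partition.nonrestricted_max,
            self.config.iso_grid_step,
        )
        self._b = scheme.b_ms_um2
        # preallocated design matrices: plain for the outer search, ridge-
        # augmented for the final solve (only column 0 changes per call)
        K, n_iso = len(scheme), self._grid.size
        self._A = np.empty((K, n_iso + 1))
        self._A[:, 1:] = self._iso_basis
        ridge = (
            self.config.ridge_penalty * float(np.mean(signal**2)) / (K * n_iso)
        )
        self._A_aug = np.zeros((K + n_iso, n_iso + 1))
        self._A_aug[:K, 1:] = self._iso_basis
        self._A_aug[K:, 1:] = np.sqrt(ridge) * np.eye(n_iso)
        self._y_aug = np.concatenate([signal, np.zeros(n_iso)])

    # -- inner solve -----------------------------------------------------
    def _aniso_column(self, lam_par: float, lam_perp: float, cos2: np.ndarray):
        return np.exp(-self._b * lam_perp - self._b * (lam_par - lam_perp) * cos2)

    def _solve_search(self, lam_par: float, lam_perp: float, cos2: np.ndarray) -> float:
        """Unpenalised residual used to rank (lam_par, lam_perp) candidates."""
        self._A[:, 0] = self._aniso_column(lam_par, lam_perp, cos2)
        w, rnorm = nnls(self._A, self.signal)
        return float(rnorm)

    def _solve_at(self, lam_par: float, lam_perp: float, cos2: np.ndarray):
        """Ridge-regularised solve reported for the selected optimum."""
        self._A_aug[: len(self.scheme), 0] = self._aniso_column(lam_par, lam_perp, cos2)
        w, _ = nnls(self._A_aug, self._y_aug)
        res = float(np.linalg.norm(self._A_aug[: len(self.scheme)] @ w - self.signal))
        return w, res

    # -- outer search ----------------------------------------------------
    def _outer_candidates(self):
        cfg = self.config
        lp_lo, lp_hi = cfg.lambda_par_bounds
        lt_lo, lt_hi = cfg.lambda_perp_bounds
        lps = np.arange(lp_lo, lp_hi + 1e-9, cfg.outer_grid_step)
        lts = np.arange(lt_lo, lt_hi + 1e-9, cfg.outer_grid_step)
        for lp in lps:
            for lt in lts:
                if lp - lt >= cfg.min_anisotropy - 1e-12:
                    yield float(lp), float(lt)

    def _clip(self, lp: float, lt: float) -> tuple[float, float]:
        cfg = self.config
        lo, hi = cfg.lambda_par_bounds
        lo2, hi2 = cfg.lambda_perp_bounds
        lp = min(max(lp, lo), hi)
        lt = min(max(min(lt, lp - cfg.min_anisotropy), lo2), hi2)
        return lp, lt

    def _search_lambdas(self, cos2: np.ndarray, start: tuple[float, float] | None = None):
        """Deterministic (lam_par, lam_perp) search: coarse grid (or warm
        start) followed by a compass search with step halving, which is
        robust to the piecewise structure NNLS active-set changes impose
        on the residual surface.  Ties break toward smaller lam_perp,
        then smaller lam_par."""
        cfg = self.config
        cache: dict[tuple[float, float], float] = {}

        def evaluate(lp: float, lt: float) -> tuple[float, float, float]:
            lp, lt = self._clip(lp, lt)
            key = (round(lp, 6), round(lt, 6))
            if key not in cache:
                cache[key] = self._solve_search(*key, cos2)
            return (cache[key], key[1], key[0])  # (res, lam_perp, lam_par)

        if start is None:
            best = min(evaluate(lp, lt) for lp, lt in self._outer_candidates())
        else:
            best = evaluate(*start)
        step = cfg.outer_grid_step / 2.0
        while step >= 2e-3:
            moved = True
            while moved:
                moved = False
                _, lt_b, lp_b = best
                for dlp, dlt in ((step, 0), (-step, 0), (0, step), (0, -step),
                                 (step, step), (step, -step), (-step, step), (-step, -step)):
                    cand = evaluate(lp_b + dlp, lt_b + dlt)
                    if cand < best:
                        best = cand
                        moved = True
            step /= 2.0
        res, lt, lp = best
        return lp, lt, res

    def _refine_orientation(
        self, orientation: np.ndarray, lp: float, lt: float
    ) -> np.ndarray:
        """Compass search over tangent-plane tilts of the fiber axis,
        minimising the inner residual at fixed (lam_par, lam_perp)."""
        v = orientation / np.linalg.norm(orientation)
        # tangent basis at v
        helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(v, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)

        def res_at(a: float, b: float) -> float:
            u = v + a * e1 + b * e2
            u /= np.linalg.norm(u)
            cos2 = (self.scheme.directions @ u) ** 2
            return self._solve_search(lp, lt, cos2)

        best = (res_at(0.0, 0.0), 0.0, 0.0)
        step = np.tan(np.radians(2.0))  # start at ~2 degrees
        while step >= np.tan(np.radians(0.05)):
            moved = True
            while moved:
                moved = False
                _, a_b, b_b = best
                for da, db in ((step, 0), (-step, 0), (0, step), (0, -step)):
                    cand = (res_at(a_b + da, b_b + db), a_b + da, b_b + db)
                    if cand[0] < best[0]:
                        best = cand
                        moved = True
            step /= 2.0
        _, a, b = best
        u = v + a * e1 + b * e2
        return _sign_normalize(u / np.linalg.norm(u))

    def fit(self, orientation: np.ndarray | None = None) -> DBSIResults:
        """Run the nested inversion; deterministic given signal and config."""
        cfg = self.config
        if orientation is None:
            orientation = estimate_orientation(self.signal, self.scheme)
        orientation = np.asarray(orientation, dtype=float)

        cos2 = (self.scheme.directions @ orientation) ** 2
        lp, lt, res = self._search_lambdas(cos2)
        if cfg.refine_orientation:
            # alternate axis refinement and diffusivity search until the
            # axis stops moving; the DTI seed is typically within ~1 degree
            # but the spectrum partition is sensitive to even that much.
            for _ in range(4):
                refined = self._refine_orientation(orientation, lp, lt)
                if abs(float(refined @ orientation)) > np.cos(np.radians(0.05)):
                    orientation = refined
                    break
                orientation = refined
                cos2 = (self.scheme.directions @ orientation) ** 2
                lp, lt, res = self._search_lambdas(cos2, start=(lp, lt))
            cos2 = (self.scheme.directions @ orientation) ** 2
            lp, lt, res = self._search_lambdas(cos2, start=(lp, lt))
        w, res = self._solve_at(lp, lt, cos2)

        total = float(w.sum())
        if total <= 0:
            log.warning("DBSI fit collapsed to zero weight; flagging voxel invalid")
            spectrum = IsotropicSpectrum(
                self._grid, np.zeros_like(self._grid), (0.0, cfg.partition.nonrestricted_max)
            )
            return DBSIResults(
                0.0, lp, lt, 0.0, 0.0, spectrum, orientation, res, 0.0, valid=False
            )
        fractions = w / total
        spectrum = IsotropicSpectrum(
            self._grid, fractions[1:], (0.0, cfg.partition.nonrestricted_max)
        )
        restricted, nonrestricted = partition_spectrum(spectrum, cfg.partition)
        return DBSIResults(
            fiber_fraction=float(fractions[0]),
            lambda_par=float(lp),
            lambda_perp=float(lt),
            restricted_fraction=restricted,
            nonrestricted_fraction=nonrestricted,
            spectrum=spectrum,
            orientation=orientation,
            residual_norm=res,
            s0=total,
        )


def fit_dbsi(
    signal: np.ndarray, scheme: GradientScheme, cfg: DBSIFitConfig | None = None
) -> DBSIResults:
    """Convenience wrapper: ``DBSIModel(signal, scheme, cfg).fit()``."""
    return DBSIModel(signal, scheme, cfg).fit()


#: map-stack metric names produced by fit_volume, in output order.
VOLUME_METRICS = (
    "fiber_fraction",
    "restricted_fraction",
    "nonrestricted_fraction",
    "dbsi_lambda_par",
    "dbsi_lambda_perp",
    "dbsi_residual",
    "dti_lambda_par",
    "dti_lambda_perp",
    "dti_fa",
    "dti_md",
)


def fit_volume(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray,
    cfg: DBSIFitConfig | None = None,
    progress_every: int = 200,
) -> dict[str, np.ndarray]:
    """Fit every masked voxel of a 4-D volume with both models.

    Returns one 3-D map per metric in ``VOLUME_METRICS``; unmasked voxels
    hold NaN.  Deterministic; progress is logged every
    ``progress_every`` voxels.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if dwi.ndim != 4:
        raise ValueError(f"dwi must be 4-D, got shape {dwi.shape}")
    if dwi.shape[3] != len(scheme):
        raise ValueError(
            f"dwi has {dwi.shape[3]} volumes but scheme has {len(scheme)} measurements"
        )
    if mask.shape != dwi.shape[:3]:
        raise ValueError(
            f"mask shape {mask.shape} does not match dwi spatial shape {dwi.shape[:3]}"
        )
    maps = {m: np.full(dwi.shape[:3], np.nan) for m in VOLUME_METRICS}
    voxels = np.argwhere(mask)
    if voxels.size == 0:
        log.warning("fit_volume: empty mask, returning all-NaN maps")
        return maps
    for i, (x, y, z) in enumerate(voxels):
        sig = dwi[x, y, z]
        try:
            dti_res = DTIModel(sig, scheme).fit()
            dbsi_res = DBSIModel(sig, scheme, cfg).fit(
                orientation=_sign_normalize(dti_res.principal_direction.copy())
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("voxel (%d,%d,%d) failed to fit: %s", x, y, z, exc)
            continue
        maps["fiber_fraction"][x, y, z] = dbsi_res.fiber_fraction
        maps["restricted_fraction"][x, y, z] = dbsi_res.restricted_fraction
        maps["nonrestricted_fraction"][x, y, z] = dbsi_res.nonrestricted_fraction
        maps["dbsi_lambda_par"][x, y, z] = dbsi_res.lambda_par
        maps["dbsi_lambda_perp"][x, y, z] = dbsi_res.lambda_perp
        maps["dbsi_residual"][x, y, z] = dbsi_res.residual_norm
        maps["dti_lambda_par"][x, y, z] = dti_res.lambda_par
        maps["dti_lambda_perp"][x, y, z] = dti_res.lambda_perp
        maps["dti_fa"][x, y, z] = dti_res.fa
        maps["dti_md"][x, y, z] = dti_res.md
        if progress_every and (i + 1) % progress_every == 0:
            log.info("fit_volume: %d / %d voxels done", i + 1, len(voxels))
    return maps
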