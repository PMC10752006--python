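"""Conventional single-tensor (DTI) fit and scalar metrics.

The comparison arm of the analysis: a weighted log-linear least-squares
estimate of the 3x3 symmetric diffusion tensor, eigen-decomposed into
axial diffusivity (largest eigenvalue), radial diffusivity (mean of the
two smaller eigenvalues), FA and MD (trace/3).  On mixed fiber +
restricted-isotropic voxels the single-tensor axial diffusivity is
dragged below the fiber's true axial diffusivity -- the confound that
motivates the spectrum decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schemes import GradientScheme

__all__ = ["DTIResults", "DTIModel", "fit_dti"]

#: signals are clamped to this floor (relative to the b=0 mean) before log.
SIGNAL_FLOOR = 1e-8


def _sign_normalize(v: np.ndarray) -> np.ndarray:
    """Canonical antipodal representative: non-negative z, then y, then x."""
    eps = 1e-12
    if v[2] < -eps or (abs(v[2]) <= eps and (v[1] < -eps or (abs(v[1]) <= eps and v[0] < 0))):
        return -v
    return v


@dataclass(frozen=True)
class DTIResults:
    """Scalar metrics of a single-tensor fit.

    ``valid`` is False when the voxel needed signal flooring or produced
    a non-physical (negative-eigenvalue) tensor; eigenvalues are reported
    as fitted, without clipping, so diagnostics stay visible.
    """

    lambda_par: float
    lambda_perp: float
    fa: float
    md: float
    principal_direction: np.ndarray
    eigenvalues: np.ndarray
    s0: float
    valid: bool = True

    def summary(self) -> str:
        lines = [
            "DTI single-tensor fit",
            "---------------------",
            f"  axial diffusivity  (AD): {self.lambda_par: .4f} um2/ms",
            f"  radial diffusivity (RD): {self.lambda_perp: .4f} um2/ms",
            f"  fractional anisotropy  : {self.fa: .4f}",
            f"  mean diffusivity   (MD): {self.md: .4f} um2/ms",
            f"  principal direction    : ({self.principal_direction[0]: .3f}, "
            f"{self.principal_direction[1]: .3f}, {self.principal_direction[2]: .3f})",
            f"  valid                  : {self.valid}",
        ]
        return "\n".join(lines)


def fa_from_eigenvalues(evals: np.ndarray) -> float:
    evals = np.asarray(evals, dtype=float)
    md = evals.mean()
    denom = float((evals**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(1.5 * ((evals - md) ** 2).sum() / denom))


class DTIModel:
    """Single diffusion tensor model for one voxel's signal vector.

    Parameters
    ----------
    signal : (K,) array
        Measured signal, same order as the scheme.
    scheme : GradientScheme
        Acquisition design; needs >= 6 non-collinear weighted directions
        plus a b = 0 reference.
    """

    def __init__(self, signal: np.ndarray, scheme: GradientScheme):
        signal = np.asarray(signal, dtype=float).ravel()
        if signal.size != len(scheme):
            raise ValueError(
                f"signal length {signal.size} does not match scheme length {len(scheme)}"
            )
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal contains non-finite values")
        self.signal = signal
        self.scheme = scheme
        self.design = self._design_matrix(scheme)
        if np.linalg.matrix_rank(self.design) < 7:
            raise ValueError(
                "rank-deficient DTI design: scheme with "
                f"{int((~scheme.b0_mask).sum())} weighted directions and "
                f"{scheme.n_weighted_levels} b-levels does not determine a tensor"
            )

    @staticmethod
    def _design_matrix(scheme: GradientScheme) -> np.ndarray:
        b = scheme.b_ms_um2
        g = scheme.directions
        return np.column_stack(
            [
                np.ones_like(b),
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2 * b * g[:, 0] * g[:, 1],
                -2 * b * g[:, 0] * g[:, 2],
                -2 * b * g[:, 1] * g[:, 2],
            ]
        )

    def fit(self) -> DTIResults:
        """Weighted log-linear LS fit (weights = squared predicted signal)."""
        floor = SIGNAL_FLOOR * max(self.signal.max(), 1e-300)
        clamped = np.maximum(self.signal, floor)
        flagged = bool(np.any(self.signal <= 0))
        y = np.log(clamped)
        X = self.design
        # first pass: OLS; second pass: reweight by predicted signal^2
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        w = np.exp(X @ beta)
        Xw = X * w[:, None]
        beta = np.linalg.lstsq(Xw, y * w, rcond=None)[0]
        tensor = np.array(
            [
                [beta[1], beta[4], beta[5]],
                [beta[4], beta[2], beta[6]],
                [beta[5], beta[6], beta[3]],
            ]
        )
        evals, evecs = np.linalg.eigh(tensor)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        principal = _sign_normalize(evecs[:, 0].copy())
        valid = not flagged and bool(np.all(evals > -1e-9))
        return DTIResults(
            lambda_par=float(evals[0]),
            lambda_perp=float(evals[1:].mean()),
            fa=fa_from_eigenvalues(evals),
            md=float(evals.mean()),
            principal_direction=principal,
            eigenvalues=evals,
            s0=float(np.exp(beta[0])),
            valid=valid,
        )


def fit_dti(signal: np.ndarray, scheme: GradientScheme) -> DTIResults:
    """Convenience wrapper: ``DTIModel(signal, scheme).fit()``."""
    return DTIModel(signal, scheme).fit()
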