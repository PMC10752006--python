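import itertools

import numpy as np
import pytest

from dbsimri import (
    DBSIFitConfig,
    DBSIModel,
    estimate_orientation,
    fit_dbsi,
    fit_volume,
    nnls_spectrum,
)
from dbsimri.schemes import GradientScheme

from conftest import make_mixture_signal

Z = np.array([0.0, 0.0, 1.0])


def simplex_grid_residual(A, y, step=0.05):
    """Exhaustive search over weight vectors on the unit simplex grid;
    independent brute-force oracle for the inner non-negative solver."""
    n = A.shape[1]
    ticks = int(round(1.0 / step))
    best = np.inf
    for cuts in itertools.combinations(range(ticks + n - 1), n - 1):
        # stars-and-bars enumeration of grid points with sum = 1
        parts = np.diff((-1, *cuts, ticks + n - 1)) - 1
        w = np.asarray(parts) * step
        res = np.linalg.norm(A @ w - y)
        if res < best:
            best = res
    return best


# ---------------------------------------------------------------- orientation
def test_orientation_axis_aligned(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 1.0, 1.8, 0.2, 0.0, 0.0, orientation=Z)
    np.testing.assert_allclose(estimate_orientation(sig, invivo_scheme), Z, atol=1e-6)
    # antipodal normalisation: -z maps to +z
    sig = make_mixture_signal(invivo_scheme, 1.0, 1.8, 0.2, 0.0, 0.0, orientation=-Z)
    np.testing.assert_allclose(estimate_orientation(sig, invivo_scheme), Z, atol=1e-6)


def test_orientation_oblique_with_contamination(invivo_scheme):
    axis = np.ones(3) / np.sqrt(3)
    sig = make_mixture_signal(
        invivo_scheme, 0.8, 1.8, 0.2, 0.2, 0.0, orientation=axis
    )
    est = estimate_orientation(sig, invivo_scheme)
    angle = np.degrees(np.arccos(min(1.0, abs(est @ axis))))
    assert angle < 1.0


# ---------------------------------------------------------------- single voxel
def test_pure_fiber_voxel(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 1.0, 1.89, 0.15, 0.0, 0.0)
    res = fit_dbsi(sig, invivo_scheme)
    assert res.fiber_fraction >= 0.98
    assert res.restricted_fraction <= 0.02
    assert res.lambda_par == pytest.approx(1.89, abs=0.05)
    assert res.lambda_perp == pytest.approx(0.15, abs=0.02)


def test_pure_restricted_voxel(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 0.0, 1.0, 0.5, 1.0, 0.0)
    res = fit_dbsi(sig, invivo_scheme)
    assert res.fiber_fraction <= 0.02
    assert res.restricted_fraction >= 0.98


def test_tbi_like_mixture_recovery(invivo_scheme, day30_compositions):
    fiber, restricted, nonrestricted, lam_par, lam_perp = day30_compositions["TBI"]
    sig = make_mixture_signal(
        invivo_scheme, fiber, lam_par, lam_perp, restricted, nonrestricted
    )
    res = fit_dbsi(sig, invivo_scheme)
    assert res.fiber_fraction == pytest.approx(fiber, abs=0.03)
    assert res.restricted_fraction == pytest.approx(restricted, abs=0.03)
    assert res.nonrestricted_fraction == pytest.approx(nonrestricted, abs=0.03)
    assert res.lambda_par == pytest.approx(lam_par, abs=0.05)
    assert res.lambda_perp == pytest.approx(lam_perp, abs=0.05)


def test_fractions_partition_unity(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 0.6, 1.7, 0.2, 0.25, 0.15)
    res = fit_dbsi(sig, invivo_scheme)
    total = (
        res.fiber_fraction + res.restricted_fraction
        + res.nonrestricted_fraction + res.excluded_fraction
    )
    assert total == pytest.approx(1.0, abs=1e-6)


def test_monotone_confound(invivo_scheme):
    """Adding restricted-water mass to a fixed fiber raises the fitted
    restricted fraction and lowers the fitted fiber fraction."""
    restricted_levels = (0.0, 0.1, 0.2, 0.3)
    restr, fib = [], []
    for r in restricted_levels:
        sig = make_mixture_signal(invivo_scheme, 1.0 - r, 1.8, 0.2, r, 0.0)
        res = fit_dbsi(sig, invivo_scheme)
        restr.append(res.restricted_fraction)
        fib.append(res.fiber_fraction)
    assert np.all(np.diff(restr) > 0)
    assert np.all(np.diff(fib) < 0)


def test_fit_determinism(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 0.7, 1.6, 0.25, 0.2, 0.1)
    a = fit_dbsi(sig, invivo_scheme)
    b = fit_dbsi(sig, invivo_scheme)
    assert a.lambda_par == b.lambda_par
    assert a.lambda_perp == b.lambda_perp
    np.testing.assert_array_equal(a.spectrum.weights, b.spectrum.weights)


def test_random_mixture_recovery_statistics(invivo_scheme):
    """Parameter recovery over random noise-free mixtures within
    physiologic bounds: median error <= 0.02 (fractions) and
    <= 0.05 um2/ms (diffusivities)."""
    rng = np.random.default_rng(42)
    frac_err, diff_err = [], []
    for _ in range(100):
        lam_par = rng.uniform(1.2, 2.2)
        lam_perp = rng.uniform(0.05, 0.4)
        fiber = rng.uniform(0.5, 0.95)
        restricted = rng.uniform(0.0, 1.0 - fiber)
        nonrestricted = 1.0 - fiber - restricted
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        sig = make_mixture_signal(
            invivo_scheme, fiber, lam_par, lam_perp, restricted, nonrestricted,
            orientation=axis,
        )
        res = fit_dbsi(sig, invivo_scheme)
        frac_err.extend([
            abs(res.fiber_fraction - fiber),
            abs(res.restricted_fraction - restricted),
            abs(res.nonrestricted_fraction - nonrestricted),
        ])
        diff_err.extend([
            abs(res.lambda_par - lam_par), abs(res.lambda_perp - lam_perp)
        ])
    assert np.median(frac_err) <= 0.02
    assert np.median(diff_err) <= 0.05


def test_noise_robustness_restricted_fraction(invivo_scheme, day30_compositions):
    """At Rician SNR 30 the mean recovered restricted fraction over
    repeats of a sham-like voxel stays within 0.03 of the generator."""
    from dbsimri.phantom import add_rician_noise

    fiber, restricted, nonrestricted, lam_par, lam_perp = day30_compositions["sham"]
    clean = make_mixture_signal(
        invivo_scheme, fiber, lam_par, lam_perp, restricted, nonrestricted
    )
    rng = np.random.default_rng(2024)
    values = []
    for _ in range(50):
        noisy = add_rician_noise(clean, 1.0 / 30.0, rng)
        values.append(fit_dbsi(noisy, invivo_scheme).restricted_fraction)
    assert abs(np.mean(values) - restricted) <= 0.03


# ---------------------------------------------------------------- inner solver
def test_nnls_matches_simplex_grid_oracle(invivo_scheme):
    """The inner non-negative solver attains (at least) the residual of
    an exhaustive simplex-grid search on reduced 5-basis problems."""
    b = invivo_scheme.b_ms_um2
    rng = np.random.default_rng(9)
    for _ in range(10):
        diffs = np.sort(rng.uniform(0.1, 3.0, size=5))
        A = np.exp(-np.outer(b, diffs))
        w_true = rng.dirichlet(np.ones(5))
        y = A @ w_true
        w, res = nnls_spectrum(A, y)
        grid_best = simplex_grid_residual(A, y, step=0.05)
        assert res <= grid_best + 1e-10
        # within the grid's own resolution
        assert grid_best - res <= np.linalg.norm(A, 2) * 0.05 * np.sqrt(5) / 2


def test_ridge_penalty_not_in_reported_residual(invivo_scheme):
    b = invivo_scheme.b_ms_um2
    A = np.exp(-np.outer(b, np.array([0.2, 0.8, 1.5, 2.2, 2.9])))
    y = A @ np.array([0.3, 0.3, 0.2, 0.1, 0.1])
    w, res = nnls_spectrum(A, y, ridge=0.5)
    assert res == pytest.approx(np.linalg.norm(A @ w - y), abs=1e-12)


# ---------------------------------------------------------------- errors
def test_all_zero_signal_rejected(invivo_scheme):
    with pytest.raises(ValueError, match="all-zero"):
        DBSIModel(np.zeros(len(invivo_scheme)), invivo_scheme)


def test_insufficient_b_diversity_rejected():
    dirs = np.vstack([np.zeros(3), np.eye(3), -np.eye(3), [np.ones(3) / np.sqrt(3)]])
    scheme = GradientScheme(dirs, np.r_[0.0, np.full(7, 1000.0)])
    with pytest.raises(ValueError, match="shells"):
        DBSIModel(np.ones(8), scheme)


# ---------------------------------------------------------------- volume fits
def test_fit_volume_single_voxel_equals_voxel_fit(invivo_scheme):
    sig = make_mixture_signal(invivo_scheme, 0.8, 1.8, 0.2, 0.1, 0.1)
    dwi = np.zeros((2, 2, 1, len(invivo_scheme)))
    mask = np.zeros((2, 2, 1), dtype=bool)
    dwi[0, 1, 0] = sig
    mask[0, 1, 0] = True
    maps = fit_volume(dwi, invivo_scheme, mask)
    ref = fit_dbsi(sig, invivo_scheme)
    assert maps["fiber_fraction"][0, 1, 0] == pytest.approx(ref.fiber_fraction, abs=1e-12)
    assert np.isnan(maps["fiber_fraction"][0, 0, 0])


def test_fit_volume_empty_mask_warns(invivo_scheme, caplog):
    dwi = np.ones((2, 2, 1, len(invivo_scheme)))
    mask = np.zeros((2, 2, 1), dtype=bool)
    with caplog.at_level("WARNING"):
        maps = fit_volume(dwi, invivo_scheme, mask)
    assert np.isnan(maps["dti_fa"]).all()
    assert any("empty mask" in r.message for r in caplog.records)


def test_fit_volume_shape_mismatches(invivo_scheme):
    with pytest.raises(ValueError, match="volumes"):
        fit_volume(np.ones((2, 2, 1, 7)), invivo_scheme, np.ones((2, 2, 1), bool))
    with pytest.raises(ValueError, match="mask shape"):
        fit_volume(
            np.ones((2, 2, 1, len(invivo_scheme))), invivo_scheme, np.ones((3, 2, 1), bool)
        )


def test_fit_volume_cross_section_recovery(invivo_scheme, day30_compositions):
    fiber, restricted, nonrestricted, lam_par, lam_perp = day30_compositions["sham"]
    sig = make_mixture_signal(
        invivo_scheme, fiber, lam_par, lam_perp, restricted, nonrestricted
    )
    dwi = np.tile(sig, (3, 3, 1, 1))
    mask = np.ones((3, 3, 1), dtype=bool)
    maps = fit_volume(dwi, invivo_scheme, mask)
    np.testing.assert_allclose(maps["fiber_fraction"], fiber, atol=0.03)
    np.testing.assert_allclose(maps["dbsi_lambda_par"], lam_par, atol=0.05)
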