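import numpy as np
import pandas as pd
import pytest

from dbsimri import (
    ROISpec,
    axon_volume,
    nerve_volume,
    pearson_r2,
    percent_change,
    roi_mean,
    round_percent,
    summarize_cohort,
    two_way_anova,
    welch_ttest,
)


# ------------------------------------------------------------------ ROI means
def test_roi_mean_examples():
    vol = 0.00343
    const = np.full((3, 3, 1), 0.7)
    roi = ROISpec(((0, 0, 0), (1, 1, 0)), vol)
    assert roi_mean(const, roi) == pytest.approx(0.7)
    two = np.zeros((2, 2, 1))
    two[0, 0, 0], two[1, 1, 0] = 0.10, 0.14
    assert roi_mean(two, ROISpec(((0, 0, 0), (1, 1, 0)), vol)) == pytest.approx(0.12)


def test_roi_mean_skips_invalid_voxels(caplog):
    m = np.arange(9.0).reshape(3, 3, 1)
    m[1, 1, 0] = np.nan
    roi = ROISpec.from_mask(np.ones((3, 3, 1), bool), 0.01)
    valid = [v for v in np.arange(9.0) if v != 4.0]
    with caplog.at_level("WARNING"):
        assert roi_mean(m, roi) == pytest.approx(np.mean(valid))
    assert any("invalid" in r.message for r in caplog.records)


def test_roi_mean_degenerate_inputs():
    with pytest.raises(ValueError, match="empty"):
        roi_mean(np.ones((2, 2, 1)), ROISpec((), 0.01))
    nan_map = np.full((2, 2, 1), np.nan)
    with pytest.raises(ValueError, match="invalid"):
        roi_mean(nan_map, ROISpec(((0, 0, 0),), 0.01))
    with pytest.raises(IndexError):
        roi_mean(np.ones((2, 2, 1)), ROISpec(((5, 0, 0),), 0.01))
    with pytest.raises(ValueError, match="metric_roi"):
        roi_mean(np.ones((2, 2, 1)), ROISpec(((0, 0, 0),), 0.01, "whole_nerve_roi"))


# ------------------------------------------------------------------- volumes
def test_nerve_volume_examples():
    idx10 = tuple((i, 0, 0) for i in range(10))
    assert nerve_volume(ROISpec(idx10, 0.01, "whole_nerve_roi")) == pytest.approx(0.10)
    idx41 = tuple((i, j, 0) for i in range(41) for j in (0,))
    assert nerve_volume(ROISpec(idx41, 0.00343, "whole_nerve_roi")) == pytest.approx(
        0.1406, abs=1e-4
    )
    with pytest.raises(ValueError, match="empty"):
        nerve_volume(ROISpec((), 0.01, "whole_nerve_roi"))


def test_axon_volume():
    # consistent (after rounding) with the published day-7 sham pair
    assert axon_volume(0.15, 0.76) == pytest.approx(0.114)
    assert axon_volume(0.14, 0.81) == pytest.approx(0.1134)
    assert axon_volume(0.2, 0.0) == 0.0
    with pytest.raises(ValueError, match="fraction"):
        axon_volume(0.1, 1.2)
    with pytest.raises(ValueError, match="volume"):
        axon_volume(-0.1, 0.5)
    # exactly multiplicative, monotone in both arguments
    assert axon_volume(0.2, 0.5) == pytest.approx(2 * axon_volume(0.1, 0.5))
    assert axon_volume(0.2, 0.6) > axon_volume(0.2, 0.5)


# ------------------------------------------------------------ percent change
@pytest.mark.parametrize(
    "ref,cmp_,denom,expected",
    [
        (0.03, 0.12, "reference", 300.0),       # published restricted-fraction rise
        (1.89, 1.47, "reference", -22.2),       # published axial-diffusivity drop
        (0.10, 0.19, "comparison", 47.4),       # published ex vivo convention
        (5.0, 5.0, "reference", 0.0),
    ],
)
def test_percent_change_examples(ref, cmp_, denom, expected):
    assert percent_change(ref, cmp_, denom) == pytest.approx(expected, abs=0.05)


def test_percent_change_asymmetry_and_errors():
    assert percent_change(0.03, 0.12, "reference") != pytest.approx(
        -percent_change(0.12, 0.03, "reference")
    )
    with pytest.raises(ZeroDivisionError):
        percent_change(0.0, 0.1, "reference")
    with pytest.raises(ValueError, match="denominator"):
        percent_change(1.0, 2.0, "median")


@pytest.mark.parametrize("x,expected", [(266.67, 267), (-22.22, -22), (12.5, 13),
                                        (-12.5, -13), (0.4, 0)])
def test_round_percent(x, expected):
    assert round_percent(x) == expected


# ---------------------------------------------------------------- correlation
def test_pearson_collinear_and_orthogonal():
    r, r2, p = pearson_r2([1, 2, 3, 4], [2, 4, 6, 8])
    assert r2 == pytest.approx(1.0)
    r, r2, p = pearson_r2([0, 1, 2], [0, 1, 0])
    assert r == pytest.approx(0.0, abs=1e-12)


def test_pearson_matches_direct_formula():
    rng = np.random.default_rng(3)
    x = rng.normal(size=10)
    y = 0.8 * x + rng.normal(scale=0.5, size=10)
    r, r2, p = pearson_r2(x, y)
    # independent direct covariance computation
    xc, yc = x - x.mean(), y - y.mean()
    r_direct = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    assert r == pytest.approx(r_direct, abs=1e-12)
    from scipy import stats as sps

    t = r_direct * np.sqrt(8 / (1 - r_direct**2))
    assert p == pytest.approx(2 * sps.t.sf(abs(t), df=8), abs=1e-12)


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError, match="3 pairs"):
        pearson_r2([1, 2], [3, 4])
    with pytest.raises(ValueError, match="constant"):
        pearson_r2([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------- ANOVA
def _tidy(groups):
    rows = []
    for (group, day), values in groups.items():
        for i, v in enumerate(values):
            rows.append({"animal": f"{group}{i}", "group": group, "eye": "L",
                         "day": day, "metric": "m", "value": v})
    return pd.DataFrame(rows)


def test_anova_identical_groups_gives_null_group_effect():
    table = _tidy({("sham", 1): [1.0, 2.0, 3.0], ("TBI", 1): [1.0, 2.0, 3.0],
                   ("sham", 3): [2.0, 3.0, 4.0], ("TBI", 3): [2.0, 3.0, 4.0]})
    aov = two_way_anova(table, "m")
    assert aov.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
    assert aov.loc["group", "p"] == pytest.approx(1.0, abs=1e-9)


def test_anova_matches_manual_sums_of_squares():
    """2x2 balanced toy table checked against hand-rolled SS arithmetic."""
    cells = {("sham", 1): [1.0, 2.0], ("sham", 3): [3.0, 4.0],
             ("TBI", 1): [5.0, 6.0], ("TBI", 3): [7.0, 8.0]}
    aov = two_way_anova(_tidy(cells), "m")
    all_vals = np.concatenate(list(cells.values()))
    grand = all_vals.mean()
    n = 2  # per cell
    g_means = {g: np.mean(cells[(g, 1)] + cells[(g, 3)]) for g in ("sham", "TBI")}
    d_means = {d: np.mean(cells[("sham", d)] + cells[("TBI", d)]) for d in (1, 3)}
    ss_group = 2 * n * sum((m - grand) ** 2 for m in g_means.values())
    ss_day = 2 * n * sum((m - grand) ** 2 for m in d_means.values())
    cell_means = {k: np.mean(v) for k, v in cells.items()}
    ss_inter = n * sum(
        (cell_means[(g, d)] - g_means[g] - d_means[d] + grand) ** 2
        for g in ("sham", "TBI") for d in (1, 3)
    )
    ss_resid = sum(
        (v - cell_means[k]) ** 2 for k, vals in cells.items() for v in vals
    )
    assert aov.loc["group", "sum_sq"] == pytest.approx(ss_group, abs=1e-10)
    assert aov.loc["day", "sum_sq"] == pytest.approx(ss_day, abs=1e-10)
    assert aov.loc["group:day", "sum_sq"] == pytest.approx(ss_inter, abs=1e-10)
    assert aov.loc["residual", "sum_sq"] == pytest.approx(ss_resid, abs=1e-10)
    f_group = (ss_group / 1) / (ss_resid / 4)
    assert aov.loc["group", "F"] == pytest.approx(f_group, abs=1e-10)


def test_anova_detects_additive_shift():
    rng = np.random.default_rng(8)
    cells = {}
    for day in (1, 3):
        cells[("sham", day)] = list(rng.normal(0.0, 1.0, 10))
        cells[("TBI", day)] = list(rng.normal(3.0, 1.0, 10))  # 3 within-cell SDs
    aov = two_way_anova(_tidy(cells), "m")
    assert aov.loc["group", "p"] < 1e-3


def test_anova_reports_empty_cells():
    table = _tidy({("sham", 1): [1.0, 2.0], ("TBI", 1): [1.0, 2.0],
                   ("sham", 3): [2.0, 3.0], ("TBI", 3): [2.5]})
    with pytest.raises(ValueError, match="TBI"):
        two_way_anova(table, "m")
    with pytest.raises(ValueError, match="no records"):
        two_way_anova(table, "absent")


def test_welch_and_summary():
    t, p = welch_ttest([1, 2, 3, 4], [1, 2, 3, 4])
    assert p == pytest.approx(1.0)
    table = _tidy({("sham", 1): [1.0, 2.0], ("TBI", 1): [3.0, 4.0]})
    summary = summarize_cohort(table)
    sham_row = summary[(summary.group == "sham")].iloc[0]
    assert sham_row["mean"] == pytest.approx(1.5)
    assert sham_row["count"] == 2
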