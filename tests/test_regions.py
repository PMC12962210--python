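"""Region statistics: masks, erosion, percentiles, bootstrap test, trends."""

import numpy as np
import pytest

from rsnr import (
    RegionMaskSet,
    bootstrap_percentile_test,
    breast_volume_ml,
    erode_mask,
    extract_region_values,
    percentile_summary,
    ratio_vs_volume_trend,
    validate_region_masks,
)
from rsnr.regions import AXILLA, BREAST, CHEST_WALL
from rsnr.relative import RSNRVolume


def _masks(labels, vox=1.0):
    return RegionMaskSet(np.asarray(labels, dtype=np.int16), voxel_size_mm=vox)


@pytest.fixture
def simple_masks():
    labels = np.zeros((8, 8, 4), dtype=np.int16)
    labels[1:4, 1:4, :] = BREAST
    labels[5:7, 1:4, :] = CHEST_WALL
    labels[5:7, 5:7, :] = AXILLA
    return _masks(labels)


def test_validate_passes_and_counts(simple_masks):
    out = validate_region_masks(simple_masks)
    assert out is simple_masks
    assert out.region_counts() == {"breast": 36, "chest_wall": 24, "axilla": 16}


def test_validate_rejects_unknown_label(simple_masks):
    labels = simple_masks.labels.copy()
    labels[0, 0, 0] = 5
    with pytest.raises(ValueError, match=r"unknown label.*\(0, 0, 0\)"):
        validate_region_masks(_masks(labels))


def test_validate_rejects_empty_region(simple_masks):
    labels = simple_masks.labels.copy()
    labels[labels == AXILLA] = 0
    with pytest.raises(ValueError, match="axilla"):
        validate_region_masks(_masks(labels))


def test_erosion_radius_zero_is_identity(simple_masks):
    assert erode_mask(simple_masks, 0) is simple_masks


def test_erosion_shrinks_disk_by_its_radius():
    """A 10-px disk eroded by a 2-px disk is close to an 8-px disk.

    The exact reference is a brute-force morphological erosion (a pixel
    survives iff its whole 2-px-disk neighbourhood lies inside the region);
    the surviving area is also checked against the continuous-disk area
    pi (10 - 2)^2 to within rasterisation tolerance.
    """
    n = 32
    y, x = np.ogrid[-n // 2 : n // 2, -n // 2 : n // 2]
    labels = np.zeros((n, n, 3), dtype=np.int16)
    disk10 = (x * x + y * y) <= 10 * 10
    labels[disk10, :] = BREAST
    eroded = erode_mask(_masks(labels), 2)
    got_mask = eroded.labels[:, :, 1] == BREAST

    offsets = [
        (dy, dx)
        for dy in range(-2, 3)
        for dx in range(-2, 3)
        if dy * dy + dx * dx <= 4
    ]
    brute = np.zeros((n, n), dtype=bool)
    for i in range(2, n - 2):
        for j in range(2, n - 2):
            brute[i, j] = all(disk10[i + dy, j + dx] for dy, dx in offsets)
    assert np.array_equal(got_mask, brute)
    analytic_area = np.pi * 8.0**2
    assert abs(got_mask.sum() - analytic_area) / analytic_area < 0.05


def test_erosion_acts_within_each_slice(simple_masks):
    """Slicewise erosion never couples neighbouring S/I slices."""
    eroded = erode_mask(simple_masks, 1)
    for k in range(simple_masks.shape[2]):
        single = simple_masks.labels.copy()
        single[:, :, np.arange(simple_masks.shape[2]) != k] = 0
        ref = erode_mask(_masks(single), 1)
        assert np.array_equal(eroded.labels[:, :, k], ref.labels[:, :, k])


def test_extract_region_values_respects_validity(simple_masks):
    rsnr = np.full(simple_masks.shape, 2.0)
    valid = np.ones(simple_masks.shape, dtype=bool)
    valid[1, 1, :] = False  # knock out 4 breast voxels
    vol = RSNRVolume(rsnr, valid)
    vals = extract_region_values(vol, simple_masks, BREAST)
    assert vals.size == 36 - 4
    assert np.all(vals == 2.0)


def test_extract_empty_intersection_raises(simple_masks):
    vol = RSNRVolume(np.ones(simple_masks.shape), np.zeros(simple_masks.shape, bool))
    with pytest.raises(ValueError, match="no valid"):
        extract_region_values(vol, simple_masks, BREAST)


def test_percentile_summary_interpolates():
    s = percentile_summary(np.arange(1.0, 101.0))
    assert s[50] == 50.5
    assert s[25] == pytest.approx(25.75)
    const = percentile_summary(np.full(10, 3.0))
    assert all(v == 3.0 for v in const.values())


def test_percentile_summary_matches_sort_oracle():
    """Linear-interpolation percentiles == an explicit sort-based oracle."""
    rng = np.random.default_rng(4)
    for _ in range(100):
        x = rng.standard_normal(rng.integers(5, 400))
        s = percentile_summary(x)
        xs = np.sort(x)
        for p, got in s.items():
            h = (xs.size - 1) * p / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, xs.size - 1)
            expect = xs[lo] + (h - lo) * (xs[hi] - xs[lo])
            assert got == pytest.approx(expect, abs=1e-12)


def test_bootstrap_null_on_identical_samples():
    rng = np.random.default_rng(0)
    a = rng.standard_normal(300)
    res = bootstrap_percentile_test(a, a, 50, n_boot=500, seed=1)
    assert res.p_value > 0.5
    assert not res.significant
    assert res.direction == "none"


def test_bootstrap_detects_a_half_iqr_shift():
    """Power check: median shift of 0.5 IQR, n = 500 per group."""
    rng = np.random.default_rng(7)
    rejections = 0
    trials = 30
    for t in range(trials):
        a = rng.standard_normal(500)
        b = rng.standard_normal(500) + 0.5 * 1.349  # IQR of a standard normal
        res = bootstrap_percentile_test(a, b, 50, n_boot=500, alpha=0.01, seed=rng)
        rejections += res.significant
        if res.significant:
            assert res.direction == "b_greater"
    assert rejections / trials > 0.9


def test_bootstrap_input_validation():
    with pytest.raises(ValueError, match="at least 50"):
        bootstrap_percentile_test(np.ones(10), np.ones(100), 50)
    with pytest.raises(ValueError, match="percentile"):
        bootstrap_percentile_test(np.ones(100), np.ones(100), 42)


def test_breast_volume_unit_conversion():
    labels = np.zeros((10, 10, 10), dtype=np.int16)
    labels.reshape(-1)[:1000] = BREAST
    assert breast_volume_ml(_masks(labels, vox=1.0)) == pytest.approx(1.0)


def test_ellipsoid_volume_matches_analytic():
    semi = np.array([15.0, 11.0, 9.0])
    n = 40
    coords = np.stack(np.meshgrid(*[np.arange(n) - n / 2 + 0.5] * 3, indexing="ij"), -1)
    inside = (((coords / semi) ** 2).sum(-1)) <= 1.0
    labels = np.where(inside, BREAST, 0).astype(np.int16)
    vol = breast_volume_ml(_masks(labels, vox=1.0))
    expect = 4.0 / 3.0 * np.pi * semi.prod() / 1000.0
    assert abs(vol - expect) / expect < 0.02


def test_trend_two_point_line():
    fit = ratio_vs_volume_trend([(1000.0, 2.0), (2000.0, 1.0)], BREAST)
    assert fit.slope == pytest.approx(-0.001)
    assert fit.intercept == pytest.approx(3.0)
    assert fit.n_above_unity == 1


def test_trend_recovers_noisy_slope():
    rng = np.random.default_rng(12)
    x = np.linspace(800, 3000, 10)
    y = 2.0 - 0.0005 * x + rng.normal(0, 0.05, x.size)
    fit = ratio_vs_volume_trend(list(zip(x, y)), BREAST)
    # standard error of the OLS slope
    resid = y - (fit.intercept + fit.slope * x)
    se = np.sqrt((resid**2).sum() / (x.size - 2) / ((x - x.mean()) ** 2).sum())
    assert abs(fit.slope - (-0.0005)) < 3.0 * se


def test_trend_identical_x_rejected():
    with pytest.raises(ValueError, match="identical x"):
        ratio_vs_volume_trend([(1000.0, 1.0), (1000.0, 2.0)], BREAST)


def test_region_medians_stable_under_erosion():
    """Erosion by 1-2 px changes region medians of a smooth rSNR map < 10%.

    Run at 2 mm voxels so the 1-2 px erosion disks correspond to the
    1.4-2.8 mm in-plane pixels segmentations are typically drawn on; the
    rSNR spatial structure is surrogated by the array's root-sum-of-squares
    sensitivity (which carries the coil-proximity gradient that could move
    a region median).
    """
    from rsnr import make_digital_subject
    from rsnr.coils import evaluate_sensitivities, make_coil_array

    subj = make_digital_subject(
        "supine", 1000.0, grid_shape=(144, 120, 96), voxel_size_mm=2.0, seed=3
    )
    coil = make_coil_array("surface_conformal", subj, 30, 70.0)
    rss = np.sqrt((np.abs(evaluate_sensitivities(coil, subj.signal)) ** 2).sum(0))
    vol = RSNRVolume(rss, subj.body_mask, voxel_size_mm=2.0)
    for lab in (BREAST, CHEST_WALL, AXILLA):
        base = np.median(extract_region_values(vol, subj.labels, lab))
        for r in (1, 2):
            eroded = erode_mask(subj.labels, r)
            med = np.median(extract_region_values(vol, eroded, lab))
            assert abs(med - base) / base < 0.10
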