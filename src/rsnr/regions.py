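"""Region-wise rSNR statistics.

Holds the integer label volume (breast incl. skin / chest wall / axilla),
slicewise morphological erosion for segmentation-robustness checks, the
five-number percentile summary used throughout the figures, the two-tailed
bootstrapped percentile-difference test, breast-volume estimation, and the
median-ratio-versus-volume trend fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import _as_vec3

logger = logging.getLogger(__name__)

BACKGROUND = 0
BREAST = 1
CHEST_WALL = 2
AXILLA = 3
REGION_NAMES = {BREAST: "breast", CHEST_WALL: "chest_wall", AXILLA: "axilla"}
REGION_LABELS = tuple(REGION_NAMES)

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class RegionMaskSet:
    """Integer label volume aligned to an SNR/rSNR grid.

    Labels: 0 background, 1 breast (including skin), 2 chest wall, 3 axilla.
    Regions are mutually exclusive by construction of the integer encoding.
    """

    labels: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int16)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "voxel_size_mm", _as_vec3(self.voxel_size_mm))

    @property
    def shape(self):
        return self.labels.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def region_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == lab))
            for lab, name in REGION_NAMES.items()
        }


def validate_region_masks(masks: RegionMaskSet) -> RegionMaskSet:
    """Assert the label domain and that every region is non-empty.

    Returns the input unchanged on success; logs per-region voxel counts.
    """
    present = np.unique(masks.labels)
    allowed = {BACKGROUND, *REGION_LABELS}
    bad = [int(v) for v in present if int(v) not in allowed]
    if bad:
        idx = np.argwhere(np.isin(masks.labels, bad))[0]
        raise ValueError(
            f"unknown label(s) {bad}; first offending voxel at {tuple(int(i) for i in idx)}"
        )
    counts = masks.region_counts()
    for lab, name in REGION_NAMES.items():
        if counts[name] == 0:
            raise ValueError(f"region '{name}' (label {lab}) is empty")
    logger.info("region voxel counts: %s", counts)
    return masks


def _disk_structure(radius_px: int) -> np.ndarray:
    """Flat disk structuring element of the given pixel radius (2D)."""
    r = int(radius_px)
    y, x = np.ogrid[-r : r + 1, -r : r + 1]
    return (x * x + y * y) <= r * r


def erode_mask(masks: RegionMaskSet, radius_px: int) -> RegionMaskSet:
    """Erode each region independently, slicewise, by a disk.

    Erosion acts in the (A/P, R/L) plane of every S/I slice — the plane the
    segmentations are drawn in — with a disk structuring element.  Radius 0
    is the identity.  A region that erodes away entirely is left empty with
    a warning rather than an error so downstream code can decide.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return masks
    disk2d = _disk_structure(radius_px)
    structure = disk2d[:, :, None]  # no coupling along S/I => slicewise
    out = np.zeros_like(masks.labels)
    for lab in REGION_LABELS:
        region = masks.labels == lab
        if not region.any():
            continue
        eroded = ndimage.binary_erosion(region, structure=structure)
        if not eroded.any():
            logger.warning(
                "erosion radius %d emptied region '%s'", radius_px, REGION_NAMES[lab]
            )
        out[eroded] = lab
    return RegionMaskSet(out, voxel_size_mm=masks.voxel_size_mm)


def extract_region_values(rsnr, masks: RegionMaskSet, region_label: int) -> np.ndarray:
    """All valid rSNR values inside one region, in lexicographic voxel order.

    ``rsnr`` is an :class:`~rsnr.relative.RSNRVolume` (anything exposing
    ``rsnr`` and ``valid_mask`` arrays works).  Voxels outside the rSNR
    validity mask are dropped; the retained count is logged.
    """
    if rsnr.rsnr.shape != masks.shape:
        raise ValueError("rSNR grid and mask grid differ")
    region = masks.region_mask(region_label)
    keep = region & rsnr.valid_mask
    n_total, n_keep = int(region.sum()), int(keep.sum())
    if n_keep == 0:
        raise ValueError(
            f"region '{REGION_NAMES.get(region_label, region_label)}' has no valid rSNR voxels"
        )
    if n_keep < n_total:
        logger.info(
            "region %s: %d of %d voxels inside the validity mask",
            REGION_NAMES.get(region_label, region_label), n_keep, n_total,
        )
    return rsnr.rsnr[keep]  # boolean indexing is C-order == lexicographic


def percentile_summary(sample) -> dict[int, float]:
    """{5, 25, 50, 75, 95}th percentiles by linear interpolation of ranks."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("sample is empty")
    vals = np.percentile(x, PERCENTILES, method="linear")
    return {p: float(v) for p, v in zip(PERCENTILES, vals)}


@dataclass(frozen=True)
class PercentileTestResult:
    """Outcome of the two-tailed bootstrapped percentile-difference test."""

    percentile: int
    diff: float  # observed q_p(a) - q_p(b)
    p_value: float
    n_boot: int
    alpha: float
    significant: bool
    direction: str  # 'a_greater' | 'b_greater' | 'none'


def bootstrap_percentile_test(
    sample_a,
    sample_b,
    percentile: int,
    n_boot: int = 10_000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
    batch: int = 2_000,
) -> PercentileTestResult:
    """Two-tailed bootstrap test for a difference between percentiles.

    Both groups are independently resampled with replacement ``n_boot``
    times; the bootstrap distribution of ``d* = q_p(a*) - q_p(b*)`` is
    compared against zero and the two-tailed p-value is

        p = 2 * min( (#{d* <= 0} + 1), (#{d* >= 0} + 1) ) / (n_boot + 1)

    capped at 1.  Significance is declared at ``p < alpha`` and the
    direction is taken from the sign of the observed difference.
    """
    if percentile not in PERCENTILES:
        raise ValueError(f"percentile must be one of {PERCENTILES}")
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 50 or b.size < 50:
        raise ValueError("each sample must contain at least 50 values")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = percentile
    observed = float(np.percentile(a, q) - np.percentile(b, q))

    n_le = 0
    n_ge = 0
    done = 0
    while done < n_boot:
        m = min(batch, n_boot - done)
        qa = np.percentile(a[rng.integers(0, a.size, size=(m, a.size))], q, axis=1)
        qb = np.percentile(b[rng.integers(0, b.size, size=(m, b.size))], q, axis=1)
        d = qa - qb
        n_le += int(np.count_nonzero(d <= 0))
        n_ge += int(np.count_nonzero(d >= 0))
        done += m
    p = 2.0 * min(n_le + 1, n_ge + 1) / (n_boot + 1)
    p = min(p, 1.0)
    significant = p < alpha
    if not significant or observed == 0.0:
        direction = "none"
    else:
        direction = "a_greater" if observed > 0 else "b_greater"
    return PercentileTestResult(
        percentile=q,
        diff=observed,
        p_value=float(p),
        n_boot=int(n_boot),
        alpha=float(alpha),
        significant=bool(significant),
        direction=direction,
    )


def breast_volume_ml(masks: RegionMaskSet) -> float:
    """Segmented breast-tissue volume in millilitres (count x voxel volume)."""
    n = int(np.count_nonzero(masks.labels == BREAST))
    if n == 0:
        raise ValueError("breast region is empty")
    return n * float(np.prod(masks.voxel_size_mm)) / 1000.0


@dataclass(frozen=True)
class TrendFit:
    """Ordinary least-squares line through (breast volume, median-rSNR ratio)."""

    slope: float  # ratio per mL
    intercept: float
    region_label: int
    n_points: int
    n_above_unity: int  # points with ratio > 1 (above the y = 1 reference)


def ratio_vs_volume_trend(points, region_label: int) -> TrendFit:
    """Fit ratio = slope * volume + intercept by OLS over subject points.

    ``points`` is a sequence of (breast_volume_ml, median_rsnr_ratio) pairs;
    at least two points with distinct volumes are required.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (volume, ratio) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("identical x values: slope is undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        region_label=int(region_label),
        n_points=int(pts.shape[0]),
        n_above_unity=int(np.count_nonzero(y > 1.0)),
    )
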