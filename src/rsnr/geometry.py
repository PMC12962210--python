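"""Distance-from-coil analysis.

Coil element positions are represented as point sets in scanner mm
coordinates (bars are sampled as point lattices at voxel pitch, so the
distance to a continuous bar is approximated to within half a voxel).
Per-voxel distance to the nearest element point feeds median-rSNR-versus-
distance profiles binned in 2 mm chunks, per region and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import voxel_centers_mm
from .regions import BREAST, REGION_NAMES, PERCENTILES, RegionMaskSet
from .subjects import DigitalSubject
from .coils import farthest_point_sample

DEFAULT_BIN_MM = 2.0


@dataclass(frozen=True)
class CoilGeometry:
    """Element reference points; possibly many points per physical element."""

    element_points_mm: np.ndarray  # (n, 3)
    model_tag: str  # 'prone_bars' | 'supine_surface'

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.element_points_mm, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 3:
            raise ValueError("element_points_mm must be (n, 3) with n >= 1")
        if not np.all(np.isfinite(pts)):
            raise ValueError("element points must be finite")
        object.__setattr__(self, "element_points_mm", pts)


def prone_coil_geometry(masks: RegionMaskSet, origin_mm=(0.0, 0.0, 0.0)) -> CoilGeometry:
    """Prone paddles as bars flanking each breast laterally.

    For every connected breast component, two rectangular point lattices
    (pitch = voxel size) are placed one voxel lateral of the component's
    R/L bounding-box faces, spanning its A/P and S/I extent.
    """
    breast = masks.region_mask(BREAST)
    if not breast.any():
        raise ValueError("breast region is empty")
    vox = masks.voxel_size_mm
    origin = np.asarray(origin_mm, dtype=float)
    comp, n_comp = ndimage.label(breast)
    points = []
    for c in range(1, n_comp + 1):
        ii, jj, kk = np.nonzero(comp == c)
        ap = origin[0] + np.arange(ii.min(), ii.max() + 1) * vox[0]
        si = origin[2] + np.arange(kk.min(), kk.max() + 1) * vox[2]
        for j_bar in (jj.min() - 1, jj.max() + 1):
            rl = origin[1] + j_bar * vox[1]
            grid_ap, grid_si = np.meshgrid(ap, si, indexing="ij")
            bar = np.column_stack(
                [grid_ap.ravel(), np.full(grid_ap.size, rl), grid_si.ravel()]
            )
            points.append(bar)
    return CoilGeometry(element_points_mm=np.vstack(points), model_tag="prone_bars")


def supine_coil_geometry(
    subject: DigitalSubject, element_count: int = 60, element_diameter_mm: float = 70.0
) -> CoilGeometry:
    """Supine flexible-array elements lying insulated against the skin.

    Element centres are spread approximately uniformly over the skin
    surface (greedy farthest-point placement, insulation offset 0 mm).
    """
    surf = subject.skin_points_mm()
    if surf.shape[0] == 0:
        raise ValueError("subject has no skin surface")
    if element_count > surf.shape[0]:
        raise ValueError(
            f"element_count {element_count} exceeds {surf.shape[0]} surface voxels"
        )
    idx = farthest_point_sample(surf, element_count)
    return CoilGeometry(element_points_mm=surf[idx], model_tag="supine_surface")


def distance_to_coil_map(grid, geometry: CoilGeometry) -> np.ndarray:
    """Euclidean mm distance from every voxel centre to the nearest element point.

    ``grid`` is anything with ``shape``, ``voxel_size_mm`` and ``origin_mm``
    (a SignalVolume, SNRVolume or RSNRVolume).  Uses a k-d tree; results
    equal the brute-force nearest-point distance to floating-point
    precision.
    """
    shape = tuple(int(n) for n in (grid.shape if not hasattr(grid, "rsnr") else grid.rsnr.shape))
    centers = voxel_centers_mm(shape, grid.voxel_size_mm, grid.origin_mm)
    tree = cKDTree(geometry.element_points_mm)
    d, _ = tree.query(centers.reshape(-1, 3))
    return d.reshape(shape)


@dataclass(frozen=True)
class DistanceProfile:
    """Median rSNR per 2 mm distance bin, with voxel counts per bin."""

    bin_edges_mm: np.ndarray  # (n_bins + 1,), regular pitch, left edge label
    median_rsnr: np.ndarray  # (n_bins,), NaN for empty bins
    voxel_count: np.ndarray  # (n_bins,)
    region: str  # region name or 'pooled'
    distance_percentiles_mm: dict = field(default_factory=dict)


def _profile_for(values, dists, bin_mm, region_name) -> DistanceProfile:
    n_bins = int(np.floor(dists.max() / bin_mm)) + 1 if dists.size else 1
    edges = np.arange(n_bins + 1) * bin_mm
    idx = np.minimum((dists / bin_mm).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    medians = np.full(n_bins, np.nan)
    order = np.argsort(idx, kind="stable")
    sorted_vals = values[order]
    boundaries = np.cumsum(counts)
    start = 0
    for b in range(n_bins):
        stop = boundaries[b]
        if stop > start:
            medians[b] = np.median(sorted_vals[start:stop])
        start = stop
    pct = {}
    if dists.size:
        pct = {p: float(v) for p, v in zip(PERCENTILES, np.percentile(dists, PERCENTILES))}
    return DistanceProfile(
        bin_edges_mm=edges,
        median_rsnr=medians,
        voxel_count=counts,
        region=region_name,
        distance_percentiles_mm=pct,
    )


def rsnr_vs_distance(
    rsnr, distmap: np.ndarray, masks: RegionMaskSet, bin_mm: float = DEFAULT_BIN_MM
) -> dict[str, DistanceProfile]:
    """Median rSNR versus distance-to-coil, per region and pooled.

    Voxels are bucketed into half-open bins [k*bin, (k+1)*bin) mm labelled
    by their left edge.  Each region's distance distribution is also
    summarised by its 5/25/50/75/95th percentiles.  Returns a dict keyed by
    region name plus ``'pooled'`` (all labelled regions together).
    """
    if bin_mm <= 0:
        raise ValueError("bin_mm must be positive")
    if rsnr.rsnr.shape != distmap.shape or distmap.shape != masks.shape:
        raise ValueError("rSNR, distance map and mask grids differ")
    out: dict[str, DistanceProfile] = {}
    pooled = np.zeros(masks.shape, dtype=bool)
    for lab, name in REGION_NAMES.items():
        sel = masks.region_mask(lab) & rsnr.valid_mask
        pooled |= sel
        out[name] = _profile_for(rsnr.rsnr[sel], distmap[sel], bin_mm, name)
    out["pooled"] = _profile_for(rsnr.rsnr[pooled], distmap[pooled], bin_mm, "pooled")
    return out
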