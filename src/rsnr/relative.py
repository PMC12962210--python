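"""Relative SNR (rSNR) maps and the tissue-independence machinery.

rSNR is the voxelwise ratio of an external array coil's SNR map to the
body-coil reference SNR map of the same object in the same position,

    rSNR = SNR_ext / SNR_ref .

Because both maps share the object's signal, tissue contrast cancels in
the ratio: rSNR depends only on coil sensitivity, noise, and geometry.
The percent-difference map between two rSNR maps from different contrasts,
and the FWHM of its histogram, quantify how well the cancellation holds at
finite noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import _as_vec3
from .recon import SNRVolume

#: reference-SNR floor: body-coil SNR in air is near zero and would blow up
#: the ratio, so voxels with SNR_ref below this are marked invalid
DEFAULT_MIN_REF_SNR = 2.0
#: histogram bin width (percent-difference units) for FWHM estimation
DEFAULT_FWHM_BIN = 0.5


@dataclass(frozen=True)
class RSNRVolume:
    """Voxelwise SNR_ext / SNR_ref with a validity mask."""

    rsnr: np.ndarray
    valid_mask: np.ndarray
    accel: tuple = (1, 1)
    meta: dict = field(default_factory=dict)
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "voxel_size_mm", _as_vec3(self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", _as_vec3(self.origin_mm))

    def values(self) -> np.ndarray:
        """Valid rSNR values as a flat sample (lexicographic voxel order)."""
        return self.rsnr[self.valid_mask]


@dataclass(frozen=True)
class DiffMap:
    """Symmetric percent-difference map between two rSNR maps."""

    percent_diff: np.ndarray
    valid_mask: np.ndarray

    def values(self) -> np.ndarray:
        return self.percent_diff[self.valid_mask]


def compute_rsnr(
    snr_ext: SNRVolume,
    snr_ref: SNRVolume,
    min_ref_snr: float = DEFAULT_MIN_REF_SNR,
) -> RSNRVolume:
    """Voxelwise rSNR = SNR_ext / SNR_ref with a reference-SNR floor.

    Valid where both supports hold and SNR_ref >= ``min_ref_snr``; the map
    is 0 (and flagged invalid) elsewhere.  Grids must match exactly — the
    array and body acquisitions of a pair share FOV and matrix so the ratio
    needs no resampling.
    """
    if snr_ext.snr.shape != snr_ref.snr.shape:
        raise ValueError("SNR map grids differ")
    if not np.allclose(snr_ext.voxel_size_mm, snr_ref.voxel_size_mm):
        raise ValueError("SNR map voxel sizes differ")
    valid = snr_ext.support_mask & snr_ref.support_mask & (snr_ref.snr >= min_ref_snr)
    out = np.zeros_like(snr_ext.snr)
    out[valid] = snr_ext.snr[valid] / snr_ref.snr[valid]
    return RSNRVolume(
        rsnr=out,
        valid_mask=valid,
        accel=snr_ext.accel,
        meta={"ext": snr_ext.provenance, "ref": snr_ref.provenance},
        voxel_size_mm=snr_ext.voxel_size_mm,
        origin_mm=snr_ext.origin_mm,
    )


def percent_difference_map(rsnr_a: RSNRVolume, rsnr_b: RSNRVolume) -> DiffMap:
    """Symmetric percent difference 100 (a - b) / ((a + b)/2).

    The symmetric denominator makes the map antisymmetric under swapping
    the inputs and keeps a near-zero-centred histogram well defined.
    Defined on the intersection of the two validity masks.
    """
    if rsnr_a.rsnr.shape != rsnr_b.rsnr.shape:
        raise ValueError("rSNR grids differ")
    valid = rsnr_a.valid_mask & rsnr_b.valid_mask
    if not valid.any():
        raise ValueError("validity masks do not intersect")
    a = rsnr_a.rsnr
    b = rsnr_b.rsnr
    out = np.zeros_like(a)
    mean = 0.5 * (a[valid] + b[valid])
    out[valid] = 100.0 * (a[valid] - b[valid]) / mean
    return DiffMap(percent_diff=out, valid_mask=valid)


def histogram_fwhm(values, bin_width: float = DEFAULT_FWHM_BIN) -> float:
    """Full width at half maximum of a sample's histogram.

    The histogram uses fixed-width bins with a bin centred at 0.  The peak
    bin is located and the two half-maximum crossings are found by linear
    interpolation between adjacent bin centres; their separation is the
    FWHM, in the sample's units.

    Raises
    ------
    ValueError
        For fewer than 100 finite values, a degenerate (all-equal) sample,
        or a peak at the histogram edge (no crossing on one side).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"need at least 100 finite values, got {x.size}")
    if np.ptp(x) < 1e-9 * bin_width:
        raise ValueError("degenerate sample: spread far below bin resolution")
    # bin edges at (k - 1/2) * w so bin centres sit on multiples of w
    lo = np.floor(x.min() / bin_width - 0.5)
    hi = np.ceil(x.max() / bin_width + 0.5)
    edges = (np.arange(lo, hi + 1) + 0.5) * bin_width
    counts, _ = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0

    def crossing(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if counts[i] <= half:
                # linear interpolation between bin centres i and prev
                c0, c1 = counts[i], counts[prev]
                if c1 == c0:
                    return centers[i]
                frac = (half - c0) / (c1 - c0)
                return centers[i] + frac * (centers[prev] - centers[i])
            prev = i
        raise ValueError("no half-maximum crossing: peak at histogram edge")

    left = crossing(range(peak - 1, -1, -1))
    right = crossing(range(peak + 1, len(counts)))
    return float(right - left)
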