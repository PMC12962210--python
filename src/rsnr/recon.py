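"""SENSE reconstruction with analytic noise propagation.

Pipeline: estimate the channel noise covariance from the prescan block,
estimate coil sensitivity maps from a windowed central k-space calibration
region, optionally subsample the phase-encode lattice retrospectively, and
unfold with the generalised-least-squares SENSE estimator

    v = (S^H psi^-1 S)^-1 S^H psi^-1 a

where S stacks the sensitivities of the voxels aliased onto one location.
The per-voxel noise standard deviation follows from the diagonal of
(S^H psi^-1 S)^-1 and the geometry factor is

    g = sqrt( [(S^H psi^-1 S)^-1]_rr * [S^H psi^-1 S]_rr )  >= 1.

A unitary DFT convention is used throughout so k-space and image noise
variance coincide; with the retained-line fraction 1/R this makes the
aliased data vector ``a = R x (zero-filled inverse DFT)`` carry noise
covariance ``R psi``, and the unfolded noise variance is
``R * diag((S^H psi^-1 S)^-1)``.  All SNR statements are internal
consistency statements under this fixed convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

from .acquisition import KSpaceDataset, NoiseCovariance, ifftc
from .grids import _as_vec3

DEFAULT_CALIB_REGION = (24, 24, 12)
#: support mask keeps voxels whose RSS exceeds this fraction of its robust max
SUPPORT_THRESHOLD_FRACTION = 0.05
#: relative pseudo-inverse tolerance for the unfolding matrix
PINV_RTOL = 1e-8


def estimate_noise_covariance(noise_block) -> NoiseCovariance:
    """Sample covariance psi = (1/n) sum x x^H of a zero-mean noise block."""
    x = np.atleast_2d(np.asarray(noise_block, dtype=complex))
    c, n = x.shape
    if not np.all(np.isfinite(x.view(float))):
        raise ValueError("noise block contains non-finite samples")
    if n < 2 * c:
        raise ValueError(f"need at least 2 x channels = {2*c} samples, got {n}")
    psi = (x @ x.conj().T) / n
    psi = 0.5 * (psi + psi.conj().T)
    return NoiseCovariance(psi=psi, n_samples_used=n)


@dataclass(frozen=True)
class SensitivityMaps:
    """Normalised complex coil sensitivities with a validity support mask."""

    maps: np.ndarray  # (channels,) + grid, zero off support
    support_mask: np.ndarray
    calib_region: tuple = DEFAULT_CALIB_REGION
    window_name: str = "tukey"

    @property
    def channel_count(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self):
        return self.maps.shape[1:]


def _separable_window(calib_region, window_name: str) -> np.ndarray:
    def w1(n):
        if window_name == "tukey":
            return windows.tukey(n, alpha=0.5)
        if window_name == "hann":
            return windows.hann(n)
        if window_name == "rect":
            return np.ones(n)
        raise ValueError(f"unknown window '{window_name}'")

    wa, wb, wc = (w1(int(n)) for n in calib_region)
    return wa[:, None, None] * wb[None, :, None] * wc[None, None, :]


def _center_slices(full, part):
    out = []
    for n, c in zip(full, part):
        start = n // 2 - c // 2
        out.append(slice(start, start + c))
    return tuple(out)


def normalize_sensitivities(coil_images: np.ndarray, support_mask: np.ndarray | None = None):
    """RSS-normalise coil images with phase referenced to a virtual channel.

    The virtual channel is the principal component of the channel-by-channel
    correlation over the support; its phase is divided out so the combined
    (matched-filter) image of a smooth object is smooth.  Returns
    ``(maps, support_mask)`` with maps zeroed off support.
    """
    imgs = np.asarray(coil_images, dtype=complex)
    rss = np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
    if support_mask is None:
        robust_max = np.percentile(rss, 99)
        support_mask = rss > SUPPORT_THRESHOLD_FRACTION * robust_max
    flat = imgs[:, support_mask]
    corr = flat @ flat.conj().T
    w_eig, v = np.linalg.eigh(corr)
    principal = v[:, -1]
    k = int(np.argmax(np.abs(principal)))
    principal = principal * np.exp(-1j * np.angle(principal[k]))
    virtual = np.einsum("c...,c->...", imgs, principal.conj())
    phase = np.where(np.abs(virtual) > 0, virtual / np.maximum(np.abs(virtual), 1e-300), 1.0)
    denom = rss * phase
    maps = np.zeros_like(imgs)
    maps[:, support_mask] = imgs[:, support_mask] / denom[None][:, support_mask]
    return maps, support_mask


def estimate_sensitivity_maps(
    kspace: KSpaceDataset,
    calib_region=DEFAULT_CALIB_REGION,
    window_name: str = "tukey",
) -> SensitivityMaps:
    """Estimate sensitivity maps from the windowed central k-space region.

    The central ``calib_region`` of k-space is extracted (it must be fully
    sampled), apodised with a separable window to reduce ringing,
    zero-padded back to the full grid, and inverse-transformed to low-
    resolution coil images which are then RSS-normalised with the phase
    referenced to the principal-component virtual channel.
    """
    calib = tuple(int(c) for c in calib_region)
    grid = kspace.grid_shape
    if any(c > n for c, n in zip(calib, grid)):
        raise ValueError(f"calibration region {calib} exceeds grid {grid}")
    sl = _center_slices(grid, calib)
    mask_center = kspace.sampling_mask[sl[1], sl[2]]
    if not mask_center.all():
        raise ValueError("k-space is not fully sampled in the calibration region")
    center = kspace.data[(slice(None),) + sl]
    center = center * _separable_window(calib, window_name)[None]
    padded = np.zeros_like(kspace.data)
    padded[(slice(None),) + sl] = center
    lowres = ifftc(padded)
    maps, support = normalize_sensitivities(lowres)
    return SensitivityMaps(
        maps=maps, support_mask=support, calib_region=calib, window_name=window_name
    )


def sensitivity_maps_from_model(sens_array: np.ndarray, support_mask=None) -> SensitivityMaps:
    """Wrap model (ground-truth) sensitivities in the estimator's normalisation."""
    maps, support = normalize_sensitivities(np.asarray(sens_array, complex), support_mask)
    return SensitivityMaps(maps=maps, support_mask=support, calib_region=(0, 0, 0),
                           window_name="none")


def subsample_kspace(kspace: KSpaceDataset, accel) -> KSpaceDataset:
    """Retrospectively subsample the phase-encode lattice.

    ``accel = (R_si, R_rl)`` keeps every R-th phase-encode line starting at
    stored index 0 along S/I and R/L respectively; the frequency (A/P)
    direction is untouched.  Discarded lines are zeroed and the sampling
    mask updated.
    """
    r_si, r_rl = (int(r) for r in accel)
    if r_si < 1 or r_rl < 1:
        raise ValueError("acceleration factors must be >= 1")
    _, _, n_rl, n_si = kspace.data.shape
    if n_rl % r_rl or n_si % r_si:
        raise ValueError(
            f"phase-encode dims ({n_rl}, {n_si}) not divisible by accel (R/L={r_rl}, S/I={r_si})"
        )
    if (r_si, r_rl) == (1, 1):
        return kspace
    mask = np.zeros((n_rl, n_si), dtype=bool)
    mask[::r_rl, ::r_si] = True
    mask &= kspace.sampling_mask
    data = np.where(mask[None, None], kspace.data, 0.0)
    return KSpaceDataset(
        data=data,
        noise_block=kspace.noise_block,
        voxel_size_mm=kspace.voxel_size_mm,
        origin_mm=kspace.origin_mm,
        sampling_mask=mask,
        axis_tags=kspace.axis_tags,
        coil_name=kspace.coil_name,
        seed=kspace.seed,
    )


@dataclass(frozen=True)
class ReconResult:
    """Combined image with analytic noise map and SENSE geometry factor."""

    image: np.ndarray  # complex grid
    noise_std: np.ndarray  # same units as image, > 0 on the valid mask
    gfactor: np.ndarray  # >= 1 on the valid mask; == 1 at R = 1
    valid_mask: np.ndarray
    accel: tuple  # (R_si, R_rl)
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))


def _alias_phases(n: int, r: int) -> np.ndarray:
    """Phase factor per aliasing replica for a centred-array sampling lattice.

    With the lattice anchored at stored index 0 and the DFT centre at
    ``n // 2``, replica t of the fold carries exp(2 pi i t (n//2) / r).
    """
    t = np.arange(r)
    return np.exp(2j * np.pi * t * (n // 2) / r)


def sense_reconstruct(
    kspace: KSpaceDataset,
    sens: SensitivityMaps,
    ncov: NoiseCovariance,
    accel=(1, 1),
) -> ReconResult:
    """SENSE unfolding with analytic noise propagation.

    Solves the generalised least-squares unfolding per aliased voxel set and
    propagates the measured channel covariance into a per-voxel noise
    standard deviation and g-factor.  Aliased sets whose unfolding matrix is
    singular beyond the pseudo-inverse tolerance are flagged invalid rather
    than filled with fabricated values.  At R = 1 the estimator reduces to
    the matched-filter combination with g identically 1 on the support.
    """
    r_si, r_rl = (int(r) for r in accel)
    grid = kspace.grid_shape
    if sens.grid_shape != grid:
        raise ValueError("sensitivity grid differs from k-space grid")
    if ncov.channel_count != kspace.channel_count:
        raise ValueError("noise covariance dimension differs from channel count")
    n_ap, n_rl, n_si = grid
    if n_rl % r_rl or n_si % r_si:
        raise ValueError("grid not divisible by acceleration factors")
    expected = np.zeros((n_rl, n_si), dtype=bool)
    expected[::r_rl, ::r_si] = True
    if not np.array_equal(kspace.sampling_mask, expected):
        raise ValueError("sampling mask does not match the requested acceleration")

    r_tot = r_si * r_rl
    n1r, n2r = n_rl // r_rl, n_si // r_si
    n_alias = r_rl * r_si
    ch = kspace.channel_count

    zf = ifftc(np.where(kspace.sampling_mask[None, None], kspace.data, 0.0))
    a = r_tot * zf[:, :, :n1r, :n2r]  # (ch, n_ap, n1r, n2r)

    # group sensitivities by aliased set: axis split N -> (R, N/R) puts
    # replica index first, matching m = t * (N/R) + j
    s_group = sens.maps.reshape(ch, n_ap, r_rl, n1r, r_si, n2r)
    sup_group = sens.support_mask.reshape(n_ap, r_rl, n1r, r_si, n2r)
    phases = _alias_phases(n_rl, r_rl)[:, None] * _alias_phases(n_si, r_si)[None, :]
    # S: (n_ap, n1r, n2r, ch, A) with A = r_rl * r_si
    s_mat = np.transpose(s_group, (1, 3, 5, 0, 2, 4)).reshape(
        n_ap, n1r, n2r, ch, n_alias
    ) * phases.reshape(n_alias)

    wmat = ncov.whitener()
    sw = np.einsum("dc,...ca->...da", wmat, s_mat, optimize=True)
    aw = np.einsum("dc,c...->...d", wmat, a, optimize=True)  # (n_ap, n1r, n2r, ch)

    m_mat = np.einsum("...ca,...cb->...ab", sw.conj(), sw, optimize=True)
    rhs = np.einsum("...ca,...c->...a", sw.conj(), aw, optimize=True)

    if n_alias == 1:
        m_diag = m_mat[..., 0, 0].real
        tol = PINV_RTOL * m_diag.max() if m_diag.size else 0.0
        inv_diag = np.where(m_diag > tol, 1.0 / np.maximum(m_diag, 1e-300), 0.0)
        v = rhs[..., 0] * inv_diag
        var = r_tot * inv_diag
        g = np.where(m_diag > tol, 1.0, 0.0)
        v = v[..., None]
        var = var[..., None]
        g = g[..., None]
    else:
        m_inv = np.linalg.pinv(m_mat, rcond=PINV_RTOL, hermitian=True)
        v = np.einsum("...ab,...b->...a", m_inv, rhs, optimize=True)
        inv_diag = np.einsum("...aa->...a", m_inv).real
        var = r_tot * inv_diag
        g_sq = inv_diag * np.einsum("...aa->...a", m_mat).real
        g = np.sqrt(np.clip(g_sq, 0.0, None))

    # scatter aliased sets back onto the full grid
    def scatter(stack, dtype):
        out = np.empty(grid, dtype=dtype)
        arr = stack.reshape(n_ap, n1r, n2r, r_rl, r_si)
        out.reshape(n_ap, r_rl, n1r, r_si, n2r)[:] = np.transpose(
            arr, (0, 3, 1, 4, 2)
        )
        return out

    image = scatter(v, complex)
    noise_std = np.sqrt(np.clip(scatter(var, float), 0.0, None))
    gfactor = scatter(g, float)
    valid = sens.support_mask & (noise_std > 0) & np.isfinite(noise_std)
    valid &= gfactor >= 1.0 - 1e-6
    image = np.where(valid, image, 0.0)
    gfactor = np.where(valid, gfactor, 0.0)
    return ReconResult(
        image=image,
        noise_std=noise_std,
        gfactor=gfactor,
        valid_mask=valid,
        accel=(r_si, r_rl),
        voxel_size_mm=kspace.voxel_size_mm,
        origin_mm=kspace.origin_mm,
    )


@dataclass(frozen=True)
class SNRVolume:
    """Per-voxel SNR magnitude map (dimensionless)."""

    snr: np.ndarray
    support_mask: np.ndarray
    provenance: str  # 'array' | 'body'
    accel: tuple = (1, 1)
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))


def snr_map(recon: ReconResult, support_mask=None, provenance: str = "array") -> SNRVolume:
    """SNR = |image| / noise_std on the support; 0 elsewhere."""
    support = recon.valid_mask if support_mask is None else (support_mask & recon.valid_mask)
    snr = np.zeros(recon.image.shape, dtype=float)
    ok = support & (recon.noise_std > 0)
    snr[ok] = np.abs(recon.image[ok]) / recon.noise_std[ok]
    return SNRVolume(
        snr=snr,
        support_mask=ok,
        provenance=provenance,
        accel=recon.accel,
        voxel_size_mm=recon.voxel_size_mm,
        origin_mm=recon.origin_mm,
    )


def body_coil_snr_map(kspace_body: KSpaceDataset, ncov_body: NoiseCovariance) -> SNRVolume:
    """Single-channel (body-coil) specialisation: unit sensitivity, R = 1."""
    if kspace_body.channel_count != 1:
        raise ValueError("body-coil SNR map requires single-channel data")
    if ncov_body.channel_count != 1:
        raise ValueError("body-coil noise covariance must be 1 x 1")
    grid = kspace_body.grid_shape
    sens = SensitivityMaps(
        maps=np.ones((1,) + grid, dtype=complex),
        support_mask=np.ones(grid, dtype=bool),
        calib_region=(0, 0, 0),
        window_name="none",
    )
    recon = sense_reconstruct(kspace_body, sens, ncov_body, accel=(1, 1))
    return snr_map(recon, provenance="body")
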