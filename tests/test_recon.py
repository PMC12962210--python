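"""SENSE reconstruction: covariance estimation, sensitivity calibration,
subsampling, unfolding oracle, noise propagation and SNR maps."""

import numpy as np
import pytest

from rsnr import (
    KSpaceDataset,
    NoiseCovariance,
    SensitivityMaps,
    body_coil_snr_map,
    estimate_noise_covariance,
    estimate_sensitivity_maps,
    make_shepp_logan_volume,
    sense_reconstruct,
    sensitivity_maps_from_model,
    simulate_acquisition,
    snr_map,
    subsample_kspace,
)
from rsnr.acquisition import complex_gaussian_noise, fftc, ifftc
from rsnr.coils import CoilModel, evaluate_sensitivities, make_coil_array
from rsnr.recon import DEFAULT_CALIB_REGION


# ---------------------------------------------------------------- covariance

def test_noise_covariance_estimate_converges():
    rng = np.random.default_rng(1)
    psi = NoiseCovariance(np.eye(2, dtype=complex))
    x = complex_gaussian_noise(rng, psi, 100_000)
    est = estimate_noise_covariance(x)
    assert np.abs(est.psi - psi.psi).max() < 0.02
    assert est.n_samples_used == 100_000


def test_duplicated_channel_flagged_degenerate():
    rng = np.random.default_rng(2)
    x1 = (rng.standard_normal(4096) + 1j * rng.standard_normal(4096)) / np.sqrt(2)
    est = estimate_noise_covariance(np.stack([x1, x1]))
    w = np.linalg.eigvalsh(est.psi)
    assert w.min() < 1e-10 * np.trace(est.psi).real
    assert est.is_degenerate


def test_covariance_estimate_input_validation():
    with pytest.raises(ValueError, match="samples"):
        estimate_noise_covariance(np.zeros((4, 6), dtype=complex))
    bad = np.ones((2, 100), dtype=complex)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        estimate_noise_covariance(bad)


# -------------------------------------------------------- sensitivity maps

def test_single_channel_unit_sensitivity_recovered(small_phantom):
    sens = np.ones((1,) + small_phantom.shape, dtype=complex)
    ds = simulate_acquisition(
        small_phantom, sens, NoiseCovariance(np.zeros((1, 1), complex)), seed=0
    )
    est = estimate_sensitivity_maps(ds, (16, 16, 8))
    on = est.support_mask
    assert on.any()
    assert np.abs(est.maps[0, on] - 1.0).max() < 1e-6


def test_smooth_sensitivities_recovered_within_3pct():
    """Noiseless 8-channel estimate matches the generator's smooth fields.

    Uses gently varying fields (large elements at a 20 mm stand-off) so the
    windowed low-resolution calibration resolves them; comparison is on the
    eroded object interior after per-voxel virtual-reference phase alignment.
    """
    from scipy import ndimage

    vol = make_shepp_logan_volume((64, 64, 64), voxel_size_mm=4.0)
    coil = make_coil_array("surface_conformal", vol, 8, 140.0)
    centers = coil.element_centers_mm.copy()
    centers[:, 0] -= 20.0
    coil = CoilModel(centers, coil.element_radius_mm, coil.phase_gradients, "loop")
    sens = evaluate_sensitivities(coil, vol)
    ds = simulate_acquisition(vol, sens, NoiseCovariance(np.zeros((8, 8), complex)), seed=0)
    est = estimate_sensitivity_maps(ds, DEFAULT_CALIB_REGION)
    truth = sensitivity_maps_from_model(sens, support_mask=est.support_mask)
    interior = ndimage.binary_erosion(vol.values > 0, iterations=3)
    e, t = est.maps[:, interior], truth.maps[:, interior]
    inner = (e.conj() * t).sum(axis=0)
    phase = inner / np.maximum(np.abs(inner), 1e-300)
    rel_rms = np.sqrt((np.abs(e * phase - t) ** 2).sum() / (np.abs(t) ** 2).sum())
    assert rel_rms < 0.03


def test_calibration_region_must_fit():
    data = np.zeros((2, 16, 16, 16), dtype=complex)
    ds = KSpaceDataset(data=data, noise_block=np.zeros((2, 8), complex))
    with pytest.raises(ValueError, match="exceeds grid"):
        estimate_sensitivity_maps(ds, (24, 24, 12))


# --------------------------------------------------------------- subsample

def test_subsample_identity_at_r1(noiseless_kspace):
    out = subsample_kspace(noiseless_kspace, (1, 1))
    assert out is noiseless_kspace


def test_subsample_2x4_keeps_one_eighth(noiseless_kspace):
    out = subsample_kspace(noiseless_kspace, (2, 4))
    assert out.sampling_mask.sum() == out.sampling_mask.size // 8
    # regular lattice anchored at (0, 0): strides 4 along R/L, 2 along S/I
    expected = np.zeros_like(out.sampling_mask)
    expected[::4, ::2] = True
    assert np.array_equal(out.sampling_mask, expected)
    assert np.all(out.data[:, :, 1, :] == 0)  # discarded lines zeroed


def test_subsample_indivisible_dims_rejected(noiseless_kspace):
    with pytest.raises(ValueError, match="not divisible"):
        subsample_kspace(noiseless_kspace, (3, 4))


# ------------------------------------------------------------------- SENSE

def test_orthogonal_sensitivities_decouple_exactly():
    """Two channels, two-fold R/L aliasing, orthogonal sensitivity columns.

    The effective unfolding matrix is the identity, so the aliased voxel
    pair unfolds to the true values, the unfolded noise variance equals the
    acceleration factor (unit covariance, unitary DFT convention) and g = 1.
    """
    shape = (2, 2, 2)
    x = np.zeros(shape, dtype=complex)
    x[:, 0, :] = 3.0
    x[:, 1, :] = 4.0
    # channel 0 sees only rl=0; channel 1 only rl=1 (with the alias-phase
    # factor absorbed so the unfolding matrix is exactly the identity)
    sens = np.zeros((2,) + shape, dtype=complex)
    sens[0, :, 0, :] = 1.0
    sens[1, :, 1, :] = -1.0
    k = fftc(sens * x[None])
    ds = KSpaceDataset(data=k, noise_block=np.zeros((2, 4), complex))
    sub = subsample_kspace(ds, (1, 2))
    maps = SensitivityMaps(maps=sens, support_mask=np.ones(shape, bool))
    psi = NoiseCovariance(np.eye(2, dtype=complex))
    rec = sense_reconstruct(sub, maps, psi, (1, 2))
    assert np.allclose(rec.image[:, 0, :], 3.0, atol=1e-10)
    assert np.allclose(rec.image[:, 1, :], 4.0, atol=1e-10)
    assert np.allclose(rec.noise_std, np.sqrt(2.0))  # sqrt(R) x unit std
    assert np.allclose(rec.gfactor, 1.0, atol=1e-9)


def _random_instance(rng, shape=(2, 8, 8), channels=5, accel=(2, 4)):
    """Random smooth-free SENSE instance: complex image + random sens maps."""
    full = (shape[0], shape[1], shape[2])
    x = rng.standard_normal(full) + 1j * rng.standard_normal(full)
    sens = rng.standard_normal((channels,) + full) + 1j * rng.standard_normal(
        (channels,) + full
    )
    a = rng.standard_normal((channels, channels))
    psi = NoiseCovariance((a @ a.T).astype(complex) + 0.1 * np.eye(channels))
    return x, sens, psi


def _alias_coefficient(n, r, t):
    """Numerically derive the replica coefficient of the sampling operator.

    Places a unit impulse at stored index t * n / r, transforms, subsamples
    the centred lattice {0, r, 2r, ...} and reads the zero-filled inverse
    transform at index 0 — entirely independent of the library's internals.
    """
    e = np.zeros(n, dtype=complex)
    e[t * (n // r)] = 1.0
    k = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(e), norm="ortho"))
    mask = np.zeros(n, dtype=bool)
    mask[::r] = True
    z = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(k * mask), norm="ortho"))
    return r * z[0]


def test_unfolding_equals_whitened_least_squares_on_random_instances():
    """SENSE unfolding == independent whitened LS oracle, 100 instances."""
    rng = np.random.default_rng(2024)
    shape = (2, 8, 8)
    channels = 5
    r_si, r_rl = 2, 2
    coef_rl = [_alias_coefficient(shape[1], r_rl, t) for t in range(r_rl)]
    coef_si = [_alias_coefficient(shape[2], r_si, t) for t in range(r_si)]
    for _ in range(100):
        x, sens, psi = _random_instance(rng, shape, channels)
        k = fftc(sens * x[None])
        ds = KSpaceDataset(data=k, noise_block=np.zeros((channels, 2 * channels), complex))
        sub = subsample_kspace(ds, (r_si, r_rl))
        maps = SensitivityMaps(maps=sens, support_mask=np.ones(shape, bool))
        rec = sense_reconstruct(sub, maps, psi, (r_si, r_rl))

        # independent oracle: assemble each aliased system from the zero-
        # filled image and solve the whitened normal equations directly
        zf = ifftc(np.where(sub.sampling_mask[None, None], sub.data, 0))
        w = np.linalg.cholesky(np.linalg.inv(psi.psi)).conj().T
        n1r, n2r = shape[1] // r_rl, shape[2] // r_si
        r_tot = r_si * r_rl
        for i in range(shape[0]):
            for j in range(0, n1r, 3):
                for l in range(0, n2r, 3):
                    a_vec = r_tot * zf[:, i, j, l]
                    cols, locs = [], []
                    for t1 in range(r_rl):
                        for t2 in range(r_si):
                            m1, m2 = j + t1 * n1r, l + t2 * n2r
                            cols.append(sens[:, i, m1, m2] * coef_rl[t1] * coef_si[t2])
                            locs.append((m1, m2))
                    s_mat = np.column_stack(cols)
                    v, *_ = np.linalg.lstsq(w @ s_mat, w @ a_vec, rcond=None)
                    for (m1, m2), val in zip(locs, v):
                        assert abs(rec.image[i, m1, m2] - val) < 1e-8
                    # analytic noise map from the same normal equations
                    minv = np.linalg.inv(s_mat.conj().T @ np.linalg.inv(psi.psi) @ s_mat)
                    for t, (m1, m2) in enumerate(locs):
                        expect = np.sqrt(r_tot * minv[t, t].real)
                        assert abs(rec.noise_std[i, m1, m2] - expect) < 1e-8


def test_g_is_one_at_r1_and_at_least_one_accelerated(
    small_phantom, phantom_sens, noiseless_kspace
):
    maps = sensitivity_maps_from_model(
        phantom_sens, support_mask=small_phantom.values > 0
    )
    psi = NoiseCovariance(0.01 * np.eye(8, dtype=complex))
    r1 = sense_reconstruct(noiseless_kspace, maps, psi, (1, 1))
    assert np.all(np.abs(r1.gfactor[r1.valid_mask] - 1.0) < 1e-9)
    sub = subsample_kspace(noiseless_kspace, (2, 4))
    r24 = sense_reconstruct(sub, maps, psi, (2, 4))
    assert np.all(r24.gfactor[r24.valid_mask] >= 1.0 - 1e-6)


def test_whitening_invariance(small_phantom, phantom_sens, noiseless_kspace):
    """Pre-whitening channels and setting psi = I leaves SNR unchanged."""
    rng = np.random.default_rng(3)
    a = rng.standard_normal((8, 8))
    psi = NoiseCovariance((a @ a.T).astype(complex) + 0.5 * np.eye(8))
    maps = sensitivity_maps_from_model(
        phantom_sens, support_mask=small_phantom.values > 0
    )
    rec = sense_reconstruct(noiseless_kspace, maps, psi, (1, 1))
    w = psi.whitener()
    k_w = np.einsum("dc,c...->d...", w, noiseless_kspace.data)
    ds_w = KSpaceDataset(
        data=k_w, noise_block=np.zeros((8, 16), complex),
        voxel_size_mm=noiseless_kspace.voxel_size_mm,
    )
    maps_w = SensitivityMaps(
        maps=np.einsum("dc,c...->d...", w, maps.maps),
        support_mask=maps.support_mask,
    )
    rec_w = sense_reconstruct(
        ds_w, maps_w, NoiseCovariance(np.eye(8, dtype=complex)), (1, 1)
    )
    on = rec.valid_mask & rec_w.valid_mask
    assert np.abs(rec.image[on] - rec_w.image[on]).max() < 1e-8
    assert np.abs(rec.noise_std[on] - rec_w.noise_std[on]).max() < 1e-8


def test_subsampled_noiseless_recon_matches_fully_sampled(
    small_phantom, phantom_sens, noiseless_kspace
):
    maps = sensitivity_maps_from_model(
        phantom_sens, support_mask=small_phantom.values > 0
    )
    psi = NoiseCovariance(0.01 * np.eye(8, dtype=complex))
    full = sense_reconstruct(noiseless_kspace, maps, psi, (1, 1))
    sub = sense_reconstruct(
        subsample_kspace(noiseless_kspace, (2, 4)), maps, psi, (2, 4)
    )
    on = full.valid_mask & sub.valid_mask
    num = np.abs(sub.image[on] - full.image[on])
    den = np.abs(full.image[on])
    assert np.sqrt((num**2).sum() / (den**2).sum()) < 0.01


# ---------------------------------------------------------------- SNR maps

def test_snr_map_is_magnitude_over_noise(noiseless_kspace, small_phantom, phantom_sens):
    maps = sensitivity_maps_from_model(
        phantom_sens, support_mask=small_phantom.values > 0
    )
    psi = NoiseCovariance(0.01 * np.eye(8, dtype=complex))
    rec = sense_reconstruct(noiseless_kspace, maps, psi, (1, 1))
    vol = snr_map(rec)
    on = vol.support_mask
    assert np.allclose(vol.snr[on], np.abs(rec.image[on]) / rec.noise_std[on])
    assert np.all(vol.snr[~on] == 0)


def test_snr_scales_linearly_with_signal(small_phantom, phantom_sens, zero_cov8):
    from rsnr.grids import SignalVolume

    psi = NoiseCovariance(0.01 * np.eye(8, dtype=complex))
    maps = sensitivity_maps_from_model(
        phantom_sens, support_mask=small_phantom.values > 0
    )
    doubled = SignalVolume(
        2.0 * small_phantom.values, small_phantom.voxel_size_mm, small_phantom.origin_mm
    )
    snr1 = snr_map(sense_reconstruct(
        simulate_acquisition(small_phantom, phantom_sens, zero_cov8, seed=0),
        maps, psi, (1, 1)))
    snr2 = snr_map(sense_reconstruct(
        simulate_acquisition(doubled, phantom_sens, zero_cov8, seed=0),
        maps, psi, (1, 1)))
    on = snr1.support_mask & snr2.support_mask & (snr1.snr > 0)
    assert np.allclose(snr2.snr[on] / snr1.snr[on], 2.0, atol=1e-8)


def test_single_channel_snr_matches_pseudo_replica():
    """Analytic noise map == empirical complex-replica std within 5% RMS.

    The pseudo-replica convention measures the standard deviation of the
    complex reconstructed images across noise realisations; under the
    unitary DFT the analytic value for unit sensitivity is the k-space
    noise std itself.
    """
    rng = np.random.default_rng(9)
    vol = make_shepp_logan_volume((16, 16, 16), voxel_size_mm=12.0)
    sens = np.ones((1,) + vol.shape, dtype=complex)
    sigma = 0.05
    psi = NoiseCovariance(np.array([[sigma**2]], dtype=complex))
    ds0 = simulate_acquisition(vol, sens, NoiseCovariance(np.zeros((1, 1), complex)), seed=0)
    base = body_coil_snr_map(
        KSpaceDataset(ds0.data, np.full((1, 4), 0.0), voxel_size_mm=vol.voxel_size_mm),
        psi,
    )
    imgs = []
    for _ in range(500):
        noise = complex_gaussian_noise(rng, psi, vol.values.size).reshape(ds0.data.shape)
        imgs.append(ifftc(ds0.data + noise)[0])
    stack = np.stack(imgs)
    emp_std = np.sqrt(np.mean(np.abs(stack - stack.mean(0)) ** 2, axis=0))
    on = vol.values > 0.2
    analytic = sigma  # unitary DFT: image noise std equals k-space std
    rel = (emp_std[on] - analytic) / analytic
    assert np.sqrt(np.mean(rel**2)) < 0.05
    assert np.allclose(base.snr[on], np.abs(ifftc(ds0.data)[0][on]) / sigma)


def test_body_coil_requires_single_channel(noiseless_kspace):
    psi = NoiseCovariance(np.eye(8, dtype=complex))
    with pytest.raises(ValueError, match="single-channel"):
        body_coil_snr_map(noiseless_kspace, psi)


def test_body_coil_snr_halves_when_noise_variance_quadruples(small_phantom):
    sens = np.ones((1,) + small_phantom.shape, dtype=complex)
    ds = simulate_acquisition(
        small_phantom, sens, NoiseCovariance(np.zeros((1, 1), complex)), seed=0
    )
    s1 = body_coil_snr_map(ds, NoiseCovariance(np.array([[0.01]], complex)))
    s2 = body_coil_snr_map(ds, NoiseCovariance(np.array([[0.04]], complex)))
    on = s1.support_mask & (s1.snr > 0)
    assert np.allclose(s2.snr[on] / s1.snr[on], 0.5, atol=1e-10)


def test_body_coil_repeatability_consistent_with_noise_model(small_phantom):
    sens = np.ones((1,) + small_phantom.shape, dtype=complex)
    sigma = 0.02
    psi = NoiseCovariance(np.array([[sigma**2]], dtype=complex))
    maps = [
        body_coil_snr_map(simulate_acquisition(small_phantom, sens, psi, seed=s), psi)
        for s in (101, 202)
    ]
    on = small_phantom.values > 0.5
    diff = np.abs(maps[0].snr[on] - maps[1].snr[on])
    # SNR-map difference of two unit-noise measurements: median |N(0, sqrt 2)|
    predicted = 0.954 * np.sqrt(2.0)
    assert np.median(diff) < 3.0 * predicted
    assert np.median(diff) > predicted / 3.0
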