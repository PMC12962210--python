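"""Multichannel Cartesian k-space simulation with a prescan noise block.

The forward model is the centred, unitary DFT of (sensitivity x signal)
per channel, plus circular complex Gaussian noise that is i.i.d. across
k-space locations and correlated across channels with a prescribed
Hermitian covariance.  Real and imaginary parts are independent, each
carrying half the per-channel variance, so ``E[n n^H] = psi``.  A
noise-only block (default 2048 samples) drawn from the same channel
covariance accompanies every acquisition, mirroring a prescan noise
acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import AXIS_TAGS, SignalVolume, _as_vec3

DEFAULT_NOISE_BLOCK_LEN = 2048


@dataclass(frozen=True)
class NoiseCovariance:
    """Hermitian channel x channel receiver-noise covariance (psi)."""

    psi: np.ndarray
    n_samples_used: int = 0

    def __post_init__(self):
        p = np.asarray(self.psi, dtype=complex)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("psi must be a square matrix")
        if not np.allclose(p, p.conj().T, atol=1e-10 * max(1.0, np.abs(p).max())):
            raise ValueError("psi must be Hermitian")
        p = 0.5 * (p + p.conj().T)
        w = np.linalg.eigvalsh(p)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            raise ValueError("psi must be positive semi-definite")
        object.__setattr__(self, "psi", p)

    @property
    def channel_count(self) -> int:
        return self.psi.shape[0]

    @property
    def is_degenerate(self) -> bool:
        """True when some channel combination carries (numerically) no noise."""
        w = np.linalg.eigvalsh(self.psi)
        return bool(w.min() < 1e-10 * np.trace(self.psi).real)

    def sqrt_factor(self) -> np.ndarray:
        """A matrix L with L L^H = psi (eigendecomposition, PSD-safe)."""
        w, v = np.linalg.eigh(self.psi)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)

    def whitener(self) -> np.ndarray:
        """psi^(-1/2) (pseudo-inverse square root for degenerate channels)."""
        w, v = np.linalg.eigh(self.psi)
        wmax = max(w.max(), 0.0)
        keep = w > 1e-12 * max(wmax, 1e-300)
        inv = np.zeros_like(w)
        inv[keep] = 1.0 / np.sqrt(w[keep])
        return (v * inv) @ v.conj().T


def fftc(x: np.ndarray, axes=(1, 2, 3)) -> np.ndarray:
    """Centred unitary forward DFT (image -> k-space, DC at the array centre)."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifftc(x: np.ndarray, axes=(1, 2, 3)) -> np.ndarray:
    """Centred unitary inverse DFT (k-space -> image)."""
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


@dataclass(frozen=True)
class KSpaceDataset:
    """One acquisition: multichannel k-space + prescan noise block + metadata.

    ``data`` has shape (channels, n_ap, n_rl, n_si) with the frequency axis
    first after the channel axis; ``sampling_mask`` lives on the (R/L, S/I)
    phase-encode plane and is all ones when fully sampled.
    """

    data: np.ndarray
    noise_block: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sampling_mask: np.ndarray | None = None
    axis_tags: tuple = AXIS_TAGS
    coil_name: str = ""
    seed: int | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=complex)
        if d.ndim != 4:
            raise ValueError("data must be (channels, n_ap, n_rl, n_si)")
        nb = np.atleast_2d(np.asarray(self.noise_block, dtype=complex))
        if nb.shape[0] != d.shape[0]:
            raise ValueError("noise_block channel count differs from data")
        if nb.shape[1] < 2 * d.shape[0]:
            raise ValueError("noise_block must hold at least 2 x channels samples")
        mask = self.sampling_mask
        if mask is None:
            mask = np.ones(d.shape[2:], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != d.shape[2:]:
            raise ValueError("sampling_mask must match the phase-encode plane")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "noise_block", nb)
        object.__setattr__(self, "sampling_mask", mask)
        object.__setattr__(self, "voxel_size_mm", _as_vec3(self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", _as_vec3(self.origin_mm))

    @property
    def channel_count(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def fully_sampled(self) -> bool:
        return bool(self.sampling_mask.all())


def complex_gaussian_noise(
    rng: np.random.Generator, cov: NoiseCovariance, n_samples: int
) -> np.ndarray:
    """(channels, n_samples) circular complex noise with E[n n^H] = psi."""
    c = cov.channel_count
    z = (
        rng.standard_normal((c, n_samples)) + 1j * rng.standard_normal((c, n_samples))
    ) / np.sqrt(2.0)
    return cov.sqrt_factor() @ z


def simulate_acquisition(
    signal: SignalVolume,
    sensitivities: np.ndarray,
    noise_cov: NoiseCovariance,
    noise_block_len: int = DEFAULT_NOISE_BLOCK_LEN,
    seed: int = 0,
    coil_name: str = "",
) -> KSpaceDataset:
    """Simulate a fully sampled multichannel acquisition of ``signal``.

    k-space is the centred unitary DFT of ``sensitivities * signal`` per
    channel plus channel-correlated complex Gaussian noise; a noise-only
    prescan block is drawn from the same covariance.  A fixed seed gives
    bit-identical output.
    """
    sens = np.asarray(sensitivities, dtype=complex)
    if sens.shape[1:] != signal.shape:
        raise ValueError("sensitivities grid differs from signal grid")
    if noise_cov.channel_count != sens.shape[0]:
        raise ValueError("noise covariance dimension differs from channel count")
    rng = np.random.default_rng(seed)
    kspace = fftc(sens * signal.values[None])
    n_vox = int(np.prod(signal.shape))
    if np.trace(noise_cov.psi).real > 0:
        noise = complex_gaussian_noise(rng, noise_cov, n_vox)
        kspace = kspace + noise.reshape(sens.shape)
        block = complex_gaussian_noise(rng, noise_cov, noise_block_len)
    else:
        block = np.zeros((sens.shape[0], noise_block_len), dtype=complex)
    return KSpaceDataset(
        data=kspace,
        noise_block=block,
        voxel_size_mm=signal.voxel_size_mm,
        origin_mm=signal.origin_mm,
        coil_name=coil_name,
        seed=seed,
    )
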