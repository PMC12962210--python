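"""Image-grid primitives shared across the pipeline.

All volumes live on a regular 3D Cartesian grid in a right-handed scanner
frame measured in millimetres.  Array axes are ordered

    axis 0 : anterior→posterior   (A/P, the frequency-encode direction)
    axis 1 : right→left           (R/L, first phase-encode direction)
    axis 2 : superior→inferior    (S/I, second phase-encode direction)

Voxel indices are 0-based and voxel centres sit at
``origin_mm + index * voxel_size_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_TAGS = ("A/P", "R/L", "S/I")
#: index of the frequency-encode axis (never subsampled)
FREQ_AXIS = 0
#: indices of the two phase-encode axes (R/L, S/I)
PHASE_AXES = (1, 2)


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise ValueError(f"expected a scalar or 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class SignalVolume:
    """A real, non-negative 3D signal volume with grid metadata.

    Parameters
    ----------
    values : ndarray, shape (n_ap, n_rl, n_si)
        Noise-free signal magnitude in arbitrary units; finite and >= 0.
    voxel_size_mm : array-like of 3 floats
        Voxel pitch along (A/P, R/L, S/I); strictly positive.
    origin_mm : array-like of 3 floats
        Scanner-frame coordinates of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={vals.ndim}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        if np.any(vals < 0):
            raise ValueError("values must be non-negative")
        vox = _as_vec3(self.voxel_size_mm)
        if np.any(vox <= 0):
            raise ValueError("voxel_size_mm must be strictly positive")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "origin_mm", _as_vec3(self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in mm (three 1D arrays)."""
        return tuple(
            self.origin_mm[a] + self.voxel_size_mm[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def voxel_centers_mm(self) -> np.ndarray:
        """Dense (n_ap, n_rl, n_si, 3) array of voxel-centre coordinates."""
        ax = self.axis_coordinates()
        grids = np.meshgrid(*ax, indexing="ij")
        return np.stack(grids, axis=-1)

    def same_grid(self, other: "SignalVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


def voxel_centers_mm(shape, voxel_size_mm, origin_mm) -> np.ndarray:
    """Voxel-centre coordinate array for a bare grid (no signal values)."""
    vox = _as_vec3(voxel_size_mm)
    org = _as_vec3(origin_mm)
    ax = [org[a] + vox[a] * np.arange(shape[a]) for a in range(3)]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
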