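"""Parameterised digital subjects for prone/supine breast-imaging studies.

Each subject is a labelled torso-and-breast geometry on a scanner-frame
grid: an elliptic torso slab, two breast ellipsoids (pendant and elongated
along A/P when prone; flattened and spread laterally when supine), a chest
wall slab at the anterior face of the torso, and two axilla spheres lateral
to the chest wall.  The two positions are independent parameterised
geometries — no biomechanical deformation is modelled, so prone and supine
subjects of the same nominal size agree in breast volume but not voxelwise.

The breast ellipsoid scale is solved numerically so the rasterised breast
label hits a requested volume target even when the two breasts merge
centrally (common for large supine breasts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import SignalVolume, _as_vec3
from .regions import AXILLA, BREAST, CHEST_WALL, RegionMaskSet

POSITIONS = ("prone", "supine")

#: breast ellipsoid semi-axis ratios (A/P, R/L, S/I) per position
_BREAST_RATIOS = {"prone": (1.6, 1.0, 1.0), "supine": (0.55, 1.3, 1.2)}
#: anterior chest-surface position as a fraction of the A/P grid extent
_CHEST_FRONT_FRAC = {"prone": 0.55, "supine": 0.35}
#: breast centre offset from the midline as a fraction of the R/L extent
_BREAST_OFFSET_FRAC = {"prone": 0.22, "supine": 0.16}

#: baseline tissue intensities (arbitrary units)
_SIGNAL = {BREAST: 1.0, CHEST_WALL: 0.8, AXILLA: 0.9, "torso": 0.7}


@dataclass(frozen=True)
class DigitalSubject:
    """A labelled digital subject: signal, region labels, skin surface."""

    signal: SignalVolume
    labels: RegionMaskSet
    skin_surface: np.ndarray  # (n, 3) voxel indices of the anterior surface
    position_tag: str

    def __post_init__(self):
        if self.position_tag not in POSITIONS:
            raise ValueError(f"position_tag must be one of {POSITIONS}")
        if self.signal.shape != self.labels.shape:
            raise ValueError("signal and label grids differ")

    @property
    def body_mask(self) -> np.ndarray:
        return self.signal.values > 0

    def skin_points_mm(self) -> np.ndarray:
        """Skin-surface voxel centres in scanner mm coordinates."""
        return (
            self.signal.origin_mm[None, :]
            + self.skin_surface * self.signal.voxel_size_mm[None, :]
        )


def _ellipsoid_mask(centers_mm, center, semi_axes) -> np.ndarray:
    d = (centers_mm - np.asarray(center)) / np.asarray(semi_axes)
    return np.einsum("...i,...i->...", d, d) <= 1.0


def anterior_surface_indices(body_mask: np.ndarray) -> np.ndarray:
    """First body voxel along +A/P in every (R/L, S/I) column, as (n, 3) indices."""
    any_body = body_mask.any(axis=0)
    first = body_mask.argmax(axis=0)
    jj, kk = np.nonzero(any_body)
    return np.column_stack([first[any_body], jj, kk]).astype(int)


def make_digital_subject(
    position_tag: str,
    breast_volume_ml: float = 1000.0,
    grid_shape=(72, 60, 48),
    voxel_size_mm=4.0,
    seed: int = 0,
    signal_heterogeneity: float = 0.15,
) -> DigitalSubject:
    """Generate a prone- or supine-positioned digital subject.

    Parameters
    ----------
    position_tag : {'prone', 'supine'}
        Prone gives pendant breasts elongated along A/P; supine gives
        flattened breasts spread along R/L and S/I over the chest slab.
    breast_volume_ml : float
        Target total breast-label volume in mL, within [200, 4000]; the
        rasterised label is brought within 10% of this target (typically
        much closer) or an error is raised.
    grid_shape, voxel_size_mm :
        Grid definition; the default 72 x 60 x 48 at 4 mm spans
        288 x 240 x 192 mm.
    seed : int
        Seeds the smooth multiplicative signal-heterogeneity field only;
        the geometry is deterministic in the shape parameters.
    signal_heterogeneity : float
        Relative amplitude of the smooth tissue-intensity variation.
    """
    if position_tag not in POSITIONS:
        raise ValueError(f"position_tag must be one of {POSITIONS}")
    if not 200.0 <= breast_volume_ml <= 4000.0:
        raise ValueError("breast_volume_ml must lie in [200, 4000] mL")
    shape = tuple(int(n) for n in grid_shape)
    vox = _as_vec3(voxel_size_mm)
    extent = vox * np.asarray(shape)
    centers = (
        np.stack(
            np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
        )
        * vox
    )

    cf = _CHEST_FRONT_FRAC[position_tag] * extent[0]
    mid_rl, mid_si = extent[1] / 2.0, extent[2] / 2.0
    offset = _BREAST_OFFSET_FRAC[position_tag] * extent[1]
    ratios = np.asarray(_BREAST_RATIOS[position_tag])

    torso = (
        (centers[..., 0] >= cf)
        & (centers[..., 0] <= 0.93 * extent[0])
        & (np.abs(centers[..., 1] - mid_rl) <= 0.45 * extent[1])
    )

    def breast_mask(scale: float) -> np.ndarray:
        semi = ratios * scale
        # centre depth: pendant breasts hang mostly anterior of the chest
        # surface; supine breasts sit on it with a small posterior overlap
        anterior_frac = 0.85 if position_tag == "prone" else 0.6
        c_ap = cf - anterior_frac * semi[0]
        m = np.zeros(shape, dtype=bool)
        for sgn in (-1.0, 1.0):
            m |= _ellipsoid_mask(
                centers, (c_ap, mid_rl + sgn * offset, mid_si), semi
            )
        return m

    # solve the ellipsoid scale so the rasterised (possibly merged) breast
    # label meets the volume target
    vox_ml = float(np.prod(vox)) / 1000.0
    scale = (breast_volume_ml * 1000.0 / (2.0 * 4.0 / 3.0 * np.pi * np.prod(ratios))) ** (
        1.0 / 3.0
    )
    breast = breast_mask(scale)
    for _ in range(12):
        got = breast.sum() * vox_ml
        if got > 0 and abs(got - breast_volume_ml) / breast_volume_ml < 0.02:
            break
        if got == 0:
            raise ValueError("breast volume target unachievable on this grid")
        scale *= (breast_volume_ml / got) ** (1.0 / 3.0)
        breast = breast_mask(scale)
    got = breast.sum() * vox_ml
    if abs(got - breast_volume_ml) / breast_volume_ml > 0.10:
        raise ValueError(
            f"breast volume target {breast_volume_ml} mL unachievable: got {got:.0f} mL"
        )

    chest_wall = (
        torso
        & (centers[..., 0] <= cf + 28.0)
        & (np.abs(centers[..., 1] - mid_rl) <= 0.36 * extent[1])
        & (np.abs(centers[..., 2] - mid_si) <= 0.38 * extent[2])
    )

    axilla = np.zeros(shape, dtype=bool)
    ax_r = 17.0  # mm: a 3-4 cm diameter region
    for sgn in (-1.0, 1.0):
        c = (
            cf + 14.0,
            mid_rl + sgn * 0.40 * extent[1],
            mid_si + 0.22 * extent[2],
        )
        axilla |= _ellipsoid_mask(centers, c, (ax_r, ax_r, ax_r))

    labels = np.zeros(shape, dtype=np.int16)
    labels[torso] = 0  # unlabelled torso tissue stays background label
    labels[chest_wall] = CHEST_WALL
    labels[axilla & ~chest_wall] = AXILLA
    labels[breast] = BREAST  # breast wins every overlap (it includes the skin)

    body = torso | breast | axilla
    rng = np.random.default_rng(seed)
    rough = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(rough, sigma=3.0)
    smooth /= max(np.abs(smooth).max(), 1e-12)
    texture = 1.0 + signal_heterogeneity * smooth

    signal = np.zeros(shape, dtype=float)
    signal[torso] = _SIGNAL["torso"]
    signal[labels == CHEST_WALL] = _SIGNAL[CHEST_WALL]
    signal[labels == AXILLA] = _SIGNAL[AXILLA]
    signal[labels == BREAST] = _SIGNAL[BREAST]
    signal *= np.clip(texture, 0.5, 1.5)
    signal[~body] = 0.0

    vol = SignalVolume(signal, voxel_size_mm=vox, origin_mm=np.zeros(3))
    masks = RegionMaskSet(labels, voxel_size_mm=vox)
    skin = anterior_surface_indices(body)
    return DigitalSubject(
        signal=vol, labels=masks, skin_surface=skin, position_tag=position_tag
    )
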