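"""Coil-array models and smooth surrogate sensitivity fields.

Three array geometries are supported:

* ``surface_conformal`` — element centres spread approximately uniformly
  over a subject's anterior skin surface (flexible array laid on the skin,
  insulation thickness 0 mm),
* ``side_paddles`` — element centres on two planes flanking each breast
  laterally (rigid paddle-style prone coil),
* ``body`` — a single channel with spatially uniform sensitivity, the
  transmit/receive body-coil reference.

Element fields use the on-axis circular-loop magnitude generalised to an
isotropic distance falloff, |s|(d) = a^3 / (a^2 + d^2)^(3/2) for element
radius a (so |s| = 1 at the element centre), with a smooth per-element
linear phase ramp.  This captures the near/far behaviour that drives
coil-proximity SNR trends without a full Biot–Savart integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import SignalVolume, voxel_centers_mm
from .regions import BREAST
from .subjects import DigitalSubject, anterior_surface_indices

GEOMETRIES = ("surface_conformal", "side_paddles", "body")


@dataclass(frozen=True)
class CoilModel:
    """A receive array: element reference points plus falloff parameters."""

    element_centers_mm: np.ndarray  # (n, 3)
    element_radius_mm: float
    phase_gradients: np.ndarray  # (n, 3) rad/mm, smooth per-element phase ramp
    kind: str = "loop"  # 'loop' | 'body'
    name: str = ""

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.element_centers_mm, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 3:
            raise ValueError("element_centers_mm must be (n, 3) with n >= 1")
        if self.element_radius_mm <= 0:
            raise ValueError("element radius must be positive")
        object.__setattr__(self, "element_centers_mm", pts)
        object.__setattr__(
            self, "phase_gradients", np.atleast_2d(np.asarray(self.phase_gradients, float))
        )

    @property
    def channel_count(self) -> int:
        return self.element_centers_mm.shape[0]


def _default_phase_gradients(n: int, period_mm: float = 500.0) -> np.ndarray:
    """Deterministic slowly-varying phase ramps, one per element."""
    k = 2.0 * np.pi / period_mm
    ang = 2.0 * np.pi * np.arange(n) / max(n, 1)
    return k * np.column_stack(
        [np.cos(ang), np.sin(ang), np.cos(2.0 * ang + 0.7)]
    ) * 0.5


def farthest_point_sample(points: np.ndarray, n: int, start: int | None = None) -> np.ndarray:
    """Greedy farthest-point subset of ``points`` (deterministic).

    Starts from ``start`` (default: the most anterior point, ties broken by
    index) and repeatedly adds the point farthest from the chosen set.
    Returns indices into ``points``.
    """
    pts = np.asarray(points, dtype=float)
    if n > pts.shape[0]:
        raise ValueError(f"requested {n} samples from {pts.shape[0]} points")
    if start is None:
        start = int(np.argmin(pts[:, 0]))
    chosen = [start]
    d = np.linalg.norm(pts - pts[start], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    return np.asarray(chosen, dtype=int)


def _surface_points_mm(subject) -> np.ndarray:
    if isinstance(subject, DigitalSubject):
        return subject.skin_points_mm()
    if isinstance(subject, SignalVolume):
        idx = anterior_surface_indices(subject.values > 0)
        return subject.origin_mm[None, :] + idx * subject.voxel_size_mm[None, :]
    raise TypeError("expected a DigitalSubject or SignalVolume for surface placement")


def make_coil_array(
    geometry: str,
    subject_or_extent,
    element_count: int,
    element_diameter_mm: float = 70.0,
    name: str = "",
) -> CoilModel:
    """Build a coil array of the requested geometry.

    Parameters
    ----------
    geometry : {'surface_conformal', 'side_paddles', 'body'}
    subject_or_extent :
        A :class:`DigitalSubject` or :class:`SignalVolume` for the surface
        and paddle geometries (needed for the skin surface / breast bounding
        boxes); anything is accepted for ``body``.
    element_count : int
        Number of receive channels (>= 1); ``body`` forces 1.
    element_diameter_mm : float
        Physical loop diameter; enters only through the sensitivity falloff.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}")
    if element_count < 1:
        raise ValueError("element_count must be >= 1")
    radius = element_diameter_mm / 2.0

    if geometry == "body":
        return CoilModel(
            element_centers_mm=np.zeros((1, 3)),
            element_radius_mm=max(radius, 1.0),
            phase_gradients=np.zeros((1, 3)),
            kind="body",
            name=name or "body",
        )

    if geometry == "surface_conformal":
        if subject_or_extent is None:
            raise ValueError("surface_conformal placement requires a subject")
        surf = _surface_points_mm(subject_or_extent)
        idx = farthest_point_sample(surf, element_count)
        centers = surf[idx]
        return CoilModel(
            element_centers_mm=centers,
            element_radius_mm=radius,
            phase_gradients=_default_phase_gradients(element_count),
            kind="loop",
            name=name or "surface_conformal",
        )

    # side_paddles: bars flanking each breast laterally, elements strung
    # along S/I on each bar at the breast's A/P centre
    subject = subject_or_extent
    if not isinstance(subject, DigitalSubject):
        raise ValueError("side_paddles placement requires a DigitalSubject")
    vox = subject.signal.voxel_size_mm
    origin = subject.signal.origin_mm
    breast = subject.labels.region_mask(BREAST)
    if not breast.any():
        raise ValueError("subject has no breast label")
    comp, n_comp = ndimage.label(breast)
    planes = []  # (rl_mm, ap_center_mm, si_lo_mm, si_hi_mm)
    for c in range(1, n_comp + 1):
        ii, jj, kk = np.nonzero(comp == c)
        rl_lo = origin[1] + (jj.min() - 1) * vox[1]
        rl_hi = origin[1] + (jj.max() + 1) * vox[1]
        ap_c = origin[0] + 0.5 * (ii.min() + ii.max()) * vox[0]
        si_lo = origin[2] + kk.min() * vox[2]
        si_hi = origin[2] + kk.max() * vox[2]
        planes.append((rl_lo, ap_c, si_lo, si_hi))
        planes.append((rl_hi, ap_c, si_lo, si_hi))
    per_plane = int(np.ceil(element_count / len(planes)))
    centers = []
    for rl, ap_c, si_lo, si_hi in planes:
        si = np.linspace(si_lo, si_hi, per_plane + 2)[1:-1]
        for s in si:
            centers.append((ap_c, rl, s))
    centers = np.asarray(centers)[:element_count]
    return CoilModel(
        element_centers_mm=centers,
        element_radius_mm=radius,
        phase_gradients=_default_phase_gradients(centers.shape[0]),
        kind="loop",
        name=name or "side_paddles",
    )


def evaluate_sensitivities(coil: CoilModel, grid) -> np.ndarray:
    """Evaluate complex channel sensitivities on a volume's grid.

    ``grid`` is a :class:`SignalVolume` (or anything with ``shape``,
    ``voxel_size_mm`` and ``origin_mm``).  Returns a complex array of shape
    ``(channels,) + grid.shape``.  The body model returns constant 1.
    """
    shape = tuple(grid.shape)
    if coil.kind == "body":
        return np.ones((1,) + shape, dtype=complex)
    centers = voxel_centers_mm(shape, grid.voxel_size_mm, grid.origin_mm)
    a = coil.element_radius_mm
    out = np.empty((coil.channel_count,) + shape, dtype=complex)
    for c in range(coil.channel_count):
        rel = centers - coil.element_centers_mm[c]
        d2 = np.einsum("...i,...i->...", rel, rel)
        mag = a**3 / (a**2 + d2) ** 1.5
        phase = np.einsum("...i,i->...", rel, coil.phase_gradients[c])
        out[c] = mag * np.exp(1j * phase)
    return out


def min_pairwise_spacing_mm(coil: CoilModel) -> float:
    """Smallest distance between any two element centres."""
    pts = coil.element_centers_mm
    if pts.shape[0] < 2:
        return np.inf
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(d[:, 1].min())
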