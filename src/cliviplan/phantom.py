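"""Parametric synthetic skull-base phantoms.

The generator emulates the retro-condylar region around the inferior clivus
on a desk-scale voxel grid (default 96 mm cube at 1 mm isotropic): occipital
condyle, jugular tubercle, foramen magnum rim, clival and petrous bone walls,
medulla, cerebellar hemisphere with tonsil and biventral lobule, the
vertebral artery with PICA/AICA branches, the sigmoid sinus draining through
the jugular bulb plus the inferior petrosal sinus, and thin cranial-nerve
bundles (VI through XII).  Structures are analytic primitives -- ellipsoids,
capsule tubes along polyline centerlines, half-space slabs -- rasterised by
voxel-center inclusion and painted in a fixed precedence order
(bone > artery > vein > nerve > brain > space) so overlaps are deterministic.

Anatomical variation enters through a handful of physical parameters: the
vertebral-artery caliber (hypoplastic to grossly dilated), sigmoid-sinus
dominance (scales the sinus/bulb caliber), the height of the accessory-nerve
(CN XI) bundle, tubercle and condyle size, and a seeded jitter applied to
landmarks.  Identical parameters (including the seed) give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .anatomy import (
    ARTERY,
    BONE,
    BRAINSTEM,
    CEREBELLUM,
    CRANIAL_NERVE,
    SPACE,
    VEIN,
    AnatomyError,
    LabelMap,
    LandmarkSet,
)

__all__ = ["PhantomParams", "PhantomSizingError", "generate_phantom", "DEFAULT_LANDMARK_FRACTIONS"]

#: Reference domain (mm) in which the nominal coordinates below are expressed;
#: all positions scale linearly with the actual physical grid extent.
_REFERENCE_EXTENT = 96.0

#: Nominal landmark positions (mm in the 96 mm reference domain, RAS).
#: These are the documented default placements; seeded jitter is added on top.
DEFAULT_LANDMARK_FRACTIONS: Dict[str, Tuple[float, float, float]] = {
    "a": (74.0, 16.0, 64.0),  # posterolateral entry, retroauricular point
    "b": (60.0, 12.0, 88.0),  # posterolateral entry, retrosigmoid point
    "c": (66.0, 12.0, 8.0),   # posterior rim of the foramen magnum
    "d": (60.0, 38.0, 12.0),  # posterosuperior condylar margin
    "e": (56.0, 34.0, 20.0),  # vertebral-artery dural entry
    "f": (52.0, 50.0, 50.0),  # jugular tubercle apex
    "g": (52.0, 46.0, 30.0),  # hypoglossal canal opening
    "h": (62.0, 48.0, 75.0),  # dome of the jugular bulb
    "i": (46.0, 72.0, 66.0),  # mid-clival target point
    "j": (48.0, 70.0, 38.0),  # inferior clival target point
    "k": (56.0, 68.0, 68.0),  # petroclival / jugular foramen target point
}


class PhantomSizingError(AnatomyError):
    """The requested grid cannot contain a structure at the requested size."""


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic subject.

    Size parameters are physical millimetres; ``sinus_dominance`` runs from 0
    (non-dominant, slender sigmoid-jugular system) to 1 (fully dominant).
    """

    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    va_radius_mm: float = 2.0
    sinus_dominance: float = 0.5
    cn11_height_mm: float = 6.0
    tubercle_size_mm: float = 7.0
    condyle_size_mm: float = 10.0
    jitter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise AnatomyError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise AnatomyError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        for name in ("va_radius_mm", "cn11_height_mm", "tubercle_size_mm", "condyle_size_mm"):
            if getattr(self, name) <= 0:
                raise AnatomyError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.sinus_dominance <= 1.0:
            raise AnatomyError(f"sinus_dominance must be in [0, 1], got {self.sinus_dominance}")
        if self.jitter_mm < 0:
            raise AnatomyError(f"jitter_mm must be >= 0, got {self.jitter_mm}")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise AnatomyError(f"seed must be a non-negative integer, got {self.seed!r}")

    def with_(self, **kwargs) -> "PhantomParams":
        return replace(self, **kwargs)

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing_mm)


def _check_fits(params: PhantomParams) -> None:
    extent = params.extent_mm
    min_extent = float(extent.min())
    requirements = [
        ("occipital condyle", 3.2 * params.condyle_size_mm),
        ("jugular tubercle", 4.0 * params.tubercle_size_mm),
        ("vertebral artery", 10.0 * params.va_radius_mm),
        ("accessory nerve (CN XI)", 2.5 * params.cn11_height_mm + 16.0),
        ("foramen magnum rim", 48.0 * min(1.0, min_extent / _REFERENCE_EXTENT) + 8.0),
    ]
    for structure, needed in requirements:
        if needed > min_extent:
            raise PhantomSizingError(
                f"grid extent {extent.tolist()} mm is too small to contain the "
                f"{structure} (needs about {needed:.0f} mm)"
            )


def _paint_ellipsoid(grid, X, Y, Z, center, semi, code) -> None:
    cx, cy, cz = center
    sx, sy, sz = semi
    mask = ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2 <= 1.0
    grid[mask] = code


def _paint_tube(grid, X, Y, Z, polyline, radius, code, spacing) -> None:
    """Capsule along a polyline; each segment processed in its bounding box."""
    pts = np.asarray(polyline, dtype=float)
    shape = np.array(grid.shape)
    for p0, p1 in zip(pts[:-1], pts[1:]):
        lo = np.minimum(p0, p1) - radius - spacing
        hi = np.maximum(p0, p1) + radius + spacing
        i0 = np.maximum(np.floor(lo / spacing), 0).astype(int)
        i1 = np.minimum(np.ceil(hi / spacing), shape - 1).astype(int)
        if np.any(i1 < i0):
            continue
        sl = (slice(i0[0], i1[0] + 1), slice(i0[1], i1[1] + 1), slice(i0[2], i1[2] + 1))
        x, y, z = X[sl], Y[sl], Z[sl]
        d = p1 - p0
        seg_len2 = float(d @ d)
        rx, ry, rz = x - p0[0], y - p0[1], z - p0[2]
        if seg_len2 == 0.0:
            dist2 = rx**2 + ry**2 + rz**2
        else:
            t = np.clip((rx * d[0] + ry * d[1] + rz * d[2]) / seg_len2, 0.0, 1.0)
            dist2 = (rx - t * d[0]) ** 2 + (ry - t * d[1]) ** 2 + (rz - t * d[2]) ** 2
        grid[sl][dist2 <= radius * radius] = code


def generate_phantom(params: PhantomParams) -> Tuple[LabelMap, LandmarkSet]:
    """Generate one synthetic subject: a label map and its landmark set.

    Deterministic: a pure function of ``params`` (including the seed).
    """
    _check_fits(params)
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(n) for n in params.grid_shape)
    spacing = np.asarray(params.spacing_mm, dtype=float)
    extent = params.extent_mm
    scale = extent / _REFERENCE_EXTENT  # per-axis anisotropic scale

    def at(x, y, z) -> np.ndarray:
        """Scale a nominal reference-frame point into this grid's physical frame."""
        return np.array([x, y, z]) * scale

    ii, jj, kk = np.indices(shape, dtype=np.float32)
    X = ii * spacing[0]
    Y = jj * spacing[1]
    Z = kk * spacing[2]
    grid = np.zeros(shape, dtype=np.int16)

    # --- brain (lowest precedence) ----------------------------------------
    _paint_ellipsoid(grid, X, Y, Z, at(34, 36, 62), at(23, 25, 25), CEREBELLUM)  # hemisphere
    _paint_ellipsoid(grid, X, Y, Z, at(51, 34, 58), at(10, 11, 11), CEREBELLUM)  # biventral lobule
    _paint_ellipsoid(grid, X, Y, Z, at(44, 48, 38), at(7, 8, 10), CEREBELLUM)    # tonsil
    # medulla ascending into the pons
    _paint_tube(grid, X, Y, Z, [at(42, 60, 4), at(42, 60, 52)], 8.5 * scale.mean(), BRAINSTEM, spacing)
    _paint_tube(grid, X, Y, Z, [at(42, 60, 52), at(40, 58, 90)], 9.5 * scale.mean(), BRAINSTEM, spacing)

    # --- cranial nerves ----------------------------------------------------
    h11 = params.cn11_height_mm
    nerves = [
        ([at(44, 58, 30), at(52, 46, 30)], 0.8),                     # CN XII to hypoglossal canal
        ([at(44, 57, 54), at(56, 54, 60)], 0.8),                     # CN IX
        ([at(44, 57, 58), at(57, 53, 62)], 0.8),                     # CN X
        ([at(42, 64, 68), at(46, 70, 74)], 0.7),                     # CN VI
        ([at(44, 60, 76), at(58, 50, 78)], 1.0),                     # CN VII/VIII bundle
    ]
    # CN XI: ascending rootlets toward the jugular foramen; the height
    # parameter raises the whole bundle
    cn11 = [at(44, 56, 30) + [0, 0, h11], at(55, 52, 52) + [0, 0, 0.6 * h11]]
    nerves.append((cn11, 0.9))
    for line, r in nerves:
        _paint_tube(grid, X, Y, Z, line, r, CRANIAL_NERVE, spacing)

    # --- veins -------------------------------------------------------------
    sinus_r = 1.2 + 4.3 * params.sinus_dominance
    sigmoid = [at(76, 24, 86), at(68, 34, 80), at(62, 42, 72), at(58, 46, 64), at(56, 49, 58)]
    _paint_tube(grid, X, Y, Z, sigmoid, sinus_r, VEIN, spacing)
    # jugular bulb at the foot of the sigmoid groove
    _paint_ellipsoid(grid, X, Y, Z, at(58, 46, 66),
                     (2.2 + 3.3 * params.sinus_dominance) * scale, VEIN)
    # inferior petrosal sinus along the petroclival fissure
    _paint_tube(grid, X, Y, Z, [at(50, 66, 60), at(53, 63, 60), at(56, 58, 63)], 1.8, VEIN, spacing)

    # --- arteries ----------------------------------------------------------
    va = [at(72, 28, 10), at(62, 34, 14), at(56, 34, 20), at(55, 48, 30), at(54, 56, 42), at(52, 63, 52)]
    _paint_tube(grid, X, Y, Z, va, params.va_radius_mm, ARTERY, spacing)
    _paint_tube(grid, X, Y, Z, [at(55, 48, 30), at(52, 50, 28), at(48, 52, 32)], 1.2, ARTERY, spacing)  # PICA
    _paint_tube(grid, X, Y, Z, [at(52, 63, 52), at(52, 58, 58), at(56, 54, 62)], 1.0, ARTERY, spacing)  # AICA

    # --- bone (highest precedence) ----------------------------------------
    grid[Z < 6.0 * scale[2]] = BONE                        # skull-base floor
    grid[Z > 90.0 * scale[2]] = BONE                       # petrous / tentorial roof
    grid[X > 88.0 * scale[0]] = BONE                       # lateral temporal wall
    grid[Y > 86.0 * scale[1]] = BONE                       # clival wall
    c = params.condyle_size_mm / 10.0
    _paint_ellipsoid(grid, X, Y, Z, at(58, 36, 10), (10 * c * scale[0], 12 * c * scale[1], 9 * c * scale[2]), BONE)
    # jugular process: bony shelf rising from the condyle toward the jugular foramen
    _paint_ellipsoid(grid, X, Y, Z, at(61, 37, 22), (7 * c * scale[0], 6 * c * scale[1], 7 * c * scale[2]), BONE)
    t = params.tubercle_size_mm / 7.0
    _paint_ellipsoid(grid, X, Y, Z, at(52, 50, 50), (7 * t * scale[0], 7 * t * scale[1], 6 * t * scale[2]), BONE)
    # foramen magnum rim: a flat annulus around the medulla
    rim_r = np.sqrt(((X - 46.0 * scale[0]) / scale[0]) ** 2 + ((Y - 58.0 * scale[1]) / scale[1]) ** 2)
    rim = (rim_r >= 17.0) & (rim_r <= 23.0) & (Z >= 6.0 * scale[2]) & (Z <= 13.0 * scale[2])
    grid[rim] = BONE

    labelmap = LabelMap(grid=grid, spacing_mm=spacing, origin_mm=np.zeros(3))

    # --- landmarks ---------------------------------------------------------
    lo, hi = labelmap.bounds_mm
    points = {}
    for key in sorted(DEFAULT_LANDMARK_FRACTIONS):
        base = at(*DEFAULT_LANDMARK_FRACTIONS[key])
        jitter = rng.normal(0.0, params.jitter_mm, size=3) if params.jitter_mm > 0 else np.zeros(3)
        points[key] = np.clip(base + jitter, lo + 0.5 * spacing, hi - 0.5 * spacing)
    landmarks = LandmarkSet(points)
    return labelmap, landmarks


def free_space_connected(
    labelmap: LabelMap, p_from: np.ndarray, p_to: np.ndarray, snap_mm: float = 8.0
) -> bool:
    """True if two physical points lie in the same connected free-space region.

    Each probe point is snapped to the nearest free-space voxel within
    ``snap_mm`` (probes may sit on a structure surface); returns False if no
    free space exists near a probe.
    """
    space = labelmap.grid == SPACE
    labels, _ = ndimage.label(space)

    def component(p):
        idx = np.round((np.asarray(p) - labelmap.origin_mm) / labelmap.spacing_mm).astype(int)
        idx = np.clip(idx, 0, np.array(labelmap.shape) - 1)
        if labels[tuple(idx)] != 0:
            return labels[tuple(idx)]
        reach = np.maximum(np.round(snap_mm / labelmap.spacing_mm).astype(int), 1)
        lo = np.maximum(idx - reach, 0)
        hi = np.minimum(idx + reach, np.array(labelmap.shape) - 1)
        sub = labels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        free = np.argwhere(sub != 0)
        if free.size == 0:
            return 0
        centers = (free + lo) * labelmap.spacing_mm + labelmap.origin_mm
        nearest = free[np.argmin(np.linalg.norm(centers - np.asarray(p), axis=1))]
        return sub[tuple(nearest)]

    a, b = component(p_from), component(p_to)
    return bool(a != 0 and a == b)
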