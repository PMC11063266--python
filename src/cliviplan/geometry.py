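"""Tetrahedron volumetry and per-tissue voxel accounting.

A corridor segment is the tetrahedron spanned by four landmarks.  Its
analytic volume is |det| / 6; the tissue content is counted by voxel-center
inclusion against a :class:`~cliviplan.anatomy.LabelMap`: a voxel belongs to
the tetrahedron iff its center does (boundary counts as inside, with a small
relative epsilon on the barycentric test).  Voxel-center inclusion keeps the
accounting exactly conservative -- the per-class volumes always sum to
``voxel_volume`` times the number of included centers -- and makes a clean
Monte-Carlo cross-check possible.  Partial-volume weighting is deliberately
not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .anatomy import CLASS_NAMES, LabelMap

__all__ = [
    "Tetrahedron",
    "DegenerateTetrahedronError",
    "tetra_volume",
    "point_in_tetra",
    "points_in_tetra",
    "tissue_volumes_in_tetra",
    "BARYCENTRIC_EPS",
]

#: Relative tolerance on barycentric coordinates: points with all coordinates
#: >= -BARYCENTRIC_EPS count as inside, so faces and vertices are inside.
BARYCENTRIC_EPS = 1e-9


class DegenerateTetrahedronError(ValueError):
    """Raised when an operation requires a non-degenerate tetrahedron."""


@dataclass(frozen=True)
class Tetrahedron:
    """Four vertices in mm.  Degenerate (coplanar) tetrahedra are allowed and
    simply have zero volume."""

    vertices: np.ndarray

    def __init__(self, vertices) -> None:
        arr = np.asarray(vertices, dtype=float)
        if arr.shape != (4, 3) or not np.all(np.isfinite(arr)):
            raise ValueError(f"tetrahedron needs 4 finite 3-D vertices, got shape {arr.shape}")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "vertices", arr)

    @classmethod
    def from_landmarks(cls, landmarks, ids) -> "Tetrahedron":
        return cls(np.stack([landmarks[i] for i in ids]))

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def edge_matrix(self) -> np.ndarray:
        v = self.vertices
        return (v[1:] - v[0]).T  # columns are edge vectors from vertex 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tetrahedron):
            return NotImplemented
        return np.array_equal(self.vertices, other.vertices)


def tetra_volume(t: Tetrahedron) -> float:
    """Analytic volume |det(v1-v0, v2-v0, v3-v0)| / 6 in mm^3."""
    return float(abs(np.linalg.det(t.edge_matrix())) / 6.0)


def _barycentric(points: np.ndarray, t: Tetrahedron) -> np.ndarray:
    """Barycentric coordinates of points w.r.t. t; shape (n, 4)."""
    m = t.edge_matrix()
    det = np.linalg.det(m)
    if abs(det) < 1e-300:
        raise DegenerateTetrahedronError(
            "tetrahedron is degenerate (coplanar vertices); barycentric "
            "coordinates are undefined"
        )
    rel = np.atleast_2d(points) - t.vertices[0]
    lam = np.linalg.solve(m, rel.T).T  # (n, 3): coords of vertices 1..3
    lam0 = 1.0 - lam.sum(axis=1, keepdims=True)
    return np.hstack([lam0, lam])


def points_in_tetra(points: np.ndarray, t: Tetrahedron, eps: float = BARYCENTRIC_EPS) -> np.ndarray:
    """Vectorised inclusion test; boundary points count as inside."""
    lam = _barycentric(np.asarray(points, dtype=float), t)
    return np.all(lam >= -eps, axis=1)

def point_in_tetra(p, t: Tetrahedron, eps: float = BARYCENTRIC_EPS) -> bool:
    """True iff all four barycentric coordinates of p are >= -eps."""
    return bool(points_in_tetra(np.asarray(p, dtype=float)[None, :], t, eps)[0])


def tissue_volumes_in_tetra(labelmap: LabelMap, t: Tetrahedron) -> Dict[int, float]:
    """Per-tissue-class volume (mm^3) of voxel centers inside the tetrahedron.

    Returns a dict mapping every tissue-class code to a volume; classes absent
    from the corridor map to 0.0.  Only the voxel bounding box of the
    tetrahedron is scanned.  Degenerate tetrahedra and tetrahedra that do not
    overlap the label map yield all-zero volumes.
    """
    zeros = {code: 0.0 for code in CLASS_NAMES}
    try:
        m = t.edge_matrix()
        if abs(np.linalg.det(m)) < 1e-300:
            return zeros
    except np.linalg.LinAlgError:  # pragma: no cover - det never raises here
        return zeros

    lo_idx = np.floor((t.vertices.min(axis=0) - labelmap.origin_mm) / labelmap.spacing_mm)
    hi_idx = np.ceil((t.vertices.max(axis=0) - labelmap.origin_mm) / labelmap.spacing_mm)
    lo = np.maximum(lo_idx, 0).astype(int)
    hi = np.minimum(hi_idx, np.array(labelmap.shape) - 1).astype(int)
    if np.any(hi < lo):
        return zeros

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    centers = labelmap.voxel_centers_mm((ii.ravel(), jj.ravel(), kk.ravel()))
    inside = points_in_tetra(centers, t)
    if not inside.any():
        return zeros
    sub = labelmap.grid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    labels = sub.ravel()[inside]
    counts = np.bincount(labels, minlength=max(CLASS_NAMES) + 1)
    vv = labelmap.voxel_volume
    return {code: float(counts[code]) * vv for code in CLASS_NAMES}
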