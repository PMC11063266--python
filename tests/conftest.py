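"""Shared fixtures and the independent Monte-Carlo volumetry oracle."""

from __future__ import annotations

import numpy as np
import pytest

from cliviplan import PhantomParams, generate_phantom
from cliviplan.topology import default_topology
from cliviplan.weighting import default_coefficients


@pytest.fixture(scope="session")
def topo():
    return default_topology()


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


#: Coarse but full-extent phantom: 48^3 voxels at 2 mm cover the same 96 mm
#: physical domain as the default grid, an order of magnitude faster.
COARSE = PhantomParams(grid_shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0), jitter_mm=0.0)


@pytest.fixture(scope="session")
def coarse_phantom():
    return generate_phantom(COARSE)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(jitter_mm=0.0))


def mc_tissue_volumes(labelmap, tetra, n, rng):
    """Monte-Carlo oracle: per-class volume from uniform points in the tetra.

    Samples barycentric weights ~ Dirichlet(1,1,1,1), classifies each point
    by its nearest voxel's label, and scales class fractions by the analytic
    tetra volume.  Independent of the bounding-box voxel-center scan it is
    used to check.
    """
    verts = tetra.vertices
    vol = abs(np.linalg.det((verts[1:] - verts[0]).T)) / 6.0
    w = rng.dirichlet(np.ones(4), size=n)
    pts = w @ verts
    idx = np.round((pts - labelmap.origin_mm) / labelmap.spacing_mm).astype(int)
    idx = np.clip(idx, 0, np.array(labelmap.shape) - 1)
    labels = labelmap.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    out = {}
    for code in range(8):
        frac = float((labels == code).mean())
        se = vol * np.sqrt(max(frac * (1.0 - frac), 1e-12) / n)
        out[code] = (vol * frac, se)
    return out


def boundary_shell_counts(labelmap, tetra, offset_mm):
    """Per-class counts of voxel centers in a shell around the tetra surface.

    Built from two homothetic copies of the tetrahedron offset by about
    ``offset_mm`` either side of each face; used to size the discretization
    term of the comparison standard error.
    """
    from cliviplan.geometry import points_in_tetra, tetra_volume

    verts = tetra.vertices
    cen = verts.mean(axis=0)
    vol = tetra_volume(tetra)

    def face_area(a, b, c):
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a))

    surf = sum(
        face_area(verts[i], verts[j], verts[k])
        for i, j, k in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))
    )
    insphere = 3.0 * vol / surf
    eps = offset_mm / insphere
    from cliviplan.geometry import Tetrahedron

    t_in = Tetrahedron(cen + (verts - cen) * (1.0 - eps))
    t_out = Tetrahedron(cen + (verts - cen) * (1.0 + eps))
    lo = np.maximum(np.floor((verts.min(0) - labelmap.origin_mm) / labelmap.spacing_mm) - 2, 0).astype(int)
    hi = np.minimum(
        np.ceil((verts.max(0) - labelmap.origin_mm) / labelmap.spacing_mm) + 2,
        np.array(labelmap.shape) - 1,
    ).astype(int)
    ii, jj, kk = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    centers = labelmap.voxel_centers_mm((ii.ravel(), jj.ravel(), kk.ravel()))
    shell = points_in_tetra(centers, t_out) & ~points_in_tetra(centers, t_in)
    labels = labelmap.grid[ii.ravel(), jj.ravel(), kk.ravel()][shell]
    return {code: int((labels == code).sum()) for code in range(8)}
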