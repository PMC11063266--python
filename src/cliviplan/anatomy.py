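"""Anatomical data model: tissue classes, voxel label maps and landmarks.

Everything downstream (corridor volumetry, risk weighting, planning) consumes
these three objects.  Conventions are fixed once here:

* coordinate frame is RAS (+x right, +y anterior, +z superior), millimetres;
* voxel ``(i, j, k)`` has its *center* at ``origin_mm + index * spacing_mm``;
* label maps hold small-integer tissue-class codes, with free operative
  space always coded 0.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Dict, Iterable, Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "TissueClass",
    "TISSUE_CLASSES",
    "SPACE",
    "BONE",
    "CEREBELLUM",
    "BRAINSTEM",
    "ARTERY",
    "VEIN",
    "CRANIAL_NERVE",
    "OTHER",
    "CLASS_NAMES",
    "NAME_TO_CODE",
    "LabelMap",
    "LandmarkSet",
    "read_labelmap",
    "write_labelmap",
    "read_landmarks",
    "write_landmarks",
    "AnatomyError",
    "FormatError",
]


class AnatomyError(ValueError):
    """Invalid anatomical data (bad codes, out-of-bounds landmarks, ...)."""


class FormatError(AnatomyError):
    """A file could not be interpreted as the expected format."""


@dataclass(frozen=True)
class TissueClass:
    """One tissue class: a small integer code and a canonical name."""

    code: int
    name: str


#: The seven scored tissue classes plus a spare "other" bucket.  Free space is
#: always code 0; the remaining classes collapse named structures to the level
#: at which risk coefficients are assigned (e.g. VA, PICA and AICA are all
#: "artery"; sigmoid sinus, jugular bulb and inferior petrosal sinus are all
#: "vein").
TISSUE_CLASSES: tuple[TissueClass, ...] = (
    TissueClass(0, "space"),
    TissueClass(1, "bone"),
    TissueClass(2, "cerebellum"),
    TissueClass(3, "brainstem"),
    TissueClass(4, "artery"),
    TissueClass(5, "vein"),
    TissueClass(6, "cranial_nerve"),
    TissueClass(7, "other"),
)

SPACE, BONE, CEREBELLUM, BRAINSTEM, ARTERY, VEIN, CRANIAL_NERVE, OTHER = (
    t.code for t in TISSUE_CLASSES
)
CLASS_NAMES: Dict[int, str] = {t.code: t.name for t in TISSUE_CLASSES}
NAME_TO_CODE: Dict[str, int] = {t.name: t.code for t in TISSUE_CLASSES}
_VALID_CODES = frozenset(CLASS_NAMES)


@dataclass
class LabelMap:
    """A 3-D voxel grid of tissue-class codes with physical geometry.

    Parameters
    ----------
    grid
        Integer array of shape ``(nx, ny, nz)`` holding tissue-class codes.
    spacing_mm
        Per-axis voxel size in mm, all entries positive.
    origin_mm
        Physical position (mm, RAS) of the *center* of voxel ``(0, 0, 0)``.
    """

    grid: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise AnatomyError(f"label grid must be 3-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise FormatError(f"label grid must be integer, got dtype {self.grid.dtype}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise AnatomyError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        if self.origin_mm.shape != (3,):
            raise AnatomyError(f"origin_mm must be length 3, got {self.origin_mm}")
        bad = np.setdiff1d(np.unique(self.grid), sorted(_VALID_CODES))
        if bad.size:
            raise FormatError(
                f"label grid contains unknown tissue codes {bad.tolist()}; "
                f"valid codes are {sorted(_VALID_CODES)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (product of the spacings)."""
        return float(np.prod(self.spacing_mm))

    @property
    def bounds_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent covered by voxel volumes: (lower, upper) corners."""
        lo = self.origin_mm - 0.5 * self.spacing_mm
        hi = self.origin_mm + (np.array(self.shape) - 0.5) * self.spacing_mm
        return lo, hi

    def voxel_centers_mm(self, index_arrays: Iterable[np.ndarray]) -> np.ndarray:
        """Physical coordinates of voxel centers for index arrays (i, j, k)."""
        idx = np.stack([np.asarray(a, dtype=float) for a in index_arrays], axis=-1)
        return self.origin_mm + idx * self.spacing_mm

    def contains_point(self, p: np.ndarray) -> bool:
        lo, hi = self.bounds_mm
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def class_volume_mm3(self, code: int) -> float:
        """Total labelled volume of a tissue class, exact voxel count x volume."""
        return float(np.count_nonzero(self.grid == code)) * self.voxel_volume

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return (
            np.array_equal(self.grid, other.grid)
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


class LandmarkSet:
    """Named 3-D points (mm) in the same RAS frame as a :class:`LabelMap`.

    Behaves like a read-only mapping from landmark id to a length-3 float
    array.  Ids are arbitrary strings; the bundled default topology uses the
    single letters ``a`` through ``k``.
    """

    def __init__(self, points: Mapping[str, Iterable[float]]):
        self._points: Dict[str, np.ndarray] = {}
        for key, value in points.items():
            key = str(key)
            if key in self._points:
                raise AnatomyError(f"duplicate landmark id {key!r}")
            arr = np.asarray(tuple(value), dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise AnatomyError(f"landmark {key!r} must be 3 finite coordinates, got {arr}")
            self._points[key] = arr

    def __getitem__(self, key: str) -> np.ndarray:
        return self._points[key]

    def __contains__(self, key: str) -> bool:
        return key in self._points

    def __iter__(self):
        return iter(self._points)

    def __len__(self) -> int:
        return len(self._points)

    def ids(self) -> list[str]:
        return sorted(self._points)

    def items(self):
        return self._points.items()

    def asdict(self) -> Dict[str, list[float]]:
        return {k: [float(x) for x in v] for k, v in sorted(self._points.items())}

    def require(self, ids: Iterable[str]) -> None:
        """Raise if any of the given landmark ids is missing."""
        missing = sorted(set(ids) - set(self._points))
        if missing:
            raise AnatomyError(f"missing landmark ids: {missing}")

    def check_inside(self, labelmap: LabelMap) -> None:
        """Raise if any landmark lies outside the label map's physical bounds."""
        outside = sorted(k for k, p in self._points.items() if not labelmap.contains_point(p))
        if outside:
            raise AnatomyError(f"landmarks outside label map bounds: {outside}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        return set(self._points) == set(other._points) and all(
            np.array_equal(self._points[k], other._points[k]) for k in self._points
        )

    def __repr__(self) -> str:
        return f"LandmarkSet({len(self)} landmarks: {', '.join(self.ids())})"


# ---------------------------------------------------------------------------
# File I/O


def write_labelmap(labelmap: LabelMap, path: str | FsPath) -> None:
    """Write a label map as NIfTI-1 with an RAS affine built from its geometry."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(labelmap.spacing_mm)
    affine[:3, 3] = labelmap.origin_mm
    img = nib.Nifti1Image(labelmap.grid.astype(np.int16), affine)
    img.header.set_zooms(tuple(labelmap.spacing_mm))
    nib.save(img, str(path))


def read_labelmap(path: str | FsPath) -> LabelMap:
    """Read a NIfTI-1 label map; rejects non-integer data and unknown codes."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError(f"{path}: label map data is not integer-valued")
        data = np.round(data).astype(np.int16)
    affine = img.affine
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(affine[:3, 3], dtype=float)
    return LabelMap(grid=data, spacing_mm=spacing, origin_mm=origin)


def write_landmarks(landmarks: LandmarkSet, path: str | FsPath) -> None:
    """Write landmarks as JSON (id -> [x, y, z]) or CSV (id,x,y,z) by suffix."""
    path = FsPath(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y", "z"])
            for key, p in sorted(landmarks.items()):
                writer.writerow([key, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    else:
        with open(path, "w") as fh:
            json.dump(landmarks.asdict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_landmarks(path: str | FsPath) -> LandmarkSet:
    """Read landmarks from JSON (id -> [x, y, z]) or CSV (id,x,y,z)."""
    path = FsPath(path)
    if path.suffix.lower() == ".csv":
        points: Dict[str, list[float]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:4]] != ["id", "x", "y", "z"]:
                raise FormatError(f"{path}: expected CSV header 'id,x,y,z'")
            for row in reader:
                if not row or not "".join(row).strip():
                    continue
                if len(row) < 4:
                    raise FormatError(f"{path}: short CSV row {row!r}")
                key = row[0].strip()
                if key in points:
                    raise AnatomyError(f"{path}: duplicate landmark id {key!r}")
                points[key] = [float(v) for v in row[1:4]]
        return LandmarkSet(points)
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a JSON object of id -> [x, y, z]")
    return LandmarkSet(raw)
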