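"""Injury risk, surgical freedom and net path weight.

For a corridor tetrahedron with per-class tissue volumes ``V_c``:

* injury risk  = sum over tissue classes of ``V_c * r_c`` where ``r_c`` is the
  class risk coefficient (free space has coefficient 0 by definition);
* surgical freedom = ``V_space``, the free operative volume;
* weight = injury risk - surgical freedom.

Weights may be negative (a roomy corridor is a benefit) and are never
clamped.  Risk and freedom share one scale (mm^3 and coefficient-weighted
mm^3) so the subtraction is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path as FsPath
from typing import Dict, Mapping

import yaml

from .anatomy import CLASS_NAMES, NAME_TO_CODE, SPACE, LandmarkSet, LabelMap
from .geometry import Tetrahedron, tissue_volumes_in_tetra
from .topology import Path

__all__ = [
    "RiskCoefficients",
    "WeightBreakdown",
    "CoefficientError",
    "injury_risk",
    "surgical_freedom",
    "path_weight",
    "default_coefficients",
    "load_coefficients",
]


class CoefficientError(ValueError):
    """Invalid or incomplete risk-coefficient table."""


@dataclass(frozen=True)
class RiskCoefficients:
    """Per-tissue-class dimensionless risk coefficients; space is fixed at 0."""

    by_code: Dict[int, float]

    def __post_init__(self) -> None:
        coeffs = dict(self.by_code)
        if coeffs.get(SPACE, 0.0) != 0.0:
            raise CoefficientError("the free-space coefficient is fixed at 0")
        coeffs[SPACE] = 0.0
        for code, value in coeffs.items():
            if code not in CLASS_NAMES:
                raise CoefficientError(f"unknown tissue code {code!r} in coefficients")
            if not (value >= 0.0):
                raise CoefficientError(
                    f"risk coefficient for {CLASS_NAMES[code]!r} must be >= 0, got {value}"
                )
        object.__setattr__(self, "by_code", coeffs)

    @classmethod
    def from_names(cls, by_name: Mapping[str, float]) -> "RiskCoefficients":
        unknown = sorted(set(by_name) - set(NAME_TO_CODE))
        if unknown:
            raise CoefficientError(f"unknown tissue class names {unknown}")
        return cls({NAME_TO_CODE[n]: float(v) for n, v in by_name.items()})

    def coefficient(self, code: int) -> float:
        if code not in self.by_code:
            raise CoefficientError(
                f"no risk coefficient configured for tissue class "
                f"{CLASS_NAMES.get(code, code)!r}"
            )
        return self.by_code[code]

    def asdict(self) -> Dict[str, float]:
        return {CLASS_NAMES[c]: float(v) for c, v in sorted(self.by_code.items())}

    def scaled(self, k: float) -> "RiskCoefficients":
        return RiskCoefficients({c: v * k for c, v in self.by_code.items()})


@dataclass(frozen=True)
class WeightBreakdown:
    """Full per-path accounting: volumes, risk, freedom and net weight."""

    path_id: str
    tissue_volumes: Dict[int, float]
    injury_risk: float
    surgical_freedom: float
    weight: float

    def volumes_by_name(self) -> Dict[str, float]:
        return {CLASS_NAMES[c]: v for c, v in sorted(self.tissue_volumes.items())}


def injury_risk(volumes: Mapping[int, float], coeffs: RiskCoefficients) -> float:
    """Weighted tissue volume: sum of volume(class) * coefficient(class).

    Raises :class:`CoefficientError` if a class with positive volume has no
    configured coefficient.
    """
    total = 0.0
    for code, volume in volumes.items():
        if code == SPACE:
            continue
        if volume == 0.0 and code not in coeffs.by_code:
            continue
        total += volume * coeffs.coefficient(code)
    return total


def surgical_freedom(volumes: Mapping[int, float]) -> float:
    """Free operative volume: the volume of the 'space' class."""
    return float(volumes.get(SPACE, 0.0))


def path_weight(
    labelmap: LabelMap,
    landmarks: LandmarkSet,
    path: Path,
    coeffs: RiskCoefficients,
) -> WeightBreakdown:
    """Score one corridor segment: weight = injury risk - surgical freedom."""
    landmarks.require(path.landmarks)
    tetra = Tetrahedron.from_landmarks(landmarks, path.landmarks)
    volumes = tissue_volumes_in_tetra(labelmap, tetra)
    risk = injury_risk(volumes, coeffs)
    freedom = surgical_freedom(volumes)
    return WeightBreakdown(
        path_id=path.id,
        tissue_volumes=volumes,
        injury_risk=risk,
        surgical_freedom=freedom,
        weight=risk - freedom,
    )


def load_coefficients(source: str | FsPath | Mapping[str, float]) -> RiskCoefficients:
    """Load a coefficient table from YAML (class name -> float) or a mapping."""
    if isinstance(source, (str, FsPath)):
        raw = yaml.safe_load(FsPath(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise CoefficientError("coefficient config must map class names to numbers")
    return RiskCoefficients.from_names({str(k): float(v) for k, v in raw.items()})


def default_coefficients() -> RiskCoefficients:
    """The bundled default coefficient table (severity-ordered; see data/)."""
    ref = resources.files("cliviplan").joinpath("data/default_coefficients.yaml")
    with resources.as_file(ref) as path:
        return load_coefficients(path)
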