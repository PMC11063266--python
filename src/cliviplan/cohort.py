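"""Cohort simulation: screen many synthetic subjects and tabulate winners.

Mirrors the screening workflow on patient-derived models: draw anatomical
variation (vertebral-artery caliber with a hypoplasia mass point, sigmoid-
sinus dominance, CN XI height, bony prominence sizes, landmark jitter),
generate one phantom per subject, run the full planner on each, and count
which labelled approach wins.  Per-subject RNG streams are derived from the
master seed by subject index, so extending a cohort never reshuffles earlier
subjects.

The simulated frequency ordering (ITA most common, STA rare) reproduces the
ordinal structure of real-cohort screening; the exact percentages of any
patient series depend on real anatomy and are out of the phantoms' reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path as FsPath
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .anatomy import AnatomyError
from .phantom import PhantomParams, generate_phantom
from .planner import PlanResult, compute_all_weights, rank_plans
from .topology import CorridorTopology
from .weighting import RiskCoefficients

__all__ = [
    "VariationDistribution",
    "CohortResult",
    "SubjectOutcome",
    "simulate_cohort",
    "sensitivity_sweep",
    "default_variation",
    "load_variation",
]


@dataclass(frozen=True)
class VariationDistribution:
    """Samplers for :class:`PhantomParams`, fully determined by the seed.

    ``va_radius`` is a two-component mixture: with probability
    ``va_hypoplasia_prob`` the artery is hypoplastic (fixed small caliber),
    otherwise a truncated normal.  ``sinus_dominance`` is Beta-distributed.
    """

    seed: int = 7
    va_hypoplasia_prob: float = 0.15
    va_hypoplasia_radius_mm: float = 0.8
    va_radius_mean_mm: float = 2.1
    va_radius_sd_mm: float = 1.0
    va_radius_min_mm: float = 0.5
    va_radius_max_mm: float = 4.5
    sinus_dominance_alpha: float = 2.5
    sinus_dominance_beta: float = 1.5
    cn11_height_mean_mm: float = 6.0
    cn11_height_sd_mm: float = 2.0
    cn11_height_min_mm: float = 1.0
    cn11_height_max_mm: float = 14.0
    tubercle_size_mean_mm: float = 7.0
    tubercle_size_sd_mm: float = 0.8
    condyle_size_mean_mm: float = 10.0
    condyle_size_sd_mm: float = 1.0
    jitter_mm: float = 1.0
    base: PhantomParams = field(default_factory=PhantomParams)

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise AnatomyError(f"seed must be a non-negative integer, got {self.seed!r}")
        if not 0.0 <= self.va_hypoplasia_prob <= 1.0:
            raise AnatomyError("va_hypoplasia_prob must be in [0, 1]")

    def subject_params(self, index: int) -> PhantomParams:
        """Draw the phantom parameters of one subject (pure in seed, index)."""
        rng = np.random.default_rng([int(self.seed), int(index)])

        def truncated(mean, sd, lo, hi):
            for _ in range(64):
                v = rng.normal(mean, sd)
                if lo <= v <= hi:
                    return float(v)
            return float(np.clip(mean, lo, hi))

        if rng.random() < self.va_hypoplasia_prob:
            va = self.va_hypoplasia_radius_mm
        else:
            va = truncated(self.va_radius_mean_mm, self.va_radius_sd_mm,
                           self.va_radius_min_mm, self.va_radius_max_mm)
        dominance = float(rng.beta(self.sinus_dominance_alpha, self.sinus_dominance_beta))
        cn11 = truncated(self.cn11_height_mean_mm, self.cn11_height_sd_mm,
                         self.cn11_height_min_mm, self.cn11_height_max_mm)
        tub = truncated(self.tubercle_size_mean_mm, self.tubercle_size_sd_mm,
                        0.5 * self.tubercle_size_mean_mm, 1.5 * self.tubercle_size_mean_mm)
        con = truncated(self.condyle_size_mean_mm, self.condyle_size_sd_mm,
                        0.5 * self.condyle_size_mean_mm, 1.5 * self.condyle_size_mean_mm)
        seed = int(rng.integers(0, 2**31 - 1))
        return self.base.with_(
            va_radius_mm=va,
            sinus_dominance=dominance,
            cn11_height_mm=cn11,
            tubercle_size_mm=tub,
            condyle_size_mm=con,
            jitter_mm=self.jitter_mm,
            seed=seed,
        )


@dataclass(frozen=True)
class SubjectOutcome:
    """Audit record for one simulated subject."""

    index: int
    params: PhantomParams
    winner_plan_id: str
    winner_label: str
    total_weight: float


@dataclass(frozen=True)
class CohortResult:
    """Winner tabulation over a simulated cohort."""

    n: int
    subjects: Tuple[SubjectOutcome, ...]
    frequency: Dict[str, Tuple[int, float]]  # label -> (count, percent)

    def counts(self) -> Dict[str, int]:
        return {label: c for label, (c, _) in self.frequency.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject": s.index,
                    "winner_plan": s.winner_plan_id,
                    "winner_label": s.winner_label,
                    "total_weight": s.total_weight,
                    "va_radius_mm": s.params.va_radius_mm,
                    "sinus_dominance": s.params.sinus_dominance,
                    "cn11_height_mm": s.params.cn11_height_mm,
                }
                for s in self.subjects
            ]
        )


def _plan_subject(params: PhantomParams, topology: CorridorTopology,
                  coeffs: RiskCoefficients) -> List[PlanResult]:
    labelmap, landmarks = generate_phantom(params)
    weights = compute_all_weights(labelmap, landmarks, topology, coeffs)
    return rank_plans(topology, weights, landmarks)


def simulate_cohort(
    dist: VariationDistribution,
    n: int,
    topology: CorridorTopology,
    coeffs: RiskCoefficients,
) -> CohortResult:
    """Plan ``n`` independent synthetic subjects and tabulate winning labels."""
    if n < 1:
        raise AnatomyError(f"cohort size must be >= 1, got {n}")
    subjects: List[SubjectOutcome] = []
    for i in range(n):
        params = dist.subject_params(i)
        try:
            ranking = _plan_subject(params, topology, coeffs)
        except Exception as exc:
            raise RuntimeError(f"planning failed for subject {i}: {exc}") from exc
        winner = ranking[0]
        subjects.append(
            SubjectOutcome(
                index=i,
                params=params,
                winner_plan_id=winner.plan_id,
                winner_label=winner.approach_label,
                total_weight=winner.total_weight,
            )
        )
    counts: Dict[str, int] = {}
    for s in subjects:
        counts[s.winner_label] = counts.get(s.winner_label, 0) + 1
    frequency = {
        label: (count, 100.0 * count / n) for label, count in sorted(counts.items())
    }
    return CohortResult(n=n, subjects=tuple(subjects), frequency=frequency)


def sensitivity_sweep(
    base: PhantomParams,
    parameter: str,
    grid: Sequence[float],
    topology: CorridorTopology,
    coeffs: RiskCoefficients,
) -> pd.DataFrame:
    """Re-plan one phantom while sweeping a single parameter.

    Everything else (including the seed) is held fixed.  Returns a DataFrame
    with one row per grid value: the winning plan/label and the total weight
    of every enumerated plan (columns ``weight:<plan_id>``).
    """
    if parameter not in PhantomParams.__dataclass_fields__:
        raise AnatomyError(
            f"unknown phantom parameter {parameter!r}; valid: "
            f"{sorted(PhantomParams.__dataclass_fields__)}"
        )
    rows = []
    for value in grid:
        params = base.with_(**{parameter: value})
        ranking = _plan_subject(params, topology, coeffs)
        row: Dict[str, object] = {
            parameter: value,
            "winner_plan": ranking[0].plan_id,
            "winner_label": ranking[0].approach_label,
        }
        for r in ranking:
            row[f"weight:{r.plan_id}"] = r.total_weight
        rows.append(row)
    return pd.DataFrame(rows)


def load_variation(source: str | FsPath | Mapping) -> VariationDistribution:
    """Load a variation distribution from YAML or a mapping."""
    if isinstance(source, (str, FsPath)):
        raw = yaml.safe_load(FsPath(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, Mapping):
        raise AnatomyError("variation config must be a mapping")
    known = set(VariationDistribution.__dataclass_fields__) - {"base"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise AnatomyError(f"unknown variation parameters {unknown}")
    kwargs = {k: (int(v) if k == "seed" else float(v)) for k, v in raw.items()}
    return VariationDistribution(**kwargs)


def default_variation() -> VariationDistribution:
    """The bundled default variation distribution (frozen seed)."""
    ref = resources.files("cliviplan").joinpath("data/default_variation.yaml")
    with resources.as_file(ref) as path:
        return load_variation(path)
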