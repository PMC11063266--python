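"""Evaluation statistics: exact Fisher 2x2 test and Spearman correlation.

The two statistics behind the headline evaluation numbers are implemented
with explicit, documented conventions:

* ``fisher_exact_2x2`` -- the exact hypergeometric two-sided p-value under
  the "sum of small p" convention: the probabilities of all tables sharing
  the observed margins whose point probability does not exceed that of the
  observed table are summed.  (Mid-p and doubling conventions differ; the
  sum-of-small-p convention is the one consistent with standard software.)
  Accumulation runs through log-space point probabilities so large margins
  neither overflow nor underflow to exactly 0.

* ``spearman_rho_ci`` -- Spearman's rho as the Pearson correlation of
  average ranks (ties averaged), with a confidence interval from the Fisher
  z-transform using the large-sample standard error 1/sqrt(n - 3).  The
  interval method is tagged in the result so it is never silently compared
  against intervals computed by other methods (e.g. bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ContingencyTable2x2",
    "CorrelationResult",
    "StatsError",
    "fisher_exact_2x2",
    "spearman_rho_ci",
]


class StatsError(ValueError):
    """Undefined statistic for the given input."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows are conditions (e.g. pre/post-instruction), columns
    are outcomes (e.g. satisfactory / not satisfactory)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise StatsError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise StatsError("contingency table is all zero")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)


def _log_pmf(x: int, n: int, K: int, N1: int) -> float:
    """log P(X = x) for X ~ Hypergeometric(n, K, N1): x successes in the
    first row when column-1 total is K and row-1 total is N1."""
    return float(
        gammaln(K + 1) - gammaln(x + 1) - gammaln(K - x + 1)
        + gammaln(n - K + 1) - gammaln(N1 - x + 1) - gammaln(n - K - (N1 - x) + 1)
        - (gammaln(n + 1) - gammaln(N1 + 1) - gammaln(n - N1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Exact two-sided Fisher p-value ("sum of small p" convention).

    Conditions on both margins; sums the hypergeometric probabilities of all
    tables at least as extreme (point probability <= observed, with a tiny
    relative tolerance against floating-point equality artefacts).
    Raises :class:`StatsError` when a margin is zero (the test is undefined:
    only one table is possible).
    """
    n = table.a + table.b + table.c + table.d
    N1 = table.a + table.b
    K = table.a + table.c
    if 0 in table.row_margins or 0 in table.col_margins:
        raise StatsError("Fisher exact test undefined: a margin is zero")
    lo = max(0, N1 - (n - K))
    hi = min(K, N1)
    log_obs = _log_pmf(table.a, n, K, N1)
    logs = np.array([_log_pmf(x, n, K, N1) for x in range(lo, hi + 1)])
    keep = logs <= log_obs + 1e-7
    # log-sum-exp over the kept tables
    m = logs[keep].max()
    p = float(np.exp(m) * np.exp(logs[keep] - m).sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with a tagged confidence interval."""

    rho: float
    n: int
    ci_low: float
    ci_high: float
    ci_level: float
    ci_method: str = "fisher-z"


def spearman_rho_ci(x, y, level: float = 0.95) -> CorrelationResult:
    """Spearman's rho with a Fisher-z confidence interval.

    rho is the Pearson correlation of average ranks (ties averaged); the
    interval is ``tanh(atanh(rho) +/- z * 1/sqrt(n-3))``, clipped to
    [-1, 1] and tagged ``"fisher-z"``.  Requires n >= 4 and non-constant
    inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError(f"x and y must be equal-length 1-D vectors, got {x.shape} and {y.shape}")
    n = x.size
    if n < 4:
        raise StatsError(f"need at least 4 pairs, got {n}")
    if not (0.0 < level < 1.0):
        raise StatsError(f"confidence level must be in (0, 1), got {level}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) == 1.0:
        lo_v, hi_v = rho, rho  # atanh diverges; the interval degenerates
    else:
        z = float(sps.norm.ppf(0.5 + level / 2.0))
        se = 1.0 / np.sqrt(n - 3)
        zr = np.arctanh(rho)
        lo_v, hi_v = float(np.tanh(zr - z * se)), float(np.tanh(zr + z * se))
    return CorrelationResult(rho=rho, n=int(n), ci_low=lo_v, ci_high=hi_v, ci_level=level)
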