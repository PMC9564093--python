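"""Cohort-level statistics: 2x2 chi-square, bootstrap LLR tests, exclusion.

Three routine tools used throughout the analyses:

* Pearson chi-square on a 2x2 generalizer-count table, *without*
  continuity correction (df = 1);
* a one-sided nonparametric bootstrap test on the difference in mean LLR
  between two independent groups;
* outlier exclusion of low training performers at 3 scaled median
  absolute deviations (scale constant b = 1.4826) below the
  within-condition median of second-half training accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .task_env import CORRECT_RADIUS_PX  # noqa: F401  (re-exported context)

__all__ = [
    "MAD_SCALE",
    "MAD_THRESHOLD",
    "ContingencyTable2x2",
    "ExclusionReport",
    "chi_square_2x2",
    "bootstrap_mean_diff",
    "mad_exclusion",
]

logger = logging.getLogger(__name__)

MAD_SCALE: float = 1.4826
MAD_THRESHOLD: float = 3.0

#: Absolute accuracy floor used only when the within-condition MAD is 0.
DEGENERATE_MAD_FLOOR: float = 0.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) / (c, d): rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("row totals must be positive")

    @classmethod
    def from_successes(cls, k1: int, n1: int, k2: int, n2: int) -> "ContingencyTable2x2":
        """Rows (k1 of n1) vs (k2 of n2)."""
        return cls(k1, n1 - k1, k2, n2 - k2)


def chi_square_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (df = 1) and its p-value."""
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("zero column total: statistic undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bootstrap_mean_diff(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_resamples: int = 10_000,
    rng_seed: int = 0,
) -> float:
    """One-sided bootstrap p-value for mean(group_a) > mean(group_b).

    Each group is resampled with replacement ``n_resamples`` times; the
    p-value is the proportion of resampled mean differences <= 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(rng_seed)
    means_a = rng.choice(a, size=(n_resamples, a.size), replace=True).mean(axis=1)
    means_b = rng.choice(b, size=(n_resamples, b.size), replace=True).mean(axis=1)
    return float(np.mean(means_a - means_b <= 0.0))


@dataclass
class ExclusionReport:
    """Per-condition MAD exclusion of low training performers."""

    median: dict[str, float]
    mad: dict[str, float]
    threshold: dict[str, float]
    excluded: dict[str, list[str]]
    degenerate_mad: dict[str, bool]

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.excluded.values())


def mad_exclusion(
    accuracies_per_condition: Mapping[str, Mapping[str, float]],
) -> ExclusionReport:
    """Flag participants whose training accuracy is an extreme low outlier.

    ``accuracies_per_condition`` maps condition name -> {participant id
    -> fraction of second-half (blocks 8-14) training responses within
    60 px of truth}.  Within each condition the median m and
    MAD = 1.4826 * median(|x - m|) are computed and participants with
    accuracy < m - 3 * MAD are excluded.  When the MAD degenerates to 0
    the rule would exclude nobody however poor; in that case
    participants strictly below the median *and* below an absolute floor
    of 0.5 are flagged, loudly.
    """
    median: dict[str, float] = {}
    mad: dict[str, float] = {}
    threshold: dict[str, float] = {}
    excluded: dict[str, list[str]] = {}
    degenerate: dict[str, bool] = {}
    for cond, accs in accuracies_per_condition.items():
        ids = list(accs)
        x = np.asarray([accs[i] for i in ids], dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError(f"accuracies in condition {cond!r} must lie in [0, 1]")
        m = float(np.median(x))
        d = MAD_SCALE * float(np.median(np.abs(x - m)))
        median[cond] = m
        mad[cond] = d
        if d > 0:
            thr = m - MAD_THRESHOLD * d
            degenerate[cond] = False
        else:
            thr = min(m, DEGENERATE_MAD_FLOOR)
            degenerate[cond] = True
            logger.warning(
                "condition %r has zero MAD; falling back to excluding "
                "accuracies below min(median, %.2f)",
                cond,
                DEGENERATE_MAD_FLOOR,
            )
        threshold[cond] = thr
        excluded[cond] = [i for i, v in zip(ids, x) if v < thr]
    return ExclusionReport(
        median=median,
        mad=mad,
        threshold=threshold,
        excluded=excluded,
        degenerate_mad=degenerate,
    )
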