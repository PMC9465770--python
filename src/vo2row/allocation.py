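"""Matched random hold-out allocation by rejection sampling.

Repeatedly draws a uniformly random validation subgroup of size k
(without replacement) and accepts the first draw for which every
matching variable shows no significant mean difference between the
subgroup and the remaining athletes (two-sided p > alpha on each
variable).  This mirrors the common spreadsheet practice of re-drawing a
hold-out group until it is statistically indistinguishable from the
development group on the matching anthropometrics.

The comparison is subgroup vs *remainder* (e.g. 13 vs 106), and the test
is Welch's unequal-variance t by default (a pooled-variance flag is
provided).  Degenerate samples with zero variance on both sides compare
as p = 1 when the means are equal and p = 0 otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort

__all__ = [
    "AllocationResult",
    "AllocationError",
    "mean_difference_test",
    "allocate_matched",
    "split_cohort",
]

log = logging.getLogger(__name__)


class AllocationError(RuntimeError):
    """No acceptable split found within the iteration cap."""

    def __init__(self, message: str, best_pvalues: dict[str, float]):
        super().__init__(message)
        self.best_pvalues = best_pvalues


def mean_difference_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample mean-difference test.

    Welch's unequal-variance t by default (``equal_var=True`` switches
    to the pooled-variance Student t).  Returns (t, df, p).  If both
    samples have zero variance the test is degenerate: p = 1 when the
    means agree, p = 0 when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        df = float(x.size + y.size - 2)
        if np.mean(x) == np.mean(y):
            return 0.0, df, 1.0
        return math.inf, df, 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = float(x.size + y.size - 2)
    else:  # Welch–Satterthwaite
        a, b = vx / x.size, vy / y.size
        df = (a + b) ** 2 / (a**2 / (x.size - 1) + b**2 / (y.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


@dataclass(frozen=True)
class AllocationResult:
    """An accepted development/validation split.

    ``matching_pvalues`` are the per-variable p-values of the accepted
    draw; each exceeds the alpha used.  The union of the two id sets is
    the input cohort and their intersection is empty.
    """

    development_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    matching_pvalues: dict[str, float]
    iterations_used: int
    seed: Optional[int]
    alpha: float

    def to_dict(self) -> dict:
        return {
            "development_ids": list(self.development_ids),
            "validation_ids": list(self.validation_ids),
            "matching_pvalues": dict(self.matching_pvalues),
            "iterations_used": self.iterations_used,
            "seed": self.seed,
            "alpha": self.alpha,
        }


def allocate_matched(
    cohort: Cohort,
    k: int,
    matching_vars: Sequence[str] = ("lean_body_mass", "fat_pct"),
    alpha: float = 0.05,
    seed: Optional[int] = None,
    max_iter: int = 10_000,
    equal_var: bool = False,
) -> AllocationResult:
    """Draw validation subgroups of size k until one matches the remainder.

    Subsets are uniform without replacement; acceptance requires p >
    ``alpha`` simultaneously on every matching variable.  Deterministic
    for a fixed seed.  Raises :class:`AllocationError` after
    ``max_iter`` rejected draws, reporting the best draw's p-values.
    """
    n = len(cohort)
    if k < 2:
        raise ValueError(f"k must be ≥ 2, got {k}")
    if k >= n:
        raise ValueError(f"k ({k}) must be smaller than the cohort size ({n})")
    matching_vars = tuple(matching_vars)
    columns = {v: cohort.values(v) for v in matching_vars}
    for v, col in columns.items():
        if col.size != n:
            raise ValueError(f"matching variable {v!r} missing for some records")

    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort.ids())
    best_pvalues: dict[str, float] = {}
    best_min_p = -1.0
    for iteration in range(1, max_iter + 1):
        take = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[take] = True
        pvalues = {}
        for v, col in columns.items():
            _, _, p = mean_difference_test(col[mask], col[~mask], equal_var=equal_var)
            pvalues[v] = p
        min_p = min(pvalues.values())
        if min_p > best_min_p:
            best_min_p, best_pvalues = min_p, pvalues
        if all(p > alpha for p in pvalues.values()):
            log.info(
                "allocation accepted after %d iteration(s); p-values: %s",
                iteration,
                {v: round(p, 4) for v, p in pvalues.items()},
            )
            return AllocationResult(
                development_ids=tuple(ids[~mask]),
                validation_ids=tuple(ids[mask]),
                matching_pvalues=pvalues,
                iterations_used=iteration,
                seed=seed if isinstance(seed, int) else None,
                alpha=alpha,
            )
    raise AllocationError(
        f"no acceptable split in {max_iter} draws "
        f"(best draw's p-values: {best_pvalues})",
        best_pvalues,
    )


def split_cohort(
    cohort: Cohort, result: AllocationResult
) -> tuple[Cohort, Cohort]:
    """(development, validation) sub-cohorts of an accepted allocation."""
    dev = cohort.subset(result.development_ids, label=f"{cohort.label}-development")
    val = cohort.subset(result.validation_ids, label=f"{cohort.label}-validation")
    return dev, val
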