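"""Predictability and baseline-imbalance metrics.

Predictability is the fraction of allocations classified deterministic: an
observer who knows the minimisation algorithm and every previous allocation
could have named the arm with certainty.  Ties (resolved by simple
randomisation) and random twists count as unpredictable.  This is a
worst-case, full-knowledge definition -- no guessing strategies based on
recent allocations are involved.

Imbalance is measured two ways at the end of a trial:

* *overall*: the largest pairwise difference in arm sizes, as a percentage
  of N;
* *within-factor*: for each prognostic factor, the largest pairwise
  difference between arms in the percentage of their patients carrying a
  given category (proportions, not raw counts, so arms of unequal size are
  comparable).

A completed trial is flagged imbalanced when either statistic reaches a
size-dependent cutoff: 5% for N >= 50, relaxed for smaller trials where 5%
of N is a fraction of a patient (40% at N <= 10, 20% at N <= 20, 10% at
N <= 49).  At scenario level the verdict is "imbalance occurs" when at least
a `chance_threshold` fraction (default 10%) of replicate trials are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .minimisation import (
    CLASSIFICATIONS,
    DETERMINISTIC,
    AllocationRecord,
    MarginalTable,
    TrialResult,
)

__all__ = [
    "ImbalanceRule",
    "TrialFlags",
    "imbalance_cutoff",
    "overall_imbalance_percent",
    "factor_imbalance_percent",
    "trial_flags",
    "predictability_fraction",
    "classification_counts",
]


def imbalance_cutoff(n_patients: int) -> float:
    """Percentage cutoff above which a trial of ``n_patients`` is imbalanced.

    Step schedule: 40% for N <= 10, 20% for 11-20, 10% for 21-49, 5% for
    N >= 50 (at N = 50 the minimal flagged split is 27:23).  The 41-49 range
    is an extension of the N = 40 value.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if n_patients <= 10:
        return 40.0
    if n_patients <= 20:
        return 20.0
    if n_patients <= 49:
        return 10.0
    return 5.0


@dataclass(frozen=True)
class ImbalanceRule:
    """Cutoff schedule plus the replicate-level chance threshold."""

    cutoff_percent: Callable[[int], float] = imbalance_cutoff
    chance_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.chance_threshold < 1.0:
            raise ValueError(
                f"chance_threshold must lie in (0, 1), got {self.chance_threshold}"
            )


DEFAULT_RULE = ImbalanceRule()


@dataclass(frozen=True)
class TrialFlags:
    """Imbalance verdicts for one completed trial."""

    overall_imbalanced: bool
    any_factor_imbalanced: bool
    max_overall_percent: float
    max_factor_percent: float


def overall_imbalance_percent(arm_totals: Sequence[int], n_patients: int) -> float:
    """Largest pairwise arm-size difference as a percentage of N.

    ``(27, 23)`` at N = 50 gives 8.0, the minimal split flagged at the 5%
    cutoff.  Invariant under arm relabelling.
    """
    totals = np.asarray(arm_totals, dtype=np.int64)
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if int(totals.sum()) != n_patients:
        raise ValueError(
            f"arm totals {totals.tolist()} sum to {int(totals.sum())}, expected {n_patients}"
        )
    return 100.0 * float(totals.max() - totals.min()) / n_patients


def factor_imbalance_percent(table: MarginalTable, factor: int) -> float:
    """Largest percentage-point gap between arms in a category's proportion.

    Maximised over categories of ``factor`` and over arm pairs.  If any arm
    is still empty the proportions are undefined; the statistic is reported
    as 100 (maximal) with a warning -- this only arises for tiny N.
    """
    counts = table.counts[factor]
    totals = table.arm_totals
    if (totals == 0).any():
        warnings.warn(
            "factor imbalance with an empty arm reported as maximal (100%)",
            stacklevel=2,
        )
        return 100.0
    proportions = 100.0 * counts / totals  # (K, arms), percent of each arm
    return float((proportions.max(axis=1) - proportions.min(axis=1)).max())


def trial_flags(result: TrialResult, rule: ImbalanceRule = DEFAULT_RULE) -> TrialFlags:
    """Evaluate both imbalance statistics of a completed trial against the rule."""
    n = result.design.n_patients
    if result.final_table.n_allocated != n:
        raise ValueError(
            f"trial incomplete: {result.final_table.n_allocated} of {n} allocated"
        )
    cutoff = rule.cutoff_percent(n)
    overall = overall_imbalance_percent(result.final_table.arm_totals, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-arm warning already maximal
        factor_max = max(
            factor_imbalance_percent(result.final_table, f)
            for f in range(result.design.n_factors)
        )
    return TrialFlags(
        overall_imbalanced=overall >= cutoff,
        any_factor_imbalanced=factor_max >= cutoff,
        max_overall_percent=overall,
        max_factor_percent=factor_max,
    )


def classification_counts(records: Sequence[AllocationRecord]) -> dict[str, int]:
    """Counts of tie / deterministic / twist classifications; they sum to N."""
    out = {c: 0 for c in CLASSIFICATIONS}
    for rec in records:
        out[rec.classification] += 1
    return out


def predictability_fraction(records: Sequence[AllocationRecord]) -> float:
    """Fraction of allocations classified deterministic (hence predictable)."""
    if len(records) == 0:
        raise ValueError("predictability undefined for an empty record list")
    n_det = sum(1 for rec in records if rec.classification == DETERMINISTIC)
    return n_det / len(records)
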