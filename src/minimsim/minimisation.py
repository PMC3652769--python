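"""Minimisation allocator with a configurable random element.

The allocator keeps marginal totals -- counts of previously allocated
patients per (factor, category, arm) -- and scores each candidate arm for an
incoming patient by summing, over factors, the count of same-category
patients already in that arm.  The arm with the smallest marginal score is
the *optimal* arm:

* if two or more arms tie for the minimum, one of the tied arms is chosen by
  simple randomisation (classification ``tie``);
* otherwise the unique minimiser is assigned with probability P
  (``deterministic`` -- an observer who knows the algorithm and all previous
  allocations could have called it), and with probability 1 - P the patient
  goes to one of the other arms chosen uniformly (the *random twist*,
  classification ``twist``).

Scores are unweighted sums of raw marginal counts, and the patient being
allocated never contributes to their own scores: the table is updated only
after the decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import Patient, TrialDesign

__all__ = [
    "TIE",
    "DETERMINISTIC",
    "TWIST",
    "CLASSIFICATIONS",
    "MarginalTable",
    "AllocationRecord",
    "TrialResult",
    "marginal_scores",
    "allocate",
    "run_trial",
]

logger = logging.getLogger(__name__)

TIE = "tie"
DETERMINISTIC = "deterministic"
TWIST = "twist"
CLASSIFICATIONS = (TIE, DETERMINISTIC, TWIST)


class MarginalTable:
    """Running counts of allocated patients per (factor, category, arm).

    Parameters
    ----------
    n_categories
        Number of categories of each factor, in factor order.
    n_arms
        Number of treatment arms.

    Attributes
    ----------
    counts
        List (one entry per factor) of integer arrays of shape
        ``(K_f, n_arms)``.
    arm_totals
        Integer array of per-arm totals.
    n_allocated
        Number of patients entered so far.
    """

    __slots__ = ("counts", "arm_totals", "n_allocated", "n_arms")

    def __init__(self, n_categories: tuple[int, ...] | list[int], n_arms: int) -> None:
        self.n_arms = int(n_arms)
        self.counts = [np.zeros((int(k), self.n_arms), dtype=np.int64) for k in n_categories]
        self.arm_totals = np.zeros(self.n_arms, dtype=np.int64)
        self.n_allocated = 0

    @classmethod
    def for_design(cls, design: TrialDesign) -> "MarginalTable":
        return cls(design.category_counts(), design.n_arms)

    @classmethod
    def from_counts(cls, counts: list[np.ndarray] | list[list[list[int]]]) -> "MarginalTable":
        """Build a table from explicit per-factor count matrices and validate it."""
        arrays = [np.asarray(c, dtype=np.int64) for c in counts]
        if not arrays:
            raise ValueError("at least one factor count matrix is required")
        n_arms = arrays[0].shape[1]
        table = cls([a.shape[0] for a in arrays], n_arms)
        table.counts = arrays
        table.arm_totals = arrays[0].sum(axis=0)
        table.n_allocated = int(table.arm_totals.sum())
        table.validate()
        return table

    def validate(self) -> None:
        """Check internal consistency; raise ``ValueError`` on violation."""
        for f, c in enumerate(self.counts):
            if (c < 0).any():
                raise ValueError(f"factor {f}: negative count")
            if int(c.sum()) != self.n_allocated:
                raise ValueError(
                    f"factor {f}: counts sum to {int(c.sum())}, expected {self.n_allocated}"
                )
            per_arm = c.sum(axis=0)
            if not np.array_equal(per_arm, self.arm_totals):
                raise ValueError(
                    f"factor {f}: per-arm sums {per_arm.tolist()} != arm totals "
                    f"{self.arm_totals.tolist()}"
                )
        if int(self.arm_totals.sum()) != self.n_allocated:
            raise ValueError("arm totals do not sum to n_allocated")

    def add(self, patient: Patient, arm: int) -> None:
        """Enter ``patient`` into ``arm``, incrementing every factor's row."""
        for f, level in enumerate(patient.levels):
            self.counts[f][level, arm] += 1
        self.arm_totals[arm] += 1
        self.n_allocated += 1

    def copy(self) -> "MarginalTable":
        new = MarginalTable([c.shape[0] for c in self.counts], self.n_arms)
        new.counts = [c.copy() for c in self.counts]
        new.arm_totals = self.arm_totals.copy()
        new.n_allocated = self.n_allocated
        return new

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarginalTable):
            return NotImplemented
        return (
            self.n_allocated == other.n_allocated
            and np.array_equal(self.arm_totals, other.arm_totals)
            and len(self.counts) == len(other.counts)
            and all(np.array_equal(a, b) for a, b in zip(self.counts, other.counts))
        )

    def __repr__(self) -> str:
        return (
            f"MarginalTable(n_arms={self.n_arms}, n_allocated={self.n_allocated}, "
            f"arm_totals={self.arm_totals.tolist()})"
        )


@dataclass(frozen=True)
class AllocationRecord:
    """One allocation decision: patient, assigned arm, classification, scores.

    ``scores`` is the per-arm marginal score vector at decision time (before
    the patient was entered into the table).
    """

    patient: Patient
    arm: int
    classification: str
    scores: tuple[int, ...]


@dataclass(frozen=True)
class TrialResult:
    """All allocation records of one simulated trial plus the final table."""

    design: TrialDesign
    records: tuple[AllocationRecord, ...]
    final_table: MarginalTable

    def replay_table(self) -> MarginalTable:
        """Rebuild the marginal table from the records; equals ``final_table``."""
        table = MarginalTable.for_design(self.design)
        for rec in self.records:
            table.add(rec.patient, rec.arm)
        return table


def marginal_scores(table: MarginalTable, patient: Patient) -> np.ndarray:
    """Per-arm marginal score: sum over factors of same-category counts.

    For the worked example of 20 patients in two groups, a new patient who is
    female, aged under 80, with a proximal femur fracture sustained 0-3 months
    ago scores 7 + 6 + 0 + 5 = 18 for group A and 8 + 9 + 2 + 7 = 27 for
    group B.
    """
    counts = table.counts
    levels = patient.levels
    if len(levels) != len(counts):
        raise IndexError(
            f"patient has {len(levels)} levels but table tracks {len(counts)} factors"
        )
    scores = counts[0][levels[0]].copy()
    for f in range(1, len(counts)):
        scores += counts[f][levels[f]]
    return scores


def allocate(
    table: MarginalTable,
    patient: Patient,
    p_optimal: float,
    rng: np.random.Generator,
) -> AllocationRecord:
    """Allocate one patient and update ``table`` in place.

    Classification is decided before the table is updated:

    ``tie``
        the minimum score is shared by two or more arms; the arm is drawn
        uniformly among the tied arms only.
    ``deterministic``
        the minimiser is unique and (with probability ``p_optimal``) is
        assigned.
    ``twist``
        the minimiser is unique but the random element redirected the patient
        uniformly to one of the other ``n_arms - 1`` arms.

    A uniform variate is consumed in the non-tie branch even at P = 1.0, so
    replicate random streams stay aligned across values of P (common random
    numbers in P-scans).
    """
    if not 0.5 <= p_optimal <= 1.0:
        raise ValueError(f"p_optimal must lie in [0.5, 1.0], got {p_optimal!r}")
    scores = marginal_scores(table, patient)
    tied = np.flatnonzero(scores == scores.min())
    if tied.size > 1:
        arm = int(tied[rng.integers(tied.size)])
        classification = TIE
    else:
        optimal = int(tied[0])
        if rng.random() < p_optimal:  # random() < 1.0 always: P=1 never twists
            arm = optimal
            classification = DETERMINISTIC
        else:
            k = int(rng.integers(table.n_arms - 1))
            arm = k if k < optimal else k + 1
            classification = TWIST
    record = AllocationRecord(patient, arm, classification, tuple(int(s) for s in scores))
    table.add(patient, arm)
    return record


def run_trial(
    design: TrialDesign,
    cohort: list[Patient],
    rng: np.random.Generator,
) -> TrialResult:
    """Sequentially allocate a whole cohort starting from an empty table."""
    if len(cohort) != design.n_patients:
        raise ValueError(
            f"cohort has {len(cohort)} patients, design expects {design.n_patients}"
        )
    table = MarginalTable.for_design(design)
    p = design.p_optimal
    trace = logger.isEnabledFor(logging.DEBUG)
    records = []
    for i, patient in enumerate(cohort):
        rec = allocate(table, patient, p, rng)
        records.append(rec)
        if trace:
            logger.debug(
                "alloc %d: levels=%s scores=%s arm=%d class=%s",
                i + 1, patient.levels, rec.scores, rec.arm, rec.classification,
            )
    return TrialResult(design, tuple(records), table)
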