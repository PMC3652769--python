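"""Monte-Carlo engine: replicate runs, P-grid scans and scenario grids.

``run_replicates`` simulates many independent trials of one design and
aggregates classification percentages (pooled over every allocation of every
replicate) and imbalance probabilities (fraction of replicates flagged).

``scan_p`` repeats this over a descending grid of P values for a fixed
(arms, N, factors) configuration and derives:

* ``imbalance_onset_p`` -- the largest grid P at which the scenario-level
  imbalance verdict is true (``None`` if balance holds everywhere);
* ``recommended_p``    -- the smallest grid P with a false verdict, i.e. the
  most random twist the design tolerates without compromising balance;
* ``predictability_reduction_pct`` -- deterministic percentage at the top of
  the grid minus that at the recommended P: the predictability bought by the
  random element.

Seeding contract: a master seed spawns one pair of child streams (cohort,
allocation) per replicate, keyed by the replicate index, so replicates are
order-independent and the P-scan reuses the same cohorts and base uniforms
at every P (common random numbers), sharpening reduction estimates.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import FactorSpec, TrialDesign, make_design, sample_cohort
from .metrics import (
    DEFAULT_RULE,
    ImbalanceRule,
    classification_counts,
    trial_flags,
)
from .minimisation import DETERMINISTIC, TIE, TWIST, run_trial

__all__ = [
    "DEFAULT_P_GRID",
    "DEFAULT_N_REPLICATES",
    "ScenarioSummary",
    "PScanResult",
    "replicate_rngs",
    "run_replicates",
    "scan_p",
    "scenario_grid",
    "two_treatment_battery",
]

logger = logging.getLogger(__name__)

#: P values tabulated throughout the simulation study.
DEFAULT_P_GRID: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
#: Replicates per scenario cell.
DEFAULT_N_REPLICATES = 1000


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregated outcome of one (design, P) cell over replicates.

    Percentages are pooled over all N * n_replicates allocations;
    ``prob_overall_imbalance`` and ``prob_factor_imbalance`` are fractions of
    replicates whose final table was flagged.  ``imbalance_verdict`` is true
    when either probability reaches the rule's chance threshold.
    """

    n_arms: int
    n_patients: int
    p_optimal: float
    factors: tuple[FactorSpec, ...]
    n_replicates: int
    tie_pct: float
    deterministic_pct: float
    twist_pct: float
    prob_overall_imbalance: float
    prob_factor_imbalance: float
    imbalance_verdict: bool


@dataclass(frozen=True)
class PScanResult:
    """Summaries over a P grid for one configuration, plus derived quantities.

    ``no_balanced_p`` is set when the imbalance verdict is true at every grid
    value, in which case ``recommended_p`` and the reduction are ``None``.
    """

    summaries: tuple[ScenarioSummary, ...]
    recommended_p: float | None
    imbalance_onset_p: float | None
    predictability_reduction_pct: float | None
    no_balanced_p: bool = False


def replicate_rngs(
    master_seed: int, replicate: int
) -> tuple[np.random.Generator, np.random.Generator]:
    """Cohort and allocation streams for one replicate of one scenario.

    Keyed only by (master_seed, replicate index): independent of P and of the
    order replicates are run in.
    """
    cohort_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(replicate, 0)))
    )
    alloc_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(replicate, 1)))
    )
    return cohort_rng, alloc_rng


def run_replicates(
    design: TrialDesign,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    rule: ImbalanceRule = DEFAULT_RULE,
) -> ScenarioSummary:
    """Simulate ``n_replicates`` independent trials and aggregate them."""
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    t0 = time.perf_counter()
    tally = {TIE: 0, DETERMINISTIC: 0, TWIST: 0}
    n_overall_flagged = 0
    n_factor_flagged = 0
    for rep in range(n_replicates):
        cohort_rng, alloc_rng = replicate_rngs(master_seed, rep)
        cohort = sample_cohort(design, cohort_rng)
        result = run_trial(design, cohort, alloc_rng)
        for cls, n in classification_counts(result.records).items():
            tally[cls] += n
        flags = trial_flags(result, rule)
        n_overall_flagged += flags.overall_imbalanced
        n_factor_flagged += flags.any_factor_imbalanced
    n_alloc = n_replicates * design.n_patients
    prob_overall = n_overall_flagged / n_replicates
    prob_factor = n_factor_flagged / n_replicates
    summary = ScenarioSummary(
        n_arms=design.n_arms,
        n_patients=design.n_patients,
        p_optimal=design.p_optimal,
        factors=design.factors,
        n_replicates=n_replicates,
        tie_pct=100.0 * tally[TIE] / n_alloc,
        deterministic_pct=100.0 * tally[DETERMINISTIC] / n_alloc,
        twist_pct=100.0 * tally[TWIST] / n_alloc,
        prob_overall_imbalance=prob_overall,
        prob_factor_imbalance=prob_factor,
        imbalance_verdict=(
            prob_overall >= rule.chance_threshold
            or prob_factor >= rule.chance_threshold
        ),
    )
    logger.info(
        "scenario arms=%d N=%d P=%.2f factors=%d reps=%d seed=%d: "
        "tie=%.1f%% det=%.1f%% twist=%.1f%% (%.2fs)",
        design.n_arms, design.n_patients, design.p_optimal, design.n_factors,
        n_replicates, master_seed, summary.tie_pct, summary.deterministic_pct,
        summary.twist_pct, time.perf_counter() - t0,
    )
    return summary


def scan_p(
    n_arms: int,
    n_patients: int,
    factors: Sequence[FactorSpec],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    rule: ImbalanceRule = DEFAULT_RULE,
) -> PScanResult:
    """Scan a descending P grid for one (arms, N, factors) configuration."""
    if len(p_grid) == 0:
        raise ValueError("p_grid must be non-empty")
    grid = sorted((float(p) for p in p_grid), reverse=True)
    if grid[0] > 1.0 or grid[-1] < 0.5:
        raise ValueError(f"p_grid values must lie in [0.5, 1.0], got {list(p_grid)}")
    summaries = tuple(
        run_replicates(
            make_design(n_arms, n_patients, p, factors),
            n_replicates=n_replicates,
            master_seed=master_seed,
            rule=rule,
        )
        for p in grid
    )
    balanced = [s.p_optimal for s in summaries if not s.imbalance_verdict]
    imbalanced = [s.p_optimal for s in summaries if s.imbalance_verdict]
    onset = max(imbalanced) if imbalanced else None
    if balanced:
        recommended = min(balanced)
        det_at_top = summaries[0].deterministic_pct
        det_at_rec = next(
            s.deterministic_pct for s in summaries if s.p_optimal == recommended
        )
        reduction = det_at_top - det_at_rec
        return PScanResult(summaries, recommended, onset, reduction)
    logger.warning(
        "no balanced P in grid for arms=%d N=%d factors=%d", n_arms, n_patients,
        len(factors),
    )
    return PScanResult(summaries, None, onset, None, no_balanced_p=True)


def scenario_grid(
    configurations: Sequence[tuple[int, int, Sequence[FactorSpec]]],
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    rule: ImbalanceRule = DEFAULT_RULE,
) -> list[PScanResult]:
    """Run :func:`scan_p` for each (arms, N, factors) configuration.

    Rows keep the input order; each configuration gets its own child seed
    keyed by its position, so the grid is reproducible and rows are
    independent of each other.
    """
    if len(configurations) == 0:
        raise ValueError("configurations must be non-empty")
    results = []
    for i, (n_arms, n_patients, factors) in enumerate(configurations):
        child_seed = int(
            np.random.SeedSequence(master_seed, spawn_key=(i,)).generate_state(1)[0]
            % 2**31
        )
        results.append(
            scan_p(
                n_arms, n_patients, factors,
                p_grid=p_grid, n_replicates=n_replicates,
                master_seed=child_seed, rule=rule,
            )
        )
    return results


def two_treatment_battery(
    n_patients: int = 200,
) -> list[tuple[int, int, list[FactorSpec]]]:
    """The 13 two-treatment factor configurations of the summary battery.

    One-variable blocks (binary equal and unequal prevalence, three and four
    categories), five two-variable blocks, and equal/unequal three- and
    four-binary-variable blocks.  Unequal prevalences use the package's
    documented preset conventions.
    """
    from .design import PRESET_PREVALENCES

    def f(kind: str, name: str) -> FactorSpec:
        return FactorSpec(name, PRESET_PREVALENCES[kind])

    configs: list[tuple[int, int, list[FactorSpec]]] = [
        (2, n_patients, [f("binary_equal", "f1")]),
        (2, n_patients, [f("binary_unequal", "f1")]),
        (2, n_patients, [f("three_equal", "f1")]),
        (2, n_patients, [f("four_equal", "f1")]),
        (2, n_patients, [f("binary_equal", "f1"), f("binary_equal", "f2")]),
        (2, n_patients, [f("binary_unequal", "f1"), f("binary_unequal", "f2")]),
        (2, n_patients, [f("binary_equal", "f1"), f("three_equal", "f2")]),
        (2, n_patients, [f("three_equal", "f1"), f("three_equal", "f2")]),
        (2, n_patients, [f("four_equal", "f1"), f("four_equal", "f2")]),
        (2, n_patients, [f("binary_equal", f"f{i}") for i in (1, 2, 3)]),
        (2, n_patients, [f("binary_unequal", f"f{i}") for i in (1, 2, 3)]),
        (2, n_patients, [f("binary_equal", f"f{i}") for i in (1, 2, 3, 4)]),
        (2, n_patients, [f("binary_unequal", f"f{i}") for i in (1, 2, 3, 4)]),
    ]
    return configs
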