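"""Trial scenario definitions and synthetic patient cohorts.

A scenario is a :class:`TrialDesign`: the number of treatment arms, the trial
size N, the probability P of allocating to the optimal (score-minimising) arm,
and an ordered list of prognostic factors.  Each factor is a
:class:`FactorSpec` giving the population prevalence of its categories, from
which hypothetical patients are sampled independently.

Simulated cohorts model an idealised accrual: every patient's factor levels
are drawn independently from fixed categorical distributions, with no time
trends, no correlation between factors, and no dropout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DesignError",
    "FactorSpec",
    "TrialDesign",
    "Patient",
    "PRESET_PREVALENCES",
    "make_design",
    "binary_factor",
    "equal_factor",
    "sample_patient",
    "sample_cohort",
    "design_to_config",
    "design_from_config",
    "load_design",
    "save_design",
]

_PREV_TOL = 1e-9

#: Named prevalence conventions for "unequal prevalence" scenarios.  The
#: source summaries never state the unequal probabilities used, so these are
#: documented package conventions, not reproductions.
PRESET_PREVALENCES: dict[str, tuple[float, ...]] = {
    "binary_equal": (0.5, 0.5),
    "binary_unequal": (0.7, 0.3),
    "three_equal": (1 / 3, 1 / 3, 1 / 3),
    "three_unequal": (0.5, 0.3, 0.2),
    "four_equal": (0.25, 0.25, 0.25, 0.25),
    "four_unequal": (0.4, 0.3, 0.2, 0.1),
}


class DesignError(ValueError):
    """A scenario parameter violates its contract; the message names the field."""


@dataclass(frozen=True)
class FactorSpec:
    """One prognostic variable: a name and category prevalences.

    Parameters
    ----------
    name
        Text label used in reports and logs.
    prevalence
        Probability of each category in the study population.  Must have at
        least two entries, each in (0, 1], summing to 1.  Category indices are
        0-based; labels beyond the factor name are cosmetic and not stored.
    """

    name: str
    prevalence: tuple[float, ...]

    def __post_init__(self) -> None:
        prev = tuple(float(p) for p in self.prevalence)
        object.__setattr__(self, "prevalence", prev)
        if len(prev) < 2:
            raise DesignError(
                f"factor {self.name!r}: prevalence needs >= 2 categories, got {len(prev)}"
            )
        if any(p < 0 or p > 1 for p in prev):
            raise DesignError(
                f"factor {self.name!r}: prevalence entries must lie in [0, 1], got {prev}"
            )
        if abs(sum(prev) - 1.0) > _PREV_TOL:
            raise DesignError(
                f"factor {self.name!r}: prevalence must sum to 1, got sum {sum(prev)!r}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.prevalence)


@dataclass(frozen=True)
class TrialDesign:
    """A full scenario: arms, size, twist probability and factor list.

    ``p_optimal`` is the probability P that a patient with a unique
    score-minimising arm is actually allocated to it; P = 1 is the fully
    deterministic algorithm, P = 0.5 with two arms degenerates to simple
    randomisation.  Values outside [0.5, 1.0] are rejected.
    """

    n_arms: int
    n_patients: int
    p_optimal: float
    factors: tuple[FactorSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if not isinstance(self.n_arms, (int, np.integer)) or self.n_arms < 2:
            raise DesignError(f"n_arms must be an integer >= 2, got {self.n_arms!r}")
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise DesignError(f"n_patients must be an integer >= 1, got {self.n_patients!r}")
        if not 0.5 <= float(self.p_optimal) <= 1.0:
            raise DesignError(
                f"p_optimal must lie in [0.5, 1.0], got {self.p_optimal!r}"
            )
        if len(self.factors) < 1:
            raise DesignError("factors must contain at least one FactorSpec")
        for f in self.factors:
            if not isinstance(f, FactorSpec):
                raise DesignError(f"factors entries must be FactorSpec, got {type(f)!r}")

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def category_counts(self) -> tuple[int, ...]:
        return tuple(f.n_categories for f in self.factors)


@dataclass(frozen=True)
class Patient:
    """Factor levels of one hypothetical patient, aligned with the design's factors."""

    levels: tuple[int, ...]


def make_design(
    n_arms: int,
    n_patients: int,
    p_optimal: float,
    factors: Sequence[FactorSpec],
) -> TrialDesign:
    """Validate and freeze a trial scenario.

    Raises
    ------
    DesignError
        If any argument violates the :class:`TrialDesign` invariants; the
        message names the offending field.
    """
    return TrialDesign(int(n_arms), int(n_patients), float(p_optimal), tuple(factors))


def binary_factor(name: str = "factor", p: float = 0.5) -> FactorSpec:
    """A two-category factor with category-0 prevalence ``p``."""
    return FactorSpec(name, (p, 1.0 - p))


def equal_factor(name: str = "factor", k: int = 2) -> FactorSpec:
    """A ``k``-category factor with equal prevalence in every category."""
    return FactorSpec(name, tuple([1.0 / k] * k))


def sample_patient(design: TrialDesign, rng: np.random.Generator) -> Patient:
    """Draw one patient, each factor level independently from its prevalence."""
    levels = tuple(
        int(rng.choice(f.n_categories, p=f.prevalence)) for f in design.factors
    )
    return Patient(levels)


def sample_cohort(design: TrialDesign, rng: np.random.Generator) -> list[Patient]:
    """Draw ``design.n_patients`` independent patients.

    Deterministic given the generator state: the same seed yields the same
    cohort.  Levels are drawn factor by factor (vectorised) rather than
    patient by patient, so a cohort is not prefix-compatible with repeated
    :func:`sample_patient` calls on the same stream.
    """
    n = design.n_patients
    cols = [
        rng.choice(f.n_categories, size=n, p=f.prevalence) for f in design.factors
    ]
    levels = np.stack(cols, axis=1)
    return [Patient(tuple(int(v) for v in row)) for row in levels]


# -- scenario config files ---------------------------------------------------

def design_to_config(
    design: TrialDesign, reps: int | None = None, seed: int | None = None
) -> dict:
    """Serialise a design (plus optional replicate count and seed) to a plain dict."""
    cfg: dict = {
        "arms": design.n_arms,
        "n": design.n_patients,
        "p": design.p_optimal,
        "factors": [
            {"name": f.name, "prevalence": list(f.prevalence)} for f in design.factors
        ],
    }
    if reps is not None:
        cfg["reps"] = int(reps)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def design_from_config(cfg: dict) -> TrialDesign:
    """Build a validated design from a config dict (inverse of :func:`design_to_config`)."""
    try:
        factors = [
            FactorSpec(f["name"], tuple(f["prevalence"])) for f in cfg["factors"]
        ]
        return make_design(cfg["arms"], cfg["n"], cfg["p"], factors)
    except KeyError as exc:  # missing key -> named validation error
        raise DesignError(f"scenario config missing key {exc.args[0]!r}") from exc


def load_design(path: str | Path) -> TrialDesign:
    """Read a YAML (or JSON, a YAML subset) scenario config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DesignError(f"scenario config {path} did not parse to a mapping")
    return design_from_config(cfg)


def save_design(
    design: TrialDesign,
    path: str | Path,
    reps: int | None = None,
    seed: int | None = None,
) -> None:
    """Write a scenario config file; ``load_design`` round-trips it losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_config(design, reps=reps, seed=seed), fh, sort_keys=False)
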