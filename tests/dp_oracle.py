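"""Exhaustive dynamic-programming oracle for tiny minimisation trials.

Enumerates every (patient profile, random choice) path through the allocator
and propagates exact probabilities over marginal-table states.  Independent
of the package's allocator: it re-derives scoring and branching from first
principles with plain Python arithmetic, and is only feasible for small N
and few categories.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

from minimsim.design import TrialDesign


def _profiles(design: TrialDesign):
    """All patient level-vectors with their sampling probabilities."""
    cats = [range(f.n_categories) for f in design.factors]
    for levels in itertools.product(*cats):
        prob = 1.0
        for f, lvl in zip(design.factors, levels):
            prob *= f.prevalence[lvl]
        if prob > 0.0:
            yield levels, prob


def exact_step_probs(design: TrialDesign) -> list[dict[str, float]]:
    """Exact tie/deterministic/twist probability at each allocation step."""
    n_arms = design.n_arms
    p_opt = design.p_optimal
    profiles = list(_profiles(design))
    empty = tuple(
        tuple(0 for _ in range(f.n_categories * n_arms)) for f in design.factors
    )
    states: dict[tuple, float] = {empty: 1.0}
    step_probs = []
    for _ in range(design.n_patients):
        probs = {"tie": 0.0, "deterministic": 0.0, "twist": 0.0}
        nxt: dict[tuple, float] = defaultdict(float)

        def enter(state, levels, arm, prob):
            new = list(list(f) for f in state)
            for f, lvl in enumerate(levels):
                new[f][lvl * n_arms + arm] += 1
            nxt[tuple(tuple(f) for f in new)] += prob

        for state, sprob in states.items():
            for levels, pprob in profiles:
                prob = sprob * pprob
                scores = [
                    sum(state[f][lvl * n_arms + a] for f, lvl in enumerate(levels))
                    for a in range(n_arms)
                ]
                m = min(scores)
                tied = [a for a in range(n_arms) if scores[a] == m]
                if len(tied) > 1:
                    probs["tie"] += prob
                    for arm in tied:
                        enter(state, levels, arm, prob / len(tied))
                else:
                    opt = tied[0]
                    probs["deterministic"] += prob * p_opt
                    enter(state, levels, opt, prob * p_opt)
                    if p_opt < 1.0:
                        probs["twist"] += prob * (1.0 - p_opt)
                        share = prob * (1.0 - p_opt) / (n_arms - 1)
                        for arm in range(n_arms):
                            if arm != opt:
                                enter(state, levels, arm, share)
        states = dict(nxt)
        step_probs.append(probs)
    return step_probs


def exact_reachable_tables(design: TrialDesign) -> set[tuple]:
    """All marginal-table states reachable with positive probability at final N."""
    n_arms = design.n_arms
    profiles = list(_profiles(design))
    empty = tuple(
        tuple(0 for _ in range(f.n_categories * n_arms)) for f in design.factors
    )
    states = {empty}
    for _ in range(design.n_patients):
        nxt = set()
        for state in states:
            for levels, _ in profiles:
                scores = [
                    sum(state[f][lvl * n_arms + a] for f, lvl in enumerate(levels))
                    for a in range(n_arms)
                ]
                m = min(scores)
                tied = [a for a in range(n_arms) if scores[a] == m]
                arms = tied if len(tied) > 1 else (
                    [tied[0]] if design.p_optimal == 1.0 else list(range(n_arms))
                )
                for arm in arms:
                    new = list(list(f) for f in state)
                    for f, lvl in enumerate(levels):
                        new[f][lvl * n_arms + arm] += 1
                    nxt.add(tuple(tuple(f) for f in new))
        states = nxt
    return states
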