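"""Deterministic report rendering for simulation output.

CSV reports mirror the published summary-table style: one row per scenario
cell (or per P-scan), percentages to one decimal place, replicate counts and
the master seed embedded as columns.  JSON reports keep full precision and
round-trip losslessly back to the in-memory summary objects.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .design import FactorSpec
from .engine import PScanResult, ScenarioSummary
from .minimisation import TrialResult

__all__ = [
    "summary_frame",
    "scan_frame",
    "render_report",
    "summaries_from_json",
    "scan_results_from_json",
    "allocation_log_frame",
]

_PCT_COLS = ("tie_pct", "deterministic_pct", "twist_pct")


def _factor_label(factors: Sequence[FactorSpec]) -> str:
    return ";".join(
        f"{f.name}:" + "/".join(f"{p:g}" for p in f.prevalence) for f in factors
    )


def summary_frame(
    summaries: Sequence[ScenarioSummary], seed: int | None = None
) -> pd.DataFrame:
    """One row per scenario cell, fixed column order."""
    rows = []
    for s in summaries:
        row = {
            "arms": s.n_arms,
            "n": s.n_patients,
            "p": s.p_optimal,
            "n_factors": len(s.factors),
            "factors": _factor_label(s.factors),
            "n_replicates": s.n_replicates,
            "tie_pct": s.tie_pct,
            "deterministic_pct": s.deterministic_pct,
            "twist_pct": s.twist_pct,
            "prob_overall_imbalance": s.prob_overall_imbalance,
            "prob_factor_imbalance": s.prob_factor_imbalance,
            "imbalance_verdict": s.imbalance_verdict,
        }
        if seed is not None:
            row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def scan_frame(
    results: Sequence[PScanResult], seed: int | None = None
) -> pd.DataFrame:
    """One row per P-scan, mirroring the summary-table headers.

    Columns: predictability at the top of the grid, N, recommended P,
    predictability at the recommended P, reduction, imbalance-onset P.
    """
    rows = []
    for r in results:
        top = r.summaries[0]
        det_at_rec = None
        if r.recommended_p is not None:
            det_at_rec = next(
                s.deterministic_pct
                for s in r.summaries
                if s.p_optimal == r.recommended_p
            )
        row = {
            "arms": top.n_arms,
            "n": top.n_patients,
            "n_factors": len(top.factors),
            "factors": _factor_label(top.factors),
            "predictability_at_p_max": top.deterministic_pct,
            "p_max": top.p_optimal,
            "recommended_p": r.recommended_p,
            "predictability_at_recommended_p": det_at_rec,
            "predictability_reduction_pct": r.predictability_reduction_pct,
            "imbalance_onset_p": r.imbalance_onset_p,
            "no_balanced_p": r.no_balanced_p,
            "n_replicates": top.n_replicates,
        }
        if seed is not None:
            row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_to_dict(s: ScenarioSummary) -> dict:
    return {
        "n_arms": s.n_arms,
        "n_patients": s.n_patients,
        "p_optimal": s.p_optimal,
        "factors": [
            {"name": f.name, "prevalence": list(f.prevalence)} for f in s.factors
        ],
        "n_replicates": s.n_replicates,
        "tie_pct": s.tie_pct,
        "deterministic_pct": s.deterministic_pct,
        "twist_pct": s.twist_pct,
        "prob_overall_imbalance": s.prob_overall_imbalance,
        "prob_factor_imbalance": s.prob_factor_imbalance,
        "imbalance_verdict": s.imbalance_verdict,
    }


def _summary_from_dict(d: dict) -> ScenarioSummary:
    return ScenarioSummary(
        n_arms=d["n_arms"],
        n_patients=d["n_patients"],
        p_optimal=d["p_optimal"],
        factors=tuple(
            FactorSpec(f["name"], tuple(f["prevalence"])) for f in d["factors"]
        ),
        n_replicates=d["n_replicates"],
        tie_pct=d["tie_pct"],
        deterministic_pct=d["deterministic_pct"],
        twist_pct=d["twist_pct"],
        prob_overall_imbalance=d["prob_overall_imbalance"],
        prob_factor_imbalance=d["prob_factor_imbalance"],
        imbalance_verdict=d["imbalance_verdict"],
    )


def render_report(
    results: Sequence[ScenarioSummary] | Sequence[PScanResult],
    format: str = "csv",
    path: str | None = None,
    seed: int | None = None,
) -> str:
    """Render summaries or P-scan results to CSV or JSON text.

    Deterministic: the same results render to identical bytes.  CSV rounds
    percentage columns to one decimal place; JSON keeps full precision and is
    the lossless interchange format (see :func:`summaries_from_json` and
    :func:`scan_results_from_json`).  If ``path`` is given the text is also
    written there.
    """
    if len(results) == 0:
        raise ValueError("results must be non-empty")
    scans = isinstance(results[0], PScanResult)
    if format == "csv":
        frame = scan_frame(results, seed) if scans else summary_frame(results, seed)
        for col in frame.columns:
            if col.endswith("_pct") or col.startswith("predictability"):
                frame[col] = frame[col].map(
                    lambda v: None if v is None or pd.isna(v) else round(float(v), 1)
                )
        text = frame.to_csv(index=False)
    elif format == "json":
        if scans:
            payload = [
                {
                    "summaries": [_summary_to_dict(s) for s in r.summaries],
                    "recommended_p": r.recommended_p,
                    "imbalance_onset_p": r.imbalance_onset_p,
                    "predictability_reduction_pct": r.predictability_reduction_pct,
                    "no_balanced_p": r.no_balanced_p,
                }
                for r in results
            ]
        else:
            payload = [_summary_to_dict(s) for s in results]
        doc = {"seed": seed, "results": payload} if seed is not None else payload
        text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    else:
        raise ValueError(f"unknown report format {format!r} (expected 'csv' or 'json')")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def summaries_from_json(text: str) -> list[ScenarioSummary]:
    """Inverse of ``render_report(summaries, 'json')``."""
    doc = json.loads(text)
    payload = doc["results"] if isinstance(doc, dict) else doc
    return [_summary_from_dict(d) for d in payload]


def scan_results_from_json(text: str) -> list[PScanResult]:
    """Inverse of ``render_report(scan_results, 'json')``."""
    doc = json.loads(text)
    payload = doc["results"] if isinstance(doc, dict) else doc
    return [
        PScanResult(
            summaries=tuple(_summary_from_dict(s) for s in d["summaries"]),
            recommended_p=d["recommended_p"],
            imbalance_onset_p=d["imbalance_onset_p"],
            predictability_reduction_pct=d["predictability_reduction_pct"],
            no_balanced_p=d["no_balanced_p"],
        )
        for d in payload
    ]


def allocation_log_frame(result: TrialResult) -> pd.DataFrame:
    """Per-allocation audit log of one trial.

    Columns: ``entry_order`` (1-based), one level column per factor, one
    score column per arm, the assigned arm and the classification.  Replaying
    the log reproduces the final marginal table.
    """
    factors = result.design.factors
    rows = []
    for i, rec in enumerate(result.records, start=1):
        row: dict = {"entry_order": i}
        for f, level in zip(factors, rec.patient.levels):
            row[f"level_{f.name}"] = level
        for a, s in enumerate(rec.scores):
            row[f"score_arm{a}"] = s
        row["arm"] = rec.arm
        row["classification"] = rec.classification
        rows.append(row)
    return pd.DataFrame(rows)
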