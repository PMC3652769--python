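"""Packaged fixtures: the worked allocation example and reference summary rows.

The worked example is the published profile of the first 20 patients of a
fracture trial with two groups and four prognostic factors (gender, age
band, fracture type, time since fracture), stored as marginal counts, plus
the 21st patient awaiting allocation.  Reference rows transcribe the
published summary values (small-trial cutoffs, steady-state tie and
deterministic percentages, maximum predictability decreases) together with
provenance labels and tolerance annotations; the acceptance checks consume
them, keeping transcription separate from simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

from .design import Patient
from .minimisation import MarginalTable

__all__ = [
    "FixtureError",
    "ReferenceRow",
    "load_worked_example",
    "worked_example_meta",
    "load_reference_rows",
    "find_reference",
]

_CHECKSUMS = {
    "worked_example.json": "74fac72e27775f71741c66085dbe86d434523e7daf63b9b7a22bc7c9015e8415",
    "reference_rows.json": "0412618f60076fba916b1cdb4f028d002b189055421a9c2d6cbcd0da1966e3ba",
}


class FixtureError(RuntimeError):
    """A packaged fixture file is missing or corrupted."""


def _read_fixture(name: str) -> bytes:
    data = resources.files("minimsim.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(
            f"fixture {name} failed its checksum (got {digest}); reinstall the package"
        )
    return data


@dataclass(frozen=True)
class ReferenceRow:
    """One published summary value with provenance and tolerance annotations.

    ``value_high`` is set when the source prints a range (e.g. a maximum
    decrease of "4 to 12%"); otherwise the row carries a single value.
    Cutoff rows are exact (tolerance 0); simulated percentages carry a +/-3
    percentage-point band.
    """

    source_table: str
    row: str
    quantity: str
    value: float
    tolerance: float
    value_high: float | None = None


def load_worked_example() -> tuple[MarginalTable, Patient]:
    """The 20-patient marginal table and the 21st patient of the worked example.

    The returned table has four factors, two arms and arm totals (10, 10);
    the patient is female, aged under 80, with a proximal femur fracture 0 to
    3 months old, whose marginal scores against the table are (18, 27).
    """
    spec = json.loads(_read_fixture("worked_example.json"))
    table = MarginalTable.from_counts([f["counts"] for f in spec["factors"]])
    patient = Patient(tuple(spec["next_patient"]["levels"]))
    return table, patient


def worked_example_meta() -> dict:
    """Factor and category labels of the worked example (for reports)."""
    spec = json.loads(_read_fixture("worked_example.json"))
    return {
        "arms": spec["arms"],
        "factors": [
            {"name": f["name"], "categories": f["categories"]} for f in spec["factors"]
        ],
        "next_patient_profile": spec["next_patient"]["profile"],
    }


def load_reference_rows() -> list[ReferenceRow]:
    """All transcribed reference rows shipped with the package."""
    rows = json.loads(_read_fixture("reference_rows.json"))
    return [ReferenceRow(**row) for row in rows]


def find_reference(
    rows: list[ReferenceRow] | None = None,
    source_table: str | None = None,
    row: str | None = None,
    quantity: str | None = None,
) -> list[ReferenceRow]:
    """Filter reference rows by any combination of label fields."""
    if rows is None:
        rows = load_reference_rows()
    out = []
    for r in rows:
        if source_table is not None and r.source_table != source_table:
            continue
        if row is not None and r.row != row:
            continue
        if quantity is not None and r.quantity != quantity:
            continue
        out.append(r)
    return out
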