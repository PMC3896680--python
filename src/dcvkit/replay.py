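"""Replay of the published 79-item DCV study's per-item outcomes.

The raw judge data of the study behind the packaged item bank were never
deposited; what the study printed per item is the mean weighted judgment,
the t statistic, whether the intended-domain test was significant after FDR
correction, which non-intended domains were co-allocated by more than one
judge, and which of those were themselves significantly classified. Those
printed markers are transcribed — not inferred — into a fixture, and the
inclusion taxonomy can be re-applied to them to reproduce the published
partition (32 included / 47 excluded, of which 8 misclassified).
"""

from __future__ import annotations

import csv
from collections.abc import Sequence
from dataclasses import dataclass
from importlib import resources

from .errors import DcvValidationError


@dataclass(frozen=True)
class StudyResultRow:
    """One item's printed DCV outcome.

    significant_intended: the intended-domain test was significant with a
    positive mean. coallocated: non-intended domains allocated by more than
    one judge. significant_other: the subset of other domains whose own
    test was significant (a misclassification signal).
    """

    item_id: str
    intended: tuple[str, ...]
    mean: float
    t: float
    significant_intended: bool
    coallocated: tuple[str, ...]
    significant_other: tuple[str, ...]

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean <= 1.0:
            raise DcvValidationError(f"{self.item_id}: mean {self.mean} outside [-1, 1]")
        stray = [d for d in self.significant_other if d not in self.coallocated]
        if stray:
            raise DcvValidationError(
                f"{self.item_id}: significant_other {stray} not among co-allocated domains"
            )


def _split(cell: str) -> tuple[str, ...]:
    cell = (cell or "").strip()
    return tuple(cell.split(";")) if cell else ()


def load_study_results() -> tuple[StudyResultRow, ...]:
    """The packaged fixture: one row per item of the 79-item study."""
    text = resources.files("dcvkit").joinpath("data", "study_results.csv").read_text(
        encoding="utf-8"
    )
    rows = []
    for row in csv.DictReader(text.splitlines()):
        rows.append(
            StudyResultRow(
                item_id=row["item_id"],
                intended=_split(row["intended"]),
                mean=float(row["mean"]),
                t=float(row["t"]),
                significant_intended=row["sig_intended"] == "1",
                coallocated=_split(row["coallocated"]),
                significant_other=_split(row["sig_other"]),
            )
        )
    return tuple(rows)


def replay_study_classification(
    rows: Sequence[StudyResultRow],
) -> dict:
    """Apply the inclusion taxonomy to recorded outcomes (no re-computation).

    included: significant on the intended domain, nothing co-allocated,
    nothing else significant. misclassified: some other domain's test was
    significant. multi_allocated_with_intended: the remaining excluded
    items. per_domain_final counts included items by intended domain.
    """
    ids = [r.item_id for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise DcvValidationError(f"duplicate item ids in fixture: {sorted(dupes)}")

    included = 0
    misclassified = 0
    per_domain_final: dict[str, int] = {}
    for r in rows:
        for d in r.intended:
            per_domain_final.setdefault(d, 0)
        if r.significant_intended and not r.coallocated and not r.significant_other:
            included += 1
            for d in r.intended:
                per_domain_final[d] += 1
        elif r.significant_other:
            misclassified += 1
    excluded = len(rows) - included
    return {
        "total": len(rows),
        "included": included,
        "excluded": excluded,
        "misclassified": misclassified,
        "multi_allocated_with_intended": excluded - misclassified,
        "per_domain_final": dict(sorted(per_domain_final.items())),
    }
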