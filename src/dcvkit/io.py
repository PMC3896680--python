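"""Readers and writers for the study's file formats.

Formats are deliberately plain: UTF-8, RFC-4180 CSV with a header for
allocations and domain definitions; YAML for item banks, TACT mappings, and
synthetic-study configurations. Confidence values in allocation files may be
on either the percent (0-100) or fraction (0-1) scale; values above 1 are
interpreted as percent and divided by 100 on read.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import yaml

from .errors import DcvValidationError
from .model import (
    AllocationRecord,
    AllocationTable,
    Domain,
    DomainSet,
    ExpertiseRecord,
    ItemBank,
    ItemSpec,
    TactMapping,
)
from .tact import placeholders_in

PRESETS = ("tdf14", "tdf12")

_ALLOC_COLUMNS = ("judge_id", "item_id", "rank", "domain", "confidence")


def _data_path(name: str):
    return resources.files("dcvkit").joinpath("data", name)


def _read_domain_rows(rows, source: str) -> DomainSet:
    domains = []
    for row in rows:
        code = (row.get("code") or "").strip()
        if not code:
            raise DcvValidationError(f"{source}: domain row without a code: {row}")
        domains.append(
            Domain(code=code, label=(row.get("label") or "").strip(),
                   definition=(row.get("definition") or "").strip())
        )
    if not domains:
        raise DcvValidationError(f"{source}: no domain rows found")
    return DomainSet(tuple(domains))


def load_domain_set(preset_or_file: str | Path = "tdf14") -> DomainSet:
    """Load a domain set from a built-in preset or a definitions CSV.

    Presets: ``tdf14`` (the refined 14-domain TDF) and ``tdf12`` (the
    original 12-domain framework). A file must be a CSV with columns
    ``code,label,definition``.
    """
    name = str(preset_or_file)
    if name in PRESETS:
        text = _data_path(f"domains_{name}.csv").read_text(encoding="utf-8")
        rows = csv.DictReader(text.splitlines())
        return _read_domain_rows(rows, f"preset {name}")
    path = Path(preset_or_file)
    if not path.exists():
        raise DcvValidationError(
            f"unknown domain preset or missing file: {preset_or_file!r} "
            f"(presets: {', '.join(PRESETS)})"
        )
    with path.open(encoding="utf-8", newline="") as fh:
        return _read_domain_rows(csv.DictReader(fh), str(path))


def _items_from_yaml(raw, source: str) -> ItemBank:
    if not isinstance(raw, list):
        raise DcvValidationError(f"{source}: item bank must be a YAML list of items")
    items = []
    for entry in raw:
        try:
            item_id = entry["id"]
            domains = tuple(entry["domains"])
        except (KeyError, TypeError) as exc:
            raise DcvValidationError(f"{source}: malformed item entry {entry!r}") from exc
        texts = {
            lang: entry[lang]
            for lang in ("en", "nl")
            if entry.get(lang) is not None
        }
        for lang, text in texts.items():
            placeholders_in(text)  # raises on tokens outside the grammar
        items.append(
            ItemSpec(
                item_id=str(item_id),
                intended_domains=domains,
                construct=entry.get("construct", ""),
                text_by_language=texts,
                final=bool(entry.get("final", False)),
            )
        )
    return ItemBank(tuple(items))


def packaged_item_bank() -> ItemBank:
    """The built-in 79-item bilingual TDF item bank.

    79 unique items with English text; the 32 that survived the DCV screen
    are flagged ``final`` and carry Dutch text as well. The four Action
    planning items are single items intended for both Goals and Behavioral
    regulation.
    """
    raw = yaml.safe_load(_data_path("item_bank.yaml").read_text(encoding="utf-8"))
    return _items_from_yaml(raw, "packaged item bank")


def read_item_bank(path: str | Path) -> ItemBank:
    """Read an item bank from a YAML file (same schema as the packaged bank)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _items_from_yaml(raw, str(path))


def read_allocations(path: str | Path, domains: DomainSet | None = None,
                     bank: ItemBank | None = None) -> AllocationTable:
    """Read a long-format allocations CSV into a validated table.

    Expected header: ``judge_id,item_id,rank,domain,confidence``. Confidence
    above 1 is treated as percent. An empty file (header only) yields an
    empty table.
    """
    path = Path(path)
    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DcvValidationError(f"{path}: empty file (no header)")
        missing = [c for c in _ALLOC_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise DcvValidationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rank = int(row["rank"])
                confidence = float(row["confidence"])
            except (TypeError, ValueError) as exc:
                raise DcvValidationError(f"{path}:{lineno}: bad rank/confidence") from exc
            if confidence > 100 or confidence < 0:
                raise DcvValidationError(
                    f"{path}:{lineno}: confidence {confidence} outside [0, 100]"
                )
            if confidence > 1:
                confidence /= 100.0
            records.append(
                AllocationRecord(
                    judge_id=row["judge_id"].strip(),
                    item_id=row["item_id"].strip(),
                    rank=rank,
                    domain=row["domain"].strip(),
                    confidence=confidence,
                )
            )
    return AllocationTable(records, domains=domains, bank=bank)


def write_allocations(table: AllocationTable, path: str | Path) -> None:
    """Write a table back to CSV (confidence on the fraction scale)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ALLOC_COLUMNS)
        for rec in table.records:
            writer.writerow(
                [rec.judge_id, rec.item_id, rec.rank, rec.domain, f"{rec.confidence:.10g}"]
            )


def read_expertise(path: str | Path) -> tuple[ExpertiseRecord, ...]:
    """Read judge expertise ratings (CSV: judge_id,domain,rating; rating 1-7)."""
    path = Path(path)
    records = []
    with path.open(encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.DictReader(fh), start=2):
            try:
                rating = int(row["rating"])
            except (KeyError, TypeError, ValueError) as exc:
                raise DcvValidationError(f"{path}:{lineno}: bad expertise row") from exc
            records.append(
                ExpertiseRecord(judge_id=row["judge_id"].strip(),
                                domain=row["domain"].strip(), rating=rating)
            )
    return tuple(records)


def read_tact_mapping(path: str | Path) -> TactMapping:
    """Read a TACT mapping YAML: ``language: en`` plus ``mapping: {A: ..., ...}``."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "mapping" not in raw:
        raise DcvValidationError(f"{path}: expected keys 'language' and 'mapping'")
    return TactMapping(
        mapping={str(k): str(v) for k, v in raw["mapping"].items()},
        language=str(raw.get("language", "en")),
    )
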