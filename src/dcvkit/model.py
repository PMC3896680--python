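"""Domain types for discriminant content validity (DCV) studies.

The study design these types describe: a panel of judges allocates each
questionnaire item to up to three domains of a behavioral-determinant
framework (by default the 14-domain Theoretical Domains Framework), rating
their confidence in each allocation between 0 and 100%. Downstream modules
turn those allocations into confidence-weighted judgment scores, one-sample
tests, and an item taxonomy.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

from .errors import DcvValidationError

VALID_RANKS = (1, 2, 3)


@dataclass(frozen=True)
class Domain:
    """One framework domain: short code (e.g. ``D1``), label, definition."""

    code: str
    label: str
    definition: str = ""


@dataclass(frozen=True)
class DomainSet:
    """An ordered collection of uniquely coded domains."""

    domains: tuple[Domain, ...]

    def __post_init__(self) -> None:
        if not self.domains:
            raise DcvValidationError("a DomainSet must contain at least one domain")
        codes = [d.code for d in self.domains]
        if any(not c for c in codes):
            raise DcvValidationError("domain codes must be non-empty")
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise DcvValidationError(f"duplicate domain codes: {sorted(dupes)}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(d.code for d in self.domains)

    def __contains__(self, code: object) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.domains)

    def __iter__(self) -> Iterator[Domain]:
        return iter(self.domains)

    def __getitem__(self, code: str) -> Domain:
        for d in self.domains:
            if d.code == code:
                return d
        raise KeyError(code)

    def label(self, code: str) -> str:
        return self[code].label


@dataclass(frozen=True)
class ItemSpec:
    """A questionnaire item: intended domain(s), construct, templated text.

    ``text_by_language`` maps a language code ("en", "nl") to a TACT-templated
    string; placeholders such as ``[A]``, ``[C, T]``, ``[Ta]``,
    ``[innovation/guideline]`` or ``[profession]`` are substituted at render
    time. ``intended_domains`` may contain two codes for items fielded
    against a pair of domains at once.
    """

    item_id: str
    intended_domains: tuple[str, ...]
    construct: str = ""
    text_by_language: Mapping[str, str] = field(default_factory=dict)
    final: bool = False

    def __post_init__(self) -> None:
        if not self.item_id:
            raise DcvValidationError("item_id must be non-empty")
        if not self.intended_domains:
            raise DcvValidationError(f"item {self.item_id}: intended_domains is empty")
        if len(set(self.intended_domains)) != len(self.intended_domains):
            raise DcvValidationError(f"item {self.item_id}: duplicate intended domains")

    def text(self, language: str) -> str:
        try:
            return self.text_by_language[language]
        except KeyError:
            raise DcvValidationError(
                f"item {self.item_id} has no text for language {language!r}"
            ) from None


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of items, unique by id."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        ids = [i.item_id for i in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DcvValidationError(f"duplicate item ids: {sorted(dupes)}")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i.item_id for i in self.items)

    @property
    def final_items(self) -> tuple[ItemSpec, ...]:
        return tuple(i for i in self.items if i.final)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemSpec]:
        return iter(self.items)

    def __getitem__(self, item_id: str) -> ItemSpec:
        for i in self.items:
            if i.item_id == item_id:
                return i
        raise KeyError(item_id)

    def intended(self, item_id: str) -> tuple[str, ...]:
        return self[item_id].intended_domains

    def validate_against(self, domains: DomainSet) -> None:
        for item in self.items:
            unknown = [d for d in item.intended_domains if d not in domains]
            if unknown:
                raise DcvValidationError(
                    f"item {item.item_id}: intended domains {unknown} not in domain set"
                )


@dataclass(frozen=True)
class AllocationRecord:
    """One judge's allocation of one item to one domain.

    ``confidence`` is stored as a fraction in [0, 1]; file readers normalize
    percent-scale values. ``rank`` is the order in which the judge listed the
    domain (1 = first choice).
    """

    judge_id: str
    item_id: str
    rank: int
    domain: str
    confidence: float

    def __post_init__(self) -> None:
        if self.rank not in VALID_RANKS:
            raise DcvValidationError(
                f"allocation ({self.judge_id},{self.item_id}): rank must be 1-3, got {self.rank}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise DcvValidationError(
                f"allocation ({self.judge_id},{self.item_id}): confidence {self.confidence} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class ExpertiseRecord:
    """A judge's self-rated expertise on one domain (1 = layman, 7 = expert)."""

    judge_id: str
    domain: str
    rating: int

    def __post_init__(self) -> None:
        if not 1 <= int(self.rating) <= 7:
            raise DcvValidationError(
                f"expertise rating must be 1-7, got {self.rating} "
                f"({self.judge_id}, {self.domain})"
            )


class AllocationTable:
    """All allocation records of a study, validated as a whole.

    Per (judge, item) there are at most three records with distinct ranks and
    distinct domains. A judge may have no record at all for an item; scoring
    treats that as 0.
    """

    def __init__(
        self,
        records: Iterable[AllocationRecord],
        domains: DomainSet | None = None,
        bank: ItemBank | None = None,
    ) -> None:
        self.records: tuple[AllocationRecord, ...] = tuple(records)
        self._by_judge_item: dict[tuple[str, str], list[AllocationRecord]] = {}
        for rec in self.records:
            if domains is not None and rec.domain not in domains:
                raise DcvValidationError(
                    f"allocation ({rec.judge_id},{rec.item_id}): unknown domain code "
                    f"{rec.domain!r}"
                )
            if bank is not None and rec.item_id not in bank.item_ids:
                raise DcvValidationError(
                    f"allocation references unknown item {rec.item_id!r}"
                )
            self._by_judge_item.setdefault((rec.judge_id, rec.item_id), []).append(rec)
        for (judge, item), recs in self._by_judge_item.items():
            if len(recs) > 3:
                raise DcvValidationError(
                    f"judge {judge}, item {item}: more than 3 allocations"
                )
            ranks = [r.rank for r in recs]
            if len(set(ranks)) != len(ranks):
                raise DcvValidationError(
                    f"judge {judge}, item {item}: duplicate ranks {ranks}"
                )
            doms = [r.domain for r in recs]
            if len(set(doms)) != len(doms):
                raise DcvValidationError(
                    f"judge {judge}, item {item}: duplicate domains {doms}"
                )
        self.judges: tuple[str, ...] = tuple(sorted({r.judge_id for r in self.records}))
        self.items: tuple[str, ...] = tuple(sorted({r.item_id for r in self.records}))

    def __len__(self) -> int:
        return len(self.records)

    def for_judge_item(self, judge_id: str, item_id: str) -> tuple[AllocationRecord, ...]:
        return tuple(
            sorted(self._by_judge_item.get((judge_id, item_id), ()), key=lambda r: r.rank)
        )

    def domains_allocated(self, item_id: str, rank_scope: str = "any") -> dict[str, int]:
        """Distinct-judge allocation counts per domain for one item.

        ``rank_scope`` is "any" (every allocation counts) or "first"
        (first-choice allocations only).
        """
        if rank_scope not in ("any", "first"):
            raise DcvValidationError(f"rank_scope must be 'any' or 'first', got {rank_scope!r}")
        seen: dict[str, set[str]] = {}
        for rec in self.records:
            if rec.item_id != item_id:
                continue
            if rank_scope == "first" and rec.rank != 1:
                continue
            seen.setdefault(rec.domain, set()).add(rec.judge_id)
        return {d: len(js) for d, js in sorted(seen.items())}


@dataclass(frozen=True)
class TactMapping:
    """Replacement text for TACT placeholders, for one language.

    Keys are the canonical placeholder names ``A`` (action), ``C`` (context),
    ``T`` (time), ``Ta`` (target), ``innovation`` and ``profession``.
    """

    mapping: Mapping[str, str]
    language: str = "en"

    def __post_init__(self) -> None:
        for key, value in self.mapping.items():
            if not value:
                raise DcvValidationError(f"TACT mapping for {key!r} is empty")
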