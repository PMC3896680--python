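"""Synthetic judge-allocation data with known ground truth.

The generator emulates the design of a DCV exercise: ``n_judges`` judges
each allocate every item to up to three distinct domains with a confidence
rating. Each item carries a *semantic profile* — a probability distribution
over domains describing where its meaning actually lives; a pure item
concentrates its profile on its intended domain, a mixed item splits it.
Judges draw allocations from the profile passed through a row-stochastic
domain-confusion matrix, so judge fallibility and item ambiguity are
separate dials.

Additional allocations (made with probability ``p_second``, then
``p_third``) are independent draws from the same profile; under the default
``extra_policy="skip"`` a draw that duplicates an earlier domain adds
nothing — a judge writes a second domain only when a distinct one comes to
mind, so extra allocations are naturally rare for pure items and common for
mixed ones. ``extra_policy="resample"`` instead forces a distinct domain,
making the expected allocation count exactly 1 + p2 + p2*p3.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DcvValidationError
from .model import AllocationRecord, AllocationTable, DomainSet, ItemBank, ItemSpec

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class SyntheticItem:
    """One designed item: intended domain(s), semantic profile, design label."""

    item_id: str
    intended: tuple[str, ...]
    profile: Mapping[str, float]
    design: str = "pure"  # "pure" | "mixed" | "misdesigned"

    def __post_init__(self) -> None:
        total = float(sum(self.profile.values()))
        if abs(total - 1.0) > 1e-6:
            raise DcvValidationError(
                f"item {self.item_id}: profile sums to {total}, expected 1"
            )
        if any(p < 0 for p in self.profile.values()):
            raise DcvValidationError(f"item {self.item_id}: negative profile mass")
        if not self.intended:
            raise DcvValidationError(f"item {self.item_id}: no intended domain")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a simulated DCV study."""

    domains: tuple[str, ...]
    items: tuple[SyntheticItem, ...]
    n_judges: int = 19
    p_second: float = 0.5
    p_third: float = 0.15
    confusion: tuple[tuple[float, ...], ...] | None = None  # rows/cols follow `domains`
    confidence_mean: float = 0.7
    confidence_concentration: float = 10.0
    confidence_rank_decay: float = 1.0  # multiplies the Beta mean per extra rank
    rescale_confidence: bool = True  # cap a judge's per-item confidences to sum <= 1
    extra_policy: str = "skip"  # "skip" | "resample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_judges < 1:
            raise DcvValidationError("n_judges must be >= 1")
        if not (0.0 <= self.p_third <= self.p_second <= 1.0):
            raise DcvValidationError(
                f"need 0 <= p_third <= p_second <= 1, got {self.p_second}, {self.p_third}"
            )
        if self.extra_policy not in ("skip", "resample"):
            raise DcvValidationError("extra_policy must be 'skip' or 'resample'")
        if not 0.0 < self.confidence_mean <= 1.0:
            raise DcvValidationError("confidence_mean must be in (0, 1]")
        if self.confidence_concentration <= 0:
            raise DcvValidationError("confidence_concentration must be positive")
        for item in self.items:
            unknown = [d for d in item.profile if d not in self.domains]
            unknown += [d for d in item.intended if d not in self.domains]
            if unknown:
                raise DcvValidationError(f"item {item.item_id}: unknown domains {unknown}")
        if self.confusion is not None:
            mat = np.asarray(self.confusion, dtype=float)
            k = len(self.domains)
            if mat.shape != (k, k):
                raise DcvValidationError(f"confusion must be {k}x{k}, got {mat.shape}")
            if np.any(mat < 0) or np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-6):
                raise DcvValidationError("confusion rows must be non-negative and sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    """The designed truth behind a generated table, for recovery tests."""

    items: tuple[SyntheticItem, ...]
    domains: tuple[str, ...]

    def design(self, item_id: str) -> str:
        for item in self.items:
            if item.item_id == item_id:
                return item.design
        raise KeyError(item_id)

    def ids_with_design(self, design: str) -> tuple[str, ...]:
        return tuple(i.item_id for i in self.items if i.design == design)

    def to_item_bank(self) -> ItemBank:
        """A minimal bank (synthetic, placeholder-free text) for the pipeline."""
        return ItemBank(
            tuple(
                ItemSpec(
                    item_id=i.item_id,
                    intended_domains=i.intended,
                    construct=f"synthetic-{i.design}",
                    text_by_language={"en": f"Synthetic item {i.item_id} ({i.design})"},
                )
                for i in self.items
            )
        )

    def to_domain_set(self) -> DomainSet:
        from .model import Domain

        return DomainSet(tuple(Domain(code=d, label=d) for d in self.domains))


def _allocation_distribution(item: SyntheticItem, config: SyntheticConfig) -> np.ndarray:
    """Profile composed with the confusion matrix, over config.domains order."""
    p = np.array([item.profile.get(d, 0.0) for d in config.domains], dtype=float)
    if config.confusion is not None:
        p = p @ np.asarray(config.confusion, dtype=float)
    total = p.sum()
    if total <= 0:
        raise DcvValidationError(f"item {item.item_id}: degenerate allocation distribution")
    return p / total


def generate_allocations(config: SyntheticConfig) -> tuple[AllocationTable, GroundTruth]:
    """Simulate one DCV exercise; byte-identical output for a given seed."""
    rng = np.random.default_rng(config.seed)
    domains = list(config.domains)
    k = len(domains)
    judges = [f"J{j + 1:02d}" for j in range(config.n_judges)]
    records: list[AllocationRecord] = []

    for item in config.items:
        dist = _allocation_distribution(item, config)
        for judge in judges:
            chosen: list[int] = [int(rng.choice(k, p=dist))]
            for gate in (config.p_second, config.p_third):
                if rng.random() >= gate:
                    break
                if config.extra_policy == "skip":
                    draw = int(rng.choice(k, p=dist))
                    if draw in chosen:
                        break
                    chosen.append(draw)
                else:  # resample: force a distinct domain
                    rest = dist.copy()
                    rest[chosen] = 0.0
                    total = rest.sum()
                    if total <= 0:
                        unused = [i for i in range(k) if i not in chosen]
                        if not unused:
                            break
                        rest[unused] = 1.0 / len(unused)
                    else:
                        rest /= total
                    chosen.append(int(rng.choice(k, p=rest)))
            mean = config.confidence_mean
            conc = config.confidence_concentration
            confs = []
            for rank_idx in range(len(chosen)):
                m = mean * config.confidence_rank_decay**rank_idx
                if m >= 1.0:
                    confs.append(1.0)  # degenerate: perfectly confident judges
                else:
                    m = float(np.clip(m, 0.01, 0.99))
                    confs.append(float(rng.beta(m * conc, (1.0 - m) * conc)))
            if config.rescale_confidence and sum(confs) > 1.0:
                total = sum(confs)
                confs = [c / total for c in confs]
            for rank_idx, (dom_idx, conf) in enumerate(zip(chosen, confs), start=1):
                records.append(
                    AllocationRecord(
                        judge_id=judge,
                        item_id=item.item_id,
                        rank=rank_idx,
                        domain=domains[dom_idx],
                        confidence=conf,
                    )
                )
    truth = GroundTruth(items=config.items, domains=config.domains)
    return AllocationTable(records), truth


def _spread_profile(
    domains: Sequence[str], masses: Mapping[str, float], remainder: float
) -> dict[str, float]:
    """Concentrated masses plus `remainder` spread evenly over the other domains."""
    rest = [d for d in domains if d not in masses]
    profile = dict(masses)
    for d in rest:
        profile[d] = remainder / len(rest)
    return profile


def study_scenario(
    seed: int = 0,
    n_judges: int = 19,
    purity: float = 0.9,
) -> SyntheticConfig:
    """The reference scenario mirroring the published study's dimensions.

    19 judges, 79 items, 14 domains: 60 pure items (profile mass ``purity``
    on the intended domain), 15 two-domain mixed items (0.45/0.45 between
    the intended domain and a contaminant), and 4 misdesigned items (mass
    ``purity`` on a non-intended domain); p_second = 0.5, p_third = 0.15.
    """
    domains = tuple(f"D{i + 1}" for i in range(14))
    items: list[SyntheticItem] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"S{idx:02d}"

    for i in range(60):
        d = domains[i % 14]
        items.append(
            SyntheticItem(
                item_id=next_id(),
                intended=(d,),
                profile=_spread_profile(domains, {d: purity}, 1.0 - purity),
                design="pure",
            )
        )
    for i in range(15):
        d = domains[i % 14]
        other = domains[(i + 1) % 14]
        items.append(
            SyntheticItem(
                item_id=next_id(),
                intended=(d,),
                profile=_spread_profile(domains, {d: 0.45, other: 0.45}, 0.10),
                design="mixed",
            )
        )
    for i in range(4):
        d = domains[i % 14]
        actual = domains[(i + 7) % 14]
        items.append(
            SyntheticItem(
                item_id=next_id(),
                intended=(d,),
                profile=_spread_profile(domains, {actual: purity}, 1.0 - purity),
                design="misdesigned",
            )
        )
    return SyntheticConfig(domains=domains, items=tuple(items), n_judges=n_judges, seed=seed)


def uniform_scenario(seed: int = 0, n_judges: int = 19, n_items: int = 79) -> SyntheticConfig:
    """A null scenario: every item's profile is uniform over the 14 domains.

    Under it no item should systematically classify to its nominal domain
    and chance-corrected agreement should hover around zero.
    """
    domains = tuple(f"D{i + 1}" for i in range(14))
    uniform = {d: 1.0 / 14 for d in domains}
    items = tuple(
        SyntheticItem(
            item_id=f"U{i + 1:02d}",
            intended=(domains[i % 14],),
            profile=uniform,
            design="pure",
        )
        for i in range(n_items)
    )
    return SyntheticConfig(domains=domains, items=items, n_judges=n_judges, seed=seed)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """A copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
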