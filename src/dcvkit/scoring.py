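"""Confidence-weighted judgment scores.

The DCV statistic: a judge's allocation of an item to a target domain is
coded +1 (match) or -1 (no match) and multiplied by the stated confidence,
so one weighted judgment lies in [-1, 1]. A judge's score for an
(item, target domain) pair is the sum over their up-to-three allocations of
that item; a judge with no allocation scores 0 (missing is scored 0). With
at most one of three distinct-domain allocations able to match the target,
per-judge scores lie in [-3, +1].
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DcvValidationError
from .model import AllocationRecord, AllocationTable, ItemBank


def signed_weight(allocation: AllocationRecord, target_domain: str) -> float:
    """+confidence if the allocation hits the target domain, else -confidence."""
    if allocation.domain == target_domain:
        return allocation.confidence
    return -allocation.confidence


def judge_item_score(
    allocs: Sequence[AllocationRecord], target_domain: str
) -> float:
    """Sum of signed weights of one judge's allocations of one item.

    An empty sequence scores 0 (the judge skipped the item).
    """
    if allocs:
        judges = {a.judge_id for a in allocs}
        items = {a.item_id for a in allocs}
        if len(judges) > 1 or len(items) > 1:
            raise DcvValidationError(
                "judge_item_score expects records of a single judge and item; "
                f"got judges {sorted(judges)}, items {sorted(items)}"
            )
    return float(sum(signed_weight(a, target_domain) for a in allocs))


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-judge scores for every (item, target domain) pair under test.

    ``scores`` has one row per judge and a (item_id, domain) MultiIndex on
    the columns; ``test_pairs`` lists the columns in order. For each item
    the tested domains are its intended domain(s) plus every non-intended
    domain allocated by at least ``min_coalloc_judges`` distinct judges —
    the "co-allocated" domains that can disqualify the item.
    """

    scores: pd.DataFrame
    test_pairs: tuple[tuple[str, str], ...]
    intended: dict[str, tuple[str, ...]]
    coallocated: dict[str, tuple[str, ...]]
    min_coalloc_judges: int

    @property
    def n_judges(self) -> int:
        return len(self.scores.index)

    def column(self, item_id: str, domain: str) -> np.ndarray:
        """All judges' scores for one (item, domain) pair."""
        return self.scores[(item_id, domain)].to_numpy(dtype=float)


def build_score_matrix(
    table: AllocationTable,
    bank: ItemBank,
    min_coalloc_judges: int = 2,
) -> ScoreMatrix:
    """Score every judge against every test pair of every bank item.

    All enrolled judges contribute to every pair (missing allocations score
    0), so the sample size is constant across tests.
    """
    if not table.judges:
        raise DcvValidationError("allocation table has no judges")
    if min_coalloc_judges < 1:
        raise DcvValidationError("min_coalloc_judges must be >= 1")

    judges = list(table.judges)
    pairs: list[tuple[str, str]] = []
    intended: dict[str, tuple[str, ...]] = {}
    coallocated: dict[str, tuple[str, ...]] = {}
    for item in bank:
        counts = table.domains_allocated(item.item_id)
        intended[item.item_id] = item.intended_domains
        coalloc = tuple(
            d
            for d, n in counts.items()
            if n >= min_coalloc_judges and d not in item.intended_domains
        )
        coallocated[item.item_id] = coalloc
        for d in item.intended_domains + coalloc:
            pairs.append((item.item_id, d))

    columns = pd.MultiIndex.from_tuples(pairs, names=["item_id", "domain"])
    scores = pd.DataFrame(0.0, index=judges, columns=columns)
    # score(judge, item, target) = 2 * conf_on_target - total_conf
    total_conf: dict[tuple[str, str], float] = {}
    conf_by_domain: dict[tuple[str, str, str], float] = {}
    for rec in table.records:
        key = (rec.judge_id, rec.item_id)
        total_conf[key] = total_conf.get(key, 0.0) + rec.confidence
        dkey = (rec.judge_id, rec.item_id, rec.domain)
        conf_by_domain[dkey] = conf_by_domain.get(dkey, 0.0) + rec.confidence
    for item_id, domain in pairs:
        col = np.zeros(len(judges))
        for j, judge in enumerate(judges):
            total = total_conf.get((judge, item_id), 0.0)
            on_target = conf_by_domain.get((judge, item_id, domain), 0.0)
            col[j] = 2.0 * on_target - total
        scores[(item_id, domain)] = col

    return ScoreMatrix(
        scores=scores,
        test_pairs=tuple(pairs),
        intended=intended,
        coallocated=coallocated,
        min_coalloc_judges=min_coalloc_judges,
    )
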