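"""One-tailed tests, FDR control, and the item inclusion taxonomy.

An item is *classified* as measuring a domain when the judges' summed
weighted judgments against that domain are significantly greater than zero
(one-sample, one-tailed, Benjamini-Hochberg corrected across all tests in
the run). The inclusion rule is strict: an item enters the final
questionnaire only if it is classified to an intended domain, no
non-intended domain was co-allocated by two or more judges, and no test on
another domain is significant.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DcvValidationError

OUTCOMES = ("pure_intended", "mixed", "misclassified", "unclassified")


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the DCV analysis.

    alpha: per-test significance level / FDR target (default 0.05).
    fdr_method: "bh" (Benjamini-Hochberg step-up) or "none" (raw p <= alpha).
    fdr_family: "global" pools every test in the run into one family;
        "per_item" corrects within each item separately.
    min_coalloc_judges: distinct-judge threshold above which a non-intended
        domain counts as co-allocated (default 2, i.e. "more than one judge").
    tail: fixed to "greater"; the hypothesis is directional.
    """

    alpha: float = 0.05
    fdr_method: str = "bh"
    fdr_family: str = "global"
    min_coalloc_judges: int = 2
    tail: str = field(default="greater")

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DcvValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fdr_method not in ("bh", "none"):
            raise DcvValidationError(f"fdr_method must be 'bh' or 'none', got {self.fdr_method!r}")
        if self.fdr_family not in ("global", "per_item"):
            raise DcvValidationError(f"fdr_family must be 'global' or 'per_item'")
        if self.tail != "greater":
            raise DcvValidationError("only the upper-tailed test is defined for DCV")


@dataclass(frozen=True)
class OneSampleTTest:
    """Core one-sample t-test quantities (upper tail)."""

    n: int
    mean: float
    sd: float
    t: float
    df: int
    p: float


@dataclass
class DcvTestResult:
    """One (item, target domain) test, with its post-FDR rejection flag."""

    item_id: str
    target_domain: str
    n: int
    mean: float
    sd: float
    t: float
    df: int
    p: float
    is_intended: bool = False
    p_adjusted: float | None = None
    rejected: bool | None = None


@dataclass(frozen=True)
class ItemClassification:
    """Final taxonomy of one item.

    outcome: "pure_intended" (classified to an intended domain only, no
    co-allocations), "misclassified" (significantly classified to a
    non-intended domain), "mixed" (co-allocated to other domains), or
    "unclassified" (no significant positive test, no co-allocations).
    Only pure_intended items enter the final questionnaire.
    """

    item_id: str
    intended: tuple[str, ...]
    classified_domains: frozenset[str]
    coallocated_domains: frozenset[str]
    outcome: str
    include_final: bool


def one_sample_t_greater(scores: Sequence[float]) -> OneSampleTTest:
    """Upper-tailed one-sample t-test of mean > 0, sample sd (n-1 denominator).

    Zero-variance convention: sd = 0 with a positive mean is certain evidence
    (p = 0), with a negative mean certain counter-evidence (p = 1), and with
    mean 0 uninformative (p = 0.5). These arise in perfect-agreement data.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    if n < 2:
        raise DcvValidationError(f"one-sample t-test needs n >= 2, got n = {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean > 0:
            t, p = float("inf"), 0.0
        elif mean < 0:
            t, p = float("-inf"), 1.0
        else:
            t, p = 0.0, 0.5
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(stats.t.sf(t, df))
    return OneSampleTTest(n=n, mean=mean, sd=sd, t=float(t), df=df, p=p)


def bh_adjust(
    pvalues: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (rejection flags, adjusted p-values).

    Flags are in the original order; ties are handled by a stable sort.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise DcvValidationError("bh_adjust: empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DcvValidationError("bh_adjust: p-values must lie in [0, 1]")
    rejected, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected.astype(bool), adjusted


def apply_fdr(results: Iterable[DcvTestResult], params: AnalysisParams) -> None:
    """Fill ``p_adjusted`` and ``rejected`` on the given results, in place.

    The correction family is every supplied test ("global") or the tests of
    each item separately ("per_item"); with fdr_method "none" each test is
    simply compared to alpha.
    """
    results = list(results)
    if not results:
        return
    if params.fdr_method == "none":
        for r in results:
            r.p_adjusted = r.p
            r.rejected = r.p <= params.alpha
        return
    if params.fdr_family == "global":
        families = [results]
    else:
        by_item: dict[str, list[DcvTestResult]] = {}
        for r in results:
            by_item.setdefault(r.item_id, []).append(r)
        families = list(by_item.values())
    for family in families:
        flags, adjusted = bh_adjust([r.p for r in family], alpha=params.alpha)
        for r, flag, adj in zip(family, flags, adjusted):
            r.p_adjusted = float(adj)
            r.rejected = bool(flag)


def classify_item(
    results: Sequence[DcvTestResult],
    coalloc: Iterable[str],
    intended: Iterable[str],
    params: AnalysisParams,
) -> ItemClassification:
    """Apply the inclusion taxonomy to one item's post-FDR test results."""
    intended = tuple(intended)
    coalloc = frozenset(coalloc)
    if not results:
        raise DcvValidationError("classify_item: no test results supplied")
    item_ids = {r.item_id for r in results}
    if len(item_ids) > 1:
        raise DcvValidationError(f"classify_item: results span items {sorted(item_ids)}")
    item_id = next(iter(item_ids))
    tested = {r.target_domain for r in results}
    missing = [d for d in intended if d not in tested]
    if missing:
        raise DcvValidationError(
            f"classify_item: intended domain(s) {missing} missing from results of {item_id}"
        )
    if any(r.rejected is None for r in results):
        raise DcvValidationError("classify_item: run apply_fdr before classification")

    classified = frozenset(
        r.target_domain for r in results if r.rejected and r.mean > 0
    )
    intended_hit = any(d in classified for d in intended)
    other_hit = any(d not in intended for d in classified)

    if intended_hit and not coalloc and not other_hit:
        outcome = "pure_intended"
    elif other_hit:
        outcome = "misclassified"
    elif coalloc:
        outcome = "mixed"
    else:
        outcome = "unclassified"
    return ItemClassification(
        item_id=item_id,
        intended=intended,
        classified_domains=classified,
        coallocated_domains=coalloc,
        outcome=outcome,
        include_final=outcome == "pure_intended",
    )


def select_final_items(
    classifications: Sequence[ItemClassification],
    domains: Iterable[str] = (),
) -> dict[str, list[str]]:
    """Group included items by intended domain.

    ``domains`` pre-seeds the grouping so domains that received no item
    appear with an empty list (as the published final lists do). An included
    item with two intended domains is listed under each.
    """
    groups: dict[str, list[str]] = {d: [] for d in domains}
    for cls in classifications:
        if not cls.include_final:
            continue
        for d in cls.intended:
            groups.setdefault(d, []).append(cls.item_id)
    return groups
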