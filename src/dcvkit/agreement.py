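"""Inter-rater agreement: Cohen's kappa, Light's kappa, bootstrap CIs.

Light's kappa generalizes Cohen's kappa to more than two raters as the
unweighted mean of Cohen's kappa over all rater pairs. Agreement is
assessed both on the judges' first-choice domain labels (one 79 x 19
nominal matrix) and per domain on binary selected/not-selected matrices.
Confidence intervals come from a percentile bootstrap over items, since
items — not judges — are the sampling units of a DCV study.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DcvValidationError
from .model import AllocationTable, ItemBank

_EPS = 1e-12


@dataclass(frozen=True)
class KappaResult:
    """An agreement coefficient with optional percentile CI and rater audit."""

    scope: str  # "overall" or a domain code
    kappa: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_raters_used: int = 0
    excluded_raters: frozenset[str] = frozenset()
    n_items: int = 0
    ci_method: str | None = None  # "percentile bootstrap over items" when computed


def cohen_kappa(a, b) -> float:
    """Cohen's kappa between two label vectors, pairwise-complete.

    Missing entries (None or NaN) are dropped pairwise. Degenerate
    convention: if chance agreement p_e = 1 (both raters constant on the
    same label), return 1 for perfect observed agreement and 0 otherwise.
    """
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape:
        raise DcvValidationError(f"cohen_kappa: length mismatch {a.shape} vs {b.shape}")

    def _missing(x):
        return np.array([v is None or (isinstance(v, float) and np.isnan(v)) for v in x])

    mask = ~(_missing(a) | _missing(b))
    a, b = a[mask], b[mask]
    n = a.size
    if n == 0:
        raise DcvValidationError("cohen_kappa: no pairwise-complete entries")
    cats = {str(v): i for i, v in enumerate(sorted({str(x) for x in np.concatenate([a, b])}))}
    ai = np.array([cats[str(v)] for v in a])
    bi = np.array([cats[str(v)] for v in b])
    return _kappa_coded(ai, bi, len(cats))


def _kappa_coded(ai: np.ndarray, bi: np.ndarray, k: int) -> float:
    """Kappa for integer-coded complete vectors (fast path)."""
    n = ai.size
    p_o = float(np.mean(ai == bi))
    pa = np.bincount(ai, minlength=k) / n
    pb = np.bincount(bi, minlength=k) / n
    p_e = float(pa @ pb)
    if p_e >= 1.0 - _EPS:
        return 1.0 if p_o >= 1.0 - _EPS else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def _as_matrix(m) -> pd.DataFrame:
    if isinstance(m, pd.DataFrame):
        return m
    return pd.DataFrame(np.asarray(m))


def light_kappa(m) -> float:
    """Mean Cohen's kappa over all rater (column) pairs of an items x raters matrix.

    Pairs with no pairwise-complete entries are skipped; at least one pair
    must be computable.
    """
    m = _as_matrix(m)
    if m.shape[1] < 2:
        raise DcvValidationError("light_kappa needs at least 2 raters")
    arr = m.to_numpy(dtype=object)
    # integer-code once over the whole matrix (missing -> -1)
    flat = [v for v in arr.ravel() if not (v is None or (isinstance(v, float) and np.isnan(v)))]
    cats = {str(v): i for i, v in enumerate(sorted({str(x) for x in flat}))}
    coded = np.full(arr.shape, -1, dtype=int)
    for (i, j), v in np.ndenumerate(arr):
        if not (v is None or (isinstance(v, float) and np.isnan(v))):
            coded[i, j] = cats[str(v)]
    kappas = []
    for c1, c2 in combinations(range(coded.shape[1]), 2):
        a, b = coded[:, c1], coded[:, c2]
        mask = (a >= 0) & (b >= 0)
        if not mask.any():
            continue
        kappas.append(_kappa_coded(a[mask], b[mask], len(cats)))
    if not kappas:
        raise DcvValidationError("light_kappa: no rater pair has complete entries")
    return float(np.mean(kappas))


def first_choice_matrix(table: AllocationTable, items: Iterable[str] | None = None) -> pd.DataFrame:
    """Items x judges matrix of first-rank domain codes (NaN where missing)."""
    item_ids = list(items) if items is not None else list(table.items)
    judges = list(table.judges)
    m = pd.DataFrame(np.nan, index=item_ids, columns=judges, dtype=object)
    for rec in table.records:
        if rec.rank == 1 and rec.item_id in m.index:
            m.loc[rec.item_id, rec.judge_id] = rec.domain
    return m


def domain_binary_matrix(
    table: AllocationTable,
    domain: str,
    rank_scope: str = "any",
    items: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Items x judges 0/1 matrix: did the judge select this domain for the item.

    ``rank_scope`` "any" counts any of the up-to-three allocations, "first"
    only the first choice. A judge who skipped an item scores 0.
    """
    if rank_scope not in ("any", "first"):
        raise DcvValidationError(f"rank_scope must be 'any' or 'first', got {rank_scope!r}")
    item_ids = list(items) if items is not None else list(table.items)
    judges = list(table.judges)
    m = pd.DataFrame(0, index=item_ids, columns=judges, dtype=int)
    for rec in table.records:
        if rec.domain != domain or rec.item_id not in m.index:
            continue
        if rank_scope == "first" and rec.rank != 1:
            continue
        m.loc[rec.item_id, rec.judge_id] = 1
    return m


def bootstrap_kappa_ci(
    matrix,
    statistic: Callable = light_kappa,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI of an agreement statistic, resampling items (rows).

    Deterministic given ``seed``. Resamples for which the statistic is
    undefined (e.g. a rater pair losing all complete entries) are skipped.
    """
    m = _as_matrix(matrix)
    if m.shape[0] < 2:
        raise DcvValidationError("bootstrap_kappa_ci: need at least 2 items")
    if n_boot < 100:
        raise DcvValidationError("bootstrap_kappa_ci: n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = m.shape[0]
    values = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(statistic(m.iloc[idx]))
        except DcvValidationError:
            continue
    if not values:
        raise DcvValidationError("bootstrap_kappa_ci: statistic undefined on all resamples")
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def overall_kappa(
    table: AllocationTable,
    items: Iterable[str] | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> KappaResult:
    """Light's kappa over judges' first-choice labels for the given items."""
    m = first_choice_matrix(table, items=items)
    kappa = light_kappa(m)
    ci = (None, None)
    method = None
    if n_boot:
        ci = bootstrap_kappa_ci(m, light_kappa, n_boot=n_boot, seed=seed)
        method = "percentile bootstrap over items"
    return KappaResult(
        scope="overall", kappa=kappa, ci_low=ci[0], ci_high=ci[1],
        n_raters_used=m.shape[1], n_items=m.shape[0], ci_method=method,
    )


def domain_kappa(
    table: AllocationTable,
    domain: str,
    drop_empty_raters: bool = True,
    rank_scope: str = "any",
    items: Iterable[str] | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> KappaResult:
    """Light's kappa on one domain's binary selected/not-selected matrix.

    With ``drop_empty_raters`` (the default), judges who never selected the
    domain for any of the given items are excluded and recorded in
    ``excluded_raters`` — their all-zero columns carry no information about
    the domain. Raises if fewer than 2 raters remain.
    """
    m = domain_binary_matrix(table, domain, rank_scope=rank_scope, items=items)
    excluded: frozenset[str] = frozenset()
    if drop_empty_raters:
        empty = [c for c in m.columns if (m[c] == 0).all()]
        excluded = frozenset(str(c) for c in empty)
        m = m.drop(columns=empty)
    if m.shape[1] < 2:
        raise DcvValidationError(
            f"domain_kappa({domain}): fewer than 2 raters remain "
            f"({m.shape[1]} after excluding {len(excluded)})"
        )
    kappa = light_kappa(m)
    ci = (None, None)
    method = None
    if n_boot:
        ci = bootstrap_kappa_ci(m, light_kappa, n_boot=n_boot, seed=seed)
        method = "percentile bootstrap over items"
    return KappaResult(
        scope=domain, kappa=kappa, ci_low=ci[0], ci_high=ci[1],
        n_raters_used=m.shape[1], excluded_raters=excluded,
        n_items=m.shape[0], ci_method=method,
    )


def judge_match_counts(table: AllocationTable, bank: ItemBank) -> pd.Series:
    """Per judge, the number of items whose allocations include an intended domain."""
    counts = pd.Series(0, index=list(table.judges), dtype=int)
    for judge in table.judges:
        n = 0
        for item in bank:
            allocs = table.for_judge_item(judge, item.item_id)
            if any(a.domain in item.intended_domains for a in allocs):
                n += 1
        counts[judge] = n
    return counts


def judge_match_correlation(
    table: AllocationTable,
    bank: ItemBank,
    covariate: Mapping[str, float],
) -> tuple[float, float]:
    """Pearson correlation (r, p) of per-judge match counts with a covariate.

    The covariate (e.g. mean expertise rating, academic level) is indexed by
    judge id. Raises if either vector has zero variance.
    """
    counts = judge_match_counts(table, bank)
    missing = [j for j in counts.index if j not in covariate]
    if missing:
        raise DcvValidationError(f"covariate missing for judges {missing}")
    x = counts.to_numpy(dtype=float)
    y = np.array([float(covariate[j]) for j in counts.index])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DcvValidationError("judge_match_correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
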