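"""End-to-end DCV analysis and report writing.

``run_pipeline`` composes scoring -> inference -> agreement on a validated
allocation table and item bank, yielding a :class:`DcvReport` with the full
per-test table, per-item classifications, the final item lists per domain,
and agreement coefficients (overall and per domain, over all items and over
the final items only). Everything is deterministic given inputs and the
bootstrap seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .agreement import KappaResult, domain_kappa, overall_kappa
from .errors import DcvError, DcvValidationError
from .inference import (
    AnalysisParams,
    DcvTestResult,
    ItemClassification,
    apply_fdr,
    classify_item,
    one_sample_t_greater,
    select_final_items,
)
from .model import AllocationTable, DomainSet, ItemBank, TactMapping
from .scoring import build_score_matrix
from .tact import render_item


@dataclass
class DcvReport:
    """Everything one DCV run produces."""

    tests: list[DcvTestResult]
    classifications: list[ItemClassification]
    final_items: dict[str, list[str]]
    kappas_all_items: list[KappaResult]
    kappas_final_items: list[KappaResult]
    params: AnalysisParams
    seed: int | None
    n_judges: int
    n_items: int

    @property
    def included_ids(self) -> list[str]:
        return [c.item_id for c in self.classifications if c.include_final]

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.tests])

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classifications:
            rows.append(
                {
                    "item_id": c.item_id,
                    "intended": ";".join(c.intended),
                    "classified": ";".join(sorted(c.classified_domains)),
                    "coallocated": ";".join(sorted(c.coallocated_domains)),
                    "outcome": c.outcome,
                    "include_final": c.include_final,
                }
            )
        return pd.DataFrame(rows)

    def kappa_frame(self) -> pd.DataFrame:
        rows = []
        for label, results in (
            ("all_items", self.kappas_all_items),
            ("final_items", self.kappas_final_items),
        ):
            for k in results:
                rows.append(
                    {
                        "item_set": label,
                        "scope": k.scope,
                        "kappa": k.kappa,
                        "ci_low": k.ci_low,
                        "ci_high": k.ci_high,
                        "n_raters_used": k.n_raters_used,
                        "n_excluded_raters": len(k.excluded_raters),
                        "n_items": k.n_items,
                        "ci_method": k.ci_method or "",
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        counts: dict[str, int] = {}
        for c in self.classifications:
            counts[c.outcome] = counts.get(c.outcome, 0) + 1
        return {
            "n_items": self.n_items,
            "n_judges": self.n_judges,
            "included": len(self.included_ids),
            "excluded": self.n_items - len(self.included_ids),
            "outcomes": dict(sorted(counts.items())),
            "final_items_per_domain": {d: len(v) for d, v in self.final_items.items()},
            "params": asdict(self.params),
            "seed": self.seed,
            "version": _version,
        }


def _agreement_block(
    table: AllocationTable,
    domains: DomainSet,
    items: list[str],
    n_boot: int,
    seed: int | None,
) -> list[KappaResult]:
    results: list[KappaResult] = []
    try:
        results.append(overall_kappa(table, items=items, n_boot=n_boot, seed=seed))
    except DcvValidationError:
        pass
    for d in domains.codes:
        try:
            results.append(
                domain_kappa(table, d, items=items, n_boot=n_boot, seed=seed)
            )
        except DcvValidationError:
            # fewer than two informative raters: agreement undefined for this
            # domain on this item set (rendered as "-" in reports)
            continue
    return results


def run_pipeline(
    table: AllocationTable,
    bank: ItemBank,
    domains: DomainSet,
    params: AnalysisParams | None = None,
    seed: int | None = 0,
    n_boot: int = 0,
) -> DcvReport:
    """Run the full DCV analysis.

    n_boot > 0 adds percentile-bootstrap CIs to every kappa (slower); the
    point estimates do not depend on the seed.
    """
    params = params or AnalysisParams()
    if not table.judges:
        raise DcvValidationError("no judges in the allocation table")
    bank.validate_against(domains)
    matrix = build_score_matrix(table, bank, min_coalloc_judges=params.min_coalloc_judges)

    tests: list[DcvTestResult] = []
    for item_id, domain in matrix.test_pairs:
        core = one_sample_t_greater(matrix.column(item_id, domain))
        tests.append(
            DcvTestResult(
                item_id=item_id,
                target_domain=domain,
                n=core.n,
                mean=core.mean,
                sd=core.sd,
                t=core.t,
                df=core.df,
                p=core.p,
                is_intended=domain in matrix.intended[item_id],
            )
        )
    apply_fdr(tests, params)

    by_item: dict[str, list[DcvTestResult]] = {}
    for t in tests:
        by_item.setdefault(t.item_id, []).append(t)
    classifications = [
        classify_item(
            by_item[item.item_id],
            coalloc=matrix.coallocated[item.item_id],
            intended=item.intended_domains,
            params=params,
        )
        for item in bank
    ]
    final_items = select_final_items(classifications, domains=domains.codes)

    all_ids = [i.item_id for i in bank]
    final_ids = [c.item_id for c in classifications if c.include_final]
    kappas_all = _agreement_block(table, domains, all_ids, n_boot, seed)
    kappas_final = (
        _agreement_block(table, domains, final_ids, n_boot, seed)
        if len(final_ids) >= 2
        else []
    )

    return DcvReport(
        tests=tests,
        classifications=classifications,
        final_items=final_items,
        kappas_all_items=kappas_all,
        kappas_final_items=kappas_final,
        params=params,
        seed=seed,
        n_judges=len(table.judges),
        n_items=len(bank),
    )


def write_report(
    report: DcvReport,
    outdir: str | Path,
    bank: ItemBank | None = None,
    tact: TactMapping | None = None,
) -> list[Path]:
    """Write the report as TSV tables plus a machine-readable summary.

    With a bank and TACT mapping, also renders the final questionnaire.
    Output is byte-identical across re-runs with the same inputs and seed.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DcvError(f"cannot create output directory {outdir}: {exc}") from exc

    written: list[Path] = []

    def _frame(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    _frame("tests.tsv", report.tests_frame())
    _frame("classifications.tsv", report.classification_frame())
    _frame("kappa.tsv", report.kappa_frame())

    summary = report.summary()
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
    written.append(summary_path)

    config_blob = json.dumps(summary["params"], sort_keys=True) + str(report.seed)
    log = {
        "params": summary["params"],
        "seed": report.seed,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:16],
        "version": _version,
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    written.append(log_path)

    if bank is not None and tact is not None:
        lines = []
        for domain_code, item_ids in report.final_items.items():
            for item_id in item_ids:
                lines.append(f"{domain_code}\t{render_item(bank[item_id], tact)}")
        q_path = outdir / f"questionnaire_{tact.language}.txt"
        q_path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        written.append(q_path)

    return written
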