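"""Orchestration of the stepwise validation run and report rendering.

Execution follows the suggested checking order: external concordance with
the report (1), linkage (2), identity (3), completeness (4), uniformity
(5), time patterns (6), plausibility (7), event attributes (8),
cross-source consistency (9) and, when an external outcome table is
supplied, comparison against it (12).  Deduplication is computed before the
linkage denominators; report rows are always emitted in step order.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import List, Optional

import pandas as pd

from . import concordance, integrity, linkage, plausibility, temporal
from .results import RuleResult, ValidityReport
from .warehouse import Warehouse, load_warehouse

log = logging.getLogger(__name__)

#: Step number -> report section (mirrors the external/internal grouping).
STEP_GROUP = {1: "external", 12: "external"}


def validate_warehouse(
    config_or_warehouse,
    prior_year_extract: Optional[pd.DataFrame] = None,
    fix_postdeath: bool = False,
) -> ValidityReport:
    """Run the full stepwise validation and return the report.

    ``config_or_warehouse`` is a config path or an in-memory
    :class:`Warehouse`.  ``prior_year_extract`` supplements the blood-bank
    product extract for the linkage and per-year checks (repairing
    first-year boundary artifacts).  With ``fix_postdeath`` the mortality
    status of patients with post-death events is blanked before the
    post-death rule is (re-)evaluated; the fix count lands in the notes.
    Any single check failure is captured as an errored row; the run always
    continues.
    """
    if isinstance(config_or_warehouse, (str, Path)):
        w = load_warehouse(config_or_warehouse)
    else:
        w = config_or_warehouse
    t0 = time.time()
    rows: List[RuleResult] = []
    tables: dict = {}

    def guarded(step, concept, rule_id, fn):
        try:
            out = fn()
            for r in out:
                log.info(
                    "%s/%s: %s/%s", r.rule_id, r.source_id, r.numerator, r.denominator
                )
            rows.extend(out)
        except Exception as exc:  # noqa: BLE001 - isolation contract
            log.exception("check %s failed", rule_id)
            rows.append(RuleResult.not_evaluable(rule_id, step, concept, "pooled", f"error: {exc}"))

    # step 3 runs first so later denominators are post-dedup
    dedup_rows: List[RuleResult] = []
    try:
        dedup_rows, w2 = integrity.deduplicate(w)
    except Exception as exc:  # noqa: BLE001
        log.exception("deduplication failed")
        dedup_rows = [RuleResult.not_evaluable("I1", 3, "identity", "pooled", f"error: {exc}")]
        w2 = w
    rows.extend(dedup_rows)

    guarded(1, "concordance_report", "C1", lambda: concordance.report_agreement(w2))

    link_map = None

    def do_l1():
        nonlocal link_map
        res, link_map = linkage.link_transfusions_to_products(w2, prior=prior_year_extract)
        return res

    guarded(2, "linkage", "L1", do_l1)
    guarded(2, "linkage", "L2", lambda: linkage.link_products_to_transfusions(w2))
    guarded(2, "linkage", "L3", lambda: linkage.link_products_to_donations_and_donors(w2))
    guarded(4, "completeness", "K1", lambda: integrity.field_completeness(w2))
    guarded(4, "completeness", "K3", lambda: integrity.transfusion_diagnosis_coverage(w2))
    guarded(5, "uniformity", "U1", lambda: integrity.code_conformance_all(w2))
    guarded(5, "uniformity", "U3", lambda: integrity.precision_uniformity(w2, "Hb"))

    def do_temporal():
        res, tbls = temporal.run(w2, prior_year_extract)
        tables.update(tbls)
        return res

    guarded(6, "time_patterns", "T1", do_temporal)

    w3 = w2
    n_fixed = 0
    if fix_postdeath:
        try:
            w3, n_fixed = plausibility.fix_postdeath(w2)
        except Exception as exc:  # noqa: BLE001
            log.exception("post-death fix failed")
            w3 = w2
    plaus_rows = plausibility.run_all_rules(w3, w3.thresholds, link_map=link_map)
    if fix_postdeath:
        for r in plaus_rows:
            if r.rule_id == "P8":
                r.notes = (r.notes + f"; {n_fixed} patients changed mortality status to NA").strip("; ")
                r.details["patients_fixed"] = n_fixed
    rows.extend(plaus_rows)
    guarded(8, "event_attributes", "E3", lambda: linkage.link_transfusions_to_hospitalizations(w3))

    rows.append(
        concordance.hospital_consistency(
            rows, w.thresholds.consistency_flag_pct, list(w.hospitals)
        )
    )

    if w.external_outcomes is not None:
        guarded(12, "concordance_databases", "X1", lambda: _external_comparison(rows, w))
    else:
        rows.append(
            RuleResult.not_evaluable(
                "X1", 12, "concordance_databases", "pooled", "no external outcome table supplied"
            )
        )

    log.info("validation finished in %.1fs (%d rows)", time.time() - t0, len(rows))
    report = ValidityReport(rows=rows, label="warehouse", tables=tables).sorted()
    return report


def _external_comparison(rows: List[RuleResult], w: Warehouse) -> List[RuleResult]:
    """Step 12: compare this run's pooled outcomes to an externally entered
    outcome table (rule_id, numerator, denominator, percentage)."""
    own = ValidityReport(rows=rows, label="this_warehouse")
    ext_rows = []
    for _, r in w.external_outcomes.iterrows():
        ext_rows.append(
            RuleResult(
                rule_id=str(r["rule_id"]),
                step=12,
                concept="concordance_databases",
                source_id="external",
                numerator=int(r["numerator"]),
                denominator=int(r["denominator"]),
            )
        )
    ext = ValidityReport(rows=ext_rows, label="external")
    table = concordance.compare_outcomes([own, ext], w.thresholds.consistency_flag_pct)
    shared = table[table["shared"]]
    flagged = shared[shared["flagged"]]["rule_id"].tolist()
    return [
        RuleResult(
            rule_id="X1",
            step=12,
            concept="concordance_databases",
            source_id="pooled",
            numerator=len(flagged),
            denominator=len(shared) if len(shared) else None,
            direction="violation",
            offending_ids=flagged,
            details={"compared_rules": len(shared)},
            evaluable=len(shared) > 0,
        )
    ]


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def render_report(report: ValidityReport, out_dir: str | Path, formats=("csv", "md"),
                  offender_cap: int = 20) -> List[Path]:
    """Write the report as CSV (machine) and Markdown (human).

    Percentages print with two decimals; not-evaluable rows render as
    ``n/e``, never as 0 %.  Offending-id samples are capped in the Markdown
    view; the full lists go to a sidecar ``offenders.csv``.
    """
    if not report.rows:
        raise ValueError("empty report")
    unknown = set(formats) - {"csv", "md"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    frame = report.frame()
    if "csv" in formats:
        path = out / "report.csv"
        frame.to_csv(path, index=False, float_format="%.2f")
        written.append(path)
        side = []
        for r in report.rows:
            for oid in r.offending_ids:
                side.append({"rule_id": r.rule_id, "source_id": r.source_id, "record_id": oid})
        pd.DataFrame(side, columns=["rule_id", "source_id", "record_id"]).to_csv(
            out / "offenders.csv", index=False
        )
        written.append(out / "offenders.csv")
        for name, table in report.tables.items():
            table.to_csv(out / f"{name}.csv")
            written.append(out / f"{name}.csv")
    if "md" in formats:
        lines = ["# Validity report", ""]
        group = None
        header = "| Step | Concept | Rule | Source | n/N | % | Notes |"
        rule_sep = "|---|---|---|---|---|---|---|"
        for r in report.rows:
            g = STEP_GROUP.get(r.step, "internal")
            if g != group:
                group = g
                lines.extend(["", f"## {group.capitalize()} validation", "", header, rule_sep])
            pct = f"{r.percentage:.2f}" if r.percentage is not None else "n/e"
            nn = (
                f"{r.numerator}/{r.denominator}"
                if r.evaluable and r.denominator is not None
                else "n/e"
            )
            sample = ", ".join(map(str, r.offending_ids[:offender_cap]))
            notes = r.notes.replace("|", "/")
            if sample:
                notes = (notes + f" [sample: {sample}]").strip()
            lines.append(
                f"| {r.step} | {r.concept} | {r.rule_id} | {r.source_id} | {nn} | {pct} | {notes} |"
            )
        path = out / "report.md"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written


def read_report_csv(path: str | Path) -> ValidityReport:
    """Reload a rendered CSV report (the same schema compare_outcomes uses)."""
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        evaluable = bool(r["evaluable"])
        rows.append(
            RuleResult(
                rule_id=str(r["rule_id"]),
                step=int(r["step"]),
                concept=str(r["concept"]),
                source_id=str(r["source_id"]),
                numerator=int(r["numerator"]) if evaluable and pd.notna(r["numerator"]) else None,
                denominator=int(r["denominator"]) if evaluable and pd.notna(r["denominator"]) else None,
                direction=str(r["direction"]),
                notes="" if pd.isna(r["notes"]) else str(r["notes"]),
                evaluable=evaluable,
            )
        )
    return ValidityReport(rows=rows, label=Path(path).stem)

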