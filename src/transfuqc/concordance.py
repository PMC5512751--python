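"""External concordance and cross-source comparison (steps 1, 9, 12).

The report-agreement statistic compares per-product-type counts in the
warehouse with an external aggregate (e.g. an annual blood-bank report):

    agreement% = (1 - sum_p |N_ext,p - N_dwh,p| / sum_p N_dwh,p) * 100

with the absolute discrepancy summed over product types.  Agreement can go
negative when the discrepancy exceeds the warehouse count; the displayed
value is clamped at 0 with the raw value kept in the details.
"""

from __future__ import annotations

from typing import List, Optional

import pandas as pd

from .results import RuleResult, ValidityReport, round_pct, with_pooled
from .warehouse import Warehouse


def report_agreement(
    w: Warehouse, external: Optional[pd.DataFrame] = None
) -> List[RuleResult]:
    """C1: agreement between warehouse product counts and external counts.

    External rows are (year, product_type, count); counts are summed over
    years per product type.  Types present in the warehouse but absent from
    the external table are not evaluable and excluded from the overall sum.
    """
    external = external if external is not None else w.external_aggregates
    products = w.blood_bank.table("products")
    if external is None or products is None:
        return [
            RuleResult.not_evaluable(
                "C1", 1, "concordance_report", w.blood_bank.source_id,
                "no external aggregates supplied",
            )
        ]
    dwh = products["product_type"].value_counts().to_dict()
    ext = external.groupby("product_type")["count"].sum().to_dict()
    per_type = {}
    total_diff = 0
    total_dwh = 0
    gaps = []
    for ptype, n_dwh in sorted(dwh.items()):
        if ptype not in ext:
            per_type[ptype] = None
            gaps.append(ptype)
            continue
        diff = abs(int(ext[ptype]) - int(n_dwh))
        raw = (1 - diff / n_dwh) * 100 if n_dwh else None
        per_type[ptype] = {
            "external": int(ext[ptype]),
            "warehouse": int(n_dwh),
            "agreement_pct": round(max(raw, 0.0), 2) if raw is not None else None,
            "raw_agreement_pct": round(raw, 2) if raw is not None else None,
        }
        total_diff += diff
        total_dwh += int(n_dwh)
    for ptype in sorted(set(ext) - set(dwh)):
        per_type[ptype] = {"external": int(ext[ptype]), "warehouse": 0, "agreement_pct": None}
        gaps.append(ptype)
    if total_dwh == 0:
        return [
            RuleResult.not_evaluable(
                "C1", 1, "concordance_report", w.blood_bank.source_id,
                "no warehouse products in externally covered types",
            )
        ]
    agreement = max(total_dwh - total_diff, 0)
    notes = f"absolute discrepancy {total_diff} over {total_dwh} products"
    if gaps:
        notes += f"; not evaluable for types: {', '.join(gaps)}"
    return [
        RuleResult(
            rule_id="C1",
            step=1,
            concept="concordance_report",
            source_id=w.blood_bank.source_id,
            numerator=agreement,
            denominator=total_dwh,
            details={"per_type": per_type, "raw_overall_pct": round((1 - total_diff / total_dwh) * 100, 2)},
            notes=notes,
        )
    ]


def compare_outcomes(
    reports: List[ValidityReport], flag_pct: float = 5.0
) -> pd.DataFrame:
    """Per-rule comparison of two or more reports (step 9 / step 12).

    Returns one row per shared rule id with each report's percentage, the
    maximum pairwise absolute difference in percentage points, and a flag
    when it exceeds ``flag_pct``.  Rules absent from some reports are
    listed with null entries for the missing side.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    labels = []
    for i, r in enumerate(reports):
        label = r.label or f"report_{i}"
        if label in labels:
            label = f"{label}_{i}"
        labels.append(label)
    pct_by_label = {}
    for label, rep in zip(labels, reports):
        pcts = {}
        for row in rep.rows:
            if row.percentage is not None and row.rule_id not in pcts:
                pcts[row.rule_id] = row.percentage
        pct_by_label[label] = pcts
    shared = set.intersection(*(set(p) for p in pct_by_label.values()))
    all_rules = sorted(set.union(*(set(p) for p in pct_by_label.values())))
    rows = []
    for rule_id in all_rules:
        entry = {"rule_id": rule_id, "shared": rule_id in shared}
        values = []
        for label in labels:
            v = pct_by_label[label].get(rule_id)
            entry[label] = v
            if v is not None:
                values.append(v)
        diff = max(values) - min(values) if len(values) >= 2 and rule_id in shared else None
        entry["max_abs_diff_pp"] = round(diff, 2) if diff is not None else None
        entry["flagged"] = bool(diff is not None and diff > flag_pct)
        rows.append(entry)
    return pd.DataFrame(rows)


def aggregate_outcomes(reports: List[ValidityReport]) -> ValidityReport:
    """Pool reports: summed numerators/denominators per rule, with the
    unweighted mean percentage alongside.  The pooled figure is the default
    headline; both are kept because they diverge on unbalanced sources."""
    if not reports:
        raise ValueError("no reports to aggregate")
    by_rule: dict = {}
    for rep in reports:
        for row in rep.rows:
            if row.evaluable and row.denominator:
                by_rule.setdefault(row.rule_id, []).append(row)
    rows = []
    for rule_id, group in by_rule.items():
        rows.append(with_pooled(group)[-1])
    return ValidityReport(rows=rows, label="aggregate")


def hospital_consistency(
    report_rows: List[RuleResult], flag_pct: float, hospital_ids: List[str]
) -> RuleResult:
    """S1: flag rules whose per-hospital percentages diverge beyond
    ``flag_pct`` percentage points."""
    hospital_ids = set(hospital_ids)
    per_rule: dict = {}
    for r in report_rows:
        if not r.evaluable or r.percentage is None or r.source_id not in hospital_ids:
            continue
        per_rule.setdefault(r.rule_id, {})[r.source_id] = r.percentage
    flagged = []
    compared = 0
    diffs = {}
    for rule_id, sources in per_rule.items():
        if len(sources) < 2:
            continue
        compared += 1
        diff = max(sources.values()) - min(sources.values())
        diffs[rule_id] = round(diff, 2)
        if diff > flag_pct:
            flagged.append(rule_id)
    return RuleResult(
        rule_id="S1",
        step=9,
        concept="consistency",
        source_id="pooled",
        numerator=len(flagged),
        denominator=compared if compared else None,
        direction="violation",
        offending_ids=flagged,
        details={"max_abs_diff_pp": diffs, "flag_threshold_pp": flag_pct},
        notes="rules whose hospitals diverge beyond the threshold",
        evaluable=compared > 0,
    )
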