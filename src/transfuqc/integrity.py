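"""Identity, completeness and uniformity checks (steps 3-5).

Duplicates are counted beyond the first record of each identical composite
key; procedure duplicates are additionally removed (double registration is
expected there), while transfusion and donation duplicates are retained and
flagged, since coarse keys can make genuinely distinct split products look
like duplicates.  Lab precision is assessed on the lexical form of the value
as recorded in the source file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .results import OFFENDER_CAP, RuleResult, round_pct, with_pooled
from .warehouse import Warehouse

#: Composite keys used for the identity checks.
DUPLICATE_KEYS = {
    "transfusions": ["donation_code", "product_type"],
    "donations": ["donation_id", "donation_type"],
    "procedures": ["patient_id", "procedure_code", "procedure_date"],
}


def duplicate_rate(
    table: pd.DataFrame,
    key: List[str],
    rule_id: str,
    source_id: str,
    id_col: str,
    step: int = 3,
) -> RuleResult:
    """Records beyond the first within each identical key group.

    A triplicate contributes 2.  Keys containing nulls are excluded from
    grouping and tallied in the notes.
    """
    if not key:
        raise ValueError("empty duplicate key")
    for f in key:
        if f not in table.columns:
            raise ValueError(f"key field {f!r} not in table")
    has_null = table[key].isna().any(axis=1)
    grouped = table[~has_null].groupby(key, dropna=False, sort=False)
    sizes = grouped.size()
    num = int((sizes[sizes > 1] - 1).sum())
    offenders: List[str] = []
    if num:
        dup_mask = table[~has_null].duplicated(subset=key, keep="first")
        offenders = table.loc[dup_mask[dup_mask].index, id_col].tolist()
    return RuleResult(
        rule_id=rule_id,
        step=step,
        concept="identity",
        source_id=source_id,
        numerator=num,
        denominator=len(table),
        direction="violation",
        offending_ids=offenders[:OFFENDER_CAP],
        notes=f"{int(has_null.sum())} records with null key fields excluded from grouping",
    )


def deduplicate(w: Warehouse) -> Tuple[List[RuleResult], Warehouse]:
    """Step 3: report duplicate rates; drop procedure duplicates.

    Returns the identity results and a warehouse copy in which exactly one
    representative per duplicated procedure key is retained.  Transfusion
    and donation duplicates are reported but kept.
    """
    w2 = w.copy()
    results: List[RuleResult] = []
    per_hosp_tx, per_hosp_proc = [], []
    for hid, src in w2.hospitals.items():
        tx = src.table("transfusions")
        if tx is not None:
            per_hosp_tx.append(
                duplicate_rate(tx, DUPLICATE_KEYS["transfusions"], "I1", hid, "transfusion_id")
            )
        else:
            per_hosp_tx.append(RuleResult.not_evaluable("I1", 3, "identity", hid))
        proc = src.table("procedures")
        if proc is not None:
            res = duplicate_rate(proc, DUPLICATE_KEYS["procedures"], "I3", hid, "procedure_id")
            per_hosp_proc.append(res)
            key = DUPLICATE_KEYS["procedures"]
            has_null = proc[key].isna().any(axis=1)
            drop = (~has_null) & proc.duplicated(subset=key, keep="first")
            src.tables["procedures"] = proc[~drop].reset_index(drop=True)
        else:
            per_hosp_proc.append(RuleResult.not_evaluable("I3", 3, "identity", hid))
    results.extend(with_pooled(per_hosp_tx))
    donations = w2.blood_bank.table("donations")
    if donations is not None:
        results.append(
            duplicate_rate(
                donations,
                DUPLICATE_KEYS["donations"],
                "I2",
                w2.blood_bank.source_id,
                "donation_id",
            )
        )
    else:
        results.append(RuleResult.not_evaluable("I2", 3, "identity", w2.blood_bank.source_id))
    results.extend(with_pooled(per_hosp_proc))
    return results, w2


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """One assessed variable: a column, optionally restricted by a filter."""

    kind: str  # "blood_bank" | "hospital"
    table: str
    field: str
    analyte: Optional[str] = None  # labs only

    @property
    def label(self) -> str:
        if self.analyte:
            return f"{self.table}.{self.field}:{self.analyte}"
        return f"{self.table}.{self.field}"


DEFAULT_COMPLETENESS_FIELDS: Tuple[FieldSpec, ...] = (
    FieldSpec("blood_bank", "donors", "donor_id"),
    FieldSpec("blood_bank", "donors", "birth_date"),
    FieldSpec("blood_bank", "donors", "gender"),
    FieldSpec("blood_bank", "donations", "hb_value"),
    FieldSpec("blood_bank", "products", "product_code"),
    FieldSpec("blood_bank", "products", "production_date"),
    FieldSpec("blood_bank", "products", "expiration_date"),
    FieldSpec("hospital", "patients", "patient_id"),
    FieldSpec("hospital", "patients", "birth_date"),
    FieldSpec("hospital", "patients", "gender"),
    FieldSpec("hospital", "procedures", "procedure_date"),
    FieldSpec("hospital", "labs", "value", "Hb"),
    FieldSpec("hospital", "labs", "value", "thrombocytes"),
    FieldSpec("hospital", "transfusions", "product_code"),
)


def field_completeness(
    w: Warehouse, fields: Tuple[FieldSpec, ...] = DEFAULT_COMPLETENESS_FIELDS
) -> List[RuleResult]:
    """Per-field non-missing percentage plus the completeness summary (K2).

    The summary is the share of assessed variables that are at least
    ``completeness_summary_cutoff`` percent complete, over the pooled (or
    blood-bank) figure per variable.  A structurally absent column counts
    as 0 % complete and is flagged in the notes.
    """
    results: List[RuleResult] = []
    summary_pcts: List[Optional[float]] = []
    for spec in fields:
        if spec.kind == "blood_bank":
            table = w.blood_bank.table(spec.table)
            per_source = [_field_result(spec, table, w.blood_bank.source_id)]
        else:
            per_source = [
                _field_result(spec, src.table(spec.table), hid)
                for hid, src in w.hospitals.items()
            ]
        per_source = with_pooled(per_source)
        results.extend(per_source)
        headline = per_source[-1]
        summary_pcts.append(headline.percentage if headline.evaluable else None)
    assessed = [p for p in summary_pcts if p is not None]
    cutoff = w.thresholds.completeness_summary_cutoff
    ok = sum(1 for p in assessed if p >= cutoff)
    results.append(
        RuleResult(
            rule_id="K2",
            step=4,
            concept="completeness",
            source_id="pooled",
            numerator=ok,
            denominator=len(assessed),
            details={"cutoff_pct": cutoff},
            notes=f"share of variables at least {cutoff}% complete",
        )
    )
    return results


def _field_result(spec: FieldSpec, table: Optional[pd.DataFrame], source_id: str) -> RuleResult:
    rule_id = f"K1[{spec.label}]"
    if table is None:
        return RuleResult.not_evaluable(rule_id, 4, "completeness", source_id, "table absent")
    sub = table
    if spec.analyte is not None:
        sub = table[table["analyte"] == spec.analyte]
    if spec.field not in sub.columns:
        raise ValueError(f"unknown field {spec.field!r} in table {spec.table!r}")
    den = len(sub)
    if den == 0:
        return RuleResult.not_evaluable(rule_id, 4, "completeness", source_id, "no records")
    num = int(sub[spec.field].notna().sum())
    structurally_absent = num == 0 and den > 0
    return RuleResult(
        rule_id=rule_id,
        step=4,
        concept="completeness",
        source_id=source_id,
        numerator=num,
        denominator=den,
        notes="column structurally absent or fully empty" if structurally_absent else "",
    )


def transfusion_diagnosis_coverage(w: Warehouse) -> List[RuleResult]:
    """K3: transfusion date inside at least one diagnosis episode (closed
    interval; an open end date covers from start onward).  The notes carry
    the distribution of concurrent-episode counts."""
    results = []
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        dx = src.table("diagnoses")
        if tx is None or dx is None:
            results.append(RuleResult.not_evaluable("K3", 4, "completeness", hid))
            continue
        t = tx[tx["transfusion_date"].notna()]
        cand = t.merge(
            dx[["patient_id", "start_date", "end_date"]], on="patient_id", how="left"
        )
        inside = (
            cand["start_date"].notna()
            & (cand["start_date"] <= cand["transfusion_date"])
            & (cand["end_date"].isna() | (cand["transfusion_date"] <= cand["end_date"]))
        )
        per_tx = cand.assign(_in=inside).groupby("transfusion_id")["_in"].sum()
        covered = int((per_tx > 0).sum())
        dist = per_tx.value_counts().sort_index()
        results.append(
            RuleResult(
                rule_id="K3",
                step=4,
                concept="completeness",
                source_id=hid,
                numerator=covered,
                denominator=len(t),
                offending_ids=per_tx[per_tx == 0].index.tolist()[:OFFENDER_CAP],
                details={
                    "concurrent_episode_distribution": {int(k): int(v) for k, v in dist.items()},
                    "max_concurrent_episodes": int(per_tx.max()) if len(per_tx) else 0,
                },
            )
        )
    return with_pooled(results)


# ---------------------------------------------------------------------------
# Uniformity
# ---------------------------------------------------------------------------


def _normalize(codes: pd.Series) -> pd.Series:
    return codes.dropna().astype(str).str.strip().str.casefold()


def code_conformance(
    codes: pd.Series, reference: pd.Series, rule_id: str, source_id: str
) -> RuleResult:
    """Share of non-null codes found in the reference list after trim +
    case-fold normalization.  Null codes are missingness, not
    non-conformance, and are tallied in the notes."""
    ref = set(_normalize(reference))
    if not ref:
        raise ValueError("empty reference list")
    values = _normalize(codes)
    den = len(values)
    if den == 0:
        return RuleResult.not_evaluable(rule_id, 5, "uniformity", source_id, "no codes")
    hit = values.isin(ref)
    num = int(hit.sum())
    bad = codes.dropna()[~hit.values]
    return RuleResult(
        rule_id=rule_id,
        step=5,
        concept="uniformity",
        source_id=source_id,
        numerator=num,
        denominator=den,
        offending_ids=bad.astype(str).unique().tolist()[:OFFENDER_CAP],
        notes=f"{int(codes.isna().sum())} null codes counted as missing, not non-conformant",
    )


def code_conformance_all(w: Warehouse) -> List[RuleResult]:
    results: List[RuleResult] = []
    ref_products = w.reference["product_codes"]["code"]
    per_source = []
    products = w.blood_bank.table("products")
    if products is not None:
        per_source.append(
            code_conformance(products["product_code"], ref_products, "U1", w.blood_bank.source_id)
        )
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        if tx is not None:
            per_source.append(code_conformance(tx["product_code"], ref_products, "U1", hid))
        else:
            per_source.append(RuleResult.not_evaluable("U1", 5, "uniformity", hid))
    results.extend(with_pooled(per_source))
    ref_dx = w.reference["diagnosis_codes"]["code"]
    per_source = []
    for hid, src in w.hospitals.items():
        dx = src.table("diagnoses")
        if dx is not None:
            per_source.append(code_conformance(dx["diagnosis_code"], ref_dx, "U2", hid))
        else:
            per_source.append(RuleResult.not_evaluable("U2", 5, "uniformity", hid))
    results.extend(with_pooled(per_source))
    return results


def precision_uniformity(w: Warehouse, analyte: str = "Hb") -> List[RuleResult]:
    """U3: share of measurements recorded at the modal decimal precision.

    Pools hospital lab values with the blood bank's donation measurements
    of the same analyte; precision is the lexical decimal-place count as
    recorded.  Ties pick the lower decimal count.
    """
    per_source: Dict[str, pd.Series] = {}
    for hid, src in w.hospitals.items():
        labs = src.table("labs")
        if labs is None:
            continue
        sub = labs[(labs["analyte"] == analyte) & labs["value"].notna()]
        per_source[hid] = sub["value_decimals"].dropna().astype(int)
    donations = w.blood_bank.table("donations")
    if analyte == "Hb" and donations is not None:
        sub = donations[donations["hb_value"].notna()]
        per_source[w.blood_bank.source_id] = sub["hb_value_decimals"].dropna().astype(int)
    all_decs = pd.concat(per_source.values()) if per_source else pd.Series([], dtype=int)
    if len(all_decs) == 0:
        return [RuleResult.not_evaluable("U3", 5, "uniformity", "pooled", "no measurements")]
    counts = all_decs.value_counts()
    best = counts.max()
    modal = int(min(k for k, v in counts.items() if v == best))
    num = int((all_decs == modal).sum())
    breakdown = {
        sid: round_pct(int((s == modal).sum()), len(s)) if len(s) else None
        for sid, s in per_source.items()
    }
    return [
        RuleResult(
            rule_id="U3",
            step=5,
            concept="uniformity",
            source_id="pooled",
            numerator=num,
            denominator=int(len(all_decs)),
            details={"modal_decimals": modal, "per_source_pct": breakdown},
            notes=f"modal precision {modal} decimals",
        )
    ]
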