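"""Deterministic linkage rates between warehouse entity tables.

Transfusions reference issued products by the donation identification code
of the end product plus the product code; where either side lacks the code
the broader product type is used.  A transfusion counts as linked only when
its key resolves to exactly one product: ambiguous (multi-match) keys are an
identity problem and are reported separately, not counted as links.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pandas as pd

from .results import OFFENDER_CAP, RuleResult, with_pooled
from .warehouse import Warehouse

STEP_LINKAGE = 2
STEP_EVENT = 8


def _product_key_frame(products: pd.DataFrame) -> pd.DataFrame:
    cols = ["product_id", "product_code", "product_type"]
    out = products[cols].copy()
    out["_pidx"] = range(len(out))
    if "expiration_date" in products.columns:
        out["expiration_date"] = products["expiration_date"].values
    return out


def _match_transfusions(
    tx: pd.DataFrame, products: pd.DataFrame
) -> Tuple[pd.Series, pd.DataFrame]:
    """Count product matches per transfusion row.

    Returns (match counts indexed like ``tx``, merged candidate pairs with
    the product row index of each accepted match).
    """
    t = tx.reset_index().rename(columns={"index": "_tidx"})
    cand = t.merge(
        _product_key_frame(products),
        left_on="donation_code",
        right_on="product_id",
        how="inner",
        suffixes=("", "_prod"),
    )
    both_codes = cand["product_code"].notna() & cand["product_code_prod"].notna()
    code_ok = both_codes & (cand["product_code"] == cand["product_code_prod"])
    type_ok = ~both_codes & (cand["product_type"] == cand["product_type_prod"])
    accepted = cand[code_ok | type_ok]
    counts = accepted.groupby("_tidx").size().reindex(range(len(tx)), fill_value=0)
    counts.index = tx.index
    return counts, accepted


def _effective_products(w: Warehouse, prior: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
    products = w.blood_bank.table("products")
    if products is None:
        return None
    if prior is not None and len(prior):
        products = pd.concat([products, prior], ignore_index=True)
    return products


def link_transfusions_to_products(
    w: Warehouse, prior: Optional[pd.DataFrame] = None
) -> Tuple[List[RuleResult], pd.DataFrame]:
    """Share of transfusions resolving to exactly one issued product (L1).

    Also returns the link map (transfusion_id, product_id) of unambiguous
    matches for downstream checks.
    """
    products = _effective_products(w, prior)
    results: List[RuleResult] = []
    link_rows = []
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        if tx is None or products is None:
            results.append(RuleResult.not_evaluable("L1", STEP_LINKAGE, "linkage", hid))
            continue
        counts, accepted = _match_transfusions(tx, products)
        linked = int((counts == 1).sum())
        ambiguous = tx.loc[counts > 1, "transfusion_id"].tolist()
        unresolved = tx.loc[counts == 0, "transfusion_id"].tolist()
        once = counts.reset_index(drop=True)
        ok = accepted[accepted["_tidx"].map(once) == 1]
        part = ok[["transfusion_id", "product_id", "_pidx"]].copy()
        part.insert(0, "source_id", hid)
        link_rows.append(part)
        results.append(
            RuleResult(
                rule_id="L1",
                step=STEP_LINKAGE,
                concept="linkage",
                source_id=hid,
                numerator=linked,
                denominator=len(tx),
                offending_ids=(unresolved + ambiguous)[:OFFENDER_CAP],
                details={"unresolved": len(unresolved), "ambiguous": len(ambiguous)},
                notes=f"{len(unresolved)} unresolved, {len(ambiguous)} ambiguous",
            )
        )
    if link_rows:
        link_map = pd.concat(link_rows, ignore_index=True)
    else:
        link_map = pd.DataFrame(columns=["source_id", "transfusion_id", "product_id", "_pidx"])
    return with_pooled(results), link_map


def link_products_to_transfusions(w: Warehouse) -> List[RuleResult]:
    """Share of issued products matched by at least one transfusion (L2).

    The complement is the spilling rate (issued but never transfused).
    """
    products = w.blood_bank.table("products")
    if products is None:
        return [RuleResult.not_evaluable("L2", STEP_LINKAGE, "linkage", w.blood_bank.source_id)]
    if len(products) == 0:
        return [
            RuleResult.not_evaluable(
                "L2", STEP_LINKAGE, "linkage", w.blood_bank.source_id, "no issued products"
            )
        ]
    matched = pd.Series(False, index=products.index)
    for src in w.hospitals.values():
        tx = src.table("transfusions")
        if tx is None:
            continue
        p = products.reset_index().rename(columns={"index": "_pidx"})
        cand = p.merge(
            tx[["transfusion_id", "donation_code", "product_code", "product_type"]],
            left_on="product_id",
            right_on="donation_code",
            how="inner",
            suffixes=("", "_tx"),
        )
        both = cand["product_code"].notna() & cand["product_code_tx"].notna()
        ok = (both & (cand["product_code"] == cand["product_code_tx"])) | (
            ~both & (cand["product_type"] == cand["product_type_tx"])
        )
        matched.loc[cand.loc[ok, "_pidx"].unique()] = True
    num = int(matched.sum())
    den = len(products)
    spilled_ids = products.loc[~matched, "product_id"].tolist()
    pct_spill = round(100 - num / den * 100, 2)
    res = RuleResult(
        rule_id="L2",
        step=STEP_LINKAGE,
        concept="linkage",
        source_id=w.blood_bank.source_id,
        numerator=num,
        denominator=den,
        offending_ids=spilled_ids[:OFFENDER_CAP],
        details={"spilling_rate_pct": pct_spill},
        notes=f"spilling rate {pct_spill}%",
    )
    return [res]


def link_products_to_donations_and_donors(w: Warehouse) -> List[RuleResult]:
    """L3: every constituent donation resolves; L4: every donor resolves."""
    products = w.blood_bank.table("products")
    donations = w.blood_bank.table("donations")
    donors = w.blood_bank.table("donors")
    sid = w.blood_bank.source_id
    if products is None or donations is None:
        return [
            RuleResult.not_evaluable("L3", STEP_LINKAGE, "linkage", sid),
            RuleResult.not_evaluable("L4", STEP_LINKAGE, "linkage", sid),
        ]
    donation_ids = set(donations["donation_id"].dropna())
    donor_ids = set(donors["donor_id"].dropna()) if donors is not None else set()
    don_to_donor: Dict[str, set] = {}
    for _, r in donations.iterrows():
        don_to_donor.setdefault(r["donation_id"], set()).add(r["donor_id"])
    l3_bad, l4_bad = [], []
    for _, p in products.iterrows():
        ids = p["donation_ids"] or ()
        dangling = [i for i in ids if i not in donation_ids]
        if not ids or dangling:
            l3_bad.append(p["product_id"])
            l4_bad.append(p["product_id"])
            continue
        donor_ok = True
        for i in ids:
            for donor in don_to_donor.get(i, ()):
                if pd.isna(donor) or donor not in donor_ids:
                    donor_ok = False
        if not donor_ok:
            l4_bad.append(p["product_id"])
    den = len(products)
    l3 = RuleResult(
        rule_id="L3",
        step=STEP_LINKAGE,
        concept="linkage",
        source_id=sid,
        numerator=den - len(l3_bad),
        denominator=den,
        offending_ids=l3_bad[:OFFENDER_CAP],
    )
    l4 = RuleResult(
        rule_id="L4",
        step=STEP_LINKAGE,
        concept="linkage",
        source_id=sid,
        numerator=den - len(l4_bad),
        denominator=den,
        offending_ids=l4_bad[:OFFENDER_CAP],
    )
    return [l3, l4]


def link_transfusions_to_hospitalizations(w: Warehouse) -> List[RuleResult]:
    """E3: transfusion inside a hospitalization of the same patient.

    The interval is closed on both ends; an open discharge date counts as
    still admitted at extraction.  The complement indicates outpatient
    transfusions; the day-admission share among linked stays in the notes.
    """
    results = []
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        hosp = src.table("hospitalizations")
        if tx is None or hosp is None:
            results.append(RuleResult.not_evaluable("E3", STEP_EVENT, "event_attributes", hid))
            continue
        t = tx[tx["transfusion_date"].notna()].reset_index(drop=True)
        cand = t.merge(
            hosp[["patient_id", "admission_date", "discharge_date", "day_admission"]],
            on="patient_id",
            how="left",
        )
        inside = (
            cand["admission_date"].notna()
            & (cand["admission_date"] <= cand["transfusion_date"])
            & (cand["discharge_date"].isna() | (cand["transfusion_date"] <= cand["discharge_date"]))
        )
        cand = cand.assign(_in=inside)
        per_tx = cand.groupby("transfusion_id")["_in"].any()
        linked_ids = set(per_tx[per_tx].index)
        day_share = None
        if linked_ids:
            day_hits = cand[cand["_in"] & (cand["day_admission"] == True)]  # noqa: E712
            day_share = round(100 * day_hits["transfusion_id"].nunique() / len(linked_ids), 2)
        unlinked = [i for i in t["transfusion_id"] if i not in linked_ids]
        results.append(
            RuleResult(
                rule_id="E3",
                step=STEP_EVENT,
                concept="event_attributes",
                source_id=hid,
                numerator=len(linked_ids),
                denominator=len(t),
                offending_ids=unlinked[:OFFENDER_CAP],
                details={"day_admission_share_pct": day_share},
                notes=f"day-admission share among linked: {day_share}%",
            )
        )
    return with_pooled(results)


def apply_id_remap(w: Warehouse, remap: pd.DataFrame) -> Warehouse:
    """Rewrite hospital-side product references after an id-recoding incident.

    ``remap`` maps old (recoded) -> new (true) identifiers and must be
    injective.  Returns a copy; entries whose old id occurs nowhere are
    ignored and appended to the copy's load log.  Re-running L1 afterwards
    can only improve the linkage rate.
    """
    if remap["old_id"].duplicated().any() or remap["new_id"].duplicated().any():
        raise ValueError("remap must be injective (unique old and new ids)")
    mapping = dict(zip(remap["old_id"], remap["new_id"]))
    w2 = w.copy()
    seen = set()
    for src in w2.hospitals.values():
        tx = src.table("transfusions")
        if tx is None:
            continue
        hit = tx["donation_code"].isin(mapping)
        seen.update(tx.loc[hit, "donation_code"])
        tx.loc[hit, "donation_code"] = tx.loc[hit, "donation_code"].map(mapping)
    from .warehouse import LoadIssue

    for old in remap["old_id"]:
        if old not in seen:
            w2.load_log.append(
                LoadIssue("remap", "transfusions", "donation_code", -1, str(old), "remap id not found")
            )
    return w2
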