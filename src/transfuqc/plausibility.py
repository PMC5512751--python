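"""Plausibility and event-attribute rule registry (steps 7-8).

Every rule has a stable identifier, declares the tables it needs, and
returns uniform :class:`RuleResult` rows.  Rules are independent: one
rule's failure never aborts the run.

Registry overview
-----------------
P1  donation date strictly before pooling date for every constituent
P2  donations per donor per year within limits (3 F / 5 M whole blood, 23 plasma)
P3  donor age 18-70 at donation (autologous donations exempt)
P4  Hb change around RBC transfusions: |relative change| > 8.8 % within
    ±1 day is a clinical change; decreases are explained by an active
    bleeding-risk diagnosis
P5  patient age below 121 years at transfusion
P6  maximum transfusions per patient-year (descriptive)
P7  gynecology diagnoses belong to female patients
P8  no transfusion or procedure after death
P9  admission date not after discharge date (zero-length rule)
P10 product not expired at transfusion (via the link map)
E1  pooled platelet products trace to 5 or 6 unique donors
E2  patients transferred to another hospital (discharge destination)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import pandas as pd

from .bruteforce import age_years
from .config import ThresholdConfig
from .results import OFFENDER_CAP, RuleResult, with_pooled
from .warehouse import Warehouse


@dataclass(frozen=True)
class RuleSpec:
    rule_id: str
    step: int
    concept: str
    description: str
    requires: Tuple[str, ...]
    direction: str
    func: Callable


def _violation(rule_id, spec, source_id, offenders, den, details=None, notes=""):
    return RuleResult(
        rule_id=rule_id,
        step=spec.step,
        concept=spec.concept,
        source_id=source_id,
        numerator=len(offenders),
        denominator=den,
        direction="violation",
        offending_ids=list(offenders)[:OFFENDER_CAP],
        details=details or {},
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Blood-bank rules
# ---------------------------------------------------------------------------


def _p1(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    products = w.blood_bank.table("products")
    donations = w.blood_bank.table("donations")
    sid = w.blood_bank.source_id
    pooled_products = products[products["pooling_date"].notna()]
    pairs = pooled_products[["product_id", "pooling_date", "donation_ids"]].explode("donation_ids")
    don_dates = donations.drop_duplicates("donation_id").set_index("donation_id")["donation_date"]
    pairs = pairs.assign(donation_date=pairs["donation_ids"].map(don_dates))
    pairs = pairs.dropna(subset=["donation_date"])
    bad = pairs[~(pairs["donation_date"] < pairs["pooling_date"])]
    return [_violation("P1", spec, sid, bad["product_id"].unique().tolist(), len(pairs))]


def _p2(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    donations = w.blood_bank.table("donations")
    donors = w.blood_bank.table("donors")
    sid = w.blood_bank.source_id
    d = donations.dropna(subset=["donation_date", "donor_id"])
    d = d.assign(year=d["donation_date"].dt.year)
    grouped = d.groupby(["donor_id", "year", "donation_type"])["donation_id"].nunique()
    gender = donors.drop_duplicates("donor_id").set_index("donor_id")["gender"]
    offenders = []
    for (donor_id, year, dtype), n in grouped.items():
        g = gender.get(donor_id)
        if dtype == "whole_blood":
            # unknown gender gets the lenient (male) limit
            limit = t.wb_limit_female if (pd.notna(g) and g == "F") else t.wb_limit_male
        else:
            limit = t.plasma_limit
        if n > limit:
            offenders.append(f"{donor_id}:{year}:{dtype}")
    return [_violation("P2", spec, sid, offenders, int(len(grouped)))]


def _p3(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    donations = w.blood_bank.table("donations")
    donors = w.blood_bank.table("donors")
    sid = w.blood_bank.source_id
    birth = donors.drop_duplicates("donor_id").set_index("donor_id")["birth_date"]
    d = donations[donations["autologous"] != True]  # noqa: E712 - exempt autologous
    n_autologous = int((donations["autologous"] == True).sum())  # noqa: E712
    d = d.assign(birth=d["donor_id"].map(birth))
    d = d.dropna(subset=["birth", "donation_date"])
    ages = [age_years(b, dd) for b, dd in zip(d["birth"], d["donation_date"])]
    d = d.assign(age=ages)
    bad = d[(d["age"] < t.donor_age_min) | (d["age"] > t.donor_age_max)]
    return [
        _violation(
            "P3",
            spec,
            sid,
            bad["donation_id"].tolist(),
            len(d),
            details={"autologous_exempt": n_autologous},
            notes=f"{n_autologous} autologous donations exempt from the age limits",
        )
    ]


def _e1(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    products = w.blood_bank.table("products")
    donations = w.blood_bank.table("donations")
    sid = w.blood_bank.source_id
    plt = products[products["product_type"] == "PLT"]
    donor_of = donations.drop_duplicates("donation_id").set_index("donation_id")["donor_id"]
    offenders = []
    for _, p in plt.iterrows():
        ids = p["donation_ids"] or ()
        donors = {donor_of.get(i) for i in ids if donor_of.get(i) is not None and pd.notna(donor_of.get(i))}
        if len(donors) not in t.pooled_plt_donors:
            offenders.append(p["product_id"])
    return [
        _violation(
            "E1", spec, sid, offenders, len(plt),
            notes=f"expected pool sizes: {sorted(t.pooled_plt_donors)} unique donors",
        )
    ]


# ---------------------------------------------------------------------------
# Hospital rules
# ---------------------------------------------------------------------------


def _per_hospital(w, spec, tables, fn) -> List[RuleResult]:
    results = []
    for hid, src in w.hospitals.items():
        frames = {name: src.table(name) for name in tables}
        if any(v is None for v in frames.values()):
            results.append(
                RuleResult.not_evaluable(spec.rule_id, spec.step, spec.concept, hid, "table absent")
            )
            continue
        results.append(fn(hid, frames))
    return with_pooled(results)


def _p4(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    dx_ref = w.reference["diagnosis_codes"]
    bleeding_codes = set(dx_ref.loc[dx_ref["bleeding_risk"] == True, "code"])  # noqa: E712

    def one(hid, frames):
        tx, labs, dx = frames["transfusions"], frames["labs"], frames["diagnoses"]
        hb = labs[(labs["analyte"] == "Hb") & labs["value"].notna() & labs["measured_at"].notna()]
        hb = hb.sort_values(["patient_id", "measured_at"], kind="stable")
        by_patient = {pid: grp for pid, grp in hb.groupby("patient_id")}
        bleeding = dx[dx["diagnosis_code"].isin(bleeding_codes)]
        bleed_by_patient = {pid: grp for pid, grp in bleeding.groupby("patient_id")}
        counts = {"increase": 0, "decrease": 0, "no_change": 0, "unevaluable": 0}
        offenders = []
        rbc = tx[tx["product_type"] == "RBC"]
        win = pd.Timedelta(days=t.hb_window_days)
        day = pd.Timedelta(days=1)
        for _, row in rbc.iterrows():
            td = row["transfusion_date"]
            if pd.isna(td):
                counts["unevaluable"] += 1
                continue
            grp = by_patient.get(row["patient_id"])
            if grp is None:
                counts["unevaluable"] += 1
                continue
            pre_c = grp[(grp["measured_at"] >= td - win) & (grp["measured_at"] <= td - day)]
            post_c = grp[(grp["measured_at"] >= td + day) & (grp["measured_at"] <= td + win)]
            if pre_c.empty or post_c.empty:
                counts["unevaluable"] += 1
                continue
            # nearest date wins; exact ties go to the earlier recorded row on
            # the pre side and the later recorded row on the post side
            pre = pre_c[pre_c["measured_at"] == pre_c["measured_at"].max()].iloc[0]
            post = post_c[post_c["measured_at"] == post_c["measured_at"].min()].iloc[-1]
            change = (post["value"] - pre["value"]) / pre["value"] * 100
            if change > t.hb_change_pct:
                counts["increase"] += 1
            elif change < -t.hb_change_pct:
                counts["decrease"] += 1
                bl = bleed_by_patient.get(row["patient_id"])
                explained = False
                if bl is not None:
                    explained = bool(
                        (
                            bl["start_date"].notna()
                            & (bl["start_date"] <= td)
                            & (bl["end_date"].isna() | (td <= bl["end_date"]))
                        ).any()
                    )
                if not explained:
                    offenders.append(row["transfusion_id"])
            else:
                counts["no_change"] += 1
        evaluable = len(rbc) - counts["unevaluable"]
        counts["total_rbc"] = len(rbc)
        counts["unexplained_decrease"] = len(offenders)
        counts["explained_decrease"] = counts["decrease"] - len(offenders)
        return RuleResult(
            rule_id="P4",
            step=spec.step,
            concept=spec.concept,
            source_id=hid,
            numerator=len(offenders),
            denominator=evaluable,
            direction="violation",
            offending_ids=offenders[:OFFENDER_CAP],
            details=counts,
            notes="numerator counts unexplained decreases; full classification in details",
            evaluable=evaluable > 0,
        )

    return _per_hospital(w, spec, ("transfusions", "labs", "diagnoses"), one)


def _p5(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    def one(hid, frames):
        tx, patients = frames["transfusions"], frames["patients"]
        birth = patients.drop_duplicates("patient_id").set_index("patient_id")["birth_date"]
        d = tx.assign(birth=tx["patient_id"].map(birth)).dropna(
            subset=["birth", "transfusion_date"]
        )
        ages = [age_years(b, td) for b, td in zip(d["birth"], d["transfusion_date"])]
        bad = d[[a >= t.patient_age_max for a in ages]]
        return _violation("P5", spec, hid, bad["transfusion_id"].tolist(), len(d))

    return _per_hospital(w, spec, ("transfusions", "patients"), one)


def _p6(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    results = []
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        dx = src.table("diagnoses")
        if tx is None:
            results.append(RuleResult.not_evaluable("P6", spec.step, spec.concept, hid))
            continue
        d = tx.dropna(subset=["transfusion_date"])
        if d.empty:
            results.append(RuleResult.not_evaluable("P6", spec.step, spec.concept, hid, "no transfusions"))
            continue
        d = d.assign(year=d["transfusion_date"].dt.year)
        per = d.groupby(["patient_id", "year"]).size()
        (patient_id, year), n = max(per.items(), key=lambda kv: kv[1])
        sub = d[(d["patient_id"] == patient_id) & (d["year"] == year)]
        dominant = sub["product_type"].mode().iloc[0]
        covering = None
        if dx is not None:
            hits = dx[(dx["patient_id"] == patient_id)]
            if len(hits):
                covering = hits["diagnosis_code"].mode().iloc[0]
        results.append(
            RuleResult(
                rule_id="P6",
                step=spec.step,
                concept=spec.concept,
                source_id=hid,
                numerator=None,
                denominator=None,
                direction="descriptive",
                details={
                    "max_transfusions_per_patient_year": int(n),
                    "patient_id": patient_id,
                    "year": int(year),
                    "dominant_product_type": dominant,
                    "most_frequent_diagnosis": covering,
                },
                notes=f"max {int(n)} transfusions in {int(year)} (mainly {dominant})",
            )
        )
    return results


def _p7(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    dx_ref = w.reference["diagnosis_codes"]
    gyn_codes = set(dx_ref.loc[dx_ref["gynecology"] == True, "code"])  # noqa: E712

    def one(hid, frames):
        dx, patients = frames["diagnoses"], frames["patients"]
        gyn_patients = set(dx.loc[dx["diagnosis_code"].isin(gyn_codes), "patient_id"])
        p = patients[patients["patient_id"].isin(gyn_patients) & patients["gender"].notna()]
        bad = p[p["gender"] != "F"]
        return _violation("P7", spec, hid, bad["patient_id"].tolist(), len(p))

    return _per_hospital(w, spec, ("diagnoses", "patients"), one)


def _p8(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    def one(hid, frames):
        tx, proc, patients = frames["transfusions"], frames["procedures"], frames["patients"]
        events: Dict[str, pd.Timestamp] = {}
        for frame, col in ((tx, "transfusion_date"), (proc, "procedure_date")):
            d = frame.dropna(subset=[col])
            for pid, last in d.groupby("patient_id")[col].max().items():
                if pid not in events or last > events[pid]:
                    events[pid] = last
        with_events = patients[patients["patient_id"].isin(events)]
        offenders = [
            r["patient_id"]
            for _, r in with_events.iterrows()
            if pd.notna(r["death_date"]) and events[r["patient_id"]] > r["death_date"]
        ]
        return _violation("P8", spec, hid, offenders, len(with_events))

    return _per_hospital(w, spec, ("transfusions", "procedures", "patients"), one)


def _p9(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    def one(hid, frames):
        hosp = frames["hospitalizations"]
        d = hosp.dropna(subset=["admission_date", "discharge_date"])
        bad = d[d["discharge_date"] < d["admission_date"]]
        return _violation("P9", spec, hid, bad["hospitalization_id"].tolist(), len(d))

    return _per_hospital(w, spec, ("hospitalizations",), one)


def _p10(w: Warehouse, t: ThresholdConfig, spec, link_map=None, **_) -> List[RuleResult]:
    from . import linkage

    if link_map is None:
        _, link_map = linkage.link_transfusions_to_products(w)
    products = w.blood_bank.table("products")
    if products is None or link_map is None or len(link_map) == 0:
        return [RuleResult.not_evaluable("P10", spec.step, spec.concept, "pooled", "no link map")]
    exp = products["expiration_date"]
    results = []
    for hid, src in w.hospitals.items():
        tx = src.table("transfusions")
        if tx is None:
            results.append(RuleResult.not_evaluable("P10", spec.step, spec.concept, hid))
            continue
        links = link_map[link_map["source_id"] == hid]
        d = links.merge(
            tx[["transfusion_id", "transfusion_date"]], on="transfusion_id", how="inner"
        )
        d = d.assign(expiration=d["_pidx"].map(lambda i: exp.iloc[int(i)] if i < len(exp) else pd.NaT))
        d = d.dropna(subset=["expiration", "transfusion_date"])
        bad = d[d["expiration"] < d["transfusion_date"]]
        results.append(_violation("P10", spec, hid, bad["transfusion_id"].tolist(), len(d)))
    return with_pooled(results)


def _e2(w: Warehouse, t: ThresholdConfig, spec, **_) -> List[RuleResult]:
    def one(hid, frames):
        tx, hosp = frames["transfusions"], frames["hospitalizations"]
        transfused = set(tx["patient_id"].dropna())
        transferred = set(
            hosp.loc[hosp["discharge_destination"] == "other_hospital", "patient_id"]
        )
        offenders = sorted(transfused & transferred)
        return _violation(
            "E2", spec, hid, offenders, len(transfused),
            notes="denominator: transfused patients",
        )

    return _per_hospital(w, spec, ("transfusions", "hospitalizations"), one)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

RULES: Dict[str, RuleSpec] = {
    s.rule_id: s
    for s in [
        RuleSpec("P1", 7, "plausibility", "donation date before pooling date",
                 ("products", "donations"), "violation", _p1),
        RuleSpec("P2", 7, "plausibility", "donations per donor per year within limits",
                 ("donations", "donors"), "violation", _p2),
        RuleSpec("P3", 7, "plausibility", "donor age within donation limits",
                 ("donations", "donors"), "violation", _p3),
        RuleSpec("P4", 7, "plausibility", "Hb change classification around RBC transfusions",
                 ("transfusions", "labs", "diagnoses"), "violation", _p4),
        RuleSpec("P5", 7, "plausibility", "patient age below limit at transfusion",
                 ("transfusions", "patients"), "violation", _p5),
        RuleSpec("P6", 7, "plausibility", "maximum transfusions per patient-year",
                 ("transfusions",), "descriptive", _p6),
        RuleSpec("P7", 7, "plausibility", "gynecology diagnoses belong to female patients",
                 ("diagnoses", "patients"), "violation", _p7),
        RuleSpec("P8", 7, "plausibility", "no transfusion or procedure after death",
                 ("transfusions", "procedures", "patients"), "violation", _p8),
        RuleSpec("P9", 7, "plausibility", "admission date not after discharge date",
                 ("hospitalizations",), "violation", _p9),
        RuleSpec("P10", 7, "plausibility", "product not expired at transfusion",
                 ("transfusions", "products"), "violation", _p10),
        RuleSpec("E1", 8, "event_attributes", "pooled platelet products have 5-6 unique donors",
                 ("products", "donations"), "violation", _e1),
        RuleSpec("E2", 8, "event_attributes", "patients transferred to another hospital",
                 ("transfusions", "hospitalizations"), "violation", _e2),
    ]
}

BANK_TABLES = {"products", "donations", "donors"}


def _required_present(w: Warehouse, spec: RuleSpec) -> bool:
    for name in spec.requires:
        if name in BANK_TABLES:
            if w.blood_bank.table(name) is None:
                return False
        else:
            if all(src.table(name) is None for src in w.hospitals.values()):
                return False
    return True


def evaluate_rule(
    rule_id: str,
    w: Warehouse,
    t: Optional[ThresholdConfig] = None,
    link_map: Optional[pd.DataFrame] = None,
) -> List[RuleResult]:
    """Evaluate one registered rule; unknown ids raise, absent tables yield
    not-evaluable results."""
    if rule_id not in RULES:
        raise KeyError(f"unknown rule_id {rule_id!r}")
    spec = RULES[rule_id]
    t = t or w.thresholds
    if not _required_present(w, spec):
        return [
            RuleResult.not_evaluable(
                rule_id, spec.step, spec.concept, "pooled",
                f"required tables absent: {', '.join(spec.requires)}",
            )
        ]
    return spec.func(w, t, spec, link_map=link_map)


def run_all_rules(
    w: Warehouse,
    t: Optional[ThresholdConfig] = None,
    link_map: Optional[pd.DataFrame] = None,
) -> List[RuleResult]:
    """Evaluate the whole registry in order, isolating failures per rule."""
    out: List[RuleResult] = []
    for rule_id, spec in RULES.items():
        try:
            out.extend(evaluate_rule(rule_id, w, t, link_map=link_map))
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            out.append(
                RuleResult.not_evaluable(
                    rule_id, spec.step, spec.concept, "pooled", f"error: {exc}"
                )
            )
    return out


def catalogue() -> pd.DataFrame:
    """Machine-readable rule catalogue for documentation."""
    return pd.DataFrame(
        [
            {
                "rule_id": s.rule_id,
                "step": s.step,
                "concept": s.concept,
                "description": s.description,
                "requires": ";".join(s.requires),
                "direction": s.direction,
            }
            for s in RULES.values()
        ]
    )


def fix_postdeath(w: Warehouse) -> Tuple[Warehouse, int]:
    """Remediation hook: blank the death date of patients with post-death
    events (mortality status becomes not-available); events are never
    deleted.  Returns the fixed copy and the number of patients changed."""
    results = evaluate_rule("P8", w)
    w2 = w.copy()
    n = 0
    for res in results:
        if res.source_id in w2.hospitals and res.offending_ids:
            patients = w2.hospitals[res.source_id].table("patients")
            mask = patients["patient_id"].isin(res.offending_ids)
            patients.loc[mask, "death_date"] = pd.NaT
            n += int(mask.sum())
    return w2, n
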