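"""Independent brute-force implementations of every check numerator.

These are deliberately written as plain Python loops over row dictionaries,
with no shared code path with the validator modules (which use pandas
joins).  They serve as the oracle in the test suite and as the engine of
:func:`transfuqc.synthetic.truth_summary`.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import pandas as pd


def _null(v) -> bool:
    if v is None:
        return True
    if isinstance(v, (tuple, list)):
        return False
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):  # pragma: no cover
        return False


def _records(df: Optional[pd.DataFrame]) -> List[dict]:
    if df is None or len(df) == 0:
        return []
    return df.to_dict("records")


def age_years(birth, at) -> int:
    """Completed years between two dates."""
    years = at.year - birth.year
    if (at.month, at.day) < (birth.month, birth.day):
        years -= 1
    return years


def match_product(tx: dict, prod: dict) -> bool:
    """End-product key match: identifier, then code, falling back to type.

    The hospital references a product by the donation identification code of
    the end product plus the product code; when either side lacks the code,
    the broader product type is used instead.
    """
    if _null(tx.get("donation_code")) or tx["donation_code"] != prod["product_id"]:
        return False
    if not _null(tx.get("product_code")) and not _null(prod.get("product_code")):
        return tx["product_code"] == prod["product_code"]
    return tx.get("product_type") == prod.get("product_type")


def duplicates_beyond_first(rows: List[dict], key_fields: List[str]) -> Tuple[int, int]:
    counts: Dict[tuple, int] = {}
    for r in rows:
        key = tuple(r.get(f) for f in key_fields)
        if any(_null(k) for k in key):
            continue
        counts[key] = counts.get(key, 0) + 1
    num = sum(c - 1 for c in counts.values() if c > 1)
    return num, len(rows)


class WarehouseScan:
    """Row-dict view of a warehouse with one method per check."""

    def __init__(self, w):
        self.w = w
        self.donors = _records(w.blood_bank.table("donors"))
        self.donations = _records(w.blood_bank.table("donations"))
        self.products = _records(w.blood_bank.table("products"))
        self.hospitals = list(w.hospitals)
        self.transfusions = {h: _records(w.hospitals[h].table("transfusions")) for h in self.hospitals}
        self.patients = {h: _records(w.hospitals[h].table("patients")) for h in self.hospitals}
        self.hospitalizations = {
            h: _records(w.hospitals[h].table("hospitalizations")) for h in self.hospitals
        }
        self.diagnoses = {h: _records(w.hospitals[h].table("diagnoses")) for h in self.hospitals}
        self.procedures = {h: _records(w.hospitals[h].table("procedures")) for h in self.hospitals}
        self.labs = {h: _records(w.hospitals[h].table("labs")) for h in self.hospitals}
        self.all_transfusions = [t for h in self.hospitals for t in self.transfusions[h]]
        dx = w.reference.get("diagnosis_codes")
        self.bleeding_codes = set()
        self.gyn_codes = set()
        self.dx_codes = set()
        for r in _records(dx):
            code = r["code"]
            self.dx_codes.add(str(code).strip().casefold())
            if r.get("bleeding_risk") is True:
                self.bleeding_codes.add(code)
            if r.get("gynecology") is True:
                self.gyn_codes.add(code)
        self.product_codes = {
            str(r["code"]).strip().casefold() for r in _records(w.reference.get("product_codes"))
        }
        self._prod_by_id: Dict[str, List[dict]] = {}
        for p in self.products:
            self._prod_by_id.setdefault(p["product_id"], []).append(p)
        self._don_by_id: Dict[str, List[dict]] = {}
        for d in self.donations:
            self._don_by_id.setdefault(d["donation_id"], []).append(d)
        self._donor_by_id = {d["donor_id"]: d for d in self.donors}

    # -- identity -----------------------------------------------------------

    def duplicate_transfusions(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            n, d = duplicates_beyond_first(self.transfusions[h], ["donation_code", "product_type"])
            num, den = num + n, den + d
        return num, den

    def duplicate_donations(self) -> Tuple[int, int]:
        return duplicates_beyond_first(self.donations, ["donation_id", "donation_type"])

    def duplicate_procedures(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            n, d = duplicates_beyond_first(
                self.procedures[h], ["patient_id", "procedure_code", "procedure_date"]
            )
            num, den = num + n, den + d
        return num, den

    # -- linkage ------------------------------------------------------------

    def _match_count(self, tx: dict) -> int:
        n = 0
        for p in self._prod_by_id.get(tx.get("donation_code"), ()):
            if match_product(tx, p):
                n += 1
        return n

    def unlinked_transfusions(self, year: Optional[int] = None) -> Tuple[int, int]:
        """Transfusions not resolving to exactly one issued product."""
        num = den = 0
        for t in self.all_transfusions:
            if year is not None:
                d = t.get("transfusion_date")
                if _null(d) or d.year != year:
                    continue
            den += 1
            if self._match_count(t) != 1:
                num += 1
        return num, den

    def spilled_products(self) -> Tuple[int, int]:
        num = 0
        for p in self.products:
            matched = any(match_product(t, p) for t in self.all_transfusions
                          if t.get("donation_code") == p["product_id"])
            if not matched:
                num += 1
        return num, len(self.products)

    def product_donation_links(self) -> Tuple[int, int]:
        """Products whose every constituent donation id resolves."""
        ok = 0
        for p in self.products:
            ids = p.get("donation_ids") or ()
            if ids and all(i in self._don_by_id for i in ids):
                ok += 1
        return len(self.products) - ok, len(self.products)

    def product_donor_links(self) -> Tuple[int, int]:
        ok = 0
        for p in self.products:
            ids = p.get("donation_ids") or ()
            good = bool(ids)
            for i in ids:
                dons = self._don_by_id.get(i)
                if not dons or any(
                    _null(d.get("donor_id")) or d["donor_id"] not in self._donor_by_id for d in dons
                ):
                    good = False
                    break
            if good:
                ok += 1
        return len(self.products) - ok, len(self.products)

    # -- completeness / uniformity -------------------------------------------

    def missing(self, kind: str, table: str, field: str, analyte: Optional[str] = None) -> Tuple[int, int]:
        if kind == "blood_bank":
            groups = [getattr(self, table if table != "donors" else "donors")]
            if table == "donations":
                groups = [self.donations]
            elif table == "products":
                groups = [self.products]
        else:
            groups = [getattr(self, table)[h] for h in self.hospitals]
        num = den = 0
        for rows in groups:
            for r in rows:
                if analyte is not None and r.get("analyte") != analyte:
                    continue
                den += 1
                if _null(r.get(field)):
                    num += 1
        return num, den

    def nonconformant_diagnoses(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            for e in self.diagnoses[h]:
                code = e.get("diagnosis_code")
                if _null(code):
                    continue
                den += 1
                if str(code).strip().casefold() not in self.dx_codes:
                    num += 1
        return num, den

    def nonconformant_product_codes(self) -> Tuple[int, int]:
        num = den = 0
        for rows in [self.products] + [self.transfusions[h] for h in self.hospitals]:
            for r in rows:
                code = r.get("product_code")
                if _null(code):
                    continue
                den += 1
                if str(code).strip().casefold() not in self.product_codes:
                    num += 1
        return num, den

    def uncovered_transfusions(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            eps: Dict[str, List[dict]] = {}
            for e in self.diagnoses[h]:
                eps.setdefault(e["patient_id"], []).append(e)
            for t in self.transfusions[h]:
                td = t.get("transfusion_date")
                if _null(td):
                    continue
                den += 1
                covered = False
                for e in eps.get(t["patient_id"], ()):
                    s, en = e.get("start_date"), e.get("end_date")
                    if not _null(s) and s <= td and (_null(en) or td <= en):
                        covered = True
                        break
                if not covered:
                    num += 1
        return num, den

    def hb_precision(self) -> Tuple[int, int]:
        decs: List[int] = []
        for h in self.hospitals:
            for r in self.labs[h]:
                if r.get("analyte") == "Hb" and not _null(r.get("value")) and not _null(r.get("value_decimals")):
                    decs.append(int(r["value_decimals"]))
        for d in self.donations:
            if not _null(d.get("hb_value")) and not _null(d.get("hb_value_decimals")):
                decs.append(int(d["hb_value_decimals"]))
        if not decs:
            return 0, 0
        counts: Dict[int, int] = {}
        for d in decs:
            counts[d] = counts.get(d, 0) + 1
        best = max(counts.values())
        modal = min(k for k, v in counts.items() if v == best)  # tie -> fewer decimals
        off = sum(1 for d in decs if d != modal)
        return off, len(decs)

    # -- plausibility -------------------------------------------------------

    def _bleeding_windows(self, h: str) -> Dict[str, List[Tuple]]:
        out: Dict[str, List[Tuple]] = {}
        for e in self.diagnoses[h]:
            if e.get("diagnosis_code") in self.bleeding_codes:
                out.setdefault(e["patient_id"], []).append((e.get("start_date"), e.get("end_date")))
        return out

    def hb_classification(self, thresholds) -> Dict[str, int]:
        """Classify each RBC transfusion by relative Hb change around it."""
        win = thresholds.hb_window_days
        thr = thresholds.hb_change_pct
        counts = {"increase": 0, "decrease": 0, "no_change": 0, "unevaluable": 0,
                  "unexplained_decrease": 0, "total": 0}
        for h in self.hospitals:
            labs: Dict[str, List[dict]] = {}
            for r in self.labs[h]:
                if r.get("analyte") == "Hb" and not _null(r.get("value")) and not _null(r.get("measured_at")):
                    labs.setdefault(r["patient_id"], []).append(r)
            bleeding = self._bleeding_windows(h)
            for t in self.transfusions[h]:
                if t.get("product_type") != "RBC":
                    continue
                counts["total"] += 1
                td = t.get("transfusion_date")
                if _null(td):
                    counts["unevaluable"] += 1
                    continue
                pre = post = None
                for r in labs.get(t["patient_id"], ()):
                    m = r["measured_at"]
                    delta = (m - td).days
                    if -win <= delta <= -1:
                        if pre is None or m > pre["measured_at"]:
                            pre = r
                    elif 1 <= delta <= win:
                        # ties resolve toward the later-recorded measurement
                        if post is None or m <= post["measured_at"]:
                            post = r
                if pre is None or post is None:
                    counts["unevaluable"] += 1
                    continue
                change = (post["value"] - pre["value"]) / pre["value"] * 100
                if change > thr:
                    counts["increase"] += 1
                elif change < -thr:
                    counts["decrease"] += 1
                    explained = any(
                        not _null(s) and s <= td and (_null(e) or td <= e)
                        for s, e in bleeding.get(t["patient_id"], ())
                    )
                    if not explained:
                        counts["unexplained_decrease"] += 1
                else:
                    counts["no_change"] += 1
        return counts

    def unexplained_decreases(self, thresholds) -> Tuple[int, int]:
        c = self.hb_classification(thresholds)
        return c["unexplained_decrease"], c["total"] - c["unevaluable"]

    def overfrequent_donor_years(self, thresholds) -> Tuple[int, int]:
        seen: Dict[Tuple[str, int, str], set] = {}
        for d in self.donations:
            if _null(d.get("donation_date")) or _null(d.get("donor_id")):
                continue
            key = (d["donor_id"], d["donation_date"].year, d.get("donation_type"))
            seen.setdefault(key, set()).add(d["donation_id"])
        num = 0
        for (donor_id, _y, dtype), ids in seen.items():
            donor = self._donor_by_id.get(donor_id)
            gender = donor.get("gender") if donor else None
            if dtype == "whole_blood":
                is_female = not _null(gender) and gender == "F"
                limit = thresholds.wb_limit_female if is_female else thresholds.wb_limit_male
            else:
                limit = thresholds.plasma_limit
            if len(ids) > limit:
                num += 1
        return num, len(seen)

    def out_of_age_donations(self, thresholds) -> Tuple[int, int]:
        num = den = 0
        for d in self.donations:
            if d.get("autologous") is True:
                continue
            donor = self._donor_by_id.get(d.get("donor_id"))
            if donor is None or _null(donor.get("birth_date")) or _null(d.get("donation_date")):
                continue
            den += 1
            a = age_years(donor["birth_date"], d["donation_date"])
            if a < thresholds.donor_age_min or a > thresholds.donor_age_max:
                num += 1
        return num, den

    def donation_before_pooling(self) -> Tuple[int, int]:
        num = den = 0
        for p in self.products:
            if _null(p.get("pooling_date")):
                continue
            for i in p.get("donation_ids") or ():
                dons = self._don_by_id.get(i, ())
                if not dons:  # one pair per distinct constituent donation
                    continue
                d = dons[0]
                if _null(d.get("donation_date")):
                    continue
                den += 1
                if not d["donation_date"] < p["pooling_date"]:
                    num += 1
        return num, den

    def overage_patients(self, thresholds) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            by_id = {p["patient_id"]: p for p in self.patients[h]}
            for t in self.transfusions[h]:
                pt = by_id.get(t["patient_id"])
                if pt is None or _null(pt.get("birth_date")) or _null(t.get("transfusion_date")):
                    continue
                den += 1
                if age_years(pt["birth_date"], t["transfusion_date"]) >= thresholds.patient_age_max:
                    num += 1
        return num, den

    def gynecology_gender_violations(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            gyn_pat = set()
            for e in self.diagnoses[h]:
                if e.get("diagnosis_code") in self.gyn_codes:
                    gyn_pat.add(e["patient_id"])
            for p in self.patients[h]:
                if p["patient_id"] in gyn_pat and not _null(p.get("gender")):
                    den += 1
                    if p["gender"] != "F":
                        num += 1
        return num, den

    def postdeath_patients(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            events: Dict[str, List] = {}
            for t in self.transfusions[h]:
                if not _null(t.get("transfusion_date")):
                    events.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            for r in self.procedures[h]:
                if not _null(r.get("procedure_date")):
                    events.setdefault(r["patient_id"], []).append(r["procedure_date"])
            for p in self.patients[h]:
                if p["patient_id"] not in events:
                    continue
                den += 1
                dd = p.get("death_date")
                if not _null(dd) and any(e > dd for e in events[p["patient_id"]]):
                    num += 1
        return num, den

    def zero_length(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            for r in self.hospitalizations[h]:
                a, d = r.get("admission_date"), r.get("discharge_date")
                if _null(a) or _null(d):
                    continue
                den += 1
                if d < a:
                    num += 1
        return num, den

    def expired_transfusions(self) -> Tuple[int, int]:
        num = den = 0
        for t in self.all_transfusions:
            matches = [
                p for p in self._prod_by_id.get(t.get("donation_code"), ()) if match_product(t, p)
            ]
            if len(matches) != 1:
                continue
            exp = matches[0].get("expiration_date")
            if _null(exp) or _null(t.get("transfusion_date")):
                continue
            den += 1
            if exp < t["transfusion_date"]:
                num += 1
        return num, den

    def bad_pools(self, thresholds) -> Tuple[int, int]:
        num = den = 0
        for p in self.products:
            if p.get("product_type") != "PLT":
                continue
            den += 1
            donors = set()
            for i in p.get("donation_ids") or ():
                for d in self._don_by_id.get(i, ()):
                    if not _null(d.get("donor_id")):
                        donors.add(d["donor_id"])
            if len(donors) not in thresholds.pooled_plt_donors:
                num += 1
        return num, den

    def transferred_patients(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            transfused = {t["patient_id"] for t in self.transfusions[h]}
            transferred = {
                r["patient_id"]
                for r in self.hospitalizations[h]
                if r.get("discharge_destination") == "other_hospital"
            }
            den += len(transfused)
            num += len(transfused & transferred)
        return num, den

    def outpatient_transfusions(self) -> Tuple[int, int]:
        num = den = 0
        for h in self.hospitals:
            hosp: Dict[str, List[dict]] = {}
            for r in self.hospitalizations[h]:
                hosp.setdefault(r["patient_id"], []).append(r)
            for t in self.transfusions[h]:
                td = t.get("transfusion_date")
                if _null(td):
                    continue
                den += 1
                linked = False
                for r in hosp.get(t["patient_id"], ()):
                    a, d = r.get("admission_date"), r.get("discharge_date")
                    if not _null(a) and a <= td and (_null(d) or td <= d):
                        linked = True
                        break
                if not linked:
                    num += 1
        return num, den
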