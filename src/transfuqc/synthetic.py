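"""Synthetic multisource transfusion warehouse with seeded error injection.

The generator first builds a *clean backbone*: every transfusion links to
exactly one issued product, every product to its donation(s) and donors,
every transfusion falls inside a hospitalization and at least one diagnosis
episode, hemoglobin rises by a clinically plausible increment after each
red-cell transfusion, and all plausibility limits hold.  Errors are then
injected channel by channel with seeded Bernoulli draws over records that
earlier channels have not touched, so that each channel perturbs exactly
the checks it is paired with.  Every injected error is recorded once in a
ground-truth :class:`ErrorLedger`.

Volumes default to a scaled-down version of a national blood bank linked
to two teaching hospitals over 2010-2014 (about 10,000 transfusions: per
hospital-year 700 RBC, 200 FFP and 100 pooled-platelet products).  Platelet
pools draw 5-6 whole-blood donations; a 23.64 % share of single-transfusion
hospitalizations are day admissions.
"""

from __future__ import annotations

import hashlib
from datetime import date, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import bruteforce as bf
from .config import ProvenanceError, ThresholdConfig
from .warehouse import (
    BLOOD_BANK_TABLES,
    EXTERNAL_SCHEMA,
    HOSPITAL_TABLES,
    Source,
    Warehouse,
)

#: Error channels, in injection order.  Order matters: channels that copy or
#: rewire records run before channels that mutate cell values, and each
#: channel skips records already touched by an earlier one.
CHANNELS = (
    "duplicate_transfusion",
    "duplicate_donation",
    "duplicate_procedure",
    "broken_product_link",
    "prior_year_issue",
    "spilled_product",
    "missing_field",
    "unexplained_hb_decrease",
    "postdeath_event",
    "gender_mismatch_gynecology",
    "overfrequent_donor",
    "out_of_age_donor",
    "code_not_in_reference",
    "wrong_pool_cardinality",
    "expired_at_transfusion",
    "zero_length_violation",
    "transfer_out",
    "outpatient_transfusion",
)

#: Fields nulled by the missing_field channel: (source kind, table, field).
MISSING_FIELD_TARGETS = (
    ("blood_bank", "donors", "birth_date"),
    ("blood_bank", "donors", "gender"),
    ("blood_bank", "donations", "hb_value"),
    ("blood_bank", "products", "product_code"),
    ("hospital", "patients", "birth_date"),
    ("hospital", "patients", "gender"),
    ("hospital", "procedures", "procedure_date"),
    ("hospital", "labs", "value"),
    ("hospital", "transfusions", "product_code"),
)

#: Which report rules a channel perturbs (everything else must stay perfect
#: in a single-channel run).  Completeness rules are listed per field.
CHANNEL_RULES: Dict[str, Tuple[str, ...]] = {
    "duplicate_transfusion": ("I1",),
    "duplicate_donation": ("I2",),
    "duplicate_procedure": ("I3",),
    "missing_field": tuple(
        f"K1[{t}.{f}]" for _, t, f in MISSING_FIELD_TARGETS if t != "labs"
    ) + ("K1[labs.value:Hb]", "K1[labs.value:thrombocytes]", "K2"),
    "broken_product_link": ("L1", "L2", "T2"),
    "prior_year_issue": ("L1", "L2", "T2"),
    "spilled_product": ("L2",),
    "unexplained_hb_decrease": ("P4",),
    "postdeath_event": ("P8",),
    "gender_mismatch_gynecology": ("P7",),
    "overfrequent_donor": ("P2",),
    "out_of_age_donor": ("P3",),
    "code_not_in_reference": ("U2",),
    "wrong_pool_cardinality": ("E1",),
    "expired_at_transfusion": ("P10",),
    "zero_length_violation": ("P9",),
    "transfer_out": ("E2",),
    "outpatient_transfusion": ("E3",),
}

PRODUCT_CODE_LISTS = {
    "RBC": ["E0150", "E0151", "E0152", "E0153"],
    "FFP": ["E0701", "E0702", "E0703"],
    "PLT": ["E2971", "E2972", "E2973"],
}
GENERIC_DX = [f"G{i:03d}" for i in range(1, 21)]
BLEEDING_DX = ["BL001", "BL002", "BL003", "BL004"]
GYN_DX = ["GY001", "GY002", "GY003"]
PROCEDURE_CODES = [f"PR{i:03d}" for i in range(1, 9)]


class SimulationParams(BaseModel):
    """Volumes, rates and the master seed of one simulation run.

    ``products_per_year`` is per hospital per calendar year.  Error rates
    are Bernoulli probabilities per eligible record, all zero by default
    (clean backbone).  Identical params (including seed) give byte-identical
    output.
    """

    seed: int = 0
    n_hospitals: int = 2
    year_start: int = 2010
    year_end: int = 2014
    n_donors: int = 2600
    n_patients: int = 1600
    products_per_year: Dict[str, int] = Field(
        default_factory=lambda: {"RBC": 700, "FFP": 200, "PLT": 100}
    )
    plasma_donor_frac: float = 0.10
    autologous_rate: float = 0.01
    explained_decrease_rate: float = 0.03
    day_admission_frac: float = 0.2364
    extra_hospitalization_frac: float = 0.30
    deceased_frac: float = 0.05
    split_product_duplicates: bool = False
    error_rates: Dict[str, float] = Field(default_factory=dict)

    @field_validator("error_rates")
    @classmethod
    def _valid_rates(cls, v):
        for k, r in v.items():
            if k not in CHANNELS:
                raise ValueError(f"unknown error channel {k!r}")
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {k!r} outside [0, 1]")
        return v

    def rate(self, channel: str) -> float:
        return self.error_rates.get(channel, 0.0)

    def provenance(self) -> str:
        digest = hashlib.md5(self.model_dump_json().encode()).hexdigest()[:12]
        return f"sim-{digest}"

    def check_feasible(self) -> None:
        """Rough capacity check: donor pool must cover the donation demand."""
        n_wb = int(self.n_donors * (1 - self.plasma_donor_frac))
        n_pl = self.n_donors - n_wb
        years = self.year_end - self.year_start + 1
        wb_need = self.n_hospitals * (
            self.products_per_year.get("RBC", 0) + 6 * self.products_per_year.get("PLT", 0)
        )
        pl_need = self.n_hospitals * self.products_per_year.get("FFP", 0)
        if wb_need > 0.85 * n_wb * 4:  # mean WB limit over genders is 4/year
            raise ValueError(
                f"infeasible volumes: {wb_need} whole-blood donations/year "
                f"exceed the safe capacity of {n_wb} donors"
            )
        if pl_need > 0.85 * n_pl * 23:
            raise ValueError(
                f"infeasible volumes: {pl_need} plasma donations/year "
                f"exceed the safe capacity of {n_pl} plasmapheresis donors"
            )
        if years < 1 or self.n_hospitals < 1:
            raise ValueError("need at least one year and one hospital")
        if self.n_patients < 2 * self.n_hospitals:
            raise ValueError("too few patients for the requested hospitals")


class ErrorLedger:
    """Ground truth of every injected error.

    ``frame`` has one row per injected error: (channel, record_id,
    source_id, detail).  ``remap`` is the companion table for the
    broken_product_link channel (recoded id -> true id), empty otherwise.
    """

    def __init__(self, records: List[dict], remap: List[dict], provenance: str):
        self.frame = pd.DataFrame(
            records, columns=["channel", "record_id", "source_id", "detail"]
        )
        self.remap = pd.DataFrame(remap, columns=["old_id", "new_id"])
        self.provenance = provenance

    def count(self, channel: str) -> int:
        return int((self.frame["channel"] == channel).sum())

    def ids(self, channel: str) -> List[str]:
        return list(self.frame.loc[self.frame["channel"] == channel, "record_id"])


# ---------------------------------------------------------------------------
# Backbone generation
# ---------------------------------------------------------------------------


def _ts(d: Optional[date]):
    return pd.Timestamp(d) if d is not None else pd.NaT


class _Sim:
    def __init__(self, params: SimulationParams):
        params.check_feasible()
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.years = list(range(params.year_start, params.year_end + 1))
        self.hospital_ids = [f"hospital_{i + 1}" for i in range(params.n_hospitals)]
        self.donors: List[dict] = []
        self.donations: List[dict] = []
        self.products: List[dict] = []
        self.prior_products: List[dict] = []
        self.patients: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.transfusions: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.hospitalizations: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.diagnoses: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.procedures: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.labs: Dict[str, List[dict]] = {h: [] for h in self.hospital_ids}
        self.wb_caps: Dict[Tuple[str, int], int] = {}
        self.donor_by_id: Dict[str, dict] = {}
        self.labs_by_tid: Dict[str, Tuple[dict, dict]] = {}
        self.hb_explained: set = set()
        self.bleeding_cover: Dict[str, List[Tuple[date, date]]] = {}
        self.seq = {"N": 0, "B": 0, "L": 0, "E": 0, "A": 0, "R": 0}
        self.touched: Dict[str, set] = {
            k: set()
            for k in (
                "transfusions",
                "donations",
                "products",
                "donors",
                "patients",
                "hospitalizations",
                "episodes",
                "procedures",
                "labs",
            )
        }
        self.ledger_rows: List[dict] = []
        self.remap_rows: List[dict] = []

    # -- helpers ------------------------------------------------------------

    def next_id(self, prefix: str) -> str:
        self.seq[prefix] += 1
        return f"{prefix}{self.seq[prefix]:06d}"

    def _rand_day(self, year: int, lo: int, hi: int) -> date:
        return date(year, 1, 1) + timedelta(days=int(self.rng.integers(lo, hi + 1)))

    def wb_limit(self, donor: dict) -> int:
        # 3 (F) / 5 (M) whole-blood donations per calendar year
        return 3 if donor["gender"] == "F" else 5

    def pick_wb_donors(self, year: int, k: int) -> List[dict]:
        chosen: List[dict] = []
        used: set = set()
        tries = 0
        while len(chosen) < k:
            tries += 1
            idx = int(self.rng.integers(len(self.wb_donors)))
            d = self.wb_donors[idx]
            key = (d["donor_id"], year)
            if d["donor_id"] in used:
                continue
            if self.wb_caps.get(key, 0) >= self.wb_limit(d):
                if tries > 50 * k:
                    for d2 in self.wb_donors:
                        k2 = (d2["donor_id"], year)
                        if d2["donor_id"] not in used and self.wb_caps.get(k2, 0) < self.wb_limit(d2):
                            d, key = d2, k2
                            break
                    else:  # pragma: no cover - guarded by check_feasible
                        raise ValueError("whole-blood donor capacity exhausted")
                else:
                    continue
            self.wb_caps[key] = self.wb_caps.get(key, 0) + 1
            used.add(d["donor_id"])
            chosen.append(d)
        return chosen

    def add_donation(self, donor: dict, don_date: date, don_type: str) -> dict:
        row = {
            "donation_id": self.next_id("N"),
            "donor_id": donor["donor_id"],
            "donation_date": don_date,
            "donation_type": don_type,
            "hb_value": round(float(np.clip(self.rng.normal(8.6, 0.5), 7.0, 10.5)), 1),
            "hb_value_decimals": 1,
            "autologous": bool(self.rng.random() < self.p.autologous_rate),
        }
        self.donations.append(row)
        return row

    # -- backbone -----------------------------------------------------------

    def make_donors(self) -> None:
        n_wb = int(self.p.n_donors * (1 - self.p.plasma_donor_frac))
        for i in range(self.p.n_donors):
            by = int(self.rng.integers(1948, 1989))
            self.donors.append(
                {
                    "donor_id": f"D{i + 1:06d}",
                    "birth_date": date(by, int(self.rng.integers(1, 13)), int(self.rng.integers(1, 29))),
                    "gender": "F" if self.rng.random() < 0.5 else "M",
                    "_pool": "wb" if i < n_wb else "plasma",
                }
            )
        self.wb_donors = [d for d in self.donors if d["_pool"] == "wb"]
        self.plasma_donors = [d for d in self.donors if d["_pool"] == "plasma"]
        self.donor_by_id = {d["donor_id"]: d for d in self.donors}
        self._plasma_caps: Dict[Tuple[str, int], int] = {}

    def pick_plasma_donor(self, year: int) -> dict:
        while True:
            idx = int(self.rng.integers(len(self.plasma_donors)))
            d = self.plasma_donors[idx]
            key = (d["donor_id"], year)
            if self._plasma_caps.get(key, 0) < 23:
                self._plasma_caps[key] = self._plasma_caps.get(key, 0) + 1
                return d

    def make_patients(self) -> None:
        per_h = self.p.n_patients // self.p.n_hospitals
        for hi, h in enumerate(self.hospital_ids):
            for i in range(per_h):
                by = int(self.rng.integers(1930, 2001))
                self.patients[h].append(
                    {
                        "patient_id": f"H{hi + 1}P{i + 1:05d}",
                        "birth_date": date(by, int(self.rng.integers(1, 13)), int(self.rng.integers(1, 29))),
                        "gender": "F" if self.rng.random() < 0.5 else "M",
                        "death_date": None,
                    }
                )

    def make_products(self) -> None:
        self._rbc_dates: Dict[str, List[date]] = {}
        for h in self.hospital_ids:
            pts = self.patients[h]
            for year in self.years:
                for ptype in ("RBC", "FFP", "PLT"):
                    for _ in range(self.p.products_per_year.get(ptype, 0)):
                        self._one_product(h, pts, year, ptype)

    def _assign_patient(self, pts: List[dict], ptype: str, t_date: date) -> dict:
        for _ in range(40):
            pt = pts[int(self.rng.integers(len(pts)))]
            if ptype != "RBC":
                return pt
            close = any(
                abs((t_date - d).days) <= 3 for d in self._rbc_dates.get(pt["patient_id"], ())
            )
            if not close:
                return pt
        return pt  # pragma: no cover - statistically unreachable at defaults

    def _one_product(self, h: str, pts: List[dict], year: int, ptype: str) -> None:
        ri = self.rng.integers
        t_date = self._rand_day(year, 19, 361)  # Jan 20 .. Dec 28
        year_floor = date(year, 1, 1)
        if ptype == "RBC":
            issue = t_date - timedelta(days=int(ri(1, 4)))
            don_date = max(issue - timedelta(days=int(ri(6, 12))), year_floor)
            production = don_date + timedelta(days=1)
            expiration = production + timedelta(days=35)
            pooling = None
            donors = self.pick_wb_donors(year, 1)
            dons = [self.add_donation(donors[0], don_date, "whole_blood")]
        elif ptype == "FFP":
            issue = t_date - timedelta(days=int(ri(1, 4)))
            don_date = max(issue - timedelta(days=int(ri(5, 31))), year_floor)
            production = don_date + timedelta(days=1)
            expiration = production + timedelta(days=365)
            pooling = None
            donor = self.pick_plasma_donor(year)
            dons = [self.add_donation(donor, don_date, "plasma")]
        else:  # PLT, pooled from 5-6 whole-blood donations
            issue = t_date - timedelta(days=int(ri(1, 3)))
            pooling = issue - timedelta(days=int(ri(1, 4)))
            production = pooling
            expiration = production + timedelta(days=7)
            k = int(self.rng.choice([5, 6]))
            donors = self.pick_wb_donors(year, k)
            dons = [
                self.add_donation(d, pooling - timedelta(days=int(ri(1, 4))), "whole_blood")
                for d in donors
            ]
        pid = self.next_id("B")
        code = str(self.rng.choice(PRODUCT_CODE_LISTS[ptype]))
        self.products.append(
            {
                "product_id": pid,
                "product_code": code,
                "product_type": ptype,
                "donation_ids": tuple(d["donation_id"] for d in dons),
                "production_date": production,
                "expiration_date": expiration,
                "issue_date": issue,
                "pooling_date": pooling,
            }
        )
        pt = self._assign_patient(pts, ptype, t_date)
        if ptype == "RBC":
            self._rbc_dates.setdefault(pt["patient_id"], []).append(t_date)
        self.transfusions[h].append(
            {
                "transfusion_id": f"T{h[-1]}{len(self.transfusions[h]) + 1:06d}",
                "patient_id": pt["patient_id"],
                "donation_code": pid,
                "product_code": code,
                "product_type": ptype,
                "transfusion_date": t_date,
            }
        )

    def make_hospitalizations(self) -> None:
        for h in self.hospital_ids:
            by_pt: Dict[str, List[date]] = {}
            for t in self.transfusions[h]:
                by_pt.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            n_episodes = 0
            for pid, dates in by_pt.items():
                dates.sort()
                cluster = [dates[0]]
                clusters = []
                for d in dates[1:]:
                    if (d - cluster[-1]).days > 30:
                        clusters.append(cluster)
                        cluster = [d]
                    else:
                        cluster.append(d)
                clusters.append(cluster)
                for cl in clusters:
                    n_episodes += 1
                    day_adm = len(cl) == 1 and self.rng.random() < self.p.day_admission_frac
                    if day_adm:
                        adm = dis = cl[0]
                    else:
                        adm = cl[0] - timedelta(days=int(self.rng.integers(1, 6)))
                        dis = cl[-1] + timedelta(days=int(self.rng.integers(1, 11)))
                    self.hospitalizations[h].append(
                        {
                            "hospitalization_id": self.next_id("A"),
                            "patient_id": pid,
                            "admission_date": adm,
                            "discharge_date": dis,
                            "day_admission": day_adm,
                            "discharge_destination": "home",
                        }
                    )
            pts = self.patients[h]
            for _ in range(int(self.p.extra_hospitalization_frac * n_episodes)):
                pt = pts[int(self.rng.integers(len(pts)))]
                adm = self._rand_day(int(self.rng.choice(self.years)), 0, 360)
                self.hospitalizations[h].append(
                    {
                        "hospitalization_id": self.next_id("A"),
                        "patient_id": pt["patient_id"],
                        "admission_date": adm,
                        "discharge_date": adm + timedelta(days=int(self.rng.integers(0, 4))),
                        "day_admission": False,
                        "discharge_destination": "home",
                    }
                )

    def make_diagnoses(self) -> None:
        for h in self.hospital_ids:
            by_pt: Dict[str, List[date]] = {}
            for t in self.transfusions[h]:
                by_pt.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            for pt in self.patients[h]:
                pid = pt["patient_id"]
                dates = sorted(by_pt.get(pid, []))
                if dates:
                    self._add_episode(h, pid, dates[0] - timedelta(days=10), dates[-1] + timedelta(days=10))
                    for _ in range(int(self.rng.poisson(0.8))):
                        anchor = dates[int(self.rng.integers(len(dates)))]
                        span = int(self.rng.integers(5, 41))
                        self._add_episode(h, pid, anchor - timedelta(days=span), anchor + timedelta(days=span))
                elif self.rng.random() < 0.5:
                    start = self._rand_day(int(self.rng.choice(self.years)), 0, 330)
                    self._add_episode(h, pid, start, start + timedelta(days=int(self.rng.integers(5, 60))))
                if pt["gender"] == "F" and self.rng.random() < 0.30:
                    anchor = (
                        dates[int(self.rng.integers(len(dates)))]
                        if dates
                        else self._rand_day(int(self.rng.choice(self.years)), 10, 350)
                    )
                    self._add_episode(
                        h, pid, anchor - timedelta(days=10), anchor + timedelta(days=10),
                        code=str(self.rng.choice(GYN_DX)),
                    )

    def _add_episode(self, h: str, pid: str, start: date, end: Optional[date], code: Optional[str] = None) -> dict:
        row = {
            "episode_id": self.next_id("E"),
            "patient_id": pid,
            "diagnosis_code": code or str(self.rng.choice(GENERIC_DX)),
            "start_date": start,
            "end_date": end,
        }
        self.diagnoses[h].append(row)
        return row

    def make_procedures(self) -> None:
        for h in self.hospital_ids:
            transfused = sorted({t["patient_id"] for t in self.transfusions[h]})
            t_by_pt: Dict[str, List[date]] = {}
            for t in self.transfusions[h]:
                t_by_pt.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            used_keys: set = set()
            for pid in transfused:
                if self.rng.random() >= 0.4:
                    continue
                for _ in range(int(self.rng.integers(1, 3))):
                    anchor = t_by_pt[pid][int(self.rng.integers(len(t_by_pt[pid])))]
                    # keep the backbone free of accidental duplicate keys
                    for _try in range(10):
                        code = str(self.rng.choice(PROCEDURE_CODES))
                        when = anchor + timedelta(days=int(self.rng.integers(-3, 4)))
                        if (pid, code, when) not in used_keys:
                            break
                    else:
                        continue
                    used_keys.add((pid, code, when))
                    self.procedures[h].append(
                        {
                            "procedure_id": self.next_id("R"),
                            "patient_id": pid,
                            "procedure_code": code,
                            "procedure_date": when,
                        }
                    )

    def make_labs(self) -> None:
        for h in self.hospital_ids:
            for t in self.transfusions[h]:
                td = t["transfusion_date"]
                if t["product_type"] == "RBC":
                    pre = round(float(np.clip(self.rng.normal(7.0, 0.4), 5.8, 8.6)), 1)
                    post = round(pre * (1 + float(self.rng.uniform(0.12, 0.22))), 1)
                    pre_row = self._add_lab(h, t["patient_id"], "Hb", td - timedelta(days=1), pre, 1)
                    post_row = self._add_lab(h, t["patient_id"], "Hb", td + timedelta(days=1), post, 1)
                    self.labs_by_tid[t["transfusion_id"]] = (pre_row, post_row)
                elif t["product_type"] == "PLT":
                    v = float(np.clip(self.rng.normal(30, 8), 8, 60))
                    self._add_lab(h, t["patient_id"], "thrombocytes", td - timedelta(days=1), round(v), 0)
                    self._add_lab(h, t["patient_id"], "thrombocytes", td + timedelta(days=1), round(v + float(self.rng.uniform(10, 30))), 0)

    def _add_lab(self, h: str, pid: str, analyte: str, when: date, value: float, decimals: int) -> dict:
        row = {
            "lab_id": self.next_id("L"),
            "patient_id": pid,
            "analyte": analyte,
            "measured_at": when,
            "value": value,
            "value_decimals": decimals,
        }
        self.labs[h].append(row)
        return row

    def apply_explained_decreases(self) -> None:
        """A share of RBC transfusions show an Hb *decrease* that is clinically
        explained by an active bleeding-risk diagnosis; these are backbone
        features, not errors."""
        for h in self.hospital_ids:
            for t in self.transfusions[h]:
                tid = t["transfusion_id"]
                if t["product_type"] != "RBC" or tid not in self.labs_by_tid:
                    continue
                if self.rng.random() >= self.p.explained_decrease_rate:
                    continue
                pre_row, post_row = self.labs_by_tid[tid]
                post_row["value"] = round(pre_row["value"] * (1 - float(self.rng.uniform(0.12, 0.20))), 1)
                td = t["transfusion_date"]
                self._add_episode(
                    h, t["patient_id"], td - timedelta(days=3), td + timedelta(days=3),
                    code=str(self.rng.choice(BLEEDING_DX)),
                )
                self.hb_explained.add(tid)
                self.bleeding_cover.setdefault(t["patient_id"], []).append(
                    (td - timedelta(days=3), td + timedelta(days=3))
                )

    def set_deaths(self) -> None:
        for h in self.hospital_ids:
            last_event: Dict[str, date] = {}
            for rows, col in (
                (self.transfusions[h], "transfusion_date"),
                (self.procedures[h], "procedure_date"),
                (self.hospitalizations[h], "discharge_date"),
            ):
                for r in rows:
                    d = r.get(col)
                    if d is not None:
                        pid = r["patient_id"]
                        if pid not in last_event or d > last_event[pid]:
                            last_event[pid] = d
            for pt in self.patients[h]:
                pid = pt["patient_id"]
                if pid in last_event and self.rng.random() < self.p.deceased_frac:
                    pt["death_date"] = last_event[pid] + timedelta(days=int(self.rng.integers(10, 200)))

    # -- injection ----------------------------------------------------------

    def channel_rng(self, channel: str) -> np.random.Generator:
        idx = CHANNELS.index(channel)
        return np.random.default_rng(np.random.SeedSequence(entropy=[self.p.seed, 7700 + idx]))

    def record(self, channel: str, record_id: str, source_id: str, detail: str = "") -> None:
        self.ledger_rows.append(
            {"channel": channel, "record_id": record_id, "source_id": source_id, "detail": detail}
        )

    def inject_all(self) -> None:
        for channel in CHANNELS:
            rate = self.p.rate(channel)
            if rate <= 0:
                continue
            getattr(self, f"_inject_{channel}")(self.channel_rng(channel), rate)

    def _draw(self, rng, rows, rate):
        mask = rng.random(len(rows)) < rate
        return [r for r, m in zip(rows, mask) if m]

    def _inject_duplicate_transfusion(self, rng, rate) -> None:
        for h in self.hospital_ids:
            eligible = [
                t for t in self.transfusions[h]
                if t["transfusion_id"] not in self.touched["transfusions"]
                and (not self.p.split_product_duplicates or t["product_type"] != "PLT")
            ]
            for t in self._draw(rng, eligible, rate):
                dup = dict(t)
                dup["transfusion_id"] = t["transfusion_id"] + "-D"
                if self.p.split_product_duplicates:
                    # emulate split products: the copy is a real second product
                    # sharing the (donation code, product type) key
                    sib_code = str(rng.choice(PRODUCT_CODE_LISTS[t["product_type"]]))
                    dup["product_code"] = sib_code
                    src = next(p for p in self.products if p["product_id"] == t["donation_code"])
                    sib = dict(src)
                    sib["product_code"] = sib_code
                    self.products.append(sib)
                    self.touched["products"].add(sib["product_id"])
                self.transfusions[h].append(dup)
                self.touched["transfusions"].update({t["transfusion_id"], dup["transfusion_id"]})
                self.record("duplicate_transfusion", dup["transfusion_id"], h, t["transfusion_id"])

    def _inject_duplicate_donation(self, rng, rate) -> None:
        eligible = [d for d in self.donations if d["donation_id"] not in self.touched["donations"]]
        for d in self._draw(rng, eligible, rate):
            self.donations.append(dict(d))
            self.touched["donations"].add(d["donation_id"])
            self.record("duplicate_donation", d["donation_id"], "blood_bank")

    def _inject_duplicate_procedure(self, rng, rate) -> None:
        for h in self.hospital_ids:
            eligible = [r for r in self.procedures[h] if r["procedure_id"] not in self.touched["procedures"]]
            for r in self._draw(rng, eligible, rate):
                dup = dict(r)
                dup["procedure_id"] = r["procedure_id"] + "-D"
                self.procedures[h].append(dup)
                self.touched["procedures"].update({r["procedure_id"], dup["procedure_id"]})
                self.record("duplicate_procedure", dup["procedure_id"], h, r["procedure_id"])

    def _inject_missing_field(self, rng, rate) -> None:
        for kind, table, fld in MISSING_FIELD_TARGETS:
            if kind == "blood_bank":
                groups = [("blood_bank", getattr(self, table))]
                id_col = {"donors": "donor_id", "donations": "donation_id", "products": "product_id"}[table]
                touch = {"donors": "donors", "donations": "donations", "products": "products"}[table]
            else:
                groups = [(h, getattr(self, table)[h]) for h in self.hospital_ids]
                id_col = {
                    "patients": "patient_id",
                    "procedures": "procedure_id",
                    "labs": "lab_id",
                    "transfusions": "transfusion_id",
                }[table]
                touch = {
                    "patients": "patients",
                    "procedures": "procedures",
                    "labs": "labs",
                    "transfusions": "transfusions",
                }[table]
            for sid, rows in groups:
                eligible = [r for r in rows if r[id_col] not in self.touched[touch] and r.get(fld) is not None]
                for r in self._draw(rng, eligible, rate):
                    r[fld] = None
                    if fld + "_decimals" in r:
                        r[fld + "_decimals"] = None
                    self.touched[touch].add(r[id_col])
                    self.record("missing_field", r[id_col], sid, f"{table}.{fld}")

    def _inject_broken_product_link(self, rng, rate) -> None:
        for h in self.hospital_ids:
            eligible = [
                t for t in self.transfusions[h]
                if t["transfusion_id"] not in self.touched["transfusions"]
            ]
            for t in self._draw(rng, eligible, rate):
                true_code = t["donation_code"]
                t["donation_code"] = "X-" + true_code
                self.remap_rows.append({"old_id": "X-" + true_code, "new_id": true_code})
                self.touched["transfusions"].add(t["transfusion_id"])
                self.record("broken_product_link", t["transfusion_id"], h, true_code)

    def _inject_prior_year_issue(self, rng, rate) -> None:
        y0 = self.p.year_start
        eligible = [
            p for p in self.products
            if p["product_type"] == "FFP"
            and p["issue_date"] is not None
            and p["issue_date"].year == y0
            and p["product_id"] not in self.touched["products"]
        ]
        moved = set()
        for p in self._draw(rng, eligible, rate):
            new_issue = date(y0 - 1, 12, int(rng.integers(1, 29)))
            p["issue_date"] = new_issue
            p["production_date"] = new_issue - timedelta(days=1)
            p["expiration_date"] = p["production_date"] + timedelta(days=365)
            for d in self.donations:
                if d["donation_id"] in p["donation_ids"]:
                    d["donation_date"] = new_issue - timedelta(days=2)
                    moved.add(d["donation_id"])
            self.prior_products.append(p)
            self.touched["products"].add(p["product_id"])
            self.record("prior_year_issue", p["product_id"], "blood_bank", str(y0 - 1))
        self.products = [p for p in self.products if p not in self.prior_products]
        # donations issued before the extract window fall out of the extract
        self.donations = [d for d in self.donations if d["donation_id"] not in moved]

    def _inject_spilled_product(self, rng, rate) -> None:
        templates = [p for p in self.products if p["product_id"] not in self.touched["products"]]
        for tpl in self._draw(rng, templates, rate):
            year = tpl["issue_date"].year
            if tpl["product_type"] == "FFP":
                donor = self.pick_plasma_donor(year)
                dons = [self.add_donation(donor, tpl["issue_date"] - timedelta(days=6), "plasma")]
            else:
                k = len(tpl["donation_ids"])
                donors = self.pick_wb_donors(year, k)
                dons = [
                    self.add_donation(d, tpl["issue_date"] - timedelta(days=4), "whole_blood")
                    for d in donors
                ]
            pid = self.next_id("B")
            row = dict(tpl)
            row["product_id"] = pid
            row["donation_ids"] = tuple(d["donation_id"] for d in dons)
            self.products.append(row)
            self.touched["products"].add(pid)
            self.record("spilled_product", pid, "blood_bank", tpl["product_type"])

    def _inject_unexplained_hb_decrease(self, rng, rate) -> None:
        for h in self.hospital_ids:
            eligible = []
            for t in self.transfusions[h]:
                tid = t["transfusion_id"]
                if (
                    t["product_type"] == "RBC"
                    and tid in self.labs_by_tid
                    and tid not in self.touched["transfusions"]
                    and tid not in self.hb_explained
                    and all(
                        r["value"] is not None and r["lab_id"] not in self.touched["labs"]
                        for r in self.labs_by_tid[tid]
                    )
                    and not any(
                        s <= t["transfusion_date"] <= e
                        for s, e in self.bleeding_cover.get(t["patient_id"], ())
                    )
                ):
                    eligible.append(t)
            for t in self._draw(rng, eligible, rate):
                pre_row, post_row = self.labs_by_tid[t["transfusion_id"]]
                post_row["value"] = round(pre_row["value"] * (1 - float(rng.uniform(0.12, 0.20))), 1)
                self.touched["transfusions"].add(t["transfusion_id"])
                self.touched["labs"].add(post_row["lab_id"])
                self.record("unexplained_hb_decrease", t["transfusion_id"], h)

    def _inject_postdeath_event(self, rng, rate) -> None:
        for h in self.hospital_ids:
            first_tx: Dict[str, date] = {}
            for t in self.transfusions[h]:
                pid = t["patient_id"]
                if pid not in first_tx or t["transfusion_date"] < first_tx[pid]:
                    first_tx[pid] = t["transfusion_date"]
            eligible = [
                pt for pt in self.patients[h]
                if pt["death_date"] is None
                and pt["patient_id"] in first_tx
                and pt["patient_id"] not in self.touched["patients"]
            ]
            for pt in self._draw(rng, eligible, rate):
                pt["death_date"] = first_tx[pt["patient_id"]] - timedelta(days=1)
                self.touched["patients"].add(pt["patient_id"])
                self.record("postdeath_event", pt["patient_id"], h)

    def _inject_gender_mismatch_gynecology(self, rng, rate) -> None:
        for h in self.hospital_ids:
            t_by_pt: Dict[str, List[date]] = {}
            for t in self.transfusions[h]:
                t_by_pt.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            eligible = [
                pt for pt in self.patients[h]
                if pt["gender"] == "M" and pt["patient_id"] not in self.touched["patients"]
            ]
            for pt in self._draw(rng, eligible, rate):
                pid = pt["patient_id"]
                anchor = (
                    t_by_pt[pid][0] if pid in t_by_pt else self._rand_day(self.p.year_start, 30, 300)
                )
                row = self._add_episode(
                    h, pid, anchor - timedelta(days=5), anchor + timedelta(days=5),
                    code=GYN_DX[int(rng.integers(len(GYN_DX)))],
                )
                self.touched["patients"].add(pid)
                self.touched["episodes"].add(row["episode_id"])
                self.record("gender_mismatch_gynecology", pid, h)

    def _inject_overfrequent_donor(self, rng, rate) -> None:
        counts: Dict[Tuple[str, int], int] = {}
        for d in self.donations:
            if d["donation_type"] == "whole_blood" and d["donation_date"] is not None:
                counts[(d["donor_id"], d["donation_date"].year)] = (
                    counts.get((d["donor_id"], d["donation_date"].year), 0) + 1
                )
        by_donor: Dict[str, Tuple[int, int]] = {}
        for (did, year), c in counts.items():
            if did not in by_donor or c > by_donor[did][1]:
                by_donor[did] = (year, c)
        eligible = [
            d for d in self.wb_donors
            if d["donor_id"] in by_donor and d["donor_id"] not in self.touched["donors"]
        ]
        for d in self._draw(rng, eligible, rate):
            year, c = by_donor[d["donor_id"]]
            need = self.wb_limit(d) - c + 1
            for _ in range(max(need, 1)):
                self.add_donation(d, date(year, 1, 1) + timedelta(days=int(rng.integers(0, 360))), "whole_blood")
            self.touched["donors"].add(d["donor_id"])
            self.record("overfrequent_donor", d["donor_id"], "blood_bank", str(year))

    def _inject_out_of_age_donor(self, rng, rate) -> None:
        don_by_donor: Dict[str, List[dict]] = {}
        for d in self.donations:
            don_by_donor.setdefault(d["donor_id"], []).append(d)
        eligible = [
            d for d in self.donors
            if d["donor_id"] in don_by_donor
            and d["donor_id"] not in self.touched["donors"]
            and not any(x["autologous"] for x in don_by_donor[d["donor_id"]])
        ]
        for d in self._draw(rng, eligible, rate):
            first_year = min(
                x["donation_date"].year for x in don_by_donor[d["donor_id"]] if x["donation_date"]
            )
            d["birth_date"] = date(first_year - 75, 7, 1)
            self.touched["donors"].add(d["donor_id"])
            self.record("out_of_age_donor", d["donor_id"], "blood_bank")

    def _inject_code_not_in_reference(self, rng, rate) -> None:
        ref = set(GENERIC_DX)
        for h in self.hospital_ids:
            eligible = [
                e for e in self.diagnoses[h]
                if e["diagnosis_code"] in ref and e["episode_id"] not in self.touched["episodes"]
            ]
            for e in self._draw(rng, eligible, rate):
                e["diagnosis_code"] = "XX999"
                self.touched["episodes"].add(e["episode_id"])
                self.record("code_not_in_reference", e["episode_id"], h)

    def _inject_wrong_pool_cardinality(self, rng, rate) -> None:
        eligible = [
            p for p in self.products
            if p["product_type"] == "PLT"
            and len(p["donation_ids"]) >= 5
            and p["product_id"] not in self.touched["products"]
        ]
        for p in self._draw(rng, eligible, rate):
            p["donation_ids"] = p["donation_ids"][:4]
            self.touched["products"].add(p["product_id"])
            self.record("wrong_pool_cardinality", p["product_id"], "blood_bank")

    def _inject_expired_at_transfusion(self, rng, rate) -> None:
        prod_by_id = {p["product_id"]: p for p in self.products}
        for h in self.hospital_ids:
            eligible = [
                t for t in self.transfusions[h]
                if t["transfusion_id"] not in self.touched["transfusions"]
                and t["donation_code"] in prod_by_id
                and prod_by_id[t["donation_code"]]["product_id"] not in self.touched["products"]
            ]
            for t in self._draw(rng, eligible, rate):
                p = prod_by_id[t["donation_code"]]
                p["expiration_date"] = t["transfusion_date"] - timedelta(days=1)
                self.touched["products"].add(p["product_id"])
                self.touched["transfusions"].add(t["transfusion_id"])
                self.record("expired_at_transfusion", t["transfusion_id"], h, p["product_id"])

    def _covering_hospitalizations(self, h: str, pid: str, when: date) -> List[dict]:
        out = []
        for r in self.hospitalizations[h]:
            if r["patient_id"] != pid or r["admission_date"] is None:
                continue
            dis = r["discharge_date"]
            if r["admission_date"] <= when and (dis is None or when <= dis):
                out.append(r)
        return out

    def _inject_zero_length_violation(self, rng, rate) -> None:
        for h in self.hospital_ids:
            tx_dates: Dict[str, List[date]] = {}
            for t in self.transfusions[h]:
                tx_dates.setdefault(t["patient_id"], []).append(t["transfusion_date"])
            eligible = []
            for r in self.hospitalizations[h]:
                if r["hospitalization_id"] in self.touched["hospitalizations"]:
                    continue
                covers = any(
                    r["admission_date"] <= d <= r["discharge_date"]
                    for d in tx_dates.get(r["patient_id"], ())
                )
                if not covers:
                    eligible.append(r)
            for r in self._draw(rng, eligible, rate):
                r["discharge_date"] = r["admission_date"] - timedelta(days=int(rng.integers(1, 6)))
                r["day_admission"] = False
                self.touched["hospitalizations"].add(r["hospitalization_id"])
                self.record("zero_length_violation", r["hospitalization_id"], h)

    def _inject_transfer_out(self, rng, rate) -> None:
        for h in self.hospital_ids:
            transfused = {t["patient_id"] for t in self.transfusions[h]}
            hosp_by_pt: Dict[str, List[dict]] = {}
            for r in self.hospitalizations[h]:
                hosp_by_pt.setdefault(r["patient_id"], []).append(r)
            eligible = [
                pt for pt in self.patients[h]
                if pt["patient_id"] in transfused
                and pt["patient_id"] not in self.touched["patients"]
                and any(
                    r["hospitalization_id"] not in self.touched["hospitalizations"]
                    for r in hosp_by_pt.get(pt["patient_id"], ())
                )
            ]
            for pt in self._draw(rng, eligible, rate):
                row = next(
                    r for r in hosp_by_pt[pt["patient_id"]]
                    if r["hospitalization_id"] not in self.touched["hospitalizations"]
                )
                row["discharge_destination"] = "other_hospital"
                self.touched["hospitalizations"].add(row["hospitalization_id"])
                self.touched["patients"].add(pt["patient_id"])
                self.record("transfer_out", pt["patient_id"], h)

    def _inject_outpatient_transfusion(self, rng, rate) -> None:
        for h in self.hospital_ids:
            tx_dates: Dict[str, List[Tuple[str, date]]] = {}
            for t in self.transfusions[h]:
                tx_dates.setdefault(t["patient_id"], []).append(
                    (t["transfusion_id"], t["transfusion_date"])
                )
            eligible = []
            for t in self.transfusions[h]:
                if t["transfusion_id"] in self.touched["transfusions"]:
                    continue
                covering = self._covering_hospitalizations(h, t["patient_id"], t["transfusion_date"])
                if len(covering) != 1:
                    continue
                hrow = covering[0]
                if hrow["hospitalization_id"] in self.touched["hospitalizations"]:
                    continue
                others = [
                    tid for tid, d in tx_dates[t["patient_id"]]
                    if tid != t["transfusion_id"]
                    and hrow["admission_date"] <= d
                    and (hrow["discharge_date"] is None or d <= hrow["discharge_date"])
                ]
                if not others:
                    eligible.append((t, hrow))
            for t, hrow in self._draw(rng, eligible, rate):
                self.hospitalizations[h].remove(hrow)
                self.touched["transfusions"].add(t["transfusion_id"])
                self.touched["hospitalizations"].add(hrow["hospitalization_id"])
                self.record("outpatient_transfusion", t["transfusion_id"], h)

    # -- assembly -----------------------------------------------------------

    def _frame(self, rows: List[dict], schema: Dict[str, str]) -> pd.DataFrame:
        from .warehouse import table_from_records

        return table_from_records(rows, schema)

    def build(self) -> Tuple[Warehouse, ErrorLedger]:
        prov = self.p.provenance()
        bank = Source(
            source_id="blood_bank",
            kind="blood_bank",
            tables={
                "donors": self._frame(
                    [{k: v for k, v in d.items() if k != "_pool"} for d in self.donors],
                    BLOOD_BANK_TABLES["donors"],
                ),
                "donations": self._frame(self.donations, BLOOD_BANK_TABLES["donations"]),
                "products": self._frame(self.products, BLOOD_BANK_TABLES["products"]),
            },
        )
        hospitals = {}
        for h in self.hospital_ids:
            hospitals[h] = Source(
                source_id=h,
                kind="hospital",
                tables={
                    "transfusions": self._frame(self.transfusions[h], HOSPITAL_TABLES["transfusions"]),
                    "patients": self._frame(self.patients[h], HOSPITAL_TABLES["patients"]),
                    "hospitalizations": self._frame(
                        self.hospitalizations[h], HOSPITAL_TABLES["hospitalizations"]
                    ),
                    "diagnoses": self._frame(self.diagnoses[h], HOSPITAL_TABLES["diagnoses"]),
                    "procedures": self._frame(self.procedures[h], HOSPITAL_TABLES["procedures"]),
                    "labs": self._frame(self.labs[h], HOSPITAL_TABLES["labs"]),
                },
            )
        reference = {
            "product_codes": pd.DataFrame(
                {
                    "code": [c for lst in PRODUCT_CODE_LISTS.values() for c in lst],
                    "description": [
                        f"{t} product {c}" for t, lst in PRODUCT_CODE_LISTS.items() for c in lst
                    ],
                }
            ),
            "diagnosis_codes": pd.DataFrame(
                {
                    "code": GENERIC_DX + BLEEDING_DX + GYN_DX,
                    "description": [f"diagnosis {c}" for c in GENERIC_DX + BLEEDING_DX + GYN_DX],
                    "bleeding_risk": [False] * len(GENERIC_DX)
                    + [True] * len(BLEEDING_DX)
                    + [False] * len(GYN_DX),
                    "gynecology": [False] * (len(GENERIC_DX) + len(BLEEDING_DX))
                    + [True] * len(GYN_DX),
                }
            ),
        }
        counts: Dict[Tuple[int, str], int] = {}
        for p in self.products:
            if p["issue_date"] is not None:
                key = (p["issue_date"].year, p["product_type"])
                counts[key] = counts.get(key, 0) + 1
        external = pd.DataFrame(
            [{"year": y, "product_type": t, "count": c} for (y, t), c in sorted(counts.items())],
            columns=list(EXTERNAL_SCHEMA),
        )
        external["year"] = external["year"].astype("Int64")
        external["count"] = external["count"].astype("Int64")
        prior = (
            self._frame(self.prior_products, BLOOD_BANK_TABLES["products"])
            if self.prior_products
            else None
        )
        w = Warehouse(
            blood_bank=bank,
            hospitals=hospitals,
            reference=reference,
            external_aggregates=external,
            prior_year_products=prior,
            thresholds=ThresholdConfig(),
            provenance=prov,
        )
        ledger = ErrorLedger(self.ledger_rows, self.remap_rows, prov)
        return w, ledger


def simulate(params: SimulationParams) -> Tuple[Warehouse, ErrorLedger]:
    """Generate a warehouse plus the ground truth of its injected errors."""
    sim = _Sim(params)
    sim.make_donors()
    sim.make_patients()
    sim.make_products()
    sim.make_hospitalizations()
    sim.make_diagnoses()
    sim.make_procedures()
    sim.make_labs()
    sim.apply_explained_decreases()
    sim.set_deaths()
    sim.inject_all()
    return sim.build()


# ---------------------------------------------------------------------------
# Ground-truth summary (brute force, independent of the validator modules)
# ---------------------------------------------------------------------------


def truth_summary(ledger: ErrorLedger, w: Warehouse) -> pd.DataFrame:
    """Expected violation counts per channel, by brute-force warehouse scan.

    Returns one row per channel (plus one per missing_field target) with the
    violation numerator and denominator the paired validator rule should
    find.  Raises :class:`ProvenanceError` when ledger and warehouse come
    from different simulate calls.
    """
    if ledger.provenance != w.provenance:
        raise ProvenanceError(
            f"ledger provenance {ledger.provenance!r} does not match warehouse {w.provenance!r}"
        )
    t = w.thresholds
    scan = bf.WarehouseScan(w)
    rows = []

    def add(channel, num, den, detail=""):
        rows.append(
            {
                "channel": channel,
                "detail": detail,
                "expected_numerator": int(num),
                "expected_denominator": int(den),
            }
        )

    add("duplicate_transfusion", *scan.duplicate_transfusions())
    add("duplicate_donation", *scan.duplicate_donations())
    add("duplicate_procedure", *scan.duplicate_procedures())
    for kind, table, fld in MISSING_FIELD_TARGETS:
        if table == "labs":
            for analyte in ("Hb", "thrombocytes"):
                num, den = scan.missing(kind, table, fld, analyte=analyte)
                add("missing_field", num, den, f"{table}.{fld}:{analyte}")
        else:
            num, den = scan.missing(kind, table, fld)
            add("missing_field", num, den, f"{table}.{fld}")
    add("broken_product_link", *scan.unlinked_transfusions())
    add("prior_year_issue", *scan.unlinked_transfusions(year=_first_year(scan)))
    add("spilled_product", *scan.spilled_products())
    add("unexplained_hb_decrease", *scan.unexplained_decreases(t))
    add("postdeath_event", *scan.postdeath_patients())
    add("gender_mismatch_gynecology", *scan.gynecology_gender_violations())
    add("overfrequent_donor", *scan.overfrequent_donor_years(t))
    add("out_of_age_donor", *scan.out_of_age_donations(t))
    add("code_not_in_reference", *scan.nonconformant_diagnoses())
    add("wrong_pool_cardinality", *scan.bad_pools(t))
    add("expired_at_transfusion", *scan.expired_transfusions())
    add("zero_length_violation", *scan.zero_length())
    add("transfer_out", *scan.transferred_patients())
    add("outpatient_transfusion", *scan.outpatient_transfusions())
    return pd.DataFrame(rows)


def _first_year(scan: "bf.WarehouseScan") -> int:
    years = [r["transfusion_date"].year for r in scan.all_transfusions if r["transfusion_date"] is not None]
    return min(years) if years else 0
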