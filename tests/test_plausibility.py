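"""Plausibility rule registry: Hb classification, limits, registry contract."""

from __future__ import annotations

import pytest
from conftest import TINY, build_warehouse, d

from transfuqc import SimulationParams, evaluate_rule, run_all_rules, simulate
from transfuqc.config import ThresholdConfig
from transfuqc.plausibility import catalogue, fix_postdeath


def _hb_warehouse(pre, post, bleeding=False):
    """One RBC transfusion with a pre/post Hb pair one day around it."""
    tdate = d(2010, 5, 10)
    labs = [
        {"lab_id": "L1", "patient_id": "P1", "analyte": "Hb",
         "measured_at": d(2010, 5, 9), "value": pre, "value_decimals": 1},
        {"lab_id": "L2", "patient_id": "P1", "analyte": "Hb",
         "measured_at": d(2010, 5, 11), "value": post, "value_decimals": 1},
    ]
    dx = []
    if bleeding:
        dx.append({"episode_id": "E1", "patient_id": "P1", "diagnosis_code": "BL001",
                   "start_date": d(2010, 5, 1), "end_date": d(2010, 5, 20)})
    tx = [{"transfusion_id": "T1", "patient_id": "P1", "donation_code": "B1",
           "product_code": "E0150", "product_type": "RBC", "transfusion_date": tdate}]
    return build_warehouse(hospitals={"hospital_a": {
        "transfusions": tx, "labs": labs, "diagnoses": dx,
        "patients": [{"patient_id": "P1", "birth_date": d(1950, 1, 1), "gender": "F"}],
    }})


def _p4_counts(w):
    res = evaluate_rule("P4", w)
    return next(r for r in res if r.source_id == "hospital_a").details


@pytest.mark.parametrize(
    "pre,post,expected",
    [
        (5.0, 5.0, "no_change"),       # delta 0% < 8.8%
        (5.0, 6.0, "increase"),        # +20%
        (5.0, 4.0, "decrease"),        # -20%
        (5.0, 5.4, "no_change"),       # +8.0% below threshold
    ],
)
def test_hb_classification(pre, post, expected):
    counts = _p4_counts(_hb_warehouse(pre, post))
    assert counts[expected] == 1
    assert counts["total_rbc"] == 1


def test_decrease_explained_by_bleeding_risk_diagnosis():
    counts = _p4_counts(_hb_warehouse(5.0, 4.0, bleeding=True))
    assert counts["decrease"] == 1
    assert counts["unexplained_decrease"] == 0
    assert counts["explained_decrease"] == 1


def test_missing_lab_makes_transfusion_unevaluable():
    w = _hb_warehouse(5.0, 4.0)
    labs = w.hospitals["hospital_a"].tables["labs"]
    w.hospitals["hospital_a"].tables["labs"] = labs.iloc[:1]
    counts = _p4_counts(w)
    assert counts["unevaluable"] == 1


def test_partition_and_threshold_monotonicity():
    """increase + decrease + no change + unevaluable partitions RBC
    transfusions, and a wider threshold never finds more clinical changes."""
    params = SimulationParams(
        seed=21, explained_decrease_rate=0.1,
        error_rates={"unexplained_hb_decrease": 0.1}, **TINY
    )
    w, _ = simulate(params)
    counts = {}
    for thr in (8.8, 20.0):
        w.thresholds = ThresholdConfig(hb_change_pct=thr)
        per_h = [r.details for r in evaluate_rule("P4", w) if r.source_id in w.hospitals]
        agg = {k: sum(c[k] for c in per_h) for k in per_h[0]}
        assert (
            agg["increase"] + agg["decrease"] + agg["no_change"] + agg["unevaluable"]
            == agg["total_rbc"]
        )
        counts[thr] = agg
    assert counts[20.0]["increase"] <= counts[8.8]["increase"]
    assert counts[20.0]["decrease"] <= counts[8.8]["decrease"]


def test_donation_frequency_limits():
    """A female donor with 4 whole-blood donations in a year violates the
    limit of 3; the same count is fine for a male donor."""
    def warehouse(gender):
        donors = [{"donor_id": "D1", "birth_date": d(1970, 1, 1), "gender": gender}]
        donations = [
            {"donation_id": f"N{i}", "donor_id": "D1", "donation_date": d(2010, 1 + 2 * i, 1),
             "donation_type": "whole_blood", "hb_value": 8.5, "hb_value_decimals": 1,
             "autologous": False}
            for i in range(4)
        ]
        return build_warehouse(bank={"donors": donors, "donations": donations})

    r_f = evaluate_rule("P2", warehouse("F"))[0]
    assert r_f.numerator == 1
    assert r_f.offending_ids == ["D1:2010:whole_blood"]
    assert evaluate_rule("P2", warehouse("M"))[0].numerator == 0


def test_donor_age_exempts_autologous():
    donors = [{"donor_id": "D1", "birth_date": d(1930, 1, 1), "gender": "M"}]
    donations = [
        {"donation_id": "N1", "donor_id": "D1", "donation_date": d(2010, 6, 1),
         "donation_type": "whole_blood", "hb_value": 8.5, "hb_value_decimals": 1,
         "autologous": auto}
        for auto in (True, False)
    ]
    donations[1]["donation_id"] = "N2"
    r = evaluate_rule("P3", build_warehouse(bank={"donors": donors, "donations": donations}))[0]
    assert (r.numerator, r.denominator) == (1, 1)  # the autologous one is exempt
    assert r.details["autologous_exempt"] == 1


def test_pool_cardinality_violation():
    donors = [{"donor_id": f"D{i}", "birth_date": d(1970, 1, 1), "gender": "M"} for i in range(4)]
    donations = [
        {"donation_id": f"N{i}", "donor_id": f"D{i}", "donation_date": d(2010, 1, 2),
         "donation_type": "whole_blood", "hb_value": 8.5, "hb_value_decimals": 1,
         "autologous": False}
        for i in range(4)
    ]
    products = [{"product_id": "B1", "product_code": "E2971", "product_type": "PLT",
                 "donation_ids": tuple(f"N{i}" for i in range(4)),
                 "production_date": d(2010, 1, 5), "expiration_date": d(2010, 1, 12),
                 "issue_date": d(2010, 1, 6), "pooling_date": d(2010, 1, 5)}]
    w = build_warehouse(bank={"donors": donors, "donations": donations, "products": products})
    r = evaluate_rule("E1", w)[0]
    assert r.numerator == 1  # 4 unique donors not in {5, 6}
    assert r.offending_ids == ["B1"]


def test_postdeath_detection_and_remediation():
    tx = [{"transfusion_id": "T1", "patient_id": "P1", "donation_code": "B1",
           "product_code": "E0150", "product_type": "RBC", "transfusion_date": d(2010, 6, 1)}]
    patients = [{"patient_id": "P1", "birth_date": d(1950, 1, 1), "gender": "F",
                 "death_date": d(2010, 5, 1)}]
    w = build_warehouse(hospitals={"hospital_a": {"transfusions": tx, "patients": patients}})
    r = next(r for r in evaluate_rule("P8", w) if r.source_id == "hospital_a")
    assert r.offending_ids == ["P1"]
    w2, n = fix_postdeath(w)
    assert n == 1
    assert w2.hospitals["hospital_a"].table("patients")["death_date"].isna().all()
    r2 = next(r for r in evaluate_rule("P8", w2) if r.source_id == "hospital_a")
    assert r2.numerator == 0


def test_unknown_rule_rejected(clean_tiny):
    w, _ = clean_tiny
    with pytest.raises(KeyError, match="unknown rule_id"):
        evaluate_rule("P99", w)


def test_missing_lab_table_isolates_p4_only(clean_tiny):
    """Without labs P4 is not evaluable; every other rule still runs."""
    w, _ = clean_tiny
    w = w.copy()
    for hid in w.hospitals:
        w.hospitals[hid].tables["labs"] = None
    results = run_all_rules(w)
    by_rule = {}
    for r in results:
        by_rule.setdefault(r.rule_id, []).append(r)
    assert all(not r.evaluable for r in by_rule["P4"])
    for rid in ("P1", "P2", "P3", "P5", "P7", "P8", "P9", "E1", "E2"):
        assert any(r.evaluable for r in by_rule[rid]), rid


def test_catalogue_lists_all_rules():
    cat = catalogue()
    assert set(cat["rule_id"]) == {
        "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9", "P10", "E1", "E2"
    }
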