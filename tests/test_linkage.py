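"""Linkage semantics on small hand-built warehouses."""

from __future__ import annotations

import pandas as pd
import pytest
from conftest import build_warehouse, d

from transfuqc import (
    apply_id_remap,
    link_products_to_transfusions,
    link_transfusions_to_hospitalizations,
    link_transfusions_to_products,
)


def product(pid, ptype="RBC", code="E0150", **kw):
    row = {
        "product_id": pid,
        "product_code": code,
        "product_type": ptype,
        "donation_ids": ("N1",),
        "production_date": d(2010, 1, 1),
        "expiration_date": d(2010, 3, 1),
        "issue_date": d(2010, 1, 10),
    }
    row.update(kw)
    return row


def tx(tid, code, ptype="RBC", pcode="E0150", patient="P1", when=d(2010, 1, 12)):
    return {
        "transfusion_id": tid,
        "patient_id": patient,
        "donation_code": code,
        "product_code": pcode,
        "product_type": ptype,
        "transfusion_date": when,
    }


def test_two_of_three_transfusions_resolve():
    w = build_warehouse(
        bank={"products": [product("B1"), product("B2")]},
        hospitals={"hospital_a": {"transfusions": [tx("T1", "B1"), tx("T2", "B2"), tx("T3", "B9")]}},
    )
    results, link_map = link_transfusions_to_products(w)
    r = results[0]
    assert (r.numerator, r.denominator) == (2, 3)
    assert r.percentage == 66.67
    assert r.offending_ids == ["T3"]
    assert set(link_map["transfusion_id"]) == {"T1", "T2"}


def test_all_resolvable_is_hundred_with_empty_offenders():
    w = build_warehouse(
        bank={"products": [product("B1")]},
        hospitals={"hospital_a": {"transfusions": [tx("T1", "B1")]}},
    )
    results, _ = link_transfusions_to_products(w)
    assert results[0].percentage == 100.0
    assert results[0].offending_ids == []


def test_ambiguous_match_counts_as_not_linked():
    """Two products sharing key and type: identity problem, not a link."""
    w = build_warehouse(
        bank={"products": [product("B1"), product("B1")]},
        hospitals={"hospital_a": {"transfusions": [tx("T1", "B1")]}},
    )
    results, link_map = link_transfusions_to_products(w)
    assert results[0].numerator == 0
    assert results[0].details["ambiguous"] == 1
    assert len(link_map) == 0


def test_null_product_code_falls_back_to_type():
    w = build_warehouse(
        bank={"products": [product("B1", code=None)]},
        hospitals={"hospital_a": {"transfusions": [tx("T1", "B1", pcode="E9999")]}},
    )
    results, _ = link_transfusions_to_products(w)
    assert results[0].numerator == 1


def test_spilling_rate_reported():
    products = [product(f"B{i}") for i in range(1, 11)]
    transfusions = [tx(f"T{i}", f"B{i}") for i in range(1, 10)]  # B10 never transfused
    w = build_warehouse(bank={"products": products},
                        hospitals={"hospital_a": {"transfusions": transfusions}})
    r = link_products_to_transfusions(w)[0]
    assert (r.numerator, r.denominator) == (9, 10)
    assert r.details["spilling_rate_pct"] == 10.0
    assert r.offending_ids == ["B10"]


def test_no_products_not_evaluable():
    w = build_warehouse(hospitals={"hospital_a": {"transfusions": [tx("T1", "B1")]}})
    r = link_products_to_transfusions(w)[0]
    assert not r.evaluable
    assert r.percentage is None


def test_hospitalization_interval_is_closed():
    hosp = [{
        "hospitalization_id": "A1", "patient_id": "P1",
        "admission_date": d(2010, 1, 12), "discharge_date": d(2010, 1, 20),
        "day_admission": False, "discharge_destination": "home",
    }]
    w = build_warehouse(hospitals={"hospital_a": {
        "transfusions": [
            tx("T1", "B1", when=d(2010, 1, 12)),   # admission day -> linked
            tx("T2", "B1", when=d(2010, 1, 20)),   # discharge day -> linked
            tx("T3", "B1", when=d(2010, 1, 21)),   # day after discharge -> not
        ],
        "hospitalizations": hosp,
    }})
    r = link_transfusions_to_hospitalizations(w)[0]
    assert (r.numerator, r.denominator) == (2, 3)
    assert r.offending_ids == ["T3"]


def test_open_discharge_counts_as_still_admitted():
    hosp = [{
        "hospitalization_id": "A1", "patient_id": "P1",
        "admission_date": d(2010, 1, 1), "discharge_date": None,
        "day_admission": False, "discharge_destination": "unknown",
    }]
    w = build_warehouse(hospitals={"hospital_a": {
        "transfusions": [tx("T1", "B1", when=d(2012, 6, 1))],
        "hospitalizations": hosp,
    }})
    assert link_transfusions_to_hospitalizations(w)[0].numerator == 1


def test_empty_remap_is_identity(clean_tiny):
    w, _ = clean_tiny
    w2 = apply_id_remap(w, pd.DataFrame({"old_id": [], "new_id": []}))
    for hid in w.hospitals:
        pd.testing.assert_frame_equal(
            w.hospitals[hid].table("transfusions"), w2.hospitals[hid].table("transfusions")
        )


def test_non_injective_remap_rejected():
    w = build_warehouse()
    with pytest.raises(ValueError, match="injective"):
        apply_id_remap(w, pd.DataFrame({"old_id": ["a", "b"], "new_id": ["c", "c"]}))


def test_remap_unknown_ids_ignored_and_logged():
    w = build_warehouse(
        bank={"products": [product("B1")]},
        hospitals={"hospital_a": {"transfusions": [tx("T1", "X-B1")]}},
    )
    remap = pd.DataFrame({"old_id": ["X-B1", "X-NOPE"], "new_id": ["B1", "B2"]})
    w2 = apply_id_remap(w, remap)
    results, _ = link_transfusions_to_products(w2)
    assert results[0].numerator == 1
    assert any(i.raw == "X-NOPE" for i in w2.load_log)


def test_prior_extract_never_decreases_linkage(messy_tiny):
    """Monotonicity: supplementing the product extract can only help."""
    _, (w, _ledger) = messy_tiny
    base, _ = link_transfusions_to_products(w)
    if w.prior_year_products is None:
        pytest.skip("no prior-year products at this seed")
    extended, _ = link_transfusions_to_products(w, prior=w.prior_year_products)
    assert extended[-1].numerator >= base[-1].numerator
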