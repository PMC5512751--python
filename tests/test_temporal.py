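"""Time-pattern checks: yearly series and boundary-artifact diagnosis."""

from __future__ import annotations

import pandas as pd
from conftest import build_warehouse, d

from transfuqc import yearly_counts, yearly_linkage


def donation(n, when):
    return {"donation_id": f"N{n}", "donor_id": f"D{n % 5}", "donation_date": when,
            "donation_type": "whole_blood", "hb_value": 8.5, "hb_value_decimals": 1,
            "autologous": False}


def test_halved_volume_year_flagged():
    rows = [donation(i, d(2010, 3, 1)) for i in range(10)]
    rows += [donation(100 + i, d(2011, 3, 1)) for i in range(5)]
    w = build_warehouse(bank={"donations": rows})
    table, result = yearly_counts(w)
    assert table.loc[2010, "donations"] == 10
    assert table.loc[2011, "donations"] == 5
    assert any(f.startswith("donations:2010") for f in result.offending_ids)


def test_stationary_volumes_unflagged(clean_tiny):
    w, _ = clean_tiny
    _, result = yearly_counts(w)
    assert result.numerator == 0


def test_null_dates_excluded_and_tallied():
    rows = [donation(1, d(2010, 1, 1)), donation(2, None)]
    w = build_warehouse(bank={"donations": rows})
    table, result = yearly_counts(w)
    assert table["donations"].sum() == 1
    assert result.details["null_dates"]["donations"] == 1


def test_yearly_transfusion_counts_sum_to_total(messy_tiny):
    _, (w, _ledger) = messy_tiny
    table, _ = yearly_counts(w)
    total = sum(len(w.hospitals[h].table("transfusions")) for h in w.hospitals)
    nulls = sum(
        int(w.hospitals[h].table("transfusions")["transfusion_date"].isna().sum())
        for h in w.hospitals
    )
    assert table["transfusions"].sum() + nulls == total


def test_single_year_warehouse_one_row():
    tx = [{"transfusion_id": "T1", "patient_id": "P1", "donation_code": "B1",
           "product_code": "E0150", "product_type": "RBC", "transfusion_date": d(2012, 5, 1)}]
    prod = [{"product_id": "B1", "product_code": "E0150", "product_type": "RBC",
             "donation_ids": ("N1",), "production_date": d(2012, 4, 1),
             "expiration_date": d(2012, 6, 1), "issue_date": d(2012, 4, 20)}]
    w = build_warehouse(bank={"products": prod}, hospitals={"hospital_a": {"transfusions": tx}})
    table, result = yearly_linkage(w)
    assert list(table.index) == [2012]
    assert result.percentage == 100.0


def test_unlinked_share_matching_prior_extract_reported():
    """First-year deficit is attributed to the pre-window product extract."""
    tx = [{"transfusion_id": "T1", "patient_id": "P1", "donation_code": "B1",
           "product_code": "E0150", "product_type": "RBC", "transfusion_date": d(2010, 1, 20)}]
    prior = [{"product_id": "B1", "product_code": "E0150", "product_type": "RBC",
              "donation_ids": ("N1",), "production_date": d(2009, 12, 10),
              "expiration_date": d(2010, 1, 30), "issue_date": d(2009, 12, 20)}]
    w = build_warehouse(hospitals={"hospital_a": {"transfusions": tx}})
    from transfuqc.warehouse import BLOOD_BANK_TABLES, table_from_records

    w.prior_year_products = table_from_records(prior, BLOOD_BANK_TABLES["products"])
    table, _ = yearly_linkage(w)
    assert table.loc[2010, "percentage"] == 0.0
    assert table.loc[2010, "unlinked_matching_prior_extract"] == 1
    # supplying the extract repairs the year
    table2, result2 = yearly_linkage(w, prior=w.prior_year_products)
    assert table2.loc[2010, "percentage"] == 100.0
    assert result2.percentage == 100.0
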