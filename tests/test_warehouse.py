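"""Warehouse model: CSV round trip, parse logging, config errors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import yaml

from transfuqc import ConfigurationError, load_warehouse, write_warehouse
from transfuqc.warehouse import BLOOD_BANK_TABLES, load_table


def _assert_tables_equal(a, b, context):
    assert (a is None) == (b is None), context
    if a is None:
        return
    assert list(a.columns) == list(b.columns), context
    assert len(a) == len(b), context
    for col in a.columns:
        left, right = a[col], b[col]
        for i, (x, y) in enumerate(zip(left, right)):
            x_null = x is None or (not isinstance(x, (tuple, list)) and pd.isna(x))
            y_null = y is None or (not isinstance(y, (tuple, list)) and pd.isna(y))
            assert x_null == y_null, f"{context}.{col}[{i}]: {x!r} vs {y!r}"
            if not x_null:
                assert x == y, f"{context}.{col}[{i}]: {x!r} vs {y!r}"


def assert_warehouse_equal(w1, w2):
    for name in w1.blood_bank.tables:
        _assert_tables_equal(w1.blood_bank.tables[name], w2.blood_bank.tables[name], name)
    assert set(w1.hospitals) == set(w2.hospitals)
    for hid in w1.hospitals:
        for name in w1.hospitals[hid].tables:
            _assert_tables_equal(
                w1.hospitals[hid].tables[name], w2.hospitals[hid].tables[name], f"{hid}/{name}"
            )


def test_round_trip_identity_on_messy_simulation(tmp_path, messy_tiny):
    """load(write(w)) preserves every non-null cell, null cells stay null."""
    _, (w, _ledger) = messy_tiny
    cfg = write_warehouse(w, tmp_path / "wh")
    reloaded = load_warehouse(cfg)
    assert_warehouse_equal(w, reloaded)
    assert reloaded.external_aggregates is not None
    assert reloaded.provenance == w.provenance


def test_round_trip_empty_warehouse(tmp_path):
    from conftest import build_warehouse

    w = build_warehouse()
    cfg = write_warehouse(w, tmp_path / "empty")
    reloaded = load_warehouse(cfg)
    assert len(reloaded.blood_bank.table("donors")) == 0
    assert_warehouse_equal(w, reloaded)


def test_unparseable_cells_become_nulls_and_are_logged(tmp_path):
    """Bad dates never drop rows; they null out and land in the load log."""
    path = tmp_path / "donations.csv"
    path.write_text(
        "donation_id,donor_id,donation_date,donation_type,hb_value,autologous\n"
        "N1,D1,2010-13-40,whole_blood,8.1,false\n"
        "N2,D1,2010-02-03,whole_blood,not-a-number,maybe\n",
        encoding="utf-8",
    )
    issues = []
    df = load_table(path, BLOOD_BANK_TABLES["donations"], "bb", "donations", issues)
    assert len(df) == 2
    assert pd.isna(df.loc[0, "donation_date"])
    assert df.loc[1, "donation_date"] == pd.Timestamp("2010-02-03")
    assert np.isnan(df.loc[1, "hb_value"])
    assert pd.isna(df.loc[1, "autologous"])
    problems = {(i.column, i.problem) for i in issues}
    assert ("donation_date", "bad date") in problems
    assert ("hb_value", "bad number") in problems
    assert ("autologous", "bad boolean") in problems


def test_lexical_precision_preserved(tmp_path):
    path = tmp_path / "labs.csv"
    path.write_text(
        "lab_id,patient_id,analyte,measured_at,value\n"
        "L1,P1,Hb,2010-01-01,8.1\nL2,P1,Hb,2010-01-02,8\nL3,P1,Hb,2010-01-03,8.25\n",
        encoding="utf-8",
    )
    from transfuqc.warehouse import HOSPITAL_TABLES

    df = load_table(path, HOSPITAL_TABLES["labs"], "h", "labs", [])
    assert df["value_decimals"].tolist() == [1, 0, 2]


def test_missing_mandatory_table_names_table(tmp_path, clean_tiny):
    w, _ = clean_tiny
    cfg_path = write_warehouse(w, tmp_path / "wh")
    (tmp_path / "wh" / "blood_bank" / "donations.csv").unlink()
    with pytest.raises(ConfigurationError, match="donations"):
        load_warehouse(cfg_path)


def test_duplicate_column_mapping_rejected(tmp_path, clean_tiny):
    w, _ = clean_tiny
    cfg_path = write_warehouse(w, tmp_path / "wh")
    cfg = yaml.safe_load(cfg_path.read_text())
    cfg["column_mapping"] = {"donors": {"donor_id": "id", "gender": "id"}}
    cfg_path.write_text(yaml.safe_dump(cfg))
    with pytest.raises(ConfigurationError, match="duplicate column mapping"):
        load_warehouse(cfg_path)


def test_column_mapping_renames_headers(tmp_path):
    path = tmp_path / "donors.csv"
    path.write_text("id,dob,sex\nD1,1960-01-01,F\n", encoding="utf-8")
    df = load_table(
        path,
        BLOOD_BANK_TABLES["donors"],
        "bb",
        "donors",
        [],
        mapping={"donor_id": "id", "birth_date": "dob", "gender": "sex"},
    )
    assert df.loc[0, "donor_id"] == "D1"
    assert df.loc[0, "gender"] == "F"


def test_declared_absent_table_reports_not_evaluable(tmp_path, clean_tiny):
    """A declared-absent procedures table makes dependent checks n/e, not fatal."""
    from transfuqc import validate_warehouse

    w, _ = clean_tiny
    cfg_path = write_warehouse(w, tmp_path / "wh")
    cfg = yaml.safe_load(cfg_path.read_text())
    for src in cfg["sources"]:
        if src["kind"] == "hospital":
            src["tables"].pop("procedures")
            src.setdefault("absent", []).append("procedures")
    cfg_path.write_text(yaml.safe_dump(cfg))
    w2 = load_warehouse(cfg_path)
    assert w2.hospitals["hospital_1"].table("procedures") is None
    report = validate_warehouse(w2)
    for hid in w2.hospitals:
        assert not report.get("I3", hid).evaluable
    # rules not touching procedures still run
    assert report.get("L1").evaluable


def test_loaded_dates_are_date_or_null(clean_tiny, tmp_path):
    w, _ = clean_tiny
    cfg = write_warehouse(w, tmp_path / "wh")
    reloaded = load_warehouse(cfg)
    don = reloaded.blood_bank.table("donations")
    assert str(don["donation_date"].dtype).startswith("datetime64")
    assert (don["donation_date"].dt.normalize() == don["donation_date"]).all()
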