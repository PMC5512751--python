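"""Identity, completeness and uniformity checks."""

from __future__ import annotations

import pandas as pd
import pytest
from conftest import build_warehouse, d
from hypothesis import given, settings
from hypothesis import strategies as st

from transfuqc import code_conformance, duplicate_rate, field_completeness
from transfuqc.integrity import FieldSpec, deduplicate, precision_uniformity
from transfuqc.warehouse import HOSPITAL_TABLES, table_from_records


def proc(pid, code, when, rid):
    return {"procedure_id": rid, "patient_id": pid, "procedure_code": code,
            "procedure_date": when}


def _proc_table(rows):
    return table_from_records(rows, HOSPITAL_TABLES["procedures"])


@pytest.mark.parametrize(
    "rows,expected_num,expected_den,expected_pct",
    [
        # one identical pair among 10
        ([proc("P1", "C1", d(2010, 1, 1), f"R{i}") for i in range(2)]
         + [proc(f"P{i}", "C2", d(2010, 1, i), f"Q{i}") for i in range(2, 10)], 1, 10, 10.0),
        # all distinct
        ([proc(f"P{i}", "C1", d(2010, 1, 1 + i), f"R{i}") for i in range(5)], 0, 5, 0.0),
        # a triplicate among 100 contributes 2
        ([proc("P1", "C1", d(2010, 1, 1), f"R{i}") for i in range(3)]
         + [proc(f"P{i}", "C9", d(2010, 2, 1), f"Q{i}") for i in range(97)], 2, 100, 2.0),
    ],
)
def test_duplicate_rate_counts_beyond_first(rows, expected_num, expected_den, expected_pct):
    r = duplicate_rate(_proc_table(rows), ["patient_id", "procedure_code", "procedure_date"],
                       "I3", "h", "procedure_id")
    assert (r.numerator, r.denominator) == (expected_num, expected_den)
    assert r.percentage == expected_pct


def test_duplicate_rate_empty_key_rejected():
    with pytest.raises(ValueError, match="empty"):
        duplicate_rate(_proc_table([]), [], "I3", "h", "procedure_id")


def test_null_keys_excluded_from_grouping():
    rows = [proc("P1", "C1", None, "R1"), proc("P1", "C1", None, "R2")]
    r = duplicate_rate(_proc_table(rows), ["patient_id", "procedure_code", "procedure_date"],
                       "I3", "h", "procedure_id")
    assert r.numerator == 0
    assert "2 records with null key" in r.notes


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.sampled_from("ABC"), st.integers(0, 3)), max_size=30))
def test_duplicate_numerator_matches_brute_force(pairs):
    """Group-count oracle: duplicates == sum over groups of (size - 1)."""
    from collections import Counter

    rows = [proc(p, c if isinstance(c, str) else f"C{c}", d(2010, 1, 1), f"R{i}")
            for i, (p, c) in enumerate(pairs)]
    r = duplicate_rate(_proc_table(rows), ["patient_id", "procedure_code"],
                       "I3", "h", "procedure_id")
    counts = Counter((p, f"C{c}") for p, c in pairs)
    assert r.numerator == sum(v - 1 for v in counts.values() if v > 1)


def test_procedure_dedup_keeps_one_representative():
    rows = [proc("P1", "C1", d(2010, 1, 1), "R1"), proc("P1", "C1", d(2010, 1, 1), "R2"),
            proc("P2", "C1", d(2010, 1, 2), "R3")]
    w = build_warehouse(hospitals={"hospital_a": {"procedures": rows}})
    results, w2 = deduplicate(w)
    kept = w2.hospitals["hospital_a"].table("procedures")
    assert len(kept) == 2
    i3 = [r for r in results if r.rule_id == "I3" and r.source_id == "hospital_a"][0]
    assert i3.numerator == 1  # reported before removal


def test_field_completeness_and_summary():
    """Fields at {100%, 96%, 80%} with a 95% cutoff summarize to 66.67%."""
    patients = [
        {"patient_id": f"P{i}",
         "birth_date": d(1960, 1, 1) if i != 0 else None,    # 24/25 = 96%
         "gender": "F" if i < 20 else None}                   # 20/25 = 80%
        for i in range(25)
    ]
    w = build_warehouse(hospitals={"hospital_a": {"patients": patients}})
    fields = (
        FieldSpec("hospital", "patients", "patient_id"),
        FieldSpec("hospital", "patients", "birth_date"),
        FieldSpec("hospital", "patients", "gender"),
    )
    results = field_completeness(w, fields)
    by_rule = {r.rule_id: r for r in results if r.source_id == "pooled"}
    assert by_rule["K1[patients.patient_id]"].percentage == 100.0
    assert by_rule["K1[patients.birth_date]"].percentage == 96.0
    assert by_rule["K1[patients.gender]"].percentage == 80.0
    assert by_rule["K2"].percentage == 66.67


def test_simple_completeness_ratio():
    patients = [{"patient_id": f"P{i}", "birth_date": d(1960, 1, 1) if i else None,
                 "gender": "F"} for i in range(4)]
    w = build_warehouse(hospitals={"hospital_a": {"patients": patients}})
    results = field_completeness(w, (FieldSpec("hospital", "patients", "birth_date"),))
    assert results[0].percentage == 75.0


def test_unknown_completeness_field_rejected(clean_tiny):
    w, _ = clean_tiny
    with pytest.raises(ValueError, match="unknown field"):
        field_completeness(w, (FieldSpec("hospital", "patients", "no_such_column"),))


def test_code_conformance_examples():
    ref = pd.Series([f"C{i}" for i in range(10)])
    codes = pd.Series([f"C{i % 10}" for i in range(96)] + ["ZZ1", "ZZ2", "ZZ3", "ZZ4"])
    r = code_conformance(codes, ref, "U2", "h")
    assert r.percentage == 96.0
    assert set(r.offending_ids) == {"ZZ1", "ZZ2", "ZZ3", "ZZ4"}


def test_code_conformance_normalizes_whitespace_and_case():
    r = code_conformance(pd.Series(["c1 ", " C2"]), pd.Series(["C1", "c2"]), "U2", "h")
    assert r.percentage == 100.0


def test_code_conformance_nulls_are_missing_not_nonconformant():
    r = code_conformance(pd.Series(["C1", None, None]), pd.Series(["C1"]), "U2", "h")
    assert (r.numerator, r.denominator) == (1, 1)
    assert "2 null codes" in r.notes


def test_code_conformance_empty_reference_rejected():
    with pytest.raises(ValueError, match="empty reference"):
        code_conformance(pd.Series(["C1"]), pd.Series([], dtype=object), "U2", "h")


@settings(max_examples=25, deadline=None)
@given(st.lists(st.text(alphabet="abcXYZ123", min_size=1, max_size=5), min_size=1, max_size=20))
def test_conformance_identity_property(codes):
    """Any code column is 100% conformant against a reference containing it."""
    r = code_conformance(pd.Series(codes), pd.Series(codes), "U2", "h")
    assert r.percentage == 100.0


def test_precision_modal_majority():
    """Values 8.1, 7.9, 8.12 -> modal precision 1 decimal, 66.67%."""
    labs = [
        {"lab_id": f"L{i}", "patient_id": "P1", "analyte": "Hb",
         "measured_at": d(2010, 1, 1 + i), "value": v, "value_decimals": dec}
        for i, (v, dec) in enumerate([(8.1, 1), (7.9, 1), (8.12, 2)])
    ]
    w = build_warehouse(hospitals={"hospital_a": {"labs": labs}})
    r = precision_uniformity(w, "Hb")[0]
    assert r.percentage == 66.67
    assert r.details["modal_decimals"] == 1


def test_precision_tie_breaks_to_fewer_decimals():
    labs = [
        {"lab_id": f"L{i}", "patient_id": "P1", "analyte": "Hb",
         "measured_at": d(2010, 1, 1 + i), "value": v, "value_decimals": dec}
        for i, (v, dec) in enumerate([(8.0, 0), (8.12, 2)])
    ]
    w = build_warehouse(hospitals={"hospital_a": {"labs": labs}})
    r = precision_uniformity(w, "Hb")[0]
    assert r.details["modal_decimals"] == 0
    assert r.percentage == 50.0


def test_precision_pools_blood_bank_hb(clean_tiny):
    w, _ = clean_tiny
    r = precision_uniformity(w, "Hb")[0]
    assert "blood_bank" in r.details["per_source_pct"]
    assert r.percentage == 100.0
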