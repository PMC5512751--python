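"""External agreement formula and cross-report comparison."""

from __future__ import annotations

import pytest
from conftest import build_warehouse, d

from transfuqc import aggregate_outcomes, compare_outcomes, report_agreement
from transfuqc.results import RuleResult, ValidityReport


def _products(counts):
    rows = []
    i = 0
    for ptype, n in counts.items():
        for _ in range(n):
            i += 1
            rows.append({"product_id": f"B{i}", "product_code": "E0150",
                         "product_type": ptype, "donation_ids": ("N1",),
                         "production_date": d(2010, 1, 1), "expiration_date": d(2010, 2, 1),
                         "issue_date": d(2010, 1, 5)})
    return rows


def _agreement(dwh_counts, ext_counts):
    external = [{"year": 2010, "product_type": t, "count": c} for t, c in ext_counts.items()]
    w = build_warehouse(bank={"products": _products(dwh_counts)}, external=external)
    return report_agreement(w)[0]


def test_agreement_formula_hand_computed():
    """|100-98| + |50-51| = 3 over 149 warehouse products -> 97.99%."""
    r = _agreement({"RBC": 98, "PLT": 51}, {"RBC": 100, "PLT": 50})
    assert r.percentage == 97.99
    assert (r.numerator, r.denominator) == (146, 149)


def test_agreement_identity_case():
    r = _agreement({"RBC": 100, "PLT": 50}, {"RBC": 100, "PLT": 50})
    assert r.percentage == 100.0


def test_agreement_symmetric_in_discrepancy_sign():
    assert _agreement({"RBC": 98}, {"RBC": 100}).details["raw_overall_pct"] == pytest.approx(
        _agreement({"RBC": 102}, {"RBC": 100}).details["raw_overall_pct"], abs=0.1
    )


def test_agreement_missing_type_not_evaluable_cell():
    r = _agreement({"RBC": 100, "FFP": 10}, {"RBC": 100})
    assert r.details["per_type"]["FFP"] is None
    assert r.details["per_type"]["RBC"]["agreement_pct"] == 100.0
    assert "FFP" in r.notes


def test_agreement_clamped_at_zero_with_raw_in_details():
    r = _agreement({"RBC": 10}, {"RBC": 100})
    assert r.percentage == 0.0
    assert r.details["raw_overall_pct"] == -800.0


def test_no_external_aggregates_not_evaluable():
    w = build_warehouse(bank={"products": _products({"RBC": 5})})
    r = report_agreement(w)[0]
    assert not r.evaluable


def _report(label, pairs):
    rows = [
        RuleResult(rule_id=rid, step=2, concept="linkage", source_id=label,
                   numerator=n, denominator=dn)
        for rid, n, dn in pairs
    ]
    return ValidityReport(rows=rows, label=label)


def test_compare_identical_reports_no_flags():
    a = _report("A", [("L1", 99, 100), ("I1", 0, 100)])
    b = _report("B", [("L1", 99, 100), ("I1", 0, 100)])
    table = compare_outcomes([a, b])
    assert not table["flagged"].any()
    assert (table["max_abs_diff_pp"] == 0).all()


def test_compare_flags_large_difference():
    a = _report("A", [("L1", 999, 1000)])
    b = _report("B", [("L1", 930, 1000)])
    table = compare_outcomes([a, b], flag_pct=5.0)
    assert table.loc[0, "max_abs_diff_pp"] == 6.9
    assert bool(table.loc[0, "flagged"])


def test_compare_permutation_invariant():
    a = _report("A", [("L1", 90, 100), ("L2", 80, 100)])
    b = _report("B", [("L1", 95, 100), ("L2", 70, 100)])
    t1 = compare_outcomes([a, b]).set_index("rule_id")["max_abs_diff_pp"]
    t2 = compare_outcomes([b, a]).set_index("rule_id")["max_abs_diff_pp"]
    assert t1.equals(t2)


def test_compare_disjoint_rules_listed_not_compared():
    a = _report("A", [("L1", 90, 100)])
    b = _report("B", [("L9", 95, 100)])
    table = compare_outcomes([a, b]).set_index("rule_id")
    assert not table.loc["L1", "shared"]
    assert table.loc["L1", "max_abs_diff_pp"] is None or table["max_abs_diff_pp"].isna().all()


def test_compare_requires_two_reports():
    with pytest.raises(ValueError):
        compare_outcomes([_report("A", [("L1", 1, 2)])])


def test_aggregate_pooled_and_mean():
    """(9/10, 90/100): pooled 90.0 and mean 90.0; (1/2, 99/100): pooled
    98.04 but mean 74.5 - the divergence is why both are reported."""
    a = _report("A", [("L1", 9, 10), ("L2", 1, 2)])
    b = _report("B", [("L1", 90, 100), ("L2", 99, 100)])
    agg = aggregate_outcomes([a, b])
    l1 = agg.get("L1")
    assert l1.percentage == 90.0
    assert l1.details["mean_pct"] == 90.0
    l2 = agg.get("L2")
    assert l2.percentage == 98.04
    assert l2.details["mean_pct"] == 74.5


def test_aggregate_single_report_is_identity():
    a = _report("A", [("L1", 9, 10)])
    agg = aggregate_outcomes([a])
    assert agg.get("L1").percentage == 90.0
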