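"""Generator properties: determinism, clean backbone, ground-truth ledger."""

from __future__ import annotations

import pandas as pd
import pytest
from conftest import TINY

from transfuqc import (
    CHANNELS,
    ProvenanceError,
    SimulationParams,
    simulate,
    truth_summary,
    validate_warehouse,
)


def test_seed_determinism(messy_tiny):
    params, (w1, l1) = messy_tiny
    w2, l2 = simulate(params)
    pd.testing.assert_frame_equal(l1.frame, l2.frame)
    pd.testing.assert_frame_equal(l1.remap, l2.remap)
    for name, df in w1.blood_bank.tables.items():
        pd.testing.assert_frame_equal(df, w2.blood_bank.tables[name])
    for hid in w1.hospitals:
        for name, df in w1.hospitals[hid].tables.items():
            pd.testing.assert_frame_equal(df, w2.hospitals[hid].tables[name])


def test_different_seeds_differ():
    w1, _ = simulate(SimulationParams(seed=1, **TINY))
    w2, _ = simulate(SimulationParams(seed=2, **TINY))
    assert not w1.blood_bank.table("donations")["donation_date"].equals(
        w2.blood_bank.table("donations")["donation_date"]
    )


def test_clean_backbone_ledger_empty_and_truth_zero(clean_tiny):
    w, ledger = clean_tiny
    assert len(ledger.frame) == 0
    truth = truth_summary(ledger, w)
    assert (truth["expected_numerator"] == 0).all()
    assert set(truth["channel"]) == set(CHANNELS)


def test_clean_backbone_every_rule_perfect(clean_tiny):
    w, _ = clean_tiny
    report = validate_warehouse(w)
    imperfect = [r.rule_id for r in report.rows if not r.is_perfect()]
    assert imperfect == []


def test_every_channel_appears_in_ledger(messy_tiny):
    _, (w, ledger) = messy_tiny
    assert set(ledger.frame["channel"]) == set(CHANNELS)
    # every injected error appears exactly once
    assert not ledger.frame.duplicated(["channel", "record_id", "detail"]).any()


def test_provenance_mismatch_rejected(clean_tiny):
    w, _ = clean_tiny
    _, foreign_ledger = simulate(SimulationParams(seed=77, **TINY))
    with pytest.raises(ProvenanceError):
        truth_summary(foreign_ledger, w)


def test_infeasible_volumes_raise():
    with pytest.raises(ValueError, match="infeasible"):
        SimulationParams(
            n_donors=10, products_per_year={"RBC": 5000, "FFP": 10, "PLT": 10}
        ).check_feasible()


@pytest.mark.parametrize(
    "rates", [{"no_such_channel": 0.1}, {"duplicate_transfusion": 1.5}]
)
def test_invalid_rates_rejected(rates):
    with pytest.raises(ValueError):
        SimulationParams(error_rates=rates)


def test_prior_year_channel_moves_ffp_to_december(messy_tiny):
    """Flagged products sit in the prior-year extract, issued in December."""
    _, (w, ledger) = messy_tiny
    moved = ledger.ids("prior_year_issue")
    if not moved:  # pragma: no cover - rate/seed dependent
        pytest.skip("no prior-year draws at this seed")
    prior = w.prior_year_products
    assert set(prior["product_id"]) == set(moved)
    assert (prior["issue_date"].dt.month == 12).all()
    assert (prior["issue_date"].dt.year == 2009).all()
    main_ids = set(w.blood_bank.table("products")["product_id"])
    assert main_ids.isdisjoint(moved)


def test_duplicate_transfusion_count_matches_ledger():
    params = SimulationParams(seed=3, error_rates={"duplicate_transfusion": 0.02}, **TINY)
    w, ledger = simulate(params)
    truth = truth_summary(ledger, w)
    row = truth[truth["channel"] == "duplicate_transfusion"].iloc[0]
    assert row["expected_numerator"] == ledger.count("duplicate_transfusion")


def test_day_admission_share_near_target(clean_tiny):
    w, _ = clean_tiny
    hosp = pd.concat(
        [w.hospitals[h].table("hospitalizations") for h in w.hospitals], ignore_index=True
    )
    share = (hosp["day_admission"] == True).mean()  # noqa: E712
    assert 0.0 < share < 0.35  # around 23.64% of single-transfusion stays
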