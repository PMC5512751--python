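"""Time-pattern checks (step 6): yearly volumes and per-year linkage.

Extraction-window artifacts show up here: products issued in December
before the extract window starts leave their transfusions unlinked in the
first study year only, and supplying a supplementary prior-year extract
repairs exactly that deficit.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import pandas as pd

from . import linkage
from .results import RuleResult, round_pct
from .warehouse import Warehouse


def yearly_counts(w: Warehouse) -> Tuple[pd.DataFrame, RuleResult]:
    """Counts per calendar year of the event's own date, with a flag on any
    year-over-year relative change beyond ``yearly_change_flag_pct``.

    Donations, issued products and active donors are blood-bank series;
    transfusions are pooled across hospitals and broken down by product
    type.  Null-date records are excluded from the counts and tallied.
    """
    series = {}
    null_dates = {}
    donations = w.blood_bank.table("donations")
    if donations is not None:
        dates = donations["donation_date"]
        series["donations"] = dates.dropna().dt.year.value_counts().sort_index()
        null_dates["donations"] = int(dates.isna().sum())
        active = donations.dropna(subset=["donation_date", "donor_id"])
        series["donors"] = (
            active.assign(year=active["donation_date"].dt.year)
            .groupby("year")["donor_id"]
            .nunique()
            .sort_index()
        )
    products = w.blood_bank.table("products")
    if products is not None:
        dates = products["issue_date"]
        series["products"] = dates.dropna().dt.year.value_counts().sort_index()
        null_dates["products"] = int(dates.isna().sum())
    tx_frames = [
        src.table("transfusions")
        for src in w.hospitals.values()
        if src.table("transfusions") is not None
    ]
    if tx_frames:
        tx = pd.concat(tx_frames, ignore_index=True)
        dated = tx.dropna(subset=["transfusion_date"])
        null_dates["transfusions"] = int(tx["transfusion_date"].isna().sum())
        series["transfusions"] = dated["transfusion_date"].dt.year.value_counts().sort_index()
        for ptype, grp in dated.groupby("product_type"):
            series[f"transfusions_{ptype}"] = (
                grp["transfusion_date"].dt.year.value_counts().sort_index()
            )
    table = pd.DataFrame(series).fillna(0).astype(int)
    table.index.name = "year"
    flags = []
    limit = w.thresholds.yearly_change_flag_pct
    transitions = 0
    for name, s in series.items():
        s = s.sort_index()
        for prev_year, year in zip(s.index[:-1], s.index[1:]):
            transitions += 1
            prev, cur = s.loc[prev_year], s.loc[year]
            if prev > 0 and abs(cur - prev) / prev * 100 > limit:
                flags.append(f"{name}:{prev_year}->{year}")
    result = RuleResult(
        rule_id="T1",
        step=6,
        concept="time_patterns",
        source_id="pooled",
        numerator=len(flags),
        denominator=max(transitions, 1) if transitions else None,
        direction="violation",
        offending_ids=flags,
        details={"null_dates": null_dates, "flag_threshold_pct": limit},
        notes="year-over-year changes beyond threshold; raw series in report tables",
        evaluable=transitions > 0,
    )
    return table, result


def yearly_linkage(
    w: Warehouse, prior: Optional[pd.DataFrame] = None
) -> Tuple[pd.DataFrame, RuleResult]:
    """Transfusion-to-product linkage split by transfusion year (T2).

    When a supplementary prior-year product extract is given it joins the
    match; otherwise the share of unlinked keys that *would* match such an
    extract is reported, diagnosing a first-year boundary artifact.
    """
    products = w.blood_bank.table("products")
    tx_frames = {
        hid: src.table("transfusions")
        for hid, src in w.hospitals.items()
        if src.table("transfusions") is not None
    }
    if products is None or not tx_frames:
        return pd.DataFrame(), RuleResult.not_evaluable("T2", 6, "time_patterns", "pooled")
    effective = products
    if prior is not None and len(prior):
        effective = pd.concat([products, prior], ignore_index=True)
    rows = []
    total_num = total_den = 0
    all_tx = pd.concat(tx_frames.values(), ignore_index=True).dropna(subset=["transfusion_date"])
    diag_extract = w.prior_year_products if prior is None else None
    for year, grp in all_tx.groupby(all_tx["transfusion_date"].dt.year):
        counts, _ = linkage._match_transfusions(grp.reset_index(drop=True), effective)
        linked = int((counts == 1).sum())
        unlinked_keys = grp.reset_index(drop=True).loc[counts != 1]
        prior_match = None
        if diag_extract is not None and len(unlinked_keys):
            pcounts, _ = linkage._match_transfusions(
                unlinked_keys.reset_index(drop=True), diag_extract
            )
            prior_match = int((pcounts == 1).sum())
        rows.append(
            {
                "year": int(year),
                "linked": linked,
                "total": len(grp),
                "percentage": round_pct(linked, len(grp)),
                "unlinked_matching_prior_extract": prior_match,
            }
        )
        total_num += linked
        total_den += len(grp)
    table = pd.DataFrame(rows).set_index("year").sort_index()
    result = RuleResult(
        rule_id="T2",
        step=6,
        concept="time_patterns",
        source_id="pooled",
        numerator=total_num,
        denominator=total_den,
        details={"per_year": {int(y): float(p) for y, p in table["percentage"].items()}},
        notes="per-year linkage of transfusions to issued products",
    )
    return table, result


def run(
    w: Warehouse, prior: Optional[pd.DataFrame] = None
) -> Tuple[List[RuleResult], dict]:
    counts_table, t1 = yearly_counts(w)
    link_table, t2 = yearly_linkage(w, prior)
    return [t1, t2], {"yearly_counts": counts_table, "yearly_linkage": link_table}
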