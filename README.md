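# transfuqc

Stepwise validation of linked, multisource electronic health record data,
built around a blood-transfusion data warehouse: a national blood bank
(donors, donations, issued RBC/FFP/PLT products) deterministically linked to
hospital records (transfusions, patients, hospitalizations, diagnoses,
procedures, laboratory values).

Routinely collected health data are registered for care and billing, not for
research, and linking several providers multiplies the ways they can go
wrong: identifiers get recoded, extracts truncate at window boundaries,
split products masquerade as duplicates, codes drift between coding systems.
`transfuqc` turns the validation of such a warehouse into an explicit,
repeatable 12-step run — external concordance first, then linkage, identity,
completeness, uniformity, time patterns, plausibility, event attributes and
cross-source consistency — with every check reporting a uniform
numerator/denominator result and the offending record ids.

It is written for data managers and researchers who assemble linked health
registries and need a defensible data-quality report, and for methodologists
who want a fully synthetic, ground-truthed testbed for validation logic.

## The checks in brief

Every check is a rule with a stable id:

* **C1** agreement with external aggregate counts, per product type *p*:
  `agreement% = (1 − Σₚ |N_ext,p − N_dwh,p| / Σₚ N_dwh,p) × 100`
* **L1–L4, E3** directional linkage rates: transfusion→product by the end
  product's donation identification code (+ product code, falling back to
  product type), product→transfusion (complement = spilling rate),
  product→donation(s), product→donor, transfusion→hospitalization.
* **I1–I3** duplicates beyond the first per composite key
  (donation code + product type; donation id + type; patient + procedure
  code + date).
* **K1–K3** per-variable completeness, the share of variables ≥ 95 %
  complete, and coverage of transfusions by diagnosis episodes.
* **U1–U3** code-list conformance (ISBT-style product codes, diagnosis
  codes) and the lexical decimal precision of Hb measurements across
  sources.
* **T1–T2** year-over-year volume changes and per-year linkage, localizing
  extraction-window artifacts.
* **P1–P10, E1–E2** plausibility: donation before pooling; ≤ 3 (F) / 5 (M)
  whole-blood and ≤ 23 plasma donations per donor-year; donor age 18–70;
  hemoglobin change within ±1 day of an RBC transfusion, where a relative
  change beyond ±8.8 % counts as clinical and decreases are explained by an
  active bleeding-risk diagnosis; patient age < 121; gynecology diagnoses
  imply female; no events after death; admission ≤ discharge; product not
  expired at transfusion; platelet pools of 5–6 unique donors; transfer
  rate by discharge destination.

The synthetic generator builds a clean backbone in which all of these hold
by construction, then injects errors through 18 independent seeded channels
(duplicates, broken product-id recodings, prior-year issues, spilled
products, unexplained Hb decreases, post-death events, ...) and returns a
ground-truth ledger, so every reported numerator can be checked exactly.

## Worked example

```bash
python examples/simulate_and_validate.py
```

prints, for a clean three-year warehouse of 600 issued products:

```
injected errors: 0
C1  agreement with annual report           600/600 = 100.0%
L1  transfusions linked to products        600/600 = 100.0%
L2  products linked to transfusions        600/600 = 100.0%
I1  duplicated transfusions                0/600 = 0.0%
P4  unexplained Hb decreases               0/420 = 0.0%
E3  transfusions inside a hospitalization  600/600 = 100.0%
```

Satisfaction rules sit at 100 % and violation rules at 0 % because nothing
was injected.  `examples/boundary_artifact.py` shows the opposite case: with
half of the first year's plasma products issued in the December before the
extract window, per-year linkage drops to 87.0 % in 2010 only, every
unlinked key matches the prior-year extract, and supplying that extract via
`validate_warehouse(w, prior_year_extract=...)` (or `--prior-year-extract`
on the CLI) restores 100 %.  `examples/inject_and_recover.py` demonstrates
exact ledger recovery for duplicates, and
`examples/external_concordance.py` walks the agreement formula by hand
(|100−98| + |50−51| = 3 over 149 products → 97.99 %).

## Command line

```bash
transfuqc simulate --params params.yaml --out warehouse/
transfuqc validate --config warehouse/config.yaml --out report/ \
    [--prior-year-extract F] [--fix postdeath] [--strict 95]
transfuqc compare --reports a/report.csv b/report.csv --out diff.csv
```

`validate` writes `report.csv` (machine schema), `report.md` (human,
grouped external/internal), `offenders.csv`, the yearly tables and a
`link_map.csv`.  Exit code is 0 even with violations — validation
describes, it does not gate — unless `--strict` is given.

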