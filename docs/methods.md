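# Methods

## The validation model

`transfuqc` operationalizes data-quality assessment for a warehouse that
links a blood bank to several hospitals on deterministic identifiers.  The
checks split into *external concordance* (agreement of aggregates with
sources outside the warehouse) and *internal consistency* (expected
relationships within and between tables).  They run in a fixed order chosen
so that cheap, upstream problems are found before they can bias downstream
denominators: external counts first, then linkage, identity, completeness,
uniformity, time patterns, plausibility, event attributes and cross-source
consistency.  Identity (duplicate detection) is computed before the linkage
denominators; duplicate *procedures* are reduced to one representative per
key (double registration is expected there), while duplicate transfusions
and donations are reported but retained, because coarse composite keys can
make genuinely distinct split products look like duplicates and dropping
them would delete real events.

Every check returns the same result shape: numerator, denominator, the
offending record identifiers, and a `direction`.  Satisfaction rules (e.g.
linkage) are perfect at 100 %, violation rules (e.g. duplicates) at 0 %.
Percentages are recomputed from the counts and rounded to two decimals,
half away from zero.  A check whose required table was declared absent
reports *not evaluable* — never 0 % and never a crash — and one check's
failure never aborts the run.

### Linkage semantics

Hospitals reference an issued product by the donation identification code
of the end product together with the product code; when either side lacks
the code, the broader product type is used instead (this mirrors real
deployments where one hospital does not export product codes).  A
transfusion counts as linked only when the key resolves to *exactly one*
product: a multi-match is an identity problem, not a link, and is reported
separately.  Intervals (hospitalizations, diagnosis episodes) are closed on
both ends; an open end date means "still active at extraction".  All date
comparisons are at day precision.

### The hemoglobin rule (P4)

For each red-cell transfusion the pre-value is the last Hb measurement
within `hb_window_days` (default 1) *before* the transfusion date and the
post-value the first within the window *after* it; measurements dated on
the transfusion day itself are excluded from both windows, since that
measurement is typically the one that triggered the transfusion.  Among
candidates at the same date the earlier-recorded row wins on the pre side
and the later-recorded row on the post side.  The relative change
`(post − pre)/pre × 100` classifies the transfusion as increase, decrease
or no change against the ±8.8 % threshold; the change is taken relative to
the pre-value because a threshold on absolute differences would depend on
the measurement unit.  A decrease is *explained* when a diagnosis episode
flagged as bleeding-risk in the reference list covers the transfusion
date; the rule's violation numerator counts only unexplained decreases.
The four classes partition the RBC transfusions, and widening the threshold
can only shrink the clinical-change count — both properties are asserted in
the test suite.

### Other numerical choices

* Duplicate numerators count records beyond the first per identical key
  group (a triplicate contributes 2); keys containing nulls are excluded
  from grouping and tallied in the notes.
* Measurement precision is the *lexical* count of decimals as recorded in
  the source file; the CSV reader preserves it in a companion column
  because numeric parsing alone would destroy it.  The modal precision
  breaks ties toward fewer decimals.
* Donor-age checks exempt autologous donations (own-use donations follow
  different rules) and count them in the notes.  Donation-frequency limits
  fall back to the lenient (male) limit when donor gender is unknown.
* Null codes are missingness, not non-conformance; code matching applies
  trim + case-fold normalization.
* The agreement statistic can go negative when the discrepancy exceeds the
  warehouse count; the displayed value is clamped at 0 with the raw value
  kept in the details.
* Per-source results are pooled by summing numerators and denominators;
  the unweighted mean percentage is reported alongside because the two
  genuinely diverge on unbalanced sources, and the pooled figure is the
  headline.
* Loading never drops rows: unparseable cells become nulls and are counted
  in a load log, surfacing later as missingness.

### Open design points, decided

* The E2 transfer-rate denominator is transfused patients (the population
  the warehouse is about), noted in the result.
* Whether ambiguous product matches count as linked was open; they do not,
  because linkage "by id of the end product" implies uniqueness.
* Per-year linkage denominators use post-deduplication tables, consistent
  with the step ordering.
* The blood-bank export is modeled as one row per issued product carrying a
  list of constituent donation ids, the most common granularity for
  end-product extracts.

## The synthetic generator

The generator emulates the structure of a national blood bank linked to two
teaching hospitals over 2010–2014 with RBC, FFP and pooled-platelet
products.  Defaults are scaled down from such a warehouse to desk size:
700 RBC + 200 FFP + 100 PLT products per hospital-year, i.e. 10,000
transfusions over five years, from 2,600 donors (90 % whole-blood, 10 %
plasmapheresis) into 1,600 patients.  Test-suite runs use the same
generator at two smaller sizes (2,000 and 120 transfusions) so the whole
suite stays in the minutes range on one CPU; the properties asserted are
size-independent.

The *clean backbone* holds by construction: each product chain is built
backwards from its transfusion date (donation < pooling ≤ production ≤
issue ≤ transfusion ≤ expiration, all within the calendar year), donors are
drawn under the per-year frequency limits and within the 18–70 age band,
every transfusion lies inside a hospitalization and a diagnosis episode,
platelet pools draw 5 or 6 distinct donors, and post-transfusion Hb rises
by 12–22 % (safely beyond the 8.8 % threshold even after rounding to one
decimal).  23.64 % of single-transfusion stays are day admissions.  A
configurable share of RBC transfusions (default 3 %) instead shows an
*explained* decrease with a bleeding-risk episode covering the date,
exercising the explanation logic without constituting an error.  Lab values
carry one decimal everywhere, so precision uniformity is perfect until
perturbed.

Errors are injected through 18 channels in a fixed order (structural moves
before cell-level mutations), each a seeded Bernoulli draw over eligible
records, where eligibility excludes records touched by earlier channels so
that single-channel runs never create collateral violations.  Each
injection appends one ground-truth ledger row.  Notable channels:

* `broken_product_link` recodes the product identifier on the hospital side
  only and emits a remap table, so the remediation path
  (`apply_id_remap`) can be tested end to end.
* `prior_year_issue` moves a first-year FFP product (and its donation) out
  of the extract window into a supplementary prior-year file, issued in the
  preceding December — the canonical extraction boundary artifact.
* `duplicate_*` channels copy exact composite keys; an optional
  split-product mode gives copies distinct true products behind the same
  key.
* `outpatient_transfusion` removes the (sole) covering hospitalization of a
  transfusion rather than moving dates, so no other rule is disturbed.

`truth_summary` recomputes the expected numerator and denominator for every
channel by brute-force scans (plain Python loops in `bruteforce.py`,
sharing no code with the pandas-based validators); the same scans serve as
the independent oracle in the tests.

What the generator does **not** emulate: realistic clinical coding
ontologies (codes come from small synthetic reference lists), realistic lab
value and transfusion-intensity distributions, inter-hospital patient
overlap, or free-text fields.  Passing tests therefore demonstrate that the
checks compute exactly what they claim on data with known truth — not that
any particular real warehouse is valid, nor that the synthetic marginals
match a real population.

## Tunable thresholds

| Parameter | Default | Meaning |
|---|---|---|
| `hb_change_pct` | 8.8 % | relative Hb change counted as clinical |
| `hb_window_days` | 1 day | window around the transfusion for pre/post Hb |
| `wb_limit_female` / `wb_limit_male` | 3 / 5 per year | whole-blood donation limits |
| `plasma_limit` | 23 per year | plasma donation limit |
| `donor_age_min` / `donor_age_max` | 18 / 70 years | donation age band |
| `patient_age_max` | 121 years | implausible-age cutoff at transfusion |
| `pooled_plt_donors` | {5, 6} | valid unique-donor counts per platelet pool |
| `completeness_summary_cutoff` | 95 % | bar for "complete" in the summary |
| `yearly_change_flag_pct` | 20 % | year-over-year volume change worth flagging |
| `consistency_flag_pct` | 5 pp | inter-hospital percentage gap worth flagging |

The first eight are practice constants; the last two are screening
thresholds with no clinical anchor — they are deliberately configurable and
the report always shows the raw series and per-source values next to the
flags, because explicability (a new testing method reducing plasma use, a
merged ward) is a human judgment the tool does not automate.  For the same
reason concordance with literature and with expert opinion are left as
free-text concerns outside the engine, and chart-review accuracy is out of
scope.

## Known limitations

* Linkage is deterministic; there is no probabilistic or string-similarity
  matching.
* No unit conversion between Hb conventions (mmol/L vs g/dL); a single
  configured unit per warehouse is assumed and mixed units surface as
  conformance failures.
* The cross-hospital consistency check (S1) aggregates all other rules, so
  any asymmetric defect legitimately moves it; it is a screen, not an
  independent measurement.
* Remediation hooks are deliberately conservative: the post-death fix only
  blanks the death date and the id remap only rewrites references; no
  records are ever deleted.
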