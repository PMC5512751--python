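"""Uniform result containers for every check.

Each evaluated check yields a :class:`RuleResult` carrying the raw counts
(numerator / denominator), the offending record identifiers, and enough
metadata (step number, validity concept, source) to assemble the final
report.  Percentages are always recomputed from the counts and rounded to
two decimals, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Any, Iterable, Optional

import pandas as pd

#: Fig.-2-style validity concepts, in report order.
CONCEPTS = (
    "concordance_report",
    "linkage",
    "identity",
    "completeness",
    "uniformity",
    "time_patterns",
    "plausibility",
    "event_attributes",
    "consistency",
    "concordance_databases",
)

#: Maximum offending ids kept on a result; full lists go to the sidecar file.
OFFENDER_CAP = 1000


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage to 2 decimals, rounding half away from zero."""
    q = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class RuleResult:
    """One evaluated check on one source (or pooled across sources).

    ``direction`` states what the numerator counts: for ``"satisfaction"``
    rules 100 % is perfect (e.g. linkage), for ``"violation"`` rules 0 % is
    perfect (e.g. duplicates), ``"descriptive"`` rules carry no target.
    """

    rule_id: str
    step: int
    concept: str
    source_id: str
    numerator: Optional[int]
    denominator: Optional[int]
    direction: str = "satisfaction"
    offending_ids: list = field(default_factory=list)
    notes: str = ""
    details: dict = field(default_factory=dict)
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.concept not in CONCEPTS:
            raise ValueError(f"unknown concept {self.concept!r}")
        if self.evaluable and self.denominator is not None:
            n, d = self.numerator, self.denominator
            if n is None or not (0 <= n <= d):
                raise ValueError(
                    f"{self.rule_id}: numerator {n} outside [0, {d}]"
                )

    @property
    def percentage(self) -> Optional[float]:
        if not self.evaluable or not self.denominator:
            return None
        return round_pct(self.numerator, self.denominator)

    @property
    def violation_count(self) -> Optional[int]:
        """Numerator expressed in the violation direction (None if n/e)."""
        if not self.evaluable or self.numerator is None:
            return None
        if self.direction == "violation":
            return self.numerator
        if self.denominator is None:
            return None
        return self.denominator - self.numerator

    def is_perfect(self) -> bool:
        """True when the check found nothing wrong.

        Satisfaction rules must sit at 100 %, violation rules at 0
        offending records.  Descriptive and not-evaluable results count as
        perfect for lack of a target.
        """
        if not self.evaluable or self.direction == "descriptive":
            return True
        v = self.violation_count
        return v == 0 if v is not None else True

    @classmethod
    def not_evaluable(
        cls, rule_id: str, step: int, concept: str, source_id: str, notes: str = ""
    ) -> "RuleResult":
        return cls(
            rule_id=rule_id,
            step=step,
            concept=concept,
            source_id=source_id,
            numerator=None,
            denominator=None,
            notes=notes or "not evaluable",
            evaluable=False,
        )


REPORT_COLUMNS = [
    "step",
    "concept",
    "rule_id",
    "source_id",
    "numerator",
    "denominator",
    "percentage",
    "direction",
    "evaluable",
    "notes",
]


@dataclass
class ValidityReport:
    """Ordered collection of rule results, grouped by step and concept."""

    rows: list = field(default_factory=list)
    label: str = "warehouse"
    tables: dict = field(default_factory=dict)  # named DataFrames (yearly series)

    def sorted(self) -> "ValidityReport":
        order = {c: i for i, c in enumerate(CONCEPTS)}
        rows = sorted(
            self.rows,
            key=lambda r: (r.step, order[r.concept], r.rule_id, r.source_id),
        )
        return ValidityReport(rows=rows, label=self.label, tables=self.tables)

    def get(self, rule_id: str, source_id: str = "pooled") -> RuleResult:
        for r in self.rows:
            if r.rule_id == rule_id and r.source_id == source_id:
                return r
        raise KeyError(f"no result for rule {rule_id!r} / source {source_id!r}")

    def rule_ids(self) -> list:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.rule_id)
        return list(seen)

    def select(self, source_id: str) -> "ValidityReport":
        return ValidityReport(
            rows=[r for r in self.rows if r.source_id == source_id],
            label=source_id,
        )

    def frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "step": r.step,
                    "concept": r.concept,
                    "rule_id": r.rule_id,
                    "source_id": r.source_id,
                    "numerator": r.numerator,
                    "denominator": r.denominator,
                    "percentage": r.percentage,
                    "direction": r.direction,
                    "evaluable": r.evaluable,
                    "notes": r.notes,
                }
            )
        return pd.DataFrame(recs, columns=REPORT_COLUMNS)


def pooled(results: Iterable[RuleResult], source_id: str = "pooled") -> RuleResult:
    """Sum numerators/denominators across sources; unweighted mean in details.

    Both aggregations are kept because they genuinely differ on unbalanced
    sources; the pooled figure is the headline.
    """
    results = [r for r in results if r.evaluable and r.denominator]
    if not results:
        raise ValueError("nothing to pool")
    first = results[0]
    num = sum(r.numerator for r in results)
    den = sum(r.denominator for r in results)
    means = [r.percentage for r in results]
    mean_pct = round(sum(means) / len(means), 2)
    offenders: list[Any] = []
    for r in results:
        offenders.extend(r.offending_ids)
    return RuleResult(
        rule_id=first.rule_id,
        step=first.step,
        concept=first.concept,
        source_id=source_id,
        numerator=num,
        denominator=den,
        direction=first.direction,
        offending_ids=offenders[:OFFENDER_CAP],
        details={"mean_pct": mean_pct, "per_source": {r.source_id: r.percentage for r in results}},
        notes=first.notes,
    )


def with_pooled(results: list) -> list:
    """Append a pooled row when two or more evaluable per-source rows exist."""
    evaluable = [r for r in results if r.evaluable and r.denominator]
    if len(evaluable) >= 2:
        return results + [pooled(evaluable)]
    if len(evaluable) == 1:
        r = evaluable[0]
        clone = RuleResult(
            rule_id=r.rule_id,
            step=r.step,
            concept=r.concept,
            source_id="pooled",
            numerator=r.numerator,
            denominator=r.denominator,
            direction=r.direction,
            offending_ids=list(r.offending_ids),
            details=dict(r.details),
            notes=r.notes,
        )
        return results + [clone]
    return results
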