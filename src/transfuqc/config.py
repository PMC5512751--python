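"""Configuration objects: tunable thresholds and error types.

All clinically meaningful limits used by the check registry live in one
:class:`ThresholdConfig` so that a deployment can override them in the
warehouse config file without touching code.
"""

from __future__ import annotations

from pydantic import BaseModel, field_validator


class ConfigurationError(ValueError):
    """Raised for malformed warehouse configs (missing tables, bad mappings)."""


class ProvenanceError(ValueError):
    """Raised when a ground-truth ledger is paired with a foreign warehouse."""


class ThresholdConfig(BaseModel):
    """Tunable limits for the plausibility and consistency checks.

    Defaults reflect common transfusion-practice limits: a relative
    hemoglobin change beyond ±8.8 % within ±1 day of a red-cell transfusion
    counts as a clinical change; whole-blood donors may donate at most 3
    (women) or 5 (men) times per calendar year and plasma donors 23 times;
    donors must be 18-70 years old at donation; recorded patient age must
    stay below 121 years.  ``completeness_summary_cutoff`` is the bar a
    variable must clear to count as "complete" in the completeness summary.
    ``yearly_change_flag_pct`` (relative year-over-year volume change) and
    ``consistency_flag_pct`` (percentage-point gap between hospitals) guard
    the two screening checks that have no clinical constant behind them.
    """

    hb_change_pct: float = 8.8
    hb_window_days: int = 1
    wb_limit_female: int = 3
    wb_limit_male: int = 5
    plasma_limit: int = 23
    donor_age_min: int = 18
    donor_age_max: int = 70
    patient_age_max: int = 121
    pooled_plt_donors: frozenset[int] = frozenset({5, 6})
    completeness_summary_cutoff: float = 95.0
    yearly_change_flag_pct: float = 20.0
    consistency_flag_pct: float = 5.0

    @field_validator(
        "hb_change_pct",
        "hb_window_days",
        "wb_limit_female",
        "wb_limit_male",
        "plasma_limit",
        "donor_age_min",
        "donor_age_max",
        "patient_age_max",
        "completeness_summary_cutoff",
        "yearly_change_flag_pct",
        "consistency_flag_pct",
    )
    @classmethod
    def _strictly_positive(cls, v):
        if v <= 0:
            raise ValueError("thresholds must be strictly positive")
        return v

    @field_validator("pooled_plt_donors")
    @classmethod
    def _positive_pool_sizes(cls, v):
        if not v or any(k <= 0 for k in v):
            raise ValueError("pooled_plt_donors must be non-empty positive counts")
        return v
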