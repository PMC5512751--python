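"""Shared fixtures: tiny hand-built warehouses and cached simulations."""

from __future__ import annotations

from datetime import date

import pytest

from transfuqc import SimulationParams, simulate
from transfuqc.config import ThresholdConfig
from transfuqc.synthetic import BLEEDING_DX, GENERIC_DX, GYN_DX, PRODUCT_CODE_LISTS
from transfuqc.warehouse import (
    BLOOD_BANK_TABLES,
    HOSPITAL_TABLES,
    EXTERNAL_SCHEMA,
    Source,
    Warehouse,
    table_from_records,
)

#: Small volumes used throughout the unit tests (a couple of hundred rows).
TINY = dict(
    year_start=2010,
    year_end=2011,
    n_donors=150,
    n_patients=60,
    products_per_year={"RBC": 20, "FFP": 6, "PLT": 4},
)

#: Mid-size study conditions: 2 hospitals, 5 years, 2,000 transfusions.
MID = dict(
    year_start=2010,
    year_end=2014,
    n_donors=700,
    n_patients=400,
    products_per_year={"RBC": 140, "FFP": 40, "PLT": 20},
)


def default_reference():
    product_codes = [
        {"code": c, "description": f"{t} {c}"}
        for t, lst in PRODUCT_CODE_LISTS.items()
        for c in lst
    ]
    dx = [
        {"code": c, "description": c, "bleeding_risk": c in BLEEDING_DX, "gynecology": c in GYN_DX}
        for c in GENERIC_DX + BLEEDING_DX + GYN_DX
    ]
    return {
        "product_codes": table_from_records(
            product_codes, {"code": "str", "description": "str"}
        ),
        "diagnosis_codes": table_from_records(
            dx,
            {"code": "str", "description": "str", "bleeding_risk": "bool", "gynecology": "bool"},
        ),
    }


def build_warehouse(
    bank=None,
    hospitals=None,
    reference=None,
    external=None,
    thresholds=None,
    absent=(),
):
    """Construct a warehouse from record dicts.

    ``bank``: {table: rows}; ``hospitals``: {hospital_id: {table: rows}}.
    Unmentioned tables become empty frames; ``absent`` lists
    "source_id.table" names declared absent.
    """
    bank = bank or {}
    hospitals = hospitals or {"hospital_a": {}}
    absent = set(absent)

    def tables_for(sid, kind, spec):
        schemas = BLOOD_BANK_TABLES if kind == "blood_bank" else HOSPITAL_TABLES
        out = {}
        for name, schema in schemas.items():
            if f"{sid}.{name}" in absent:
                out[name] = None
            else:
                out[name] = table_from_records(spec.get(name, []), schema)
        return out

    bank_src = Source("blood_bank", "blood_bank", tables_for("blood_bank", "blood_bank", bank))
    hospital_srcs = {
        hid: Source(hid, "hospital", tables_for(hid, "hospital", spec))
        for hid, spec in hospitals.items()
    }
    ext = table_from_records(external, EXTERNAL_SCHEMA) if external is not None else None
    return Warehouse(
        blood_bank=bank_src,
        hospitals=hospital_srcs,
        reference=reference or default_reference(),
        external_aggregates=ext,
        thresholds=thresholds or ThresholdConfig(),
        provenance="built-by-test",
    )


def d(y, m, dd):
    return date(y, m, dd)


@pytest.fixture(scope="session")
def clean_tiny():
    """Clean-backbone tiny simulation shared across tests."""
    return simulate(SimulationParams(seed=1, **TINY))


@pytest.fixture(scope="session")
def messy_tiny():
    """Tiny simulation with every channel active at a high rate."""
    from transfuqc import CHANNELS

    params = SimulationParams(seed=9, error_rates={c: 0.3 for c in CHANNELS}, **TINY)
    return params, simulate(params)
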