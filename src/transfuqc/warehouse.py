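"""Typed data model for the multisource warehouse and its CSV round trip.

A warehouse bundles one blood-bank source (donors, donations, issued
products) with one or more hospital sources (transfusions, patients,
hospitalizations, diagnosis episodes, procedures, laboratory measurements),
plus reference code lists and optional external aggregate counts.

Loading never drops rows: unparseable cells become nulls and are counted in
a load log, so that bad values surface later as missingness instead of
silently shrinking denominators.  Lab values keep their lexical precision
(the count of recorded decimal places) because one of the uniformity checks
is about precision, which numeric parsing alone would destroy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .config import ConfigurationError, ThresholdConfig

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Table schemas.  Type codes: id, str, date, bool, float_lexical (keeps a
# companion "<col>_decimals" column), idlist (";"-separated references).
# ---------------------------------------------------------------------------

BLOOD_BANK_TABLES: Dict[str, Dict[str, str]] = {
    "donors": {"donor_id": "id", "birth_date": "date", "gender": "str"},
    "donations": {
        "donation_id": "id",
        "donor_id": "id",
        "donation_date": "date",
        "donation_type": "str",
        "hb_value": "float_lexical",
        "autologous": "bool",
    },
    "products": {
        "product_id": "id",
        "product_code": "str",
        "product_type": "str",
        "donation_ids": "idlist",
        "production_date": "date",
        "expiration_date": "date",
        "issue_date": "date",
        "pooling_date": "date",
    },
}

HOSPITAL_TABLES: Dict[str, Dict[str, str]] = {
    "transfusions": {
        "transfusion_id": "id",
        "patient_id": "id",
        "donation_code": "id",
        "product_code": "str",
        "product_type": "str",
        "transfusion_date": "date",
    },
    "patients": {
        "patient_id": "id",
        "birth_date": "date",
        "gender": "str",
        "death_date": "date",
    },
    "hospitalizations": {
        "hospitalization_id": "id",
        "patient_id": "id",
        "admission_date": "date",
        "discharge_date": "date",
        "day_admission": "bool",
        "discharge_destination": "str",
    },
    "diagnoses": {
        "episode_id": "id",
        "patient_id": "id",
        "diagnosis_code": "str",
        "start_date": "date",
        "end_date": "date",
    },
    "procedures": {
        "procedure_id": "id",
        "patient_id": "id",
        "procedure_code": "str",
        "procedure_date": "date",
    },
    "labs": {
        "lab_id": "id",
        "patient_id": "id",
        "analyte": "str",
        "measured_at": "date",
        "value": "float_lexical",
    },
}

REFERENCE_TABLES: Dict[str, Dict[str, str]] = {
    "product_codes": {"code": "str", "description": "str"},
    "diagnosis_codes": {
        "code": "str",
        "description": "str",
        "bleeding_risk": "bool",
        "gynecology": "bool",
    },
}

EXTERNAL_SCHEMA = {"year": "int", "product_type": "str", "count": "int"}

PRODUCT_TYPES = ("RBC", "FFP", "PLT")


@dataclass
class LoadIssue:
    source_id: str
    table: str
    column: str
    row: int
    raw: str
    problem: str


@dataclass
class Source:
    """One data provider: a blood bank or a hospital.

    ``tables`` maps table name to a DataFrame, or to ``None`` when the
    provider declared the table absent (checks then report not-evaluable).
    """

    source_id: str
    kind: str  # "blood_bank" | "hospital"
    tables: Dict[str, Optional[pd.DataFrame]] = field(default_factory=dict)

    def table(self, name: str) -> Optional[pd.DataFrame]:
        return self.tables.get(name)


@dataclass
class Warehouse:
    blood_bank: Source
    hospitals: Dict[str, Source]
    reference: Dict[str, pd.DataFrame] = field(default_factory=dict)
    external_aggregates: Optional[pd.DataFrame] = None
    prior_year_products: Optional[pd.DataFrame] = None
    external_outcomes: Optional[pd.DataFrame] = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    load_log: List[LoadIssue] = field(default_factory=list)
    provenance: str = ""

    @property
    def sources(self) -> Dict[str, Source]:
        out = {self.blood_bank.source_id: self.blood_bank}
        out.update(self.hospitals)
        return out

    def hospital_table(self, hospital_id: str, name: str) -> Optional[pd.DataFrame]:
        return self.hospitals[hospital_id].table(name)

    def copy(self) -> "Warehouse":
        def copy_src(s: Source) -> Source:
            return Source(
                source_id=s.source_id,
                kind=s.kind,
                tables={k: (v.copy() if v is not None else None) for k, v in s.tables.items()},
            )

        return Warehouse(
            blood_bank=copy_src(self.blood_bank),
            hospitals={k: copy_src(v) for k, v in self.hospitals.items()},
            reference={k: v.copy() for k, v in self.reference.items()},
            external_aggregates=(
                self.external_aggregates.copy() if self.external_aggregates is not None else None
            ),
            prior_year_products=(
                self.prior_year_products.copy() if self.prior_year_products is not None else None
            ),
            external_outcomes=(
                self.external_outcomes.copy() if self.external_outcomes is not None else None
            ),
            thresholds=self.thresholds.model_copy(),
            load_log=list(self.load_log),
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# Cell-level parsing
# ---------------------------------------------------------------------------


def _count_decimals(raw: str) -> int:
    raw = raw.strip()
    if "." in raw:
        return len(raw.split(".", 1)[1])
    return 0


def _parse_table(
    df: pd.DataFrame,
    schema: Dict[str, str],
    source_id: str,
    table: str,
    issues: List[LoadIssue],
) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col, kind in schema.items():
        if col not in df.columns:
            issues.append(LoadIssue(source_id, table, col, -1, "", "column absent"))
            raw = pd.Series([""] * len(df), index=df.index, dtype=object)
        else:
            raw = df[col].astype(str).str.strip()
            raw = raw.where(~df[col].isna(), "")
        empty = raw == ""
        if kind in ("id", "str"):
            out[col] = raw.where(~empty, pd.NA).astype(object)
        elif kind == "date":
            parsed = pd.to_datetime(raw.where(~empty, None), format="%Y-%m-%d", errors="coerce")
            bad = (~empty) & parsed.isna()
            for i in df.index[bad]:
                issues.append(LoadIssue(source_id, table, col, int(i), raw.loc[i], "bad date"))
            out[col] = parsed.dt.normalize()
        elif kind == "bool":
            mapping = {"true": True, "false": False, "1": True, "0": False}
            lowered = raw.str.lower()
            parsed = lowered.map(mapping)
            bad = (~empty) & parsed.isna()
            for i in df.index[bad]:
                issues.append(LoadIssue(source_id, table, col, int(i), raw.loc[i], "bad boolean"))
            out[col] = parsed.where(~parsed.isna(), pd.NA).astype(object)
        elif kind == "int":
            parsed = pd.to_numeric(raw.where(~empty, None), errors="coerce")
            bad = (~empty) & parsed.isna()
            for i in df.index[bad]:
                issues.append(LoadIssue(source_id, table, col, int(i), raw.loc[i], "bad integer"))
            out[col] = parsed.astype("Int64")
        elif kind == "float_lexical":
            parsed = pd.to_numeric(raw.where(~empty, None), errors="coerce")
            bad = (~empty) & parsed.isna()
            for i in df.index[bad]:
                issues.append(LoadIssue(source_id, table, col, int(i), raw.loc[i], "bad number"))
            out[col] = parsed.astype(float)
            ok = (~empty) & ~parsed.isna()
            out[col + "_decimals"] = pd.array(
                [_count_decimals(v) if o else None for v, o in zip(raw, ok)], dtype="Int64"
            )
        elif kind == "idlist":
            out[col] = [
                tuple(p for p in v.split(";") if p) if v else None for v in raw
            ]
        else:  # pragma: no cover - schema typo guard
            raise ValueError(f"unknown schema kind {kind!r}")
    return out


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[], encoding="utf-8")


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------


def _apply_mapping(df: pd.DataFrame, mapping: Dict[str, str], table: str) -> pd.DataFrame:
    """Rename actual CSV headers to canonical names (mapping canonical->actual)."""
    if not mapping:
        return df
    actuals = list(mapping.values())
    if len(set(actuals)) != len(actuals):
        raise ConfigurationError(f"duplicate column mapping for table {table!r}")
    return df.rename(columns={v: k for k, v in mapping.items()})


def load_table(
    path: Path,
    schema: Dict[str, str],
    source_id: str,
    table: str,
    issues: List[LoadIssue],
    mapping: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    raw = _read_csv(path)
    raw = _apply_mapping(raw, mapping or {}, table)
    return _parse_table(raw, schema, source_id, table, issues)


def load_warehouse(config_path: str | Path) -> Warehouse:
    """Load a warehouse from its YAML config.

    The config names every source, its table files (paths relative to the
    config file), optional column mappings, reference lists, external
    aggregate counts and threshold overrides.  Missing mandatory table
    files raise :class:`ConfigurationError`; tables listed under a source's
    ``absent`` key are declared absent and dependent checks will report
    not-evaluable instead of crashing.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigurationError(f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text(encoding="utf-8"))
    base = config_path.parent
    issues: List[LoadIssue] = []
    mapping_cfg: Dict[str, Dict[str, str]] = cfg.get("column_mapping") or {}

    blood_bank: Optional[Source] = None
    hospitals: Dict[str, Source] = {}
    for src in cfg.get("sources", []):
        sid, kind = src["id"], src["kind"]
        schemas = BLOOD_BANK_TABLES if kind == "blood_bank" else HOSPITAL_TABLES
        absent = set(src.get("absent") or [])
        tables: Dict[str, Optional[pd.DataFrame]] = {}
        declared = src.get("tables") or {}
        for name, schema in schemas.items():
            if name in absent:
                tables[name] = None
                continue
            if name not in declared:
                raise ConfigurationError(
                    f"source {sid!r}: table {name!r} neither configured nor declared absent"
                )
            path = base / declared[name]
            if not path.exists():
                raise ConfigurationError(f"source {sid!r}: missing table file for {name!r}: {path}")
            tables[name] = load_table(path, schema, sid, name, issues, mapping_cfg.get(name))
        source = Source(source_id=sid, kind=kind, tables=tables)
        if kind == "blood_bank":
            blood_bank = source
        else:
            hospitals[sid] = source
    if blood_bank is None:
        raise ConfigurationError("config declares no blood_bank source")

    reference: Dict[str, pd.DataFrame] = {}
    for name, schema in REFERENCE_TABLES.items():
        ref_cfg = (cfg.get("reference") or {}).get(name)
        if ref_cfg is None:
            raise ConfigurationError(f"missing reference list {name!r} in config")
        path = base / ref_cfg
        if not path.exists():
            raise ConfigurationError(f"missing reference list file: {path}")
        reference[name] = load_table(path, schema, "reference", name, issues)

    external = None
    if cfg.get("external_aggregates"):
        path = base / cfg["external_aggregates"]
        if not path.exists():
            raise ConfigurationError(f"missing external aggregates file: {path}")
        external = load_table(path, EXTERNAL_SCHEMA, "external", "external_aggregates", issues)

    prior = None
    if cfg.get("prior_year_products"):
        path = base / cfg["prior_year_products"]
        if not path.exists():
            raise ConfigurationError(f"missing prior-year extract file: {path}")
        prior = load_table(
            path, BLOOD_BANK_TABLES["products"], "prior_extract", "products", issues
        )

    external_outcomes = None
    if cfg.get("external_outcomes"):
        path = base / cfg["external_outcomes"]
        if not path.exists():
            raise ConfigurationError(f"missing external outcomes file: {path}")
        external_outcomes = pd.read_csv(path)

    thresholds = ThresholdConfig(**(cfg.get("thresholds") or {}))
    w = Warehouse(
        blood_bank=blood_bank,
        hospitals=hospitals,
        reference=reference,
        external_aggregates=external,
        prior_year_products=prior,
        external_outcomes=external_outcomes,
        thresholds=thresholds,
        load_log=issues,
        provenance=str(cfg.get("provenance") or ""),
    )
    if issues:
        log.info("load log: %d cell/column issues recorded", len(issues))
    return w


def table_from_records(rows: List[dict], schema: Dict[str, str]) -> pd.DataFrame:
    """Build a schema-typed table from plain record dicts (dates may be
    ``datetime.date``; missing keys become nulls).  Convenient for
    constructing small warehouses programmatically."""
    cols: Dict[str, pd.Series] = {}
    for col, kind in schema.items():
        values = [r.get(col) for r in rows]
        if kind == "date":
            cols[col] = pd.to_datetime(pd.Series(values, dtype=object))
        elif kind == "float_lexical":
            cols[col] = pd.Series(values, dtype=float)
            decs = [r.get(col + "_decimals") for r in rows]
            cols[col + "_decimals"] = pd.Series(decs, dtype="Int64")
        elif kind == "int":
            cols[col] = pd.Series(values, dtype="Int64")
        else:
            cols[col] = pd.Series(
                [v if v is not None else pd.NA for v in values], dtype=object
            )
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_cell(value, kind: str, decimals=None) -> str:
    if value is None or value is pd.NA or (isinstance(value, float) and pd.isna(value)):
        return ""
    if kind == "date":
        if pd.isna(value):
            return ""
        return pd.Timestamp(value).strftime("%Y-%m-%d")
    if kind == "bool":
        return "true" if value else "false"
    if kind == "idlist":
        return ";".join(value)
    if kind == "float_lexical":
        if decimals is not None and not pd.isna(decimals):
            return f"{value:.{int(decimals)}f}"
        return repr(float(value))
    if kind == "int":
        return str(int(value))
    return str(value)


def write_table(df: pd.DataFrame, schema: Dict[str, str], path: Path) -> None:
    cols: Dict[str, List[str]] = {}
    for col, kind in schema.items():
        decs = df.get(col + "_decimals") if kind == "float_lexical" else None
        cells = []
        for i in range(len(df)):
            d = decs.iloc[i] if decs is not None else None
            value = df[col].iloc[i] if col in df.columns else None
            cells.append(_format_cell(value, kind, d))
        cols[col] = cells
    pd.DataFrame(cols).to_csv(path, index=False, encoding="utf-8")


def write_warehouse(w: Warehouse, out_dir: str | Path) -> Path:
    """Write all warehouse tables plus a ``config.yaml`` that reloads them.

    Round trip: ``load_warehouse(write_warehouse(w) / "config.yaml")``
    equals ``w`` field-for-field on all non-null cells.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: dict = {"sources": [], "reference": {}, "provenance": w.provenance}
    for sid, src in w.sources.items():
        schemas = BLOOD_BANK_TABLES if src.kind == "blood_bank" else HOSPITAL_TABLES
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        entry: dict = {"id": sid, "kind": src.kind, "tables": {}, "absent": []}
        for name, df in src.tables.items():
            if df is None:
                entry["absent"].append(name)
                continue
            rel = f"{sid}/{name}.csv"
            write_table(df, schemas[name], out / rel)
            entry["tables"][name] = rel
        if not entry["absent"]:
            entry.pop("absent")
        cfg["sources"].append(entry)
    rdir = out / "reference"
    rdir.mkdir(exist_ok=True)
    for name, df in w.reference.items():
        rel = f"reference/{name}.csv"
        write_table(df, REFERENCE_TABLES[name], out / rel)
        cfg["reference"][name] = rel
    if w.external_aggregates is not None:
        write_table(w.external_aggregates, EXTERNAL_SCHEMA, out / "external_counts.csv")
        cfg["external_aggregates"] = "external_counts.csv"
    if w.prior_year_products is not None:
        write_table(
            w.prior_year_products, BLOOD_BANK_TABLES["products"], out / "prior_year_products.csv"
        )
        cfg["prior_year_products"] = "prior_year_products.csv"
    cfg["thresholds"] = {
        k: (sorted(v) if isinstance(v, frozenset) else v)
        for k, v in w.thresholds.model_dump().items()
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False), encoding="utf-8")
    return out / "config.yaml"
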