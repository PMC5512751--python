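"""Report orchestration, rendering and CLI surface."""

from __future__ import annotations

import pytest
import yaml
from click.testing import CliRunner
from conftest import TINY

from transfuqc import SimulationParams, simulate, validate_warehouse, write_warehouse
from transfuqc.cli import main as cli_main
from transfuqc.report import read_report_csv, render_report
from transfuqc.results import ValidityReport


def test_rows_follow_step_order(clean_tiny):
    w, _ = clean_tiny
    report = validate_warehouse(w)
    steps = [r.step for r in report.rows]
    assert steps == sorted(steps)
    assert steps[0] == 1 and steps[-1] == 12


def test_report_deterministic_for_same_warehouse(clean_tiny, tmp_path):
    w, _ = clean_tiny
    r1 = validate_warehouse(w)
    r2 = validate_warehouse(w)
    render_report(r1, tmp_path / "a")
    render_report(r2, tmp_path / "b")
    assert (tmp_path / "a" / "report.csv").read_bytes() == (tmp_path / "b" / "report.csv").read_bytes()
    assert (tmp_path / "a" / "report.md").read_bytes() == (tmp_path / "b" / "report.md").read_bytes()


def test_not_evaluable_renders_as_ne_never_zero(clean_tiny, tmp_path):
    w, _ = clean_tiny
    report = validate_warehouse(w)  # X1 has no external outcome table
    render_report(report, tmp_path)
    md = (tmp_path / "report.md").read_text()
    x1_lines = [ln for ln in md.splitlines() if "| X1 |" in ln]
    assert x1_lines and "n/e" in x1_lines[0]
    assert "| 0.00 |" not in x1_lines[0]


def test_rendered_csv_reloads_for_comparison(clean_tiny, tmp_path):
    from transfuqc import compare_outcomes

    w, _ = clean_tiny
    report = validate_warehouse(w)
    render_report(report, tmp_path)
    reloaded = read_report_csv(tmp_path / "report.csv")
    table = compare_outcomes([report, reloaded])
    shared = table[table["shared"]]
    assert len(shared) > 10
    assert not shared["flagged"].any()


def test_empty_report_rejected(tmp_path):
    with pytest.raises(ValueError, match="empty report"):
        render_report(ValidityReport(rows=[]), tmp_path)


def test_unknown_format_rejected(clean_tiny, tmp_path):
    w, _ = clean_tiny
    report = validate_warehouse(w)
    with pytest.raises(ValueError, match="unknown report format"):
        render_report(report, tmp_path, formats=("html",))


def test_single_check_failure_does_not_abort(clean_tiny):
    """A poisoned table yields an errored row; the run continues."""
    w, _ = clean_tiny
    w = w.copy()
    w.reference["product_codes"] = w.reference["product_codes"].iloc[0:0]  # U1 will raise
    report = validate_warehouse(w)
    u1 = [r for r in report.rows if r.rule_id == "U1"]
    assert u1 and all(not r.evaluable for r in u1)
    assert report.get("L1").evaluable


def test_fix_postdeath_flag_notes_changes():
    params = SimulationParams(seed=4, error_rates={"postdeath_event": 0.05}, **TINY)
    w, ledger = simulate(params)
    n = ledger.count("postdeath_event")
    report = validate_warehouse(w, fix_postdeath=True)
    p8 = report.get("P8")
    assert p8.numerator == 0
    assert p8.details.get("patients_fixed") == n


def test_cli_simulate_validate_compare(tmp_path):
    runner = CliRunner()
    params = dict(seed=2, **{k: v for k, v in TINY.items()})
    params_file = tmp_path / "params.yaml"
    params_file.write_text(yaml.safe_dump(params))
    out = tmp_path / "wh"
    res = runner.invoke(cli_main, ["simulate", "--params", str(params_file), "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert (out / "error_ledger.csv").exists()
    rep_dir = tmp_path / "rep"
    res = runner.invoke(
        cli_main, ["validate", "--config", str(out / "config.yaml"), "--out", str(rep_dir)]
    )
    assert res.exit_code == 0, res.output
    assert (rep_dir / "report.csv").exists()
    assert (rep_dir / "link_map.csv").exists()
    cmp_path = tmp_path / "cmp.csv"
    res = runner.invoke(
        cli_main,
        ["compare", "--reports", str(rep_dir / "report.csv"),
         "--reports", str(rep_dir / "report.csv"), "--out", str(cmp_path)],
    )
    assert res.exit_code == 0, res.output
    assert "0 flagged" in res.output


def test_cli_strict_gate(tmp_path):
    runner = CliRunner()
    params = dict(seed=2, error_rates={"broken_product_link": 0.2}, **TINY)
    params_file = tmp_path / "params.yaml"
    params_file.write_text(yaml.safe_dump(params))
    out = tmp_path / "wh"
    assert runner.invoke(cli_main, ["simulate", "--params", str(params_file), "--out", str(out)]).exit_code == 0
    rep_dir = tmp_path / "rep"
    res = runner.invoke(
        cli_main,
        ["validate", "--config", str(out / "config.yaml"), "--out", str(rep_dir), "--strict", "95"],
    )
    assert res.exit_code == 1
    # without the gate the exit code stays 0 even with violations
    res = runner.invoke(
        cli_main, ["validate", "--config", str(out / "config.yaml"), "--out", str(rep_dir)]
    )
    assert res.exit_code == 0
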