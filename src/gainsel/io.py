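"""Readers and writers for the pipeline's delimited text interfaces.

Trait panel: columns ``name,unit,mean[,h2]``. Covariance matrices: square
tables whose first row and first column carry trait labels; rows/columns
are aligned to panel order by label, never by position, so spreadsheet
exports with shuffled trait order read identically. Scenarios: small YAML
documents. Reads auto-detect comma vs tab; writes are always comma, with
dot decimals throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Gain, Scenario, TraitPanel, ValidationError
from .economics import ScenarioReport

log = logging.getLogger("gainsel")


def _sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_panel(path: str | Path, reference: str = "DryMatter"):
    """Read a trait panel; returns (TraitPanel, h2 vector or None)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    required = {"name", "unit", "mean"}
    if not required.issubset(df.columns):
        raise ValidationError(f"panel file needs columns {sorted(required)}, got {list(df.columns)}")
    panel = TraitPanel(names=df["name"].tolist(), units=df["unit"].tolist(),
                       means=df["mean"].to_numpy(float), reference=reference)
    h2 = df["h2"].to_numpy(float) if "h2" in df.columns else None
    return panel, h2


def write_panel(panel: TraitPanel, path: str | Path, h2: np.ndarray | None = None) -> None:
    df = pd.DataFrame({"name": panel.names, "unit": panel.units, "mean": panel.means})
    if h2 is not None:
        df["h2"] = np.asarray(h2, dtype=float)
    df.to_csv(path, index=False)


def read_matrix(path: str | Path, panel: TraitPanel) -> np.ndarray:
    """Read a labelled square matrix and align it to panel order.

    Labels must cover every panel trait; extra traits are dropped with a
    warning. Raises if a panel trait is missing or any cell is non-numeric.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    labels = set(df.index)
    if set(df.columns) != labels:
        raise ValidationError(f"{path.name}: row and column labels disagree")
    missing = [t for t in panel.names if t not in labels]
    if missing:
        raise ValidationError(f"{path.name}: missing panel trait(s) {missing}")
    extra = sorted(labels - set(panel.names))
    if extra:
        log.warning("%s: dropping %d extra trait(s): %s", path.name, len(extra), extra)
    df = df.loc[list(panel.names), list(panel.names)]
    try:
        M = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path.name}: non-numeric cell ({exc})") from exc
    if M.shape != (panel.n, panel.n):
        raise ValidationError(f"{path.name}: matrix is not square after alignment")
    return M


def write_matrix(M: np.ndarray, panel: TraitPanel, path: str | Path) -> None:
    pd.DataFrame(M, index=list(panel.names), columns=list(panel.names)).to_csv(path)


def read_scenario(path: str | Path) -> Scenario:
    """Read a scenario YAML: fields ``name`` and ``gains`` (trait, value, mode)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "name" not in doc or "gains" not in doc:
        raise ValidationError(f"{path}: scenario needs 'name' and 'gains'")
    gains = []
    for entry in doc["gains"] or []:
        mode = str(entry.get("mode", "absolute"))
        if mode not in ("absolute", "percent"):
            raise ValidationError(f"{path}: unknown gain mode {mode!r}")
        gains.append(Gain(trait=str(entry["trait"]), value=float(entry["value"]), mode=mode))
    return Scenario(name=str(doc["name"]), gains=gains)


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "name": scenario.name,
        "gains": [
            {"trait": g.trait, "value": g.value, "mode": g.mode}
            for g in scenario.gains
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_report(report: ScenarioReport, outdir: str | Path) -> dict[str, Path]:
    """Write a scenario report: delimited table + machine-readable summary.

    ``<name>_report.csv`` mirrors the scenario-table layout (one row per
    trait, responses to 2 decimals and percents to 1 in the printed
    columns, unrounded values alongside) with ``#`` header lines carrying
    the scenario name, intensity, selected fraction and economic ratios.
    ``<name>_summary.json`` holds the full-precision solution. Output is
    byte-deterministic for fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sol = report.solution
    safe = report.name.replace("*", "star")
    from .engine import format_ratio  # local import avoids a cycle

    gained = [report.panel.names[j] for j in report.mask]
    ratio_str = ", ".join(
        f"{t}={format_ratio(float(report.table.set_index('trait').loc[t, 'econ_ratio']))}"
        for t in gained
    )
    table = report.table.copy()
    table["delta_2dp"] = table["delta"].round(2)
    table["pct_1dp"] = table["pct_change"].round(1)

    report_path = outdir / f"{safe}_report.csv"
    with open(report_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# scenario,{report.name}\n")
        fh.write(f"# sigma_I,{sol.sigma_I:.6f}\n")
        fh.write(f"# intensity,{sol.i:.6f}\n")
        fh.write(f"# selected_fraction,{sol.p:.6f}\n")
        fh.write(f"# selected_percent,{100 * sol.p:.2f}\n")
        fh.write(f"# econ_ratios,{ratio_str}\n")
        fh.write(f"# monetization_mode,{report.monetization_mode}\n")
        table.to_csv(fh, index=False)

    summary_path = outdir / f"{safe}_summary.json"
    summary = {
        "scenario": report.name,
        "traits": list(report.panel.names),
        "weights_b": sol.b.tolist(),
        "econ_values_a": sol.a.tolist(),
        "econ_ratios": report.table["econ_ratio"].tolist(),
        "responses": sol.Q_star.tolist(),
        "pct_change": report.table["pct_change"].tolist(),
        "sigma_I": sol.sigma_I,
        "intensity": sol.i,
        "selected_fraction": sol.p,
        "monetization_mode": report.monetization_mode,
        "monetization": report.monetization.to_dict(orient="records"),
        "economics": {
            "density": report.econ.density,
            "price": report.econ.price,
            "currency": report.econ.currency,
        },
    }
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    log.info("wrote %s and %s", report_path, summary_path)
    return {"report": report_path, "summary": summary_path}


def read_report_table(path: str | Path) -> pd.DataFrame:
    """Read back the tabular part of a written report."""
    return pd.read_csv(path, comment="#")
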