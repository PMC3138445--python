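"""CSV / YAML readers and writers for panels, truths, tables and results.

CSV dialect: comma-separated, '.' decimal, mandatory header row,
concentrations in µM as plain floats.  A response table's header is the
panel's drug names followed by one response column per cell line, so real
plate exports can replace simulated tables with no code change.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CombinationGrid, DrugPanel, TrainingDesign
from .errors import TableParseError
from .performance import PerformanceMap
from .simulate import HillParams, InteractionTerm, ResponseTable, SyntheticTruth

# ---------------------------------------------------------------------------
# panels and truths (YAML)
# ---------------------------------------------------------------------------

def panel_to_yaml(panel: DrugPanel, path: str | Path) -> None:
    doc = {
        "drugs": list(panel.drugs),
        "levels": {d: [float(v) for v in lv] for d, lv in zip(panel.drugs, panel.levels)},
        "units": panel.units,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def panel_from_yaml(path: str | Path) -> DrugPanel:
    doc = yaml.safe_load(Path(path).read_text())
    drugs = tuple(doc["drugs"])
    return DrugPanel(
        drugs=drugs,
        levels=tuple(tuple(float(v) for v in doc["levels"][d]) for d in drugs),
        units=doc.get("units", "uM"),
    )


def truth_to_yaml(truth: SyntheticTruth, path: str | Path) -> None:
    doc = {
        "label": truth.label,
        "drugs": list(truth.panel.drugs),
        "levels": {
            d: [float(v) for v in lv] for d, lv in zip(truth.panel.drugs, truth.panel.levels)
        },
        "hill": {
            d: {"ec50": p.ec50, "h": p.h, "imax": p.imax}
            for d, p in zip(truth.panel.drugs, truth.hill)
        },
        "interactions": [
            {"drugs": [truth.panel.drugs[i] for i in t.drug_subset], "gamma": t.gamma}
            for t in truth.interactions
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def truth_from_yaml(path: str | Path) -> SyntheticTruth:
    doc = yaml.safe_load(Path(path).read_text())
    drugs = tuple(doc["drugs"])
    panel = DrugPanel(
        drugs=drugs,
        levels=tuple(tuple(float(v) for v in doc["levels"][d]) for d in drugs),
    )
    return SyntheticTruth(
        panel=panel,
        hill=tuple(
            HillParams(**{k: float(v) for k, v in doc["hill"][d].items()}) for d in drugs
        ),
        interactions=tuple(
            InteractionTerm(
                drug_subset=tuple(panel.drug_index(d) for d in t["drugs"]),
                gamma=float(t["gamma"]),
            )
            for t in doc.get("interactions", [])
        ),
        label=doc["label"],
    )


# ---------------------------------------------------------------------------
# response tables (CSV)
# ---------------------------------------------------------------------------

def write_response_table(table: ResponseTable, path: str | Path) -> None:
    df = pd.DataFrame(table.conc, columns=list(table.panel.drugs))
    for name in table.cell_lines:
        df[name] = table.responses[name]
    df.to_csv(path, index=False, float_format="%.12g")


def read_response_table(path: str | Path, panel: DrugPanel) -> ResponseTable:
    """Read a response-table CSV against a known panel.

    The header must start with the panel's drug names (in order); every
    remaining column is a cell line.  Responses outside [0, 1] and
    non-numeric cells are rejected with the offending row and column named.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TableParseError(f"{path}: empty file") from None
    if df.shape[0] == 0:
        raise TableParseError(f"{path}: no data rows")
    drugs = list(panel.drugs)
    missing = [d for d in drugs if d not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing drug columns {missing}")
    cell_lines = [c for c in df.columns if c not in drugs]
    if not cell_lines:
        raise TableParseError(f"{path}: no cell-line response columns")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise TableParseError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
            )
        df[col] = vals
    for col in cell_lines:
        v = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero((v < 0) | (v > 1))
        if len(bad):
            raise TableParseError(
                f"{path}: response {v[bad[0]]!r} outside [0,1] in column {col!r}, "
                f"row {bad[0] + 2}"
            )
    return ResponseTable(
        panel=panel,
        conc=df[drugs].to_numpy(dtype=float),
        responses={c: df[c].to_numpy(dtype=float) for c in cell_lines},
    )


# ---------------------------------------------------------------------------
# grids, designs, maps and results (CSV)
# ---------------------------------------------------------------------------

def write_grid(grid: CombinationGrid, path: str | Path) -> None:
    df = pd.DataFrame(grid.conc, columns=list(grid.panel.drugs))
    df.insert(0, "row", np.arange(len(grid)))
    df.to_csv(path, index=False, float_format="%.12g")


def write_design(design: TrainingDesign, grid: CombinationGrid, path: str | Path) -> None:
    idx = design.grid_indices
    df = pd.DataFrame(grid.conc[idx], columns=list(grid.panel.drugs))
    df.insert(0, "row", idx)
    df.to_csv(path, index=False, float_format="%.12g")


def write_performance_map(pmap: PerformanceMap, path: str | Path) -> None:
    df = pd.DataFrame(pmap.grid.conc, columns=list(pmap.grid.panel.drugs))
    df["predicted_nc"] = pmap.predicted_nc
    df["predicted_cc"] = pmap.predicted_cc
    df["score"] = pmap.score
    df.to_csv(path, index=False, float_format="%.12g")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
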