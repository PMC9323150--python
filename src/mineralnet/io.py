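"""Readers and writers for the pipeline's tabular interchange formats.

Mineral tables are CSV/TSV with configurable column names (defaults match
a Mineral Evolution Database-style export: ``mineral_name``,
``ima_chemistry``, ``max_age``, ``locality_count``).  Crustal-abundance
tables are two columns (``element``, ``weight_percent``).  All writers
emit TSV with a fixed column order so outputs are byte-comparable across
runs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd

from .elements import ELEMENT_STATS_COLUMNS, MineralRecord
from .formula import FormulaParseError, parse_formula
from .network import BipartiteNetwork, CommunityPartition
from .trends import OutlierCall, RegressionResult

__all__ = [
    "DEFAULT_COLUMN_MAP",
    "read_mineral_table",
    "read_crustal_table",
    "write_element_stats",
    "write_regression_summary",
    "write_outliers",
    "write_communities",
]

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "name": "mineral_name",
    "formula": "ima_chemistry",
    "age": "max_age",
    "localities": "locality_count",
}

_REJECT_COLUMNS = ["mineral_name", "formula", "reason"]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_mineral_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    occupancy_ambiguous: bool = False,
) -> tuple[list[MineralRecord], pd.DataFrame]:
    """Read a mineral table; divert unusable rows to a rejects frame.

    Returns ``(records, rejects)`` where rejects holds one row per mineral
    whose formula was ambiguous or unparseable, with the reason.  Duplicate
    mineral names are disambiguated with a numeric suffix and warned about.
    ``occupancy_ambiguous=True`` additionally rejects comma-grouped site
    occupancies, the stricter reading of "unambiguous formula".
    """
    cols = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cols.update(column_map)
    df = _read_table(path)
    if df.empty:
        raise ValueError(f"mineral table {path} is empty")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"mineral table {path} lacks required columns {missing}")

    records: list[MineralRecord] = []
    rejects: list[dict[str, str]] = []
    seen: dict[str, int] = {}
    for _, row in df.iterrows():
        original = str(row[cols["name"]])
        if original in seen:
            seen[original] += 1
            warnings.warn(f"duplicate mineral name {original!r}; suffixing", stacklevel=2)
            name = f"{original}_{seen[original]}"
        else:
            seen[original] = 1
            name = original
        formula = str(row[cols["formula"]])
        try:
            parsed = parse_formula(formula, occupancy_ambiguous)
        except FormulaParseError as exc:
            rejects.append({"mineral_name": name, "formula": formula, "reason": str(exc)})
            continue
        if parsed.ambiguous:
            rejects.append(
                {"mineral_name": name, "formula": formula, "reason": parsed.ambiguity_reason}
            )
            continue
        age_raw = row[cols["age"]]
        age = None if pd.isna(age_raw) else float(age_raw)
        loc_raw = row[cols["localities"]]
        loc = 0 if pd.isna(loc_raw) else int(loc_raw)
        records.append(MineralRecord(name, formula, parsed.elements, loc, age))
    return records, pd.DataFrame(rejects, columns=_REJECT_COLUMNS)


def read_crustal_table(path: str | Path) -> dict[str, float]:
    """Read a crustal-abundance table into a symbol → weight-percent map."""
    df = _read_table(path)
    required = {"element", "weight_percent"}
    if not required <= set(df.columns):
        raise ValueError(f"crustal table {path} needs columns {sorted(required)}")
    out = {}
    for _, row in df.iterrows():
        value = float(row["weight_percent"])
        if value <= 0:
            raise ValueError(f"non-positive crustal abundance for {row['element']!r}")
        out[str(row["element"])] = value
    return out


def write_element_stats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stats.loc[:, ELEMENT_STATS_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def write_regression_summary(results: Mapping[str, RegressionResult], path: str | Path) -> Path:
    rows = [
        {
            "fit": name,
            "x": r.x_name,
            "y": r.y_name,
            "transform": r.transform,
            "n": r.n,
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "p_value": r.p_value,
        }
        for name, r in results.items()
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_outliers(calls: Mapping[str, list[OutlierCall]], path: str | Path) -> Path:
    rows = [
        {
            "fit": fit,
            "symbol": c.symbol,
            "direction": c.direction,
            "studentized_residual": c.studentized_residual,
        }
        for fit, fit_calls in calls.items()
        for c in fit_calls
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["fit", "symbol", "direction", "studentized_residual"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_communities(
    network: BipartiteNetwork, partition: CommunityPartition, path: str | Path
) -> Path:
    rows = [
        {
            "node": node,
            "node_type": "mineral" if node in network.mineral_nodes else "element",
            "community": comm,
        }
        for node, comm in sorted(partition.assignment.items())
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["node", "node_type", "community"]).to_csv(
        path, sep="\t", index=False
    )
    return path
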