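"""CSV/YAML readers and writers for the pipeline's tabular interfaces.

Formats:

* spectra CSV — first column ``sample_id``, remaining columns headed by the
  wavelength in nm, one row per scan;
* composition CSV — ``sample_id, oil_pct, moisture_pct, ash_pct,
  protein_pct, carbohydrate_pct``;
* integral CSV — ``sample_id, A, B, C, D, E``;
* peak-table CSV — ``retention_time, area[, analyte]``;
* standard-series CSV — ``analyte, level_ppm, response``.

All writers emit floats at 12 significant digits so write→read round-trips
are stable; readers report malformed cells with their row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import NUTRIENT_COLUMNS, SpectraSet, validate_composition_table
from .nmr import PeakIntegrals
from .quantify import PeakRecord, StandardSeries

FLOAT_FMT = "%.12g"


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"{what} file is empty: {path}")
    table = pd.read_csv(path, dtype=str)
    if table.empty:
        raise ValueError(f"{what} file has a header but no rows: {path}")
    return table


def _numeric(table: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    """Convert columns to float, naming the first offending row/column."""
    out = table.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        raw_nan = out[col].isna() | out[col].astype(str).str.strip().str.lower().isin(
            ["nd", "na", "nan", ""]
        )
        bad = converted.isna() & ~raw_nan
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{what}: non-numeric value {out[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        out[col] = converted
    return out


# ---------------------------------------------------------------------------
# spectra


def read_spectra_csv(path: str | Path) -> SpectraSet:
    table = _read_csv(path, "spectra")
    if table.columns[0] != "sample_id":
        raise ValueError("spectra CSV must start with a 'sample_id' column")
    wl_cols = list(table.columns[1:])
    if not wl_cols:
        raise ValueError("spectra CSV has no wavelength columns")
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"spectra CSV wavelength headers must be numeric: {exc}") from exc
    table = _numeric(table, wl_cols, "spectra")
    if table[wl_cols].isna().any().any():
        col = table[wl_cols].isna().any().idxmax()
        row = int(table[wl_cols].isna().any(axis=1).idxmax())
        raise ValueError(f"spectra: missing absorbance in column {col!r}, data row {row + 1}")
    return SpectraSet(wavelengths, table[wl_cols].to_numpy(float), table["sample_id"].tolist())


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    table = pd.DataFrame(spectra.absorbance, columns=[FLOAT_FMT % w for w in spectra.wavelengths])
    table.insert(0, "sample_id", spectra.sample_ids)
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# compositions


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    table = _read_csv(path, "composition")
    missing = [c for c in ("sample_id", *NUTRIENT_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"composition CSV missing columns: {missing}")
    table = _numeric(table, list(NUTRIENT_COLUMNS), "composition")
    return validate_composition_table(table)


def write_composition_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_composition_table(table)
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# NMR integrals


def read_integrals_csv(path: str | Path) -> dict[str, PeakIntegrals]:
    table = _read_csv(path, "integrals")
    required = ["sample_id", "A", "B", "C", "D", "E"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"integrals CSV missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"integrals CSV has duplicate sample ids: {dups}")
    table = _numeric(table, ["A", "B", "C", "D", "E"], "integrals")
    return {
        row["sample_id"]: PeakIntegrals(row["A"], row["B"], row["C"], row["D"], row["E"])
        for _, row in table.iterrows()
    }


def write_integrals_csv(integrals: dict[str, PeakIntegrals], path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "A": p.A, "B": p.B, "C": p.C, "D": p.D, "E": p.E}
        for sid, p in integrals.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# chromatography


def read_peaks_csv(path: str | Path) -> list[PeakRecord]:
    table = _read_csv(path, "peaks")
    missing = [c for c in ("retention_time", "area") if c not in table.columns]
    if missing:
        raise ValueError(f"peaks CSV missing columns: {missing}")
    table = _numeric(table, ["retention_time", "area"], "peaks")
    peaks = []
    for _, row in table.iterrows():
        analyte = row.get("analyte")
        if isinstance(analyte, float) and np.isnan(analyte):
            analyte = None
        peaks.append(PeakRecord(row["retention_time"], row["area"], analyte or None))
    return peaks


def read_standard_series_csv(path: str | Path) -> dict[str, StandardSeries]:
    table = _read_csv(path, "standard series")
    missing = [c for c in ("analyte", "level_ppm", "response") if c not in table.columns]
    if missing:
        raise ValueError(f"standard-series CSV missing columns: {missing}")
    table = _numeric(table, ["level_ppm", "response"], "standard series")
    out = {}
    for analyte, grp in table.groupby("analyte", sort=False):
        out[str(analyte)] = StandardSeries(
            analyte=str(analyte),
            levels_ppm=grp["level_ppm"].to_numpy(float),
            responses=grp["response"].to_numpy(float),
        )
    return out


# ---------------------------------------------------------------------------
# reports and configuration


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")


def write_report_csv(report: dict, path: str | Path) -> None:
    pd.DataFrame([report]).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_config_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise ValueError(f"config must be a YAML mapping: {path}")
    return config
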