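"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The five proximate nutrients, in canonical order. Carbohydrate closes the
#: 100 % mass budget (by-difference definition).
NUTRIENTS: tuple[str, ...] = ("oil", "moisture", "ash", "protein", "carbohydrate")

#: Column names used in composition tables (CSV and DataFrame).
NUTRIENT_COLUMNS: tuple[str, ...] = tuple(f"{n}_pct" for n in NUTRIENTS)


@dataclass
class SpectraSet:
    """A set of absorbance scans on a common wavelength grid.

    Parameters
    ----------
    wavelengths : (p,) array
        Strictly increasing, (near-)evenly spaced grid in nm.
    absorbance : (n_scans, p) array
        One row per scan.
    sample_ids : list of str
        One label per scan; replicate scans of the same sample share a label.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        dw = np.diff(self.wavelengths)
        if self.wavelengths.size > 1 and not np.all(dw > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths.size > 2 and not np.allclose(dw, dw[0], rtol=1e-6):
            raise ValueError("wavelength grid must be evenly spaced")
        if not self.sample_ids:
            self.sample_ids = [f"scan{i}" for i in range(self.absorbance.shape[0])]
        if len(self.sample_ids) != self.absorbance.shape[0]:
            raise ValueError("one sample_id required per scan")

    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[0]

    @property
    def step(self) -> float:
        """Grid spacing in nm."""
        if self.wavelengths.size < 2:
            return float("nan")
        return float(self.wavelengths[1] - self.wavelengths[0])

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Return a copy carrying new absorbance values on the same grid."""
        return SpectraSet(self.wavelengths.copy(), absorbance, list(self.sample_ids))

    def mean_by_sample(self) -> "SpectraSet":
        """Average replicate scans sharing a sample id (first-appearance order)."""
        order: list[str] = []
        for sid in self.sample_ids:
            if sid not in order:
                order.append(sid)
        ids = np.asarray(self.sample_ids)
        means = np.vstack([self.absorbance[ids == sid].mean(axis=0) for sid in order])
        return SpectraSet(self.wavelengths.copy(), means, order)


def validate_composition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a composition table's schema and closure invariant.

    Requires a ``sample_id`` column plus the five ``*_pct`` nutrient columns;
    rows must sum to 100 % within 1e-6.
    """
    missing = [c for c in ("sample_id", *NUTRIENT_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"composition table missing columns: {missing}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    totals = table[list(NUTRIENT_COLUMNS)].sum(axis=1)
    bad = np.abs(totals - 100.0) > 1e-6
    if bad.any():
        rows = table.index[bad].tolist()
        raise ValueError(f"composition rows do not sum to 100%: rows {rows}")
    return table
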