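"""Proximate composition formulas: Kjeldahl nitrogen, gravimetric fractions,
and carbohydrate by difference.

The five-fraction budget (oil, moisture, ash, protein, carbohydrate) sums to
100 % of sample mass by construction when carbohydrate closes the budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

NITROGEN_ATOMIC_MASS = 14.007  # g/mol

#: Conventional nitrogen-to-protein conversion factor. The default used by
#: :func:`protein_percent` is 1.0 (the Kjeldahl nitrogen % reported directly
#: as protein); pass 6.25 for the generic food-protein convention.
CONVENTIONAL_PROTEIN_FACTOR = 6.25


@dataclass
class TitrationMeasurement:
    """A Kjeldahl back-titration record.

    ml_sample / ml_blank: titrant volumes (mL) for sample and blank;
    normality: titrant equivalents/L (typically 0.05 N NaOH);
    sample_mass_mg: digested sample mass in mg.
    """

    ml_sample: float
    ml_blank: float
    normality: float
    sample_mass_mg: float

    def __post_init__(self) -> None:
        if self.sample_mass_mg <= 0:
            raise ValueError("sample mass must be positive")
        if self.normality <= 0:
            raise ValueError("titrant normality must be positive")
        if self.ml_sample < 0 or self.ml_blank < 0:
            raise ValueError("titrant volumes must be >= 0")


@dataclass
class GravimetricRecord:
    """Container masses (g) before and after a gravimetric step."""

    container_mass: float
    container_plus_sample_mass: float
    container_plus_residue_mass: float

    def __post_init__(self) -> None:
        if self.container_plus_sample_mass <= self.container_mass:
            raise ValueError("sample mass must be positive")
        if not (
            self.container_mass
            <= self.container_plus_residue_mass
            <= self.container_plus_sample_mass
        ):
            raise ValueError("residue mass must lie between 0 and the sample mass")


def nitrogen_percent(t: TitrationMeasurement) -> float:
    """Kjeldahl nitrogen as % of sample mass.

    (ml_sample - ml_blank) * N * 14.007 * 100 / sample_mass_mg. A sample
    titre below the blank yields a negative value, flagged as a quality
    warning rather than clamped.
    """
    value = (
        (t.ml_sample - t.ml_blank) * t.normality * NITROGEN_ATOMIC_MASS * 100.0
        / t.sample_mass_mg
    )
    if value < 0:
        warnings.warn(
            f"nitrogen {value:.4g}% < 0 (sample titre below blank); check the "
            "titration record", stacklevel=2,
        )
    return value


def protein_percent(nitrogen_pct: float, conversion_factor: float = 1.0) -> float:
    """Protein as nitrogen % times a conversion factor (default 1.0)."""
    if conversion_factor <= 0:
        raise ValueError("conversion factor must be positive")
    return nitrogen_pct * conversion_factor


def carbohydrate_by_difference(
    moisture_pct: float, protein_pct: float, oil_pct: float, ash_pct: float
) -> float:
    """Carbohydrate % = 100 - (moisture + protein + oil + ash).

    A negative result (budget over 100 %) signals inconsistent inputs; it is
    flagged with a warning but returned unclamped so batch processing can
    carry on and the caller can triage the replicate.
    """
    for name, v in (
        ("moisture", moisture_pct), ("protein", protein_pct),
        ("oil", oil_pct), ("ash", ash_pct),
    ):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} = {v}% outside [0, 100]")
    carb = 100.0 - (moisture_pct + protein_pct + oil_pct + ash_pct)
    if carb < 0:
        warnings.warn(
            f"carbohydrate by difference is {carb:.3f}% < 0: the other four "
            "fractions exceed 100%", stacklevel=2,
        )
    return carb


def mass_fraction_percent(g: GravimetricRecord, mode: str = "residue") -> float:
    """Gravimetric mass fraction in %.

    ``mode="residue"``: residue mass / sample mass * 100 (ash; oil when the
    extracted oil is what remains in the cup). ``mode="loss"``: lost mass /
    sample mass * 100 (moisture by drying).
    """
    sample = g.container_plus_sample_mass - g.container_mass
    residue = g.container_plus_residue_mass - g.container_mass
    if mode == "residue":
        return residue / sample * 100.0
    if mode == "loss":
        return (sample - residue) / sample * 100.0
    raise ValueError(f"unknown mode {mode!r}; expected 'residue' or 'loss'")
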