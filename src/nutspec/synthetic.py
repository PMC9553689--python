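"""Synthetic instrument data with the statistical structure the analysis assumes.

Generates (a) proximate composition tables closing to 100 %, (b) NIR spectra
as Beer-Lambert-style linear mixtures of Gaussian pure-component band spectra
with baseline drift, multiplicative scatter, and additive noise, (c) NMR peak
integrals exactly consistent with the fatty-acid class equations for a chosen
profile, and (d) linear detector standard series. Everything downstream is
thereby testable without instrument access, and noise-free outputs obey exact
linear-recovery oracles.

All randomness flows through explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NUTRIENT_COLUMNS, NUTRIENTS, SpectraSet, validate_composition_table
from .nmr import FattyAcidProfile, PeakIntegrals
from .quantify import StandardSeries

# ---------------------------------------------------------------------------
# wavelength grid

#: Default scanner grid: 900 nm start, 7 nm bandwidth, 115 points (ends at
#: 1698 nm, the last full step below 1700 nm).
DEFAULT_GRID = (900.0, 1700.0, 7.0)


def wavelength_grid(start: float = 900.0, stop: float = 1700.0, step: float = 7.0) -> np.ndarray:
    """Closed wavelength grid from ``start`` stepping by ``step`` up to ``stop``."""
    if step <= 0:
        raise ValueError("grid step must be positive")
    return np.arange(start, stop + 0.5 * step, step)[: int((stop - start) // step) + 1]


# ---------------------------------------------------------------------------
# component band specs


@dataclass
class ComponentBandSpec:
    """Gaussian band description of one nutrient's pure-component NIR spectrum."""

    nutrient: str
    band_centers: list[float]    # nm
    band_widths: list[float]     # Gaussian sigma, nm
    band_amplitudes: list[float]  # unitless, > 0

    def __post_init__(self) -> None:
        if self.nutrient not in NUTRIENTS:
            raise ValueError(f"unknown nutrient {self.nutrient!r}; expected one of {NUTRIENTS}")
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_amplitudes)):
            raise ValueError("band centers, widths, and amplitudes must have equal lengths")
        if any(not 900 <= c <= 1700 for c in self.band_centers):
            raise ValueError("band centers must lie within [900, 1700] nm")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError("band widths must be positive")
        if any(a <= 0 for a in self.band_amplitudes):
            raise ValueError("band amplitudes must be positive")

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        """The pure-component spectrum: sum of Gaussian bands on the grid."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for c, w, a in zip(self.band_centers, self.band_widths, self.band_amplitudes):
            out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return out


def _bands(nutrient: str, centers: list[float], width: float = 25.0) -> ComponentBandSpec:
    return ComponentBandSpec(nutrient, centers, [width] * len(centers), [1.0] * len(centers))


#: Default pure-component band centers, one entry per nutrient, taken from
#: the wavelengths at which each nutrient's NIR regression coefficient peaks
#: (C-H combination bands for oil/carbohydrate, O-H for moisture, N-H for
#: protein, and the organic matrix correlates of mineral ash). Widths default
#: to 25 nm so neighbouring bands overlap, as real seed/nut spectra do.
DEFAULT_BANDS: dict[str, ComponentBandSpec] = {
    "oil": _bands("oil", [929, 1039, 1208, 1386, 1700]),
    "moisture": _bands("moisture", [977, 1107, 1338, 1473]),
    "ash": _bands("ash", [1149, 1305, 1411, 1494]),
    "protein": _bands("protein", [1153, 1308, 1411, 1494, 1673]),
    "carbohydrate": _bands("carbohydrate", [929, 1007, 1211, 1442, 1584, 1692]),
}


@dataclass
class NoiseSpec:
    """Instrumental artefact magnitudes for spectrum generation.

    baseline drift is a per-scan random line (slope in absorbance/nm, offset
    in absorbance); scatter is a per-scan multiplicative factor 1 + N(0, sd);
    additive noise is i.i.d. Gaussian per wavelength. Defaults are typical
    short-wave NIR magnitudes; set all sds to 0 for exact linear spectra.
    """

    baseline_slope_sd: float = 1e-5
    baseline_offset_sd: float = 0.01
    scatter_multiplier_sd: float = 0.05
    additive_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_slope_sd", "baseline_offset_sd",
                     "scatter_multiplier_sd", "additive_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISE_FREE = NoiseSpec(0.0, 0.0, 0.0, 0.0, 0)


@dataclass
class SyntheticDatasetSpec:
    """A full synthetic study design.

    ``composition_ranges`` maps each nutrient to its (min %, max %) sampling
    range; carbohydrate closes each row's budget to exactly 100 %.
    ``replicates_per_sample`` is the number of repeat scans per sample
    (default 18, the usual repetition count for handheld NIR of ground
    samples).
    """

    n_samples: int
    composition_ranges: dict[str, tuple[float, float]]
    replicates_per_sample: int = 18
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if self.replicates_per_sample < 1:
            raise ValueError("need at least 1 replicate scan per sample")
        missing = [n for n in NUTRIENTS if n not in self.composition_ranges]
        if missing:
            raise ValueError(f"composition_ranges missing nutrients: {missing}")
        for n, (lo, hi) in self.composition_ranges.items():
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"range for {n} must satisfy 0 <= min <= max <= 100")
        mins = sum(r[0] for r in self.composition_ranges.values())
        maxs = sum(r[1] for r in self.composition_ranges.values())
        if not (mins <= 100 + 1e-9 and maxs >= 100 - 1e-9):
            raise ValueError(
                f"infeasible ranges: sum of mins {mins} must be <= 100 <= sum of maxes {maxs}"
            )


#: Ranges spanning the observed per-sample extremes of the six-seed study
#: (oil 0.2-61 %, moisture 3-14.4 %, ash 1.7-5.2 %, protein 15.5-48 %,
#: carbohydrate 12.4-63.7 %).
STUDY_COMPOSITION_RANGES: dict[str, tuple[float, float]] = {
    "oil": (0.2, 61.0),
    "moisture": (3.0, 14.4),
    "ash": (1.7, 5.2),
    "protein": (15.5, 48.0),
    "carbohydrate": (12.4, 63.7),
}


def generate_compositions(spec: SyntheticDatasetSpec) -> pd.DataFrame:
    """Draw per-sample compositions; each row sums to exactly 100 %.

    Oil, moisture, ash, and protein are uniform within their ranges;
    carbohydrate is the closure term 100 - sum, and draws whose closure falls
    outside the carbohydrate range are rejected and redrawn. Reproducible
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    free = [n for n in NUTRIENTS if n != "carbohydrate"]
    lo = np.array([spec.composition_ranges[n][0] for n in free])
    hi = np.array([spec.composition_ranges[n][1] for n in free])
    c_lo, c_hi = spec.composition_ranges["carbohydrate"]
    rows = np.empty((spec.n_samples, 4))
    filled = 0
    for _ in range(10_000):
        draw = rng.uniform(lo, hi, size=(max(spec.n_samples * 2, 64), 4))
        carb = 100.0 - draw.sum(axis=1)
        ok = draw[(carb >= c_lo - 1e-12) & (carb <= c_hi + 1e-12)]
        take = min(ok.shape[0], spec.n_samples - filled)
        rows[filled:filled + take] = ok[:take]
        filled += take
        if filled == spec.n_samples:
            break
    else:
        raise ValueError(
            "could not draw compositions whose closure term stays within the "
            "carbohydrate range; widen the ranges"
        )
    table = pd.DataFrame(rows, columns=[f"{n}_pct" for n in free])
    table["carbohydrate_pct"] = 100.0 - table.sum(axis=1)
    table.insert(0, "sample_id", [f"S{i:03d}" for i in range(spec.n_samples)])
    return validate_composition_table(table[["sample_id", *NUTRIENT_COLUMNS]])


def generate_nir_spectra(
    compositions: pd.DataFrame,
    bands: dict[str, ComponentBandSpec] | None = None,
    noise: NoiseSpec = NOISE_FREE,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    replicates_per_sample: int = 1,
) -> SpectraSet:
    """Linear-mixture NIR spectra for a composition table.

    Each scan is ``sum_n (fraction_n/100 * pure_spectrum_n) * (1 + scatter)
    + baseline line + additive noise``; with all noise sds at zero the
    spectra are exactly linear in composition.
    """
    validate_composition_table(compositions)
    bands = DEFAULT_BANDS if bands is None else bands
    missing = [n for n in NUTRIENTS if n not in bands]
    if missing:
        raise ValueError(f"no component band spec for nutrients: {missing}")
    wl = wavelength_grid(*grid)
    pure = np.vstack([bands[n].spectrum(wl) for n in NUTRIENTS])  # (5, p)
    fractions = compositions[list(NUTRIENT_COLUMNS)].to_numpy() / 100.0
    clean = fractions @ pure  # (n_samples, p)

    rng = np.random.default_rng(noise.seed)
    n_scans = clean.shape[0] * replicates_per_sample
    scans = np.repeat(clean, replicates_per_sample, axis=0)
    ids = [
        sid for sid in compositions["sample_id"] for _ in range(replicates_per_sample)
    ]
    scatter = rng.normal(0.0, noise.scatter_multiplier_sd, size=(n_scans, 1))
    slope = rng.normal(0.0, noise.baseline_slope_sd, size=(n_scans, 1))
    offset = rng.normal(0.0, noise.baseline_offset_sd, size=(n_scans, 1))
    eps = rng.normal(0.0, noise.additive_noise_sd, size=(n_scans, wl.size))
    out = scans * (1.0 + scatter) + slope * (wl - wl[0]) + offset + eps
    return SpectraSet(wl, out, ids)


def integrals_from_profile(profile: FattyAcidProfile, scale: float = 1.0) -> PeakIntegrals:
    """Invert the NMR class equations: integrals that map back to ``profile``.

    ``scale`` sets the alpha-carbonyl integral D (the overall signal level);
    the terminal-methyl pool A + B is set equal to D. Round-trips with
    :func:`nutspec.nmr.profile_from_integrals` to machine precision.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    w3, w6, w9 = profile.omega3_pct, profile.omega6_pct, profile.omega9_pct
    D = float(scale)
    B = D * w3 / 100.0
    A = D - B
    C = 2.0 * D * (w3 + w6 + w9) / 100.0
    E = D * (2.0 * w3 + w6) / 100.0
    return PeakIntegrals(A=A, B=B, C=C, D=D, E=E)


def generate_standard_series(
    analyte: str,
    true_slope: float,
    true_intercept: float,
    levels_ppm: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StandardSeries:
    """A linear detector standard series with Gaussian response noise."""
    levels = np.asarray(levels_ppm, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("standard levels must be strictly positive")
    if np.unique(levels).size < 2:
        raise ValueError("need at least 2 distinct standard levels")
    rng = np.random.default_rng(seed)
    responses = true_slope * levels + true_intercept + rng.normal(0.0, noise_sd, levels.size)
    return StandardSeries(analyte=analyte, levels_ppm=levels, responses=responses)
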