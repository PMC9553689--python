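"""Linear calibration-curve quantification of chromatographic analytes.

Covers the eight-sugar HPLC-ELSD panel and LC-MS/MS resveratrol: fitting an
ordinary least-squares standard curve (response = slope * ppm + intercept),
assigning sample peaks to analytes by retention time, back-calculating
extract concentrations, and converting to an amount per 100 g of sample.

The evaporative light-scattering detector has a known power-law response;
it is modelled here as linear to match the linear standard curves typically
fitted in practice, with a log-log option for when curvature matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardSeries:
    """A calibration standard series: concentration levels vs detector response."""

    analyte: str
    levels_ppm: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.levels_ppm = np.asarray(self.levels_ppm, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.levels_ppm.shape != self.responses.shape:
            raise ValueError("levels and responses must align")
        if np.unique(self.levels_ppm).size < 2:
            raise ValueError("need at least 2 distinct concentration levels")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")


@dataclass
class CalibrationCurve:
    """A fitted linear standard curve with its valid concentration range."""

    analyte: str
    slope: float          # response per ppm
    intercept: float      # response
    r_squared: float
    range_ppm: tuple[float, float]
    log_log: bool = False

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R^2 out of [0, 1]: {self.r_squared}")


@dataclass
class PeakRecord:
    """One chromatographic peak: retention time (min) and integrated area."""

    retention_time: float
    area: float
    analyte: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError(f"retention time must be positive, got {self.retention_time}")
        if self.area < 0:
            raise ValueError(f"area must be >= 0, got {self.area}")


@dataclass
class AnalyteLibrary:
    """Expected retention times (min) per analyte for one chromatographic method."""

    retention_times: dict[str, float]

    def __post_init__(self) -> None:
        times = list(self.retention_times.values())
        if any(t <= 0 for t in times):
            raise ValueError("retention times must be positive")
        if len(set(times)) != len(times):
            raise ValueError("retention times must be unique within a method")

    def check_tolerance(self, tolerance: float) -> None:
        """Reject a matching tolerance whose windows would overlap."""
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        times = np.sort(np.array(list(self.retention_times.values())))
        gaps = np.diff(times)
        if gaps.size and gaps.min() < 2 * tolerance:
            raise ValueError(
                f"tolerance {tolerance} min makes library windows overlap "
                f"(closest analytes are {gaps.min():.3f} min apart)"
            )


#: Sugar panel retention times (min) on the hydrophilic HPLC-ELSD method;
#: monosaccharides (and sorbitol) elute before disaccharides.
SUGAR_LIBRARY = AnalyteLibrary(
    {
        "xylose": 9.34,
        "fructose": 10.53,
        "sorbitol": 11.84,
        "galactose": 12.69,
        "glucose": 13.45,
        "sucrose": 19.08,
        "lactose": 20.92,
        "maltose": 21.65,
    }
)

#: Resveratrol on the LC-MS/MS method. The MRM identity (precursor 227 m/z,
#: fragments 143 and 185 m/z) is carried as metadata only.
RESVERATROL_LIBRARY = AnalyteLibrary({"resveratrol": 3.050})
RESVERATROL_MSMS = {"precursor_mz": 227, "fragment_mz": (143, 185)}

DEFAULT_RT_TOLERANCE_MIN = 0.15


def fit_calibration(series: StandardSeries, log_log: bool = False) -> CalibrationCurve:
    """Fit response = slope * ppm + intercept by ordinary least squares.

    With ``log_log=True`` the fit is log(response) vs log(ppm) (the power-law
    ELSD model); slope and intercept then live on the log scale.
    """
    x, y = series.levels_ppm, series.responses
    if log_log:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-log fit requires positive levels and responses")
        x, y = np.log(x), np.log(y)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        analyte=series.analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        range_ppm=(float(series.levels_ppm.min()), float(series.levels_ppm.max())),
        log_log=log_log,
    )


def assign_peaks(
    peaks: list[PeakRecord],
    library: AnalyteLibrary,
    tolerance: float = DEFAULT_RT_TOLERANCE_MIN,
) -> list[PeakRecord]:
    """Assign each peak to the nearest library analyte within ``tolerance`` min.

    Unmatched peaks are returned unlabelled. When two peaks compete for one
    analyte the nearer wins and the other stays unassigned.
    """
    library.check_tolerance(tolerance)
    out = [replace(p, analyte=None) for p in peaks]
    candidates = []  # (distance, peak index, analyte)
    for i, p in enumerate(out):
        for analyte, rt in library.retention_times.items():
            d = abs(p.retention_time - rt)
            if d <= tolerance:
                candidates.append((d, i, analyte))
    used_peaks: set[int] = set()
    used_analytes: set[str] = set()
    for d, i, analyte in sorted(candidates):
        if i in used_peaks or analyte in used_analytes:
            continue
        out[i] = replace(out[i], analyte=analyte)
        used_peaks.add(i)
        used_analytes.add(analyte)
    return out


def back_calculate_ppm(curve: CalibrationCurve, area: float) -> float:
    """Invert the standard curve: extract concentration in ppm (mg/L)."""
    if curve.log_log:
        if area <= 0:
            return 0.0
        return float(np.exp((np.log(area) - curve.intercept) / curve.slope))
    if curve.slope == 0:
        raise ValueError(f"curve for {curve.analyte} has zero slope")
    return float((area - curve.intercept) / curve.slope)


def quantify_sample(
    peaks: list[PeakRecord],
    curves: dict[str, CalibrationCurve],
    sample_mass_g: float,
    extract_volume_ml: float,
    basis: str = "flour",
    dilution: float = 1.0,
) -> pd.DataFrame:
    """Quantify assigned peaks and convert to amount per 100 g of sample.

    ppm in the extract is (area - intercept)/slope; the amount per 100 g is
    ppm (mg/L) * volume (L) * dilution / mass (g) * 100, reported in
    mg/100 g for ``basis="flour"`` (sugars) or ug/100 g for ``basis="oil"``
    (resveratrol). Negative back-calculated concentrations are flagged and
    reported as 0; concentrations outside the fitted standard range are
    flagged as extrapolated.
    """
    if sample_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("sample mass and extract volume must be positive")
    if basis not in ("flour", "oil"):
        raise ValueError(f"unknown basis {basis!r}; expected 'flour' or 'oil'")
    unit = "mg/100 g flour" if basis == "flour" else "ug/100 g oil"
    rows = []
    for p in peaks:
        if p.analyte is None:
            continue
        if p.analyte not in curves:
            raise ValueError(f"no calibration curve for assigned analyte {p.analyte!r}")
        curve = curves[p.analyte]
        ppm = back_calculate_ppm(curve, p.area)
        flags = []
        if ppm < 0:
            warnings.warn(
                f"{p.analyte}: back-calculated concentration {ppm:.4g} ppm < 0; "
                "reported as 0", stacklevel=2,
            )
            flags.append("below_zero")
            ppm = 0.0
        lo, hi = curve.range_ppm
        if ppm < lo:
            flags.append("below_range")
        elif ppm > hi:
            flags.append("above_range")
        mg = ppm * (extract_volume_ml / 1000.0) * dilution  # mg in extract
        per_100g = mg / sample_mass_g * 100.0
        if basis == "oil":
            per_100g *= 1000.0  # mg -> ug
        rows.append(
            {
                "analyte": p.analyte,
                "retention_time": p.retention_time,
                "area": p.area,
                "ppm_extract": ppm,
                "amount_per_100g": per_100g,
                "unit": unit,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "analyte", "retention_time", "area", "ppm_extract",
            "amount_per_100g", "unit", "flags",
        ],
    )
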