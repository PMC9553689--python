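"""Fatty-acid class quantification from 1H-NMR peak integrals.

Proton-counting background: in a triacylglycerol spectrum the terminal methyl
protons of omega-3 chains resonate apart from those of all other chains, the
allylic methylenes flank every C=C double bond, the alpha-carbonyl methylene
is common to every acyl chain, and a further multiplet tracks
polyunsaturation. Writing A (non-omega-3 terminal methyl), B (omega-3
terminal methyl), C (allylic), D (alpha-carbonyl methylene) and E
(polyunsaturation-diagnostic) for the five integrals, the class percentages
of total fatty acids are

    omega-3 % = 100 * B / (A + B)
    omega-6 % = 100 * (E/D - 2*B/(A + B))
    omega-9 % = 100 * (C/(2*D) - E/D + B/(A + B))
    SFA %     = 100 * (1 - C/(2*D))

which sum to 100 identically for any valid integrals, and
PUFA = omega-3 + omega-6. Whether E is best read as the olefinic or the
bis-allylic region is an assignment question that does not affect the
algebra; only the stoichiometric ratios above are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PeakIntegrals:
    """The five diagnostic 1H-NMR integrals, in arbitrary consistent units.

    A: terminal methyl protons of non-omega-3 acyl chains.
    B: omega-3 terminal methyl protons.
    C: allylic protons (CH2 adjacent to one C=C).
    D: alpha-carbonyl methylene protons (one CH2 per acyl chain).
    E: polyunsaturation-diagnostic protons.
    """

    A: float
    B: float
    C: float
    D: float
    E: float

    def __post_init__(self) -> None:
        for name in "ABCDE":
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"integral {name} must be finite and >= 0, got {v}")
        if self.D <= 0:
            raise ValueError("integral D (alpha-carbonyl CH2) must be positive")
        if self.A + self.B <= 0:
            raise ValueError("A + B (terminal methyl) must be positive")
        if self.E > self.C * (1 + 1e-9) and self.C > 0 or (self.C == 0 and self.E > 0):
            warnings.warn(
                f"E ({self.E}) exceeds C ({self.C}): integrals imply more "
                "polyunsaturation protons than allylic protons", stacklevel=2,
            )
        if self.C > 2 * self.D * (1 + 1e-9):
            warnings.warn(
                f"C/(2D) = {self.C / (2 * self.D):.4f} > 1: unsaturation index "
                "exceeds one double bond per chain equivalent", stacklevel=2,
            )


@dataclass
class FattyAcidProfile:
    """Fatty-acid class composition as % of total fatty acids.

    omega3 + omega6 + omega9 + sfa = 100; pufa = omega3 + omega6.
    ``omega6_to_omega3`` is None when no omega-3 is present.
    """

    omega3_pct: float
    omega6_pct: float
    omega9_pct: float
    sfa_pct: float

    def __post_init__(self) -> None:
        vals = (self.omega3_pct, self.omega6_pct, self.omega9_pct, self.sfa_pct)
        if any(v < -1e-9 or v > 100 + 1e-9 for v in vals):
            raise ValueError(f"class percentages must lie in [0, 100]: {vals}")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise ValueError(f"class percentages must sum to 100, got {sum(vals)}")

    @property
    def pufa_pct(self) -> float:
        return self.omega3_pct + self.omega6_pct

    @property
    def omega6_to_omega3(self) -> float | None:
        if self.omega3_pct == 0:
            return None
        return self.omega6_pct / self.omega3_pct


def _clamp(value: float, what: str) -> float:
    if value < 0:
        warnings.warn(f"{what} = {value:.6g} < 0; clamped to 0 (noisy integrals)", stacklevel=3)
        return 0.0
    return value


def omega3_pct(p: PeakIntegrals) -> float:
    """Omega-3 % of total fatty acids: 100*B/(A+B)."""
    return 100.0 * p.B / (p.A + p.B)


def omega6_pct(p: PeakIntegrals) -> float:
    """Omega-6 % of total fatty acids: 100*(E/D - 2B/(A+B))."""
    return _clamp(100.0 * (p.E / p.D - 2.0 * p.B / (p.A + p.B)), "omega-6 %")


def omega9_pct(p: PeakIntegrals) -> float:
    """Omega-9 % of total fatty acids: 100*(C/(2D) - E/D + B/(A+B))."""
    return _clamp(
        100.0 * (p.C / (2.0 * p.D) - p.E / p.D + p.B / (p.A + p.B)), "omega-9 %"
    )


def sfa_pct(p: PeakIntegrals) -> float:
    """Saturated fatty acid % of total: 100*(1 - C/(2D))."""
    return _clamp(100.0 * (1.0 - p.C / (2.0 * p.D)), "SFA %")


def profile_from_integrals(p: PeakIntegrals) -> FattyAcidProfile:
    """Assemble the four-class profile from one set of integrals.

    Clamped components are renormalised so the profile still closes to 100 %.
    """
    vals = np.array([omega3_pct(p), omega6_pct(p), omega9_pct(p), sfa_pct(p)])
    total = vals.sum()
    if abs(total - 100.0) > 1e-9:  # only after clamping
        vals = vals * (100.0 / total)
    return FattyAcidProfile(*vals)


# ---------------------------------------------------------------------------
# FAME (GC) class aggregation

#: Class membership of the methyl esters quantified by GC. Monounsaturated
#: esters (oleate) belong to neither the saturated nor the polyunsaturated sum.
FAME_CLASSES: dict[str, str] = {
    "methyl_butyrate": "saturated",
    "methyl_palmitate": "saturated",
    "methyl_stearate": "saturated",
    "methyl_arachidate": "saturated",
    "methyl_behenate": "saturated",
    "methyl_oleate": "monounsaturated",
    "methyl_linoleate": "polyunsaturated",
    "methyl_gamma_linolenate": "polyunsaturated",
}


def aggregate_fame_classes(
    table: pd.DataFrame, classes: dict[str, str] = FAME_CLASSES
) -> pd.DataFrame:
    """Sum per-sample ester percentages into SFA % and PUFA % columns.

    ``table``: rows = samples, columns = ester names; NaN means the ester was
    not detected in that sample and is excluded (not zero-imputed silently —
    the sum simply skips it). Unknown ester columns raise.
    """
    unknown = [c for c in table.columns if c not in classes]
    if unknown:
        raise ValueError(f"esters without a class flag: {unknown}")
    if table.shape[1] == 0 or table.shape[0] == 0:
        warnings.warn("empty FAME table: SFA and PUFA default to 0", stacklevel=2)
        return pd.DataFrame({"sfa_pct": 0.0, "pufa_pct": 0.0}, index=table.index)
    if (table.fillna(0) < 0).any().any():
        raise ValueError("ester percentages must be >= 0")
    sat = [c for c in table.columns if classes[c] == "saturated"]
    poly = [c for c in table.columns if classes[c] == "polyunsaturated"]
    return pd.DataFrame(
        {
            "sfa_pct": table[sat].sum(axis=1, skipna=True) if sat else 0.0,
            "pufa_pct": table[poly].sum(axis=1, skipna=True) if poly else 0.0,
        },
        index=table.index,
    )
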