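"""Replicate aggregation, one-way ANOVA, pairwise significance, and report
assembly in the style of a nutrition comparison table (mean ± sd per sample
with significance marks at alpha = 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ReplicateSet:
    """Repeat measurements of one analyte on one sample."""

    sample_id: str
    analyte: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"{self.sample_id}/{self.analyte}: no replicate values")


@dataclass
class ComparisonResult:
    """A pairwise significance test between two samples for one analyte."""

    sample_a: str
    sample_b: str
    analyte: str
    p_value: float
    significant: bool


def summarize(r: ReplicateSet) -> tuple[float, float | None]:
    """Arithmetic mean and sample (n-1) sd; sd is None for a single value."""
    mean = float(r.values.mean())
    sd = float(r.values.std(ddof=1)) if r.values.size >= 2 else None
    return mean, sd


def anova_oneway(groups: list[ReplicateSet]) -> tuple[float, float]:
    """Classical one-way ANOVA over the groups' replicate values.

    Returns the F statistic and its p-value. Identical groups give F = 0 and
    p = 1 (no between-group variance).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.sample_id} needs >= 2 replicate values")
    f, p = stats.f_oneway(*[g.values for g in groups])
    if np.isnan(f):  # zero within-group variance and zero between-group variance
        f, p = 0.0, 1.0
    return float(f), float(p)


def pairwise_compare(
    groups: list[ReplicateSet], alpha: float = 0.05, method: str = "tukey"
) -> list[ComparisonResult]:
    """Test all unordered sample pairs for a mean difference.

    ``method="tukey"`` uses the Tukey honestly-significant-difference test
    (family-wise control over the whole pair set); ``method="t"`` uses
    unadjusted equal-variance two-sample t tests.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    analyte = groups[0].analyte
    results: list[ComparisonResult] = []
    if method == "tukey":
        res = stats.tukey_hsd(*[g.values for g in groups])
        for i, j in combinations(range(len(groups)), 2):
            p = float(res.pvalue[i, j])
            results.append(
                ComparisonResult(groups[i].sample_id, groups[j].sample_id,
                                 analyte, p, p < alpha)
            )
    elif method == "t":
        for i, j in combinations(range(len(groups)), 2):
            if groups[i].sample_id == groups[j].sample_id:
                p = 1.0
            else:
                p = float(stats.ttest_ind(groups[i].values, groups[j].values,
                                          equal_var=True).pvalue)
            results.append(
                ComparisonResult(groups[i].sample_id, groups[j].sample_id,
                                 analyte, p, p < alpha)
            )
    else:
        raise ValueError(f"unknown pairwise method {method!r}; expected 'tukey' or 't'")
    return results


def build_report(
    summaries: pd.DataFrame,
    comparisons: list[ComparisonResult] | None = None,
) -> pd.DataFrame:
    """Assemble a nutrition report table: analytes x samples of "mean±sd".

    ``summaries`` columns: sample_id, analyte, mean, sd (sd may be NaN), and
    optionally unit. A cell is starred when its sample differs significantly
    from every other sample for that analyte (the usual reading of per-cell
    significance marks). NaN means → "nd" (not detected). Comparisons whose
    samples are absent from the summaries raise, listing the orphans.
    """
    required = {"sample_id", "analyte", "mean"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    comparisons = comparisons or []
    known = set(summaries["sample_id"])
    orphans = sorted(
        {s for c in comparisons for s in (c.sample_a, c.sample_b)} - known
    )
    if orphans:
        raise ValueError(f"comparisons reference unknown sample ids: {orphans}")

    starred: set[tuple[str, str]] = set()
    for analyte in summaries["analyte"].unique():
        per = [c for c in comparisons if c.analyte == analyte]
        if not per:
            continue
        samples = sorted({s for c in per for s in (c.sample_a, c.sample_b)})
        for s in samples:
            mine = [c for c in per if s in (c.sample_a, c.sample_b)
                    and c.sample_a != c.sample_b]
            if mine and all(c.significant for c in mine):
                starred.add((analyte, s))

    def fmt(row: pd.Series) -> str:
        if pd.isna(row["mean"]):
            return "nd"
        star = "*" if (row["analyte"], row["sample_id"]) in starred else ""
        sd = row.get("sd", np.nan)
        if pd.isna(sd):
            return f"{row['mean']:.3f}{star}"
        return f"{row['mean']:.3f}±{sd:.3f}{star}"

    out = summaries.copy()
    out["cell"] = out.apply(fmt, axis=1)
    table = out.pivot(index="analyte", columns="sample_id", values="cell")
    # preserve input order on both axes
    table = table.reindex(index=pd.unique(summaries["analyte"]),
                          columns=pd.unique(summaries["sample_id"]))
    return table


def report_to_text(table: pd.DataFrame, footnotes: list[str] | None = None) -> str:
    """Human-readable rendering of a report table with optional footnotes."""
    lines = [table.to_string()]
    for note in footnotes or []:
        lines.append(note)
    return "\n".join(lines)
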