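"""Published reference measurements for six edible seed/nut samples.

These small tables come from a published chromatographic and spectroscopic
survey of candlenut (cnd), peanut (pnt), sesame (ssm), sunflower (snf),
sacha inchi press residue (inc), and black bean (bkb) — plus red bean (rdb)
in the proximate block. They ship with the package as worked-example inputs:
every derived quantity (class sums, grand means, ratios, totals) is computed
from them at run time, never stored.

``None``/NaN cells mean the analyte was not detected; they are excluded from
sums and means, not imputed as zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLES = ("cnd", "pnt", "ssm", "snf", "inc", "bkb")


def nmr_fatty_acid_profiles() -> pd.DataFrame:
    """NMR-derived fatty-acid class percentages (rows = samples).

    Columns omega3/omega6/omega9/sfa sum to 100 per sample; omega-3 is NaN
    where the omega-3 methyl signal was not detected.
    """
    data = {
        #        omega3   omega6   omega9    sfa
        "cnd": (23.310, 42.046, 22.480, 12.164),
        "pnt": (np.nan, 36.040, 41.102, 22.858),
        "ssm": (np.nan, 43.591, 37.489, 18.920),
        "snf": (np.nan, 58.752, 21.712, 19.536),
        "inc": (44.050, 33.792, 10.842, 11.316),
        "bkb": (10.232, 45.457, 26.796, 17.515),
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=["omega3_pct", "omega6_pct", "omega9_pct", "sfa_pct"]
    )


def nmr_published_pufa() -> pd.Series:
    """The PUFA percentages printed alongside the NMR class rows."""
    return pd.Series(
        {"cnd": 65.356, "pnt": 36.040, "ssm": 43.591, "snf": 58.752,
         "inc": 77.842, "bkb": 55.688}
    )


def fame_table() -> pd.DataFrame:
    """GC (FID) fatty-acid methyl ester percentages (rows = samples)."""
    cols = [
        "methyl_butyrate", "methyl_palmitate", "methyl_stearate", "methyl_oleate",
        "methyl_linoleate", "methyl_arachidate", "methyl_gamma_linolenate",
        "methyl_behenate",
    ]
    nd = np.nan
    data = {
        "cnd": (nd, 6.341, 3.022, 22.887, 43.003, nd, 24.747, nd),
        "pnt": (0.391, 17.529, 1.761, 23.455, 50.366, 2.006, 0.923, 3.567),
        "ssm": (nd, 9.481, 5.205, 38.422, 46.345, 0.554, nd, nd),
        "snf": (nd, 12.051, 9.206, 38.467, 36.939, 0.600, 1.102, 1.632),
        "inc": (nd, 4.152, 2.944, 8.070, 40.139, nd, 44.301, 0.395),
        "bkb": (nd, 10.328, 3.885, 25.455, 51.627, nd, 8.704, nd),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def fame_published_classes() -> pd.DataFrame:
    """The SFA/PUFA summary rows printed with the FAME table."""
    data = {
        "cnd": (9.364, 67.750),
        "pnt": (25.254, 51.289),
        "ssm": (15.240, 46.345),
        "snf": (23.488, 38.040),
        "inc": (7.491, 84.440),
        "bkb": (14.213, 60.331),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=["sfa_pct", "pufa_pct"])


def sugar_concentrations() -> pd.DataFrame:
    """Mean sugar content per sample, mg/100 g flour (rows = samples)."""
    cols = ["xylose", "fructose", "sorbitol", "galactose", "glucose",
            "sucrose", "lactose", "maltose"]
    data = {
        "cnd": (81.610, 95.100, 163.700, 223.000, 96.430, 1429.500, 132.780, 30.630),
        "pnt": (94.510, 462.270, 158.720, 533.750, 563.860, 116.660, 136.860, 34.990),
        "ssm": (80.970, 83.090, 171.990, 210.260, 77.080, 1506.260, 132.500, 33.140),
        "snf": (81.770, 80.140, 158.730, 209.760, 71.330, 2416.240, 179.480, 34.500),
        "inc": (84.270, 967.780, 158.520, 226.530, 961.220, 2485.080, 141.220, 30.890),
        "bkb": (80.830, 79.100, 158.570, 209.630, 64.310, 158.740, 131.680, 30.780),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def resveratrol_concentrations() -> pd.Series:
    """Mean resveratrol per sample, ug/100 g oil."""
    return pd.Series(
        {"cnd": 1.066, "pnt": 1.457, "ssm": 2.746, "snf": 1.888,
         "inc": 2.467, "bkb": 1.269}
    )


def proximate_means() -> pd.DataFrame:
    """NIR-predicted proximate means, % of mass (rows = samples incl. rdb)."""
    cols = ["oil_pct", "moisture_pct", "ash_pct", "protein_pct", "carbohydrate_pct"]
    data = {
        "cnd": (60.956, 4.329, 1.720, 20.521, 12.438),
        "pnt": (39.733, 7.146, 2.370, 15.586, 35.186),
        "ssm": (56.288, 3.550, 2.726, 21.543, 15.945),
        "snf": (44.390, 3.086, 4.440, 28.549, 19.542),
        "inc": (20.941, 10.485, 5.187, 47.865, 15.519),
        "bkb": (4.274, 8.927, 4.293, 31.398, 51.109),
        "rdb": (0.237, 14.388, 2.703, 18.952, 63.687),
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


def nir_oil_prediction_metrics() -> pd.DataFrame:
    """Published oil-calibration prediction metrics (SEP in %, RPD unitless).

    Used to check internal consistency of the RPD definition: the holdout
    reference sd implied by SEP * RPD must agree between the two models
    fitted on the same holdout.
    """
    return pd.DataFrame(
        {"sep": [1.724, 1.690], "rpd": [13.208, 13.492]}, index=["pls", "pcr"]
    )
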