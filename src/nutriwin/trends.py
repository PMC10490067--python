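"""Per-window nutrient trend classification.

Within each detected age window a linear model is fit per nutrient and the
association is labelled by the sign and significance of its slope:
increasing (slope > 0, p < 0.05), decreasing (slope < 0, p < 0.05), or
stable otherwise (p = 0.05 exactly counts as stable; 'below 0.05' is
strict).  Two regressand conventions are supported:

- ``mwf_on_nutrient`` (default): MWF ~ 1 + log(age) + intake over the
  window's children; the slope is the intake coefficient.
- ``intake_on_age``: intake ~ 1 + log(age); the slope is the age
  coefficient (an intake-dynamics reading of the same question).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .detect import AgeWindow

MODES = ("mwf_on_nutrient", "intake_on_age")
MIN_WINDOW_ROWS = 5


@dataclass(frozen=True)
class TrendClassification:
    window_start: int
    window_end: int
    nutrient: str
    mode: str
    slope: float
    p: float
    label: str          # increasing | decreasing | stable | NA
    reason: str = ""


def trend_label(slope: float, p: float, alpha: float = 0.05) -> str:
    """Pure labelling rule: significant positive slope -> increasing,
    significant negative -> decreasing, otherwise stable."""
    if np.isnan(slope) or np.isnan(p):
        return "NA"
    if p < alpha and slope > 0:
        return "increasing"
    if p < alpha and slope < 0:
        return "decreasing"
    return "stable"


def classify_trend(table: CohortTable, window: AgeWindow, nutrient: str,
                   mode: str = "mwf_on_nutrient") -> TrendClassification:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    ages = table.ages
    mask = np.array([window.contains_age(a) for a in ages])
    sub = table.data.loc[mask]
    base = dict(window_start=window.start_month, window_end=window.end_month,
                nutrient=nutrient, mode=mode)
    if mask.sum() < MIN_WINDOW_ROWS:
        return TrendClassification(slope=np.nan, p=np.nan, label="NA",
                                   reason=f"only {int(mask.sum())} children in window",
                                   **base)
    age = sub["age_months"].to_numpy(float)
    intake = sub[nutrient].to_numpy(float)
    if np.ptp(intake) == 0 and mode == "mwf_on_nutrient":
        return TrendClassification(slope=np.nan, p=np.nan, label="NA",
                                   reason="constant intake in window", **base)
    log_age = np.log(age)
    if mode == "mwf_on_nutrient":
        X = sm.add_constant(np.column_stack([log_age, intake]))
        fit = sm.OLS(sub["mwf"].to_numpy(float), X).fit()
        slope, p = float(fit.params[2]), float(fit.pvalues[2])
    else:
        X = sm.add_constant(log_age)
        fit = sm.OLS(intake, X).fit()
        slope, p = float(fit.params[1]), float(fit.pvalues[1])
    return TrendClassification(slope=slope, p=p, label=trend_label(slope, p),
                               **base)


def trend_table(table: CohortTable, windows: list[AgeWindow],
                mode: str = "mwf_on_nutrient") -> pd.DataFrame:
    """classify_trend over windows x non-excluded nutrients, as a frame."""
    rows = [classify_trend(table, w, nutrient, mode)
            for w in windows for nutrient in table.nutrients]
    return pd.DataFrame([r.__dict__ for r in rows])
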