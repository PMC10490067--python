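"""Cohort and nutrient-dictionary data model.

A cohort is a tidy cross-sectional table: one row per child with an age in
months, a regional myelin water fraction (MWF, a unitless fraction in (0,1)
averaged over a social-brain mask), and one column of daily intake per
nutrient.  The nutrient dictionary labels each nutrient with a category and
unit and carries the exclusion flags used to reduce the master list of 88
nutrients to the 63 analysed ones (redundant aggregates, non-essential amino
acids, and safety-flagged amino acids are removed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.4375

CATEGORIES = frozenset({
    "mineral", "vitamin", "amino_acid", "fatty_acid", "polar_lipid",
    "hmo", "carotenoid", "protein_fraction", "carbohydrate", "other",
})
EXCLUSION_REASONS = frozenset({
    "redundant_aggregate", "non_essential_amino_acid", "safety_concern", "none",
})

META_COLUMNS = ["subject_id", "age_months", "mwf"]

AGE_MIN_VALID, AGE_MAX_VALID = 1.0, 72.0


class CohortValidationError(ValueError):
    """Raised when a cohort or dictionary violates its schema."""


@dataclass(frozen=True)
class NutrientDictionary:
    """Nutrient metadata: name, category, unit, and exclusion flags."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"name", "category", "unit", "excluded", "exclusion_reason"}
        missing = required - set(t.columns)
        if missing:
            raise CohortValidationError(
                f"dictionary missing columns: {sorted(missing)}")
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].tolist()
            raise CohortValidationError(f"duplicate nutrient names: {dup}")
        bad_cat = set(t["category"]) - CATEGORIES
        if bad_cat:
            raise CohortValidationError(f"unknown categories: {sorted(bad_cat)}")
        bad_reason = set(t["exclusion_reason"]) - EXCLUSION_REASONS
        if bad_reason:
            raise CohortValidationError(
                f"unknown exclusion reasons: {sorted(bad_reason)}")
        mismatch = t["excluded"].astype(bool) != (t["exclusion_reason"] != "none")
        if mismatch.any():
            raise CohortValidationError(
                "excluded flag must be true exactly when exclusion_reason != "
                f"'none'; offending nutrients: {t.loc[mismatch, 'name'].tolist()}")

    @property
    def names(self) -> list[str]:
        return self.table["name"].tolist()

    @property
    def included_names(self) -> list[str]:
        return self.table.loc[~self.table["excluded"].astype(bool), "name"].tolist()

    @property
    def excluded_names(self) -> list[str]:
        return self.table.loc[self.table["excluded"].astype(bool), "name"].tolist()

    def names_in_categories(self, categories) -> list[str]:
        cats = set(categories)
        keep = self.table["category"].isin(cats) & ~self.table["excluded"].astype(bool)
        return self.table.loc[keep, "name"].tolist()

    def unit_of(self, name: str) -> str:
        row = self.table.loc[self.table["name"] == name]
        if row.empty:
            raise KeyError(f"nutrient {name!r} not in dictionary")
        return row["unit"].iloc[0]


def default_dictionary() -> NutrientDictionary:
    """The packaged 88-entry master dictionary (25 entries flagged excluded)."""
    ref = importlib.resources.files("nutriwin.data") / "default_dictionary.csv"
    with importlib.resources.as_file(ref) as path:
        t = pd.read_csv(path, dtype={"name": str}, keep_default_na=False)
    t["excluded"] = t["excluded"].map({"True": True, "False": False, True: True,
                                       False: False})
    return NutrientDictionary(t)


@dataclass
class CohortTable:
    """Age-sorted cross-sectional cohort plus its nutrient dictionary.

    ``data`` columns: subject_id, age_months, mwf, then one column per
    nutrient named in the attached dictionary.  Rows are sorted by
    (age_months, subject_id) so sliding-window scans are deterministic.
    """

    data: pd.DataFrame
    dictionary: NutrientDictionary = field(default_factory=default_dictionary)

    def __post_init__(self) -> None:
        self.data = _validate_cohort_frame(self.data, self.dictionary)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def nutrients(self) -> list[str]:
        dict_names = set(self.dictionary.names)
        return [c for c in self.data.columns
                if c not in META_COLUMNS and c in dict_names]

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_months"].to_numpy(float)

    @property
    def mwf(self) -> np.ndarray:
        return self.data["mwf"].to_numpy(float)

    def intake(self, nutrient: str) -> np.ndarray:
        return self.data[nutrient].to_numpy(float)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.dictionary)


def _validate_cohort_frame(df: pd.DataFrame,
                           dictionary: NutrientDictionary) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort missing columns: {missing}")
    df = df.copy()
    dict_names = set(dictionary.names)
    nutrient_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in nutrient_cols if c not in dict_names]
    if unknown:
        raise CohortValidationError(
            f"intake columns not in dictionary: {unknown}")

    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortValidationError(f"duplicate subject_ids: {dup}")

    for col in ["age_months", "mwf", *nutrient_cols]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise CohortValidationError(
                f"non-numeric value in column {col!r} at row {row}")
        if values.isna().any():
            row = df.index[values.isna()][0]
            raise CohortValidationError(
                f"missing value in column {col!r} at row {row}")
        df[col] = values.astype(float)

    ages = df["age_months"]
    bad = (ages < AGE_MIN_VALID) | (ages > AGE_MAX_VALID)
    if bad.any():
        row = df.index[bad][0]
        raise CohortValidationError(
            f"age_months outside [{AGE_MIN_VALID}, {AGE_MAX_VALID}] at row "
            f"{row} (value {ages[row]})")
    mwf = df["mwf"]
    bad = (mwf <= 0) | (mwf >= 1)
    if bad.any():
        row = df.index[bad][0]
        raise CohortValidationError(
            f"mwf outside (0,1) at row {row} (value {mwf[row]})")
    for col in nutrient_cols:
        bad = df[col] < 0
        if bad.any():
            row = df.index[bad][0]
            raise CohortValidationError(
                f"negative intake in column {col!r} at row {row} "
                f"(value {df.loc[row, col]})")

    df = df.sort_values(["age_months", "subject_id"], kind="mergesort")
    return df.reset_index(drop=True)


def load_dictionary(path) -> NutrientDictionary:
    t = pd.read_csv(path, dtype={"name": str}, keep_default_na=False)
    if "excluded" in t.columns:
        t["excluded"] = t["excluded"].map(
            {"True": True, "False": False, True: True, False: False})
    return NutrientDictionary(t)


def load_cohort(cohort_csv_path, dictionary_csv_path=None,
                age_unit: str = "months") -> CohortTable:
    """Read and validate a cohort CSV (one row per child).

    ``age_unit='days'`` converts the age column to months on load
    (30.4375 days per month).
    """
    dictionary = (default_dictionary() if dictionary_csv_path is None
                  else load_dictionary(dictionary_csv_path))
    df = pd.read_csv(cohort_csv_path)
    if age_unit == "days":
        df["age_months"] = pd.to_numeric(df["age_months"]) / DAYS_PER_MONTH
    elif age_unit != "months":
        raise ValueError(f"age_unit must be 'months' or 'days', got {age_unit!r}")
    return CohortTable(df, dictionary)


def write_cohort(table: CohortTable, path) -> None:
    table.data.to_csv(path, index=False)


def apply_nutrient_exclusions(table: CohortTable) -> CohortTable:
    """Drop the intake columns flagged excluded in the dictionary.

    Row count and the subject/age/mwf columns are untouched; the original
    table is not modified.  Raises if nothing would remain.
    """
    keep = [n for n in table.nutrients if n in set(table.dictionary.included_names)]
    if not keep:
        raise CohortValidationError(
            "all nutrients are excluded: empty predictor set")
    df = table.data[META_COLUMNS + keep].copy()
    return CohortTable(df, table.dictionary)


def summarize_intakes(table: CohortTable, windows) -> pd.DataFrame:
    """Per window x nutrient intake summary: n, mean, sample SD, min, max.

    ``windows`` is a sequence of objects with ``start_month``/``end_month``
    (closed month ranges) or (start, end) tuples.  A window with no children
    yields rows with n=0 and NA statistics; n=1 yields SD = NA.
    """
    rows = []
    ages = table.ages
    for w in windows:
        start, end = _window_bounds(w)
        mask = (ages >= start - 0.5) & (ages < end + 0.5)
        sub = table.data.loc[mask]
        for nutrient in table.nutrients:
            x = sub[nutrient].to_numpy(float)
            n = len(x)
            rows.append({
                "window_start": start,
                "window_end": end,
                "nutrient": nutrient,
                "n": n,
                "mean": float(np.mean(x)) if n else np.nan,
                "sd": float(np.std(x, ddof=1)) if n > 1 else np.nan,
                "min": float(np.min(x)) if n else np.nan,
                "max": float(np.max(x)) if n else np.nan,
            })
    return pd.DataFrame(rows)


def _window_bounds(w) -> tuple[float, float]:
    if hasattr(w, "start_month"):
        return float(w.start_month), float(w.end_month)
    start, end = w
    return float(start), float(end)


def summary_report(summary: pd.DataFrame) -> pd.DataFrame:
    """Reshape a summarize_intakes frame into printed-table form:
    Nutrient, Mean (SD), Min-Max per window block."""
    out = summary.copy()

    def fmt(row):
        if row["n"] == 0:
            return pd.Series({"Mean (SD)": "NA", "Min-Max": "NA"})
        sd = "NA" if np.isnan(row["sd"]) else f"{row['sd']:.1f}"
        return pd.Series({
            "Mean (SD)": f"{row['mean']:.1f} ({sd})",
            "Min-Max": f"{row['min']:.1f}-{row['max']:.1f}",
        })

    formatted = out.apply(fmt, axis=1)
    return pd.concat(
        [out[["window_start", "window_end", "nutrient", "n"]], formatted],
        axis=1)
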