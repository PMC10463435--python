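"""BMI classification and city-level overweight prevalence.

BMI = weight(kg) / height(m)^2, categorized by the Chinese national
standard with lower-inclusive bounds:

    underweight (0, 18.5) | normal [18.5, 24) | overweight [24, 28) | obese [28, inf)

"Overweight prevalence" counts BMI >= 24 (overweight + obese), matching
the usual BMI < 24 / >= 24 dichotomy for this population; a strict
[24, 28) variant is available via ``include_obese=False``.  The study
population is adults aged 45+, split into middle_aged [45, 60) and
elderly [60, inf).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "BMI_BREAKS",
    "BMI_CATEGORIES",
    "OVERWEIGHT_CUTOFF",
    "compute_bmi",
    "classify_bmi",
    "assign_age_group",
    "aggregate_prevalence",
]

logger = logging.getLogger(__name__)

BMI_BREAKS = (18.5, 24.0, 28.0)
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")
OVERWEIGHT_CUTOFF = 24.0
OBESITY_CUTOFF = 28.0
MIN_AGE = 45.0
ELDERLY_AGE = 60.0


def compute_bmi(height_cm, weight_kg, record_id=None):
    """Body-mass index in kg/m^2 from height (cm) and weight (kg).

    Scalar or vectorized.  Non-positive height or weight raises a
    validation error naming the offending record id(s).
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    bad = (h <= 0) | (w <= 0) | ~np.isfinite(h) | ~np.isfinite(w)
    if np.any(bad):
        if record_id is not None:
            ids = np.asarray(record_id)[bad] if np.ndim(record_id) else record_id
            raise ValueError(f"non-positive height/weight for record(s): {ids}")
        raise ValueError("non-positive height or weight")
    bmi = w / (h / 100.0) ** 2
    return float(bmi) if np.ndim(height_cm) == 0 and np.ndim(weight_kg) == 0 else bmi


def classify_bmi(bmi):
    """BMI category label(s); boundaries are lower-inclusive."""
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ValueError("BMI must be positive and finite")
    idx = np.searchsorted(BMI_BREAKS, b, side="right")
    cats = np.array(BMI_CATEGORIES, dtype=object)[idx]
    return str(cats) if np.ndim(bmi) == 0 else cats


def assign_age_group(age):
    """'middle_aged' for ages [45, 60), 'elderly' for 60+.

    Ages below the study floor of 45 raise; batch exclusion with a logged
    count happens in `aggregate_prevalence`.
    """
    a = np.asarray(age, dtype=float)
    if np.any(a < MIN_AGE):
        raise ValueError(f"age below study floor {MIN_AGE}")
    groups = np.where(a >= ELDERLY_AGE, "elderly", "middle_aged")
    return str(groups) if np.ndim(age) == 0 else groups.astype(object)


def aggregate_prevalence(
    individuals: pd.DataFrame,
    include_obese: bool = True,
    average_duplicates: bool = False,
) -> pd.DataFrame:
    """Aggregate individual records to city x age-group overweight prevalence.

    Parameters
    ----------
    individuals : DataFrame with columns id, city_id, age, height_cm, weight_kg.
    include_obese : count BMI >= 24 (default); False restricts to [24, 28).
    average_duplicates : average height/weight over repeated measurements of
        the same id (multi-wave surveys) before classification.

    Returns one row per (city_id, age_group) cell with at least one member:
    columns city_id, age_group, n, n_overweight, prevalence.  Records below
    age 45 are excluded with a logged count; empty cells are omitted rather
    than reported as zero.
    """
    required = {"id", "city_id", "age", "height_cm", "weight_kg"}
    missing = required - set(individuals.columns)
    if missing:
        raise ValueError(f"individuals table is missing columns: {sorted(missing)}")
    df = individuals.copy()
    if df.empty:
        raise ValueError("no individual records supplied")

    if average_duplicates:
        df = (df.groupby(["id", "city_id"], as_index=False)
                .agg(age=("age", "mean"), height_cm=("height_cm", "mean"),
                     weight_kg=("weight_kg", "mean")))

    under_floor = df["age"] < MIN_AGE
    if under_floor.any():
        logger.info("excluded %d record(s) below age %.0f", under_floor.sum(), MIN_AGE)
        df = df[~under_floor]
    if df.empty:
        raise ValueError("no records at or above the study age floor")

    bmi = compute_bmi(df["height_cm"].to_numpy(), df["weight_kg"].to_numpy(),
                      record_id=df["id"].to_numpy())
    if include_obese:
        overweight = bmi >= OVERWEIGHT_CUTOFF
    else:
        overweight = (bmi >= OVERWEIGHT_CUTOFF) & (bmi < OBESITY_CUTOFF)

    out = (pd.DataFrame({
            "city_id": df["city_id"].to_numpy(),
            "age_group": assign_age_group(df["age"].to_numpy()),
            "overweight": overweight.astype(int)})
           .groupby(["city_id", "age_group"], as_index=False)
           .agg(n=("overweight", "size"), n_overweight=("overweight", "sum")))
    out["prevalence"] = out["n_overweight"] / out["n"]
    return out
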