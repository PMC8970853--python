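"""Cohort data model: tables, CSV round-trip, state labeling and patient filters.

A cohort consists of two aligned tables:

``profiles``
    one row per patient with basic covariates
    (``patient_id, sex, age, weight, height, bmi``).

``series``
    long format, one row per patient x time step, carrying one column per
    monitored variable plus the labeling channels ``map`` (mmHg), ``lactate``
    (mmol/l) and ``drug_present`` (0/1).

Time is an abstract integer index starting at 1; units are fixed by the
schema (mmHg, mmol/l, kg, m) and never inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError, StateError

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["patient_id", "sex", "age", "weight", "height", "bmi"]
SERIES_INDEX_COLUMNS = ["patient_id", "time"]
LABEL_CHANNELS = ["map", "lactate", "drug_present"]
LABEL_COLUMNS = ["patient_id", "time", "label"]

#: rule-label values
SAFE = "safe"
FAILURE = "failure"

MAP_THRESHOLD = 65.0
LACTATE_THRESHOLD = 2.0


@dataclass
class Cohort:
    """Profiles plus monitored series, with optional per-time rule labels."""

    profiles: pd.DataFrame
    series: pd.DataFrame
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.profiles = self.profiles.reset_index(drop=True)
        self.series = self.series.reset_index(drop=True)
        if self.labels is not None:
            self.labels = self.labels.reset_index(drop=True)

    @property
    def patient_ids(self) -> list:
        return list(self.profiles["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.profiles)

    def monitored_variables(self) -> list[str]:
        """Monitored-variable columns; ``map`` doubles as a labeling channel."""
        skip = set(SERIES_INDEX_COLUMNS) | {"lactate", "drug_present"}
        return [c for c in self.series.columns if c not in skip]

    def has_labeling_channels(self) -> bool:
        return all(c in self.series.columns for c in LABEL_CHANNELS)

    def patient_series(self, patient_id) -> pd.DataFrame:
        sub = self.series[self.series["patient_id"] == patient_id]
        return sub.sort_values("time").reset_index(drop=True)

    def validate(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.profiles.columns]
        if missing:
            raise SchemaError(f"profiles table is missing columns: {missing}")
        missing = [c for c in SERIES_INDEX_COLUMNS if c not in self.series.columns]
        if missing:
            raise SchemaError(f"series table is missing columns: {missing}")
        prof_ids = set(self.profiles["patient_id"])
        series_ids = set(self.series["patient_id"])
        orphans = sorted(series_ids - prof_ids)
        if orphans:
            raise IntegrityError(f"series rows reference unknown patient ids: {orphans[:10]}")
        unmatched = sorted(prof_ids - series_ids)
        if unmatched:
            raise IntegrityError(f"profiles without any series rows: {unmatched[:10]}")
        if self.profiles["patient_id"].duplicated().any():
            raise IntegrityError("duplicate patient_id in profiles")
        if self.series.duplicated(subset=SERIES_INDEX_COLUMNS).any():
            raise IntegrityError("duplicate (patient_id, time) rows in series")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], path: str) -> pd.DataFrame:
    """Coerce columns to float; a non-numeric *non-blank* cell is a parse error."""
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(
                f"{path}: non-numeric value {out.loc[bad, col].iloc[0]!r} "
                f"in column '{col}' at file row {row}"
            )
        out[col] = coerced
    return out


def read_cohort(profiles_path, series_path, labels_path=None) -> Cohort:
    """Read a cohort from CSV, dropping any patient with a missing value.

    Missing values in either table drop the whole patient (no imputation);
    the dropped counts are logged.
    """
    profiles = pd.read_csv(profiles_path)
    series = pd.read_csv(series_path)

    missing = [c for c in PROFILE_COLUMNS if c not in profiles.columns]
    if missing:
        raise SchemaError(f"{profiles_path}: missing columns {missing}")
    missing = [c for c in SERIES_INDEX_COLUMNS if c not in series.columns]
    if missing:
        raise SchemaError(f"{series_path}: missing columns {missing}")

    profiles = _coerce_numeric(
        profiles, [c for c in PROFILE_COLUMNS if c != "patient_id"], str(profiles_path)
    )
    value_cols = [c for c in series.columns if c not in SERIES_INDEX_COLUMNS]
    series = _coerce_numeric(series, value_cols + ["time"], str(series_path))
    series["time"] = series["time"].astype(int)

    bad_profiles = profiles[PROFILE_COLUMNS].isna().any(axis=1)
    bad_series_ids = set(series.loc[series.isna().any(axis=1), "patient_id"])
    drop_ids = set(profiles.loc[bad_profiles, "patient_id"]) | bad_series_ids
    if drop_ids:
        n_rows = int(bad_profiles.sum()) + int(series.isna().any(axis=1).sum())
        logger.info(
            "dropped %d patients (%d rows with missing values)", len(drop_ids), n_rows
        )
        profiles = profiles[~profiles["patient_id"].isin(drop_ids)]
        series = series[~series["patient_id"].isin(drop_ids)]

    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path)
        missing = [c for c in LABEL_COLUMNS if c not in labels.columns]
        if missing:
            raise SchemaError(f"{labels_path}: missing columns {missing}")
        labels = labels[~labels["patient_id"].isin(drop_ids)]

    cohort = Cohort(profiles=profiles, series=series, labels=labels)
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> dict[str, Path]:
    """Write profiles/series (and labels when present) as CSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["profiles"] = out / "profiles.csv"
    cohort.profiles.to_csv(paths["profiles"], index=False)
    paths["series"] = out / "series.csv"
    cohort.series.to_csv(paths["series"], index=False)
    if cohort.labels is not None:
        paths["labels"] = out / "labels.csv"
        cohort.labels.to_csv(paths["labels"], index=False)
    return paths


def label_states(
    series: pd.DataFrame,
    map_threshold: float = MAP_THRESHOLD,
    lactate_threshold: float = LACTATE_THRESHOLD,
) -> pd.DataFrame:
    """Pointwise rule label: failure iff MAP <= 65 mmHg, or vasoactive/inotropic
    drugs are present and lactate exceeds 2 mmol/l; otherwise safe.

    The MAP comparison is inclusive; the lactate comparison is strict.
    Returns a ``patient_id, time, label`` table aligned row-by-row with the
    input (labeling is pointwise, so row order is irrelevant).
    """
    missing = [c for c in LABEL_CHANNELS if c not in series.columns]
    if missing:
        raise SchemaError(f"series is missing labeling channels: {missing}")
    for c in LABEL_CHANNELS:
        if not pd.api.types.is_numeric_dtype(series[c]):
            raise SchemaError(f"labeling channel '{c}' is not numeric")
    failure = (series["map"] <= map_threshold) | (
        (series["drug_present"].astype(bool)) & (series["lactate"] > lactate_threshold)
    )
    return pd.DataFrame(
        {
            "patient_id": series["patient_id"].to_numpy(),
            "time": series["time"].to_numpy(),
            "label": np.where(failure.to_numpy(), FAILURE, SAFE),
        }
    )


def filter_multistate_patients(cohort: Cohort) -> Cohort:
    """Keep only patients whose label series contains both classes.

    Single-label patients carry no ranking information and are excluded from
    AUC measurement. Idempotent; logs kept/dropped counts.
    """
    if cohort.labels is None:
        raise StateError("cohort has no labels; run label_states first")
    n_classes = cohort.labels.groupby("patient_id")["label"].nunique()
    keep = set(n_classes[n_classes >= 2].index)
    dropped = cohort.n_patients - len(keep)
    logger.info("multistate filter: kept %d patients, dropped %d", len(keep), dropped)
    return Cohort(
        profiles=cohort.profiles[cohort.profiles["patient_id"].isin(keep)],
        series=cohort.series[cohort.series["patient_id"].isin(keep)],
        labels=cohort.labels[cohort.labels["patient_id"].isin(keep)],
    )
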