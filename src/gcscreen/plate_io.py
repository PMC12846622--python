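"""Reading and writing plate-reader tables, well annotations and result files.

The on-disk dialect is deliberately minimal: plain CSV with a mandatory
header row. Plate tables are wide (one ``time_min`` column followed by one
column per well); annotations map wells to samples and experimental roles.
Vendor-native exports (Varioskan XML/xlsx and friends) are converted
upstream and are out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIME_COLUMN = "time_min"

#: Allowed values for the ``role`` field of a well annotation.
ROLES = ("blank", "control", "infected")


class PlateParseError(ValueError):
    """Raised when a plate or annotation file cannot be parsed."""


class PlateValidationError(ValueError):
    """Raised when a parsed file violates a structural invariant."""


@dataclass
class PlateRun:
    """One plate-reader run: a shared time grid plus per-well OD600 series.

    Attributes
    ----------
    times:
        Measurement times in minutes, strictly increasing.
    readings:
        Mapping well id -> OD600 series, each the same length as ``times``.
    plate_id:
        Free-text identifier of the plate/run.
    """

    times: np.ndarray
    readings: dict[str, np.ndarray]
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise PlateValidationError("need at least two time points")
        if not np.all(np.isfinite(self.times)):
            raise PlateValidationError("non-finite time values")
        if np.any(np.diff(self.times) <= 0):
            raise PlateValidationError("time column must be strictly increasing")
        clean = {}
        for well, series in self.readings.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.times.shape:
                raise PlateValidationError(
                    f"well {well}: series length {arr.size} != {self.times.size} time points"
                )
            if not np.all(np.isfinite(arr)):
                raise PlateValidationError(f"well {well}: non-finite OD values")
            clean[well] = arr
        self.readings = clean

    @property
    def wells(self) -> list[str]:
        return list(self.readings)

    @property
    def n_times(self) -> int:
        return int(self.times.size)


@dataclass
class WellAnnotation:
    """Metadata for a single well.

    ``species`` is ground truth used exclusively for post hoc evaluation;
    no clustering operation in this package accepts it.
    """

    well: str
    sample_id: str
    role: str
    species: Optional[str] = None
    moi: Optional[float] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateValidationError(
                f"well {self.well}: unknown role {self.role!r}; expected one of {ROLES}"
            )
        if self.moi is not None and not self.moi > 0:
            raise PlateValidationError(f"well {self.well}: moi must be positive")


def read_plate_table(path: str | Path) -> PlateRun:
    """Read a wide-format plate CSV into a :class:`PlateRun`.

    The first column must be ``time_min`` (minutes); every remaining column
    is one well's OD600 series.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise PlateParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise PlateParseError(f"{path}: expected a time column plus >=1 well column")
    if df.columns[0] != TIME_COLUMN:
        raise PlateParseError(
            f"{path}: first column must be {TIME_COLUMN!r}, got {df.columns[0]!r}"
        )
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # 1-based + header
        raise PlateParseError(f"{path}: missing value in row {bad}")
    times = df[TIME_COLUMN].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise PlateValidationError(f"{path}: time column must be strictly increasing")
    readings = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return PlateRun(times=times, readings=readings, plate_id=path.stem)


def read_annotations(
    path: str | Path, run: Optional[PlateRun] = None
) -> list[WellAnnotation]:
    """Read a well-annotation CSV.

    Columns: ``well,sample_id,role`` plus optional ``species,moi,replicate``.
    If ``run`` is given, annotations naming wells absent from the plate are
    reported with a warning (partial plates are normal and not an error).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str, "sample_id": str})
    required = {"well", "sample_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PlateParseError(f"{path}: missing columns {sorted(missing)}")
    if df["well"].duplicated().any():
        dupes = sorted(df.loc[df["well"].duplicated(), "well"])
        raise PlateValidationError(f"{path}: duplicate well ids {dupes}")
    annotations = []
    for _, row in df.iterrows():
        moi = row.get("moi")
        rep = row.get("replicate")
        species = row.get("species")
        annotations.append(
            WellAnnotation(
                well=str(row["well"]),
                sample_id=str(row["sample_id"]),
                role=str(row["role"]),
                species=None if pd.isna(species) else str(species),
                moi=None if moi is None or pd.isna(moi) else float(moi),
                replicate=None if rep is None or pd.isna(rep) else int(rep),
            )
        )
    if run is not None:
        orphans = [a.well for a in annotations if a.well not in run.readings]
        if orphans:
            logger.warning("annotations name wells absent from plate: %s", orphans)
    return annotations


def write_plate_table(run: PlateRun, path: str | Path) -> None:
    """Write a :class:`PlateRun` back to the wide CSV dialect."""
    df = pd.DataFrame({TIME_COLUMN: run.times})
    for well, series in run.readings.items():
        df[well] = series
    df.to_csv(path, index=False, float_format="%.10g")


def write_annotations(annotations: Iterable[WellAnnotation], path: str | Path) -> None:
    rows = [
        {
            "well": a.well,
            "sample_id": a.sample_id,
            "role": a.role,
            "species": a.species,
            "moi": a.moi,
            "replicate": a.replicate,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table(features, path: str | Path) -> None:
    """Write extracted feature vectors to CSV (one row per sample).

    ``features`` is a list of :class:`gcscreen.gc7.GC7Features` or anything
    exposing ``sample_id`` and ``as_dict()``. Round-trips losslessly to 1e-9.
    """
    features = list(features)
    if not features:
        raise ValueError("no features to write")
    rows = []
    for f in features:
        row = {"sample_id": f.sample_id}
        row.update(f.as_dict())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame indexed by sample id."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise PlateParseError(f"{path}: missing sample_id column")
    return df.set_index("sample_id")


def write_labels(sample_ids: Iterable[str], labels: Iterable[int], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "cluster": list(labels)}).to_csv(
        path, index=False
    )
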