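"""Delimited-text file formats.

Everything is plain comma-separated text with a header row so artifacts are
diffable: long-format events and demographics with ISO-8601 dates (empty
field = absent death date), wide patient x variable matrices with empty
cells for missing values, and 0/1 masks.  Files the package writes
round-trip byte-identically through read + write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import LabMatrix

EPOCH = pd.Timestamp("1970-01-01")


def _days_to_iso(days: pd.Series) -> pd.Series:
    out = pd.Series("", index=days.index, dtype=object)
    present = days.notna()
    out[present] = (
        EPOCH + pd.to_timedelta(days[present].astype(np.int64), unit="D")
    ).dt.strftime("%Y-%m-%d")
    return out


def _iso_to_days(text: pd.Series, path: str, column: str,
                 allow_empty: bool = False) -> pd.Series:
    text = text.fillna("").astype(str)
    empty = text == ""
    if empty.any() and not allow_empty:
        line = int(np.nonzero(empty.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}:{line}: empty {column!r} date")
    parsed = pd.to_datetime(text.where(~empty), format="%Y-%m-%d",
                            errors="coerce")
    bad = parsed.isna() & ~empty
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}:{line}: malformed date {text[bad].iloc[0]!r} "
            f"in column {column!r}"
        )
    days = (parsed - EPOCH).dt.days
    return days


def _check_columns(frame: pd.DataFrame, expected: list[str], path: str):
    unknown = [c for c in frame.columns if c not in expected]
    missing = [c for c in expected if c not in frame.columns]
    if unknown or missing:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(frame.columns)}"
        )


def _check_numeric(text: pd.Series, path: str, column: str) -> pd.Series:
    values = pd.to_numeric(text, errors="coerce")
    bad = values.isna() & text.notna() & (text.astype(str) != "")
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}:{line}: non-numeric value {text[bad].iloc[0]!r} "
            f"in column {column!r}"
        )
    return values


def write_long_events(events: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": events["patient_id"],
            "loinc": events["loinc"],
            "date": _days_to_iso(events["date"]),
            "value": events["value"],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_long_events(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"loinc": str},
                        float_precision="round_trip")
    _check_columns(frame, ["patient_id", "loinc", "date", "value"], str(path))
    frame["date"] = _iso_to_days(frame["date"].astype(str), str(path),
                                 "date").astype(np.int64)
    frame["value"] = _check_numeric(frame["value"], str(path), "value")
    return frame


def write_demographics(demographics: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "patient_id": demographics["patient_id"],
            "sex": demographics["sex"],
            "birth_date": _days_to_iso(demographics["birth_date"]),
            "death_date": _days_to_iso(demographics["death_date"]),
            "bmi": demographics["bmi"],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_demographics(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    _check_columns(
        frame, ["patient_id", "sex", "birth_date", "death_date", "bmi"],
        str(path),
    )
    frame["birth_date"] = _iso_to_days(
        frame["birth_date"].astype(str), str(path), "birth_date"
    ).astype(np.int64)
    frame["death_date"] = _iso_to_days(
        frame["death_date"], str(path), "death_date", allow_empty=True
    ).astype(float)
    frame["bmi"] = _check_numeric(frame["bmi"], str(path), "bmi")
    return frame


def write_wide_matrix(matrix: LabMatrix | pd.DataFrame, path) -> None:
    values = matrix.values if isinstance(matrix, LabMatrix) else matrix
    values = values.copy()
    values.index.name = "patient_id"
    values.to_csv(path, lineterminator="\n")


def read_wide_matrix(path) -> LabMatrix:
    frame = pd.read_csv(path, dtype=str)
    if frame.columns[0] != "patient_id":
        raise ValueError(f"{path}: first column must be 'patient_id'")
    dupes = frame["patient_id"].duplicated()
    if dupes.any():
        line = int(np.nonzero(dupes.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}:{line}: duplicate patient_id "
            f"{frame.loc[dupes, 'patient_id'].iloc[0]!r}"
        )
    try:
        ids = pd.to_numeric(frame["patient_id"])
    except (ValueError, TypeError):
        ids = frame["patient_id"]
    values = frame.drop(columns=["patient_id"])
    for col in values.columns:
        values[col] = _check_numeric(values[col], str(path), col)
    values.index = pd.Index(ids, name="patient_id")
    return LabMatrix(values.astype(float))


def write_mask(mask: pd.DataFrame, path) -> None:
    out = mask.astype(int).copy()
    out.index.name = "patient_id"
    out.to_csv(path, lineterminator="\n")


def read_mask(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="patient_id")
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: mask cells must be 0 or 1")
    return frame.astype(bool)


def write_transforms(transforms: dict, path) -> None:
    rows = [
        {"variable": name, "lam": p.lam, "shift": p.shift, "mean": p.mean,
         "sd": p.sd}
        for name, p in transforms.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


def read_transforms(path) -> dict:
    from .preprocess import TransformParams

    frame = pd.read_csv(path, dtype={"variable": str})
    return {
        row["variable"]: TransformParams(
            lam=row["lam"], shift=row["shift"], mean=row["mean"],
            sd=row["sd"],
        )
        for _, row in frame.iterrows()
    }


def write_panel_map(panel_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"loinc": list(panel_map), "panel_id": list(panel_map.values())}
    ).to_csv(path, index=False, lineterminator="\n")


def read_panel_map(path) -> dict[str, str]:
    frame = pd.read_csv(path, dtype=str)
    _check_columns(frame, ["loinc", "panel_id"], str(path))
    return dict(zip(frame["loinc"], frame["panel_id"]))
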