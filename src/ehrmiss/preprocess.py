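"""Long-format lab events -> one transformed value per patient per variable.

The pipeline applies, in order: demographic/temporal filtering (adult ages,
exclusion of the year preceding death, minimum variable prevalence), a
per-patient five-year observation window around the patient's median lab
date with median aggregation per variable, and per-variable Box-Cox plus
Z-standardization so that all downstream methods see roughly Gaussian,
unit-scale columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats, optimize, special

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
#: events farther than this from the patient's median date are discarded
WINDOW_DAYS = 1826  # 5 years
#: events in the final year of life are discarded
DEATH_WINDOW_DAYS = 365

MIN_AGE_YEARS = 18.0
MAX_AGE_YEARS = 90.0


@dataclass(frozen=True)
class TransformParams:
    """Per-variable Box-Cox + Z transform, stored for exact inversion.

    ``y = boxcox(x + shift, lambda)``, ``z = (y - mean) / sd``.
    """

    lam: float
    shift: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def apply(self, x: np.ndarray) -> np.ndarray:
        y = stats.boxcox(np.asarray(x, dtype=float) + self.shift,
                         lmbda=self.lam)
        return (y - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        y = np.asarray(z, dtype=float) * self.sd + self.mean
        return special.inv_boxcox(y, self.lam) - self.shift


@dataclass
class LabMatrix:
    """Patient x variable matrix with explicit missing cells.

    ``values`` is a float frame indexed by patient_id with one column per
    variable (NaN = missing).  ``panel_map`` carries per-column panel
    membership, ``transforms`` the Box-Cox/Z parameters when the matrix is on
    the transformed scale.
    """

    values: pd.DataFrame
    panel_map: dict[str, str] | None = None
    transforms: dict[str, TransformParams] | None = None

    def __post_init__(self) -> None:
        if np.isinf(self.values.to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValueError("matrix contains infinite values")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate patient_id rows")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is observed."""
        return self.values.notna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "LabMatrix":
        return LabMatrix(
            self.values.copy(),
            dict(self.panel_map) if self.panel_map else None,
            dict(self.transforms) if self.transforms else None,
        )


def filter_records(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    min_prevalence: float = 0.005,
) -> pd.DataFrame:
    """Apply the record-level inclusion rules.

    Keeps events dated between the patient's 18th and 90th birthdays, drops
    events in the 365 days preceding (or any time after) a recorded death
    date, and drops variables observed in fewer than ``min_prevalence`` of
    all patients.  Ages are computed in exact days / 365.25.
    """
    demo = demographics.set_index("patient_id")
    unknown = ~events["patient_id"].isin(demo.index)
    if unknown.any():
        missing_id = events.loc[unknown, "patient_id"].iloc[0]
        raise KeyError(
            f"event references patient {missing_id!r} absent from demographics"
        )
    birth = demo["birth_date"].reindex(events["patient_id"]).to_numpy()
    death = demo["death_date"].reindex(events["patient_id"]).to_numpy()
    age = (events["date"].to_numpy() - birth) / DAYS_PER_YEAR
    keep = (age >= MIN_AGE_YEARS) & (age <= MAX_AGE_YEARS)
    near_death = ~np.isnan(death) & (
        events["date"].to_numpy() > death - DEATH_WINDOW_DAYS
    )
    keep &= ~near_death
    out = events.loc[keep]

    n_patients = demo.index.nunique()
    if n_patients and min_prevalence > 0:
        prevalence = (
            out.drop_duplicates(["patient_id", "loinc"])
            .groupby("loinc", sort=False)["patient_id"]
            .size()
            / n_patients
        )
        rare = prevalence.index[prevalence < min_prevalence]
        if len(rare):
            logger.info("dropping %d low-prevalence variables", len(rare))
            out = out.loc[~out["loinc"].isin(set(rare))]
    return out.reset_index(drop=True)


def window_and_aggregate(
    events: pd.DataFrame, panel_map: dict[str, str] | None = None
) -> LabMatrix:
    """Collapse longitudinal events to one value per (patient, variable).

    For each patient the median event date defines a window of +/- 5 years
    (1,826 days); events outside it are discarded, and the cell value is the
    median of the surviving results for that variable (midpoint convention
    for even counts).  Pairs with no surviving event are missing.
    """
    if not len(events):
        return LabMatrix(pd.DataFrame(dtype=float), panel_map=panel_map)
    med = events.groupby("patient_id")["date"].transform("median")
    inside = (events["date"] - med).abs() <= WINDOW_DAYS
    surviving = events.loc[inside]
    dropped_patients = set(events["patient_id"]) - set(surviving["patient_id"])
    if dropped_patients:
        logger.warning(
            "%d patients lost all events to the observation window",
            len(dropped_patients),
        )
    wide = surviving.pivot_table(
        index="patient_id", columns="loinc", values="value", aggfunc="median"
    )
    wide.columns.name = None
    return LabMatrix(wide.astype(float), panel_map=panel_map)


def _boxcox_lambda(x: np.ndarray, bounds: tuple[float, float] = (-3.0, 3.0),
                   tol: float = 1e-4) -> float:
    """Profile-maximum-likelihood Box-Cox exponent on a bounded interval."""
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, x),
        bounds=bounds,
        method="bounded",
        options={"xatol": tol},
    )
    return float(res.x)


def boxcox_z(matrix: LabMatrix) -> tuple[LabMatrix, dict[str, TransformParams]]:
    """Box-Cox + Z-transform every variable on its observed cells.

    Each column is shifted to strictly positive support if needed
    (``1e-6 - min`` when the minimum is <= 0), its Box-Cox exponent chosen by
    profile maximum likelihood over [-3, 3], then standardized to mean 0 /
    sd 1 on the observed cells.  Parameters are returned per variable (and
    attached to the result) so the transform is exactly invertible.
    """
    transformed = matrix.values.copy()
    params: dict[str, TransformParams] = {}
    for col in matrix.values.columns:
        obs = matrix.values[col].dropna().to_numpy(dtype=float)
        if len(obs) < 2 or np.unique(obs).size < 2:
            raise ValueError(
                f"variable {col!r} is constant (sd = 0); cannot standardize"
            )
        shift = 0.0 if obs.min() > 0 else 1e-6 - float(obs.min())
        lam = _boxcox_lambda(obs + shift)
        y = stats.boxcox(obs + shift, lmbda=lam)
        mean = float(y.mean())
        sd = float(y.std(ddof=1))
        p = TransformParams(lam=lam, shift=shift, mean=mean, sd=sd)
        params[col] = p
        observed_idx = matrix.values[col].notna()
        transformed.loc[observed_idx, col] = (y - mean) / sd
    return (
        LabMatrix(transformed, panel_map=matrix.panel_map, transforms=params),
        params,
    )


def invert_boxcox_z(matrix: LabMatrix) -> LabMatrix:
    """Map a transformed matrix back to the original measurement scales."""
    if not matrix.transforms:
        raise ValueError("matrix carries no transform parameters")
    out = matrix.values.copy()
    for col, p in matrix.transforms.items():
        observed_idx = out[col].notna()
        out.loc[observed_idx, col] = p.invert(
            out.loc[observed_idx, col].to_numpy(dtype=float)
        )
    return LabMatrix(out, panel_map=matrix.panel_map)
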