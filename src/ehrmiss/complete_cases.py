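"""Complete-case extraction and representative covariate matching.

Benchmarking imputation requires known values, i.e. a complete-case subset;
but complete cases are demographically unlike the full population (they are
the heavily-tested patients).  The matching step corrects this: sample
patients from the population and pair each with the most similar complete
case — identical sex, minimal Euclidean distance on Z-scored age and BMI —
so the benchmark set inherits the population's covariate distribution.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import DAYS_PER_YEAR, LabMatrix

logger = logging.getLogger(__name__)


def extract_complete_cases(
    matrix: LabMatrix, variables: Sequence[str] | None = None
) -> LabMatrix:
    """Rows with no missing cell among ``variables``, restricted to them.

    ``variables=None`` means all columns; an empty sequence keeps every row
    (completeness over an empty set is vacuous).
    """
    cols = list(matrix.values.columns if variables is None else variables)
    unknown = set(cols) - set(matrix.values.columns)
    if unknown:
        raise KeyError(f"variables not in matrix: {sorted(unknown)}")
    sub = matrix.values[cols]
    keep = sub.notna().all(axis=1)
    if not keep.any():
        logger.warning("no complete cases for the %d requested variables",
                       len(cols))
    panel_map = (
        {c: matrix.panel_map[c] for c in cols if c in matrix.panel_map}
        if matrix.panel_map
        else None
    )
    return LabMatrix(sub.loc[keep].copy(), panel_map=panel_map)


def add_age(demographics: pd.DataFrame, ref_date: int) -> pd.DataFrame:
    """Attach an ``age`` column (years at ``ref_date``, exact days/365.25)."""
    out = demographics.copy()
    out["age"] = (ref_date - out["birth_date"]) / DAYS_PER_YEAR
    return out


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (values - mean) / (sd if sd > 0 else 1.0)


def nearest_same_sex(
    queries: pd.DataFrame,
    candidates: pd.DataFrame,
    exclude_self: bool = False,
    chunk: int = 2048,
) -> pd.DataFrame:
    """For each query patient, the same-sex candidate minimizing Euclidean
    distance on standardized (age, bmi).

    Both frames need ``patient_id, sex, age, bmi``.  Age and BMI are Z-scored
    on the *query* population so neither dominates by unit choice.  Ties
    break to the lowest candidate patient_id; with ``exclude_self`` a
    candidate sharing the query's patient_id is skipped.

    Returns a frame ``patient_id, matched_id, distance``.
    """
    for frame, label in ((queries, "queries"), (candidates, "candidates")):
        missing = {"patient_id", "sex", "age", "bmi"} - set(frame.columns)
        if missing:
            raise KeyError(f"{label} lack columns {sorted(missing)}")
    age_m, age_s = queries["age"].mean(), queries["age"].std(ddof=0)
    bmi_m, bmi_s = queries["bmi"].mean(), queries["bmi"].std(ddof=0)

    results = []
    for sex, group in queries.groupby("sex", sort=False):
        cand = candidates.loc[candidates["sex"] == sex]
        cand = cand.sort_values("patient_id")  # argmin tie -> lowest id
        if cand.empty:
            raise ValueError(f"no candidate of sex {sex!r} available")
        cxy = np.column_stack(
            [
                _standardize(cand["age"].to_numpy(float), age_m, age_s),
                _standardize(cand["bmi"].to_numpy(float), bmi_m, bmi_s),
            ]
        )
        cand_ids = cand["patient_id"].to_numpy()
        qxy = np.column_stack(
            [
                _standardize(group["age"].to_numpy(float), age_m, age_s),
                _standardize(group["bmi"].to_numpy(float), bmi_m, bmi_s),
            ]
        )
        q_ids = group["patient_id"].to_numpy()
        for start in range(0, len(group), chunk):
            sl = slice(start, start + chunk)
            d2 = (
                ((qxy[sl, None, :] - cxy[None, :, :]) ** 2).sum(axis=2)
            )
            if exclude_self:
                self_mask = q_ids[sl, None] == cand_ids[None, :]
                d2 = np.where(self_mask, np.inf, d2)
            best = np.argmin(d2, axis=1)
            dist = np.sqrt(d2[np.arange(len(best)), best])
            if np.isinf(dist).any():
                bad = q_ids[sl][np.isinf(dist)][0]
                raise ValueError(
                    f"no eligible candidate for patient {bad!r}"
                )
            results.append(
                pd.DataFrame(
                    {
                        "patient_id": q_ids[sl],
                        "matched_id": cand_ids[best],
                        "distance": dist,
                    }
                )
            )
    out = pd.concat(results, ignore_index=True)
    return out.set_index("patient_id").loc[queries["patient_id"]].reset_index()


def match_representative_sample(
    population: pd.DataFrame,
    complete_cases: pd.DataFrame,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``n`` population patients (without replacement) and match each
    to its nearest same-sex complete case on standardized age/BMI.

    Complete cases may serve as the match for any number of sampled patients
    (matching with replacement).  Returns ``patient_id`` (sampled),
    ``matched_id`` (complete case), ``distance``.
    """
    if n > len(population):
        raise ValueError(
            f"cannot sample {n} of {len(population)} patients without "
            "replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(population), size=n, replace=False)
    sample = population.iloc[np.sort(idx)]
    return nearest_same_sex(sample, complete_cases)
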