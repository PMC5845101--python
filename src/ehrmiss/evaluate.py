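"""Scoring imputations against withheld truth.

Accuracy is root mean square error (RMSE) at the amputed cells only,
overall or per variable.  Calibration of *multiple* imputation compares,
per variable, the error-to-truth (x: mean RMSE of each completed copy
against the truth) with the between-imputation error (y: mean pairwise RMSE
between copies).  A well-calibrated stochastic method puts points near the
unity line y = x; a deterministic method has y = 0 identically.  The mean
deviation from unity, MD = mean over variables of (x - y), summarizes this:
MD near 0 indicates the spread between imputations matches the actual
uncertainty, large positive MD indicates under-dispersion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ampute import MaskedDataset
from .impute import DETERMINISTIC_METHODS, CompletedSet, ImputationConfig, impute

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Scores for one (masked dataset, method) combination."""

    per_variable_rmse: pd.Series
    overall_rmse: float
    calibration: pd.DataFrame | None = None  # columns: variable, x, y
    md: float | None = None
    metadata: dict = field(default_factory=dict)


def _masked_diff(a: pd.DataFrame, b: pd.DataFrame,
                 mask: pd.DataFrame) -> np.ndarray:
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("matrix and mask shapes must agree")
    d = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    return np.where(mask.to_numpy(), d, np.nan)


def rmse(
    completed: pd.DataFrame,
    truth: pd.DataFrame,
    mask: pd.DataFrame,
    scope: str = "overall",
):
    """RMSE over masked cells only.

    ``scope="overall"`` returns a float (error if the mask is empty);
    ``scope="per-variable"`` returns a Series with NaN for variables whose
    mask is empty (undefined, not zero).
    """
    d = _masked_diff(completed, truth, mask)
    if scope == "overall":
        if not mask.to_numpy().any():
            raise ValueError("mask is empty; overall RMSE undefined")
        return float(np.sqrt(np.nanmean(d**2)))
    if scope == "per-variable":
        m = mask.to_numpy()
        sq = np.where(m, np.nan_to_num(d) ** 2, 0.0)
        counts = m.sum(axis=0)
        col_mse = np.divide(
            sq.sum(axis=0), counts,
            out=np.full(m.shape[1], np.nan), where=counts > 0,
        )
        return pd.Series(np.sqrt(col_mse), index=truth.columns)
    raise ValueError(f"unknown scope {scope!r}")


def mi_calibration(
    completed: CompletedSet | list[pd.DataFrame],
    truth: pd.DataFrame,
    mask: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-variable calibration points and the mean deviation from unity.

    x = mean over copies of RMSE(copy, truth); y = mean over copy pairs of
    RMSE(copy_i, copy_j); both restricted to masked cells.  MD is the mean
    of (x - y) over variables with a nonempty mask.  Requires m >= 2.
    """
    if isinstance(completed, CompletedSet):
        copies = completed.copies
        mask = completed.mask if mask is None else mask
    else:
        copies = completed
    if mask is None:
        raise ValueError("mask is required when passing bare copies")
    if len(copies) < 2:
        raise ValueError("multiple-imputation calibration requires m >= 2")
    x = pd.concat(
        [rmse(c, truth, mask, scope="per-variable") for c in copies], axis=1
    ).mean(axis=1)
    pair_rmses = [
        rmse(a, b, mask, scope="per-variable")
        for a, b in itertools.combinations(copies, 2)
    ]
    y = pd.concat(pair_rmses, axis=1).mean(axis=1)
    table = pd.DataFrame({"variable": truth.columns, "x": x.to_numpy(),
                          "y": y.to_numpy()})
    md = float((x - y).mean(skipna=True))
    return table, md


def evaluate(
    completed: CompletedSet, truth: pd.DataFrame,
    mask: pd.DataFrame | None = None,
) -> EvalReport:
    """Full report for one completed set: per-variable and overall RMSE
    (averaged over copies) plus calibration when m >= 2."""
    mask = completed.mask if mask is None else mask
    per_var = pd.concat(
        [rmse(c, truth, mask, scope="per-variable") for c in completed.copies],
        axis=1,
    ).mean(axis=1)
    overall = float(
        np.mean([rmse(c, truth, mask) for c in completed.copies])
    )
    calibration = None
    md = None
    if completed.m >= 2:
        calibration, md = mi_calibration(completed, truth, mask)
    return EvalReport(
        per_variable_rmse=per_var,
        overall_rmse=overall,
        calibration=calibration,
        md=md,
        metadata={
            "method": completed.config.method,
            "m": completed.m,
            "md_definition": "mean over variables of (error-to-truth minus "
                             "between-imputation error) at masked cells",
            "deterministic": completed.config.method
            in DETERMINISTIC_METHODS,
        },
    )


def benchmark(
    datasets: list[MaskedDataset],
    configs: list[ImputationConfig],
    seed: int = 0,
    per_variable: bool = False,
) -> pd.DataFrame:
    """Impute and score every dataset with every method.

    Returns a tidy frame with one aggregate row per dataset x method
    (``variable == "__all__"``) and, when ``per_variable``, one row per
    variable.  A method failing on a dataset is recorded with
    ``status="failed"`` and the run continues.
    """
    rows = []
    for i, ds in enumerate(datasets):
        for config in configs:
            base = {
                "dataset": i,
                "mechanism": ds.spec.mechanism,
                "spec": ds.spec.label(),
                "missing_fraction": ds.missing_fraction,
                "method": config.method,
            }
            try:
                run_config = ImputationConfig(
                    **{**config.__dict__, "seed": seed + config.seed}
                )
                completed = impute(ds, run_config)
                report = evaluate(completed, ds.truth)
            except Exception as exc:  # isolate per-cell failures
                logger.warning("method %s failed on dataset %d: %s",
                               config.method, i, exc)
                rows.append({**base, "variable": "__all__", "rmse": np.nan,
                             "x": np.nan, "y": np.nan, "md": np.nan,
                             "status": "failed", "error": str(exc)})
                continue
            rows.append({
                **base, "variable": "__all__", "rmse": report.overall_rmse,
                "x": np.nan, "y": np.nan, "md": report.md, "status": "ok",
                "error": "",
            })
            if per_variable:
                cal = (
                    report.calibration.set_index("variable")
                    if report.calibration is not None
                    else None
                )
                for var, value in report.per_variable_rmse.items():
                    rows.append({
                        **base, "variable": var, "rmse": value,
                        "x": cal.loc[var, "x"] if cal is not None else np.nan,
                        "y": cal.loc[var, "y"] if cal is not None else np.nan,
                        "md": np.nan, "status": "ok", "error": "",
                    })
    return pd.DataFrame(rows)
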